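"""Preprocessing and diversity statistics against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from rhizoecol import (
    CommunityTable,
    bf_ratio,
    bray_curtis_matrix,
    chao1,
    chao1_per_sample,
    css_normalize,
    decompose_beta,
    distance_decay_fit,
    mantel_test,
    rarefy,
    simulate_distance_decay_communities,
)
from rhizoecol.diversity import haversine_km
from rhizoecol.errors import (
    DegeneratePredictorError,
    EmptyResultError,
    LabelMismatchError,
    UndefinedRatioError,
)


def one_sample(vector):
    return CommunityTable(pd.DataFrame([vector], index=["S0"]))


class TestRarefy:
    def test_depth_equal_total_is_identity(self):
        t = rarefy(one_sample([10, 0, 5]), depth=15, seed=0)
        assert t.counts.iloc[0].tolist() == [10, 0, 5]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sums_and_zeros(self, seed):
        t = rarefy(one_sample([10, 0, 5]), depth=5, seed=seed)
        row = t.counts.iloc[0]
        assert row.sum() == 5
        assert row.iloc[1] == 0
        assert (row <= [10, 0, 5]).all()

    def test_hypergeometric_split(self):
        # two equal pools of 1e6: each retained count ~ Hypergeom, sd ≈ 15.8
        t = rarefy(one_sample([1_000_000, 1_000_000]), depth=1000, seed=3)
        assert abs(t.counts.iloc[0, 0] - 500) < 3 * 15.82

    def test_drops_shallow_samples(self):
        table = CommunityTable(pd.DataFrame([[50, 50], [2, 1]], index=["A", "B"]))
        out = rarefy(table, depth=10, seed=0)
        assert out.sample_ids == ["A"]
        with pytest.raises(EmptyResultError):
            rarefy(table, depth=1000, seed=0)


class TestCSS:
    def test_scale_invariance(self):
        table = CommunityTable(pd.DataFrame([[1, 2, 3, 4], [10, 20, 30, 40]]))
        out = css_normalize(table)
        assert np.allclose(out.counts.iloc[0], out.counts.iloc[1])

    def test_hand_computed_scale_factor(self):
        # nonzero counts {1,2,3,4}, median 2.5 -> s = 1 + 2 = 3
        out = css_normalize(one_sample([1, 2, 3, 4]), quantile=0.5)
        assert np.allclose(out.counts.iloc[0], [1000 / 3, 2000 / 3, 1000, 4000 / 3])

    def test_quantile_one_is_relative_abundance(self):
        out = css_normalize(one_sample([2, 3, 5]), quantile=1.0)
        assert np.allclose(out.counts.iloc[0], [200, 300, 500])


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([10, 10], 2.0),
            ([5, 3, 1, 1], 5.0),  # 4 + 2*1/(2*1)
            ([1, 1, 2, 2], 4 + 2 * 1 / (2 * 3)),
            ([0, 0, 0], 0.0),
        ],
    )
    def test_hand_cases(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=40))
    def test_never_below_observed_richness(self, counts):
        assert chao1(counts) >= (np.asarray(counts) > 0).sum()


class TestBFRatio:
    def test_elementwise_ratio(self):
        b = pd.Series([100.0, 60.0], index=["S0", "S1"])
        f = pd.Series([50.0, 60.0], index=["S0", "S1"])
        assert bf_ratio(b, f).tolist() == [2.0, 1.0]

    def test_zero_fungal_richness(self):
        with pytest.raises(UndefinedRatioError):
            bf_ratio(pd.Series([1.0]), pd.Series([0.0]))

    def test_bacteria_rich_fixture_exceeds_one(self, sparse_table):
        from tests.conftest import make_sparse_table

        fungi = make_sparse_table(n_samples=8, n_taxa=6, seed=1)
        ratio = bf_ratio(chao1_per_sample(sparse_table), chao1_per_sample(fungi))
        assert (ratio > 1).all()


class TestBrayCurtis:
    def test_hand_case_and_extremes(self):
        table = CommunityTable(
            pd.DataFrame([[2, 1, 0], [0, 1, 3], [2, 1, 0], [0, 0, 7]],
                         index=list("ABCD"))
        )
        dm = bray_curtis_matrix(table)
        assert dm["A", "B"] == pytest.approx(5 / 7)
        assert dm["A", "C"] == 0.0
        assert dm["A", "D"] == 1.0  # disjoint
        assert (dm.data >= 0).all() and (dm.data <= 1).all()


class TestBetaDecomposition:
    def test_hand_case(self):
        # a=2 shared, b=1, c=3 -> D=0.5, Repl=0.25, RichDiff=0.25
        table = CommunityTable(
            pd.DataFrame([[1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 1, 1]], index=["X", "Y"])
        )
        d = decompose_beta(table).pairs.iloc[0]
        assert (d.D, d.replacement, d.richness_difference) == (0.5, 0.25, 0.25)

    def test_identical_and_nested(self):
        table = CommunityTable(
            pd.DataFrame([[1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 0, 0]], index=list("PQR"))
        )
        pairs = decompose_beta(table).pairs.set_index(["sample_i", "sample_j"])
        assert pairs.loc[("P", "Q")].tolist() == [0.0, 0.0, 0.0]
        assert pairs.loc[("P", "R"), "replacement"] == 0.0  # strict nesting

    def test_podani_identity_random_pairs(self):
        rng = np.random.default_rng(0)
        table = CommunityTable(pd.DataFrame(rng.integers(0, 3, (50, 40))))
        pairs = decompose_beta(table).pairs
        assert np.abs(pairs.replacement + pairs.richness_difference - pairs.D).max() < 1e-12


class TestDistanceDecay:
    def _coords(self, n):
        return pd.DataFrame(
            {"longitude": np.linspace(0, 5, n), "latitude": np.zeros(n)},
            index=[f"S{i}" for i in range(n)],
        )

    def test_exact_linear_similarity(self):
        coords = self._coords(6)
        geo = haversine_km(coords.to_numpy(dtype=float))
        sim = 1 - 0.001 * geo
        dm = DistanceMatrix(1 - sim, ids=list(coords.index))
        fit = distance_decay_fit(dm, coords, permutations=99, seed=0)
        assert fit["slope"] == pytest.approx(-0.001, rel=1e-9)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_identical_communities_flat(self):
        dm = DistanceMatrix(np.zeros((5, 5)), ids=[f"S{i}" for i in range(5)])
        fit = distance_decay_fit(dm, self._coords(5), permutations=99, seed=0)
        assert fit["slope"] == 0.0
        assert fit["r_squared"] == 0.0

    def test_degenerate_coordinates(self):
        coords = self._coords(4) * 0
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list(coords.index))
        with pytest.raises(DegeneratePredictorError):
            distance_decay_fit(dm, coords, permutations=99, seed=0)

    def test_spatial_simulation_gives_decay(self):
        # communities with spatially drifting immigration sources lose
        # similarity with distance: slope negative in nearly all runs
        negatives = 0
        for rep in range(20):
            table = simulate_distance_decay_communities(
                n_sites=12, n_taxa=40, depth=800, seed=rep
            )
            dm = bray_curtis_matrix(table)
            fit = distance_decay_fit(dm, table.coordinates, permutations=99, seed=rep)
            negatives += fit["slope"] < 0
        assert negatives >= 18


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 6))
        d = np.triu(x, 1)
        d = d + d.T
        dm = DistanceMatrix(d, ids=[f"S{i}" for i in range(6)])
        res = mantel_test(dm, dm, permutations=99, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 100)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = np.triu(rng.random((7, 7)), 1)
        d = x + x.T
        ids = [f"S{i}" for i in range(7)]
        dm1 = DistanceMatrix(d, ids=ids)
        dm2 = DistanceMatrix(2 * d, ids=ids)
        assert mantel_test(dm1, dm2, permutations=99, seed=0)["r"] == pytest.approx(1.0)

    def test_label_mismatch(self):
        dm1 = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["A", "B"])
        dm2 = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["A", "C"])
        with pytest.raises(LabelMismatchError):
            mantel_test(dm1, dm2)

    def test_null_calibration(self):
        # independent random matrices: weak r, rarely significant
        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            ids = [f"S{i}" for i in range(30)]
            mats = []
            for _ in range(2):
                x = np.triu(rng.random((30, 30)), 1)
                mats.append(DistanceMatrix(x + x.T, ids=ids))
            res = mantel_test(mats[0], mats[1], permutations=99, seed=rep)
            ok += (abs(res["r"]) < 0.3) and (res["p"] > 0.05)
        assert ok >= 18
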