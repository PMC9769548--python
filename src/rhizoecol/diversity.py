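"""Preprocessing, alpha/beta diversity, beta decomposition, and spatial tests.

Covers the standard amplicon workflow steps: rarefaction to even depth,
cumulative-sum scaling (CSS) normalization, Chao1 richness, the
bacteria/fungi richness equilibrium ratio, Bray-Curtis dissimilarity,
Podani-family decomposition of Sørensen dissimilarity into replacement
and richness-difference components, distance-decay regression, and the
Mantel test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import CommunityTable
from .errors import (
    DegeneratePredictorError,
    EmptyResultError,
    InvalidArgumentError,
    InvalidInputError,
    LabelMismatchError,
    UndefinedPairError,
    UndefinedRatioError,
)

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning
    (multivariate hypergeometric subsampling; zeros are preserved and no
    count can increase).
    """
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    counts = table.counts.round().astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        log.warning("rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise EmptyResultError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    sub = counts.loc[keep]
    out = np.vstack(
        [rng.multivariate_hypergeometric(row, depth) for row in sub.to_numpy()]
    )
    rarefied = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    result = table.select_samples(keep)
    result.counts = rarefied
    return result


def css_normalize(table: CommunityTable, quantile: float = 0.5) -> CommunityTable:
    """Cumulative-sum scaling: divide each sample by its partial sum.

    The scale factor of sample *j* is the sum of counts less than or
    equal to the ``quantile``-th quantile of its nonzero counts; values
    are rescaled by 1000.
    """
    if not 0 < quantile <= 1:
        raise InvalidArgumentError("quantile must be in (0, 1]")
    values = table.values()
    norm = np.empty_like(values)
    for j, row in enumerate(values):
        nz = row[row > 0]
        if nz.size == 0:
            raise InvalidInputError(f"sample {table.sample_ids[j]} is all zero")
        q = np.quantile(nz, quantile)
        s = row[row <= q].sum()
        norm[j] = row / s * 1000.0
    result = table.select_samples(table.sample_ids)
    result.counts = pd.DataFrame(norm, index=table.counts.index, columns=table.counts.columns)
    return result


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    v = np.asarray(counts)
    if (v < 0).any():
        raise InvalidInputError("counts must be non-negative")
    s_obs = int((v > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def chao1_per_sample(table: CommunityTable) -> pd.Series:
    return pd.Series(
        [chao1(row) for row in table.values()], index=table.counts.index, name="chao1"
    )


def bf_ratio(alpha_bacteria: pd.Series, alpha_fungi: pd.Series) -> pd.Series:
    """Bacteria/fungi alpha-diversity equilibrium ratio per paired sample."""
    b = pd.Series(alpha_bacteria)
    f = pd.Series(alpha_fungi)
    if list(b.index) != list(f.index):
        f = f.reindex(b.index)
        if f.isna().any():
            raise LabelMismatchError("bacterial and fungal vectors must share sample ids")
    zero = f.index[f == 0]
    if len(zero):
        raise UndefinedRatioError(f"zero fungal richness for samples: {list(zero)}")
    return (b / f).rename("bf_ratio")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity over samples: sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise InvalidInputError("need at least 2 samples")
    values = table.values()
    totals = values.sum(axis=1)
    if (totals == 0).sum() >= 2:
        raise UndefinedPairError("Bray-Curtis undefined for a pair of all-zero samples")
    d = squareform(pdist(values, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class BetaDecomposition:
    """Podani-family decomposition of Sørensen dissimilarity."""

    pairs: pd.DataFrame  # sample_i, sample_j, D, replacement, richness_difference
    contributions: pd.DataFrame  # per compartment: mean % of D from Repl and RichDiff


def decompose_beta(table: CommunityTable) -> BetaDecomposition:
    """Split presence/absence Sørensen dissimilarity into replacement + richness difference.

    With ``a`` shared taxa and ``b``, ``c`` unique to each sample:
    ``D = (b+c)/(2a+b+c)``, ``Repl = 2 min(b,c)/(2a+b+c)``,
    ``RichDiff = |b-c|/(2a+b+c)``; ``Repl + RichDiff == D`` exactly.
    Mean percentage contributions of each component to D are reported per
    compartment (pairs pooled within compartment).
    """
    pa = (table.values() > 0)
    ids = table.sample_ids
    comp = table.compartment
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a = int((pa[i] & pa[j]).sum())
            b = int((pa[i] & ~pa[j]).sum())
            c = int((~pa[i] & pa[j]).sum())
            denom = 2 * a + b + c
            if denom == 0:
                raise UndefinedPairError(f"pair ({ids[i]}, {ids[j]}) shares no taxa and has none")
            d = (b + c) / denom
            repl = 2 * min(b, c) / denom
            rich = abs(b - c) / denom
            records.append((ids[i], ids[j], comp.iloc[i], comp.iloc[j], d, repl, rich))
    pairs = pd.DataFrame(
        records,
        columns=["sample_i", "sample_j", "comp_i", "comp_j", "D", "replacement",
                 "richness_difference"],
    )
    rows = []
    for label in sorted(set(comp)):
        sub = pairs[(pairs.comp_i == label) & (pairs.comp_j == label)]
        sub = sub[sub.D > 0]
        if len(sub) == 0:
            continue
        rows.append(
            {
                "compartment": label,
                "replacement_pct": float((sub.replacement / sub.D).mean() * 100.0),
                "richness_difference_pct": float(
                    (sub.richness_difference / sub.D).mean() * 100.0
                ),
            }
        )
    contrib = pd.DataFrame(rows)
    return BetaDecomposition(pairs=pairs.drop(columns=["comp_i", "comp_j"]), contributions=contrib)


# ---------------------------------------------------------------------------
# spatial structure
# ---------------------------------------------------------------------------

def haversine_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from (longitude, latitude) degrees."""
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_decay_fit(
    dissimilarity: DistanceMatrix,
    coordinates: pd.DataFrame,
    permutations: int = 999,
    seed: int = 0,
) -> dict:
    """OLS of community similarity (1 - dissimilarity) on geographic distance.

    The p-value is one-tailed toward decay (permuted slope <= observed),
    estimated by a Mantel-style permutation of sample identities with the
    +1/+1 estimator.
    """
    ids = list(dissimilarity.ids)
    if len(ids) < 3:
        raise InvalidInputError("need >= 3 samples with coordinates")
    coords = pd.DataFrame(coordinates).loc[ids].to_numpy(dtype=float)
    geo = haversine_km(coords)
    if np.allclose(geo, 0.0):
        raise DegeneratePredictorError("all coordinates are identical")
    iu = np.triu_indices(len(ids), k=1)
    sim = 1.0 - dissimilarity.data[iu]
    dist = geo[iu]
    slope, intercept, obs_r = _ols(dist, sim)
    rng = np.random.default_rng(seed)
    n = len(ids)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        sim_p = (1.0 - dissimilarity.data[np.ix_(perm, perm)])[iu]
        slope_p, _, _ = _ols(dist, sim_p)
        if slope_p <= slope:
            count += 1
    p = (count + 1) / (permutations + 1)
    return {"slope": slope, "intercept": intercept, "r_squared": obs_r**2, "p": p}


def _ols(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var()
    if vx == 0:
        raise DegeneratePredictorError("constant predictor")
    slope = np.cov(x, y, bias=True)[0, 1] / vx
    intercept = y.mean() - slope * x.mean()
    sy = y.std()
    r = 0.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1])
    return float(slope), float(intercept), r


def mantel_test(
    dm1: DistanceMatrix, dm2: DistanceMatrix, permutations: int = 999, seed: int = 0
) -> dict:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of upper-triangle entries; ``p`` is
    one-tailed (permuted r >= observed) with the +1/+1 estimator.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise LabelMismatchError("distance matrices must share labels in the same order")
    n = len(dm1.ids)
    iu = np.triu_indices(n, k=1)
    x = dm1.data[iu]
    y = dm2.data[iu]
    if x.std() == 0 or y.std() == 0:
        raise DegeneratePredictorError("constant distance matrix")
    obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        y_p = dm2.data[np.ix_(perm, perm)][iu]
        if float(np.corrcoef(x, y_p)[0, 1]) >= obs:
            count += 1
    p = (count + 1) / (permutations + 1)
    return {"r": obs, "p": p}
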