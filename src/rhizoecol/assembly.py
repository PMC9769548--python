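"""Null-model inference of community assembly processes.

Implements the Stegen-style framework: the between-community mean
nearest-taxon distance (βMNTD), its standardized effect size against a
tip-shuffling null (βNTI), the Bray-Curtis-based Raup-Crick index
(RC_Bray), a five-way classification of assembly processes from the two
indices, and the modified stochasticity ratio (MST).

Thresholds: |βNTI| > 2 indicates selection (sign distinguishes
heterogeneous from homogeneous selection), |RC_Bray| > 0.95 among the
remaining pairs indicates dispersal-driven departure from the
stochastic expectation.  Boundary values (exactly 2 or 0.95) fall on
the non-selection / undominated side.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import CommunityTable
from .errors import (
    DegenerateNullError,
    InvalidArgumentError,
    InvalidInputError,
    MissingLeafError,
)


class Process(str, Enum):
    HETEROGENEOUS_SELECTION = "heterogeneous_selection"
    HOMOGENEOUS_SELECTION = "homogeneous_selection"
    DISPERSAL_LIMITATION = "dispersal_limitation"
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    UNDOMINATED = "undominated"


# ---------------------------------------------------------------------------
# beta MNTD / beta NTI
# ---------------------------------------------------------------------------

def _patristic(table: CommunityTable, tree: TreeNode):
    """Patristic distance submatrix over the table's taxa, table order."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise MissingLeafError(missing)
    dm = tree.tip_tip_distances(endpoints=table.taxon_ids)
    order = [dm.index(t) for t in table.taxon_ids]
    return dm.data[np.ix_(order, order)]


def _pair_weights(table: CommunityTable, abundance_weighted: bool):
    """Per-sample present-taxon indices and within-sample weights."""
    values = table.values()
    present, weights = [], []
    for row in values:
        idx = np.flatnonzero(row > 0)
        if idx.size == 0:
            raise InvalidInputError("all-zero sample in beta MNTD input")
        if abundance_weighted:
            w = row[idx] / row[idx].sum()
        else:
            w = np.full(idx.size, 1.0 / idx.size)
        present.append(idx)
        weights.append(w)
    return present, weights


def _bmntd_all_pairs(dist, present, weights):
    n = len(present)
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(k + 1, n):
            sub = dist[np.ix_(present[k], present[m])]
            v = 0.5 * (weights[k] @ sub.min(axis=1) + weights[m] @ sub.min(axis=0))
            out[k, m] = out[m, k] = v
    return out


def beta_mntd(
    table: CommunityTable, tree: TreeNode, abundance_weighted: bool = True
) -> DistanceMatrix:
    """Between-community mean nearest-taxon distance for every sample pair.

    βMNTD(k, m) = 0.5 [ Σ_i f_ik min_j d_ij + Σ_j f_jm min_i d_ij ]
    where f are within-sample relative abundances (uniform if
    ``abundance_weighted`` is false) and d patristic distances.
    """
    dist = _patristic(table, tree)
    present, weights = _pair_weights(table, abundance_weighted)
    return DistanceMatrix(_bmntd_all_pairs(dist, present, weights), ids=table.sample_ids)


def bnti_null(
    table: CommunityTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    on_degenerate: str = "raise",
) -> DistanceMatrix:
    """βNTI: standardized effect size of βMNTD against a tip-shuffling null.

    Each null iteration permutes taxon labels across all tree tips (one
    permutation applied to every sample pair); βNTI = (obs - mean) / sd
    of the null distribution per pair.

    A pair whose null distribution has zero spread (which happens when
    two samples share exactly the same taxon membership, so βMNTD is 0
    under every relabelling) raises :class:`DegenerateNullError` by
    default; with ``on_degenerate="zero"`` such pairs get βNTI = 0
    (observed equals the null expectation exactly).
    """
    if n_null < 99:
        raise InvalidArgumentError("n_null must be >= 99")
    # canonical taxon order: results do not depend on input column order
    table = table.select_taxa(sorted(table.taxon_ids))
    dist = _patristic(table, tree)
    present, weights = _pair_weights(table, abundance_weighted)
    obs = _bmntd_all_pairs(dist, present, weights)
    rng = np.random.default_rng(seed)
    n = table.n_samples
    nulls = np.empty((n_null, n, n))
    for b in range(n_null):
        perm = rng.permutation(dist.shape[0])
        nulls[b] = _bmntd_all_pairs(dist[np.ix_(perm, perm)], present, weights)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=0)
    iu = np.triu_indices(n, k=1)
    if np.any(sd[iu] == 0):
        if on_degenerate != "zero":
            raise DegenerateNullError("null βMNTD has zero spread for at least one pair")
        sd = np.where(sd == 0, np.inf, sd)
    z = np.zeros((n, n))
    z[iu] = (obs[iu] - mean[iu]) / sd[iu]
    z = z + z.T
    return DistanceMatrix(z, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis) and its shared null generator
# ---------------------------------------------------------------------------

def _null_communities(table: CommunityTable, n_null: int, rng):
    """Null communities fixing each sample's richness and total reads.

    Taxa are drawn without replacement with probability proportional to
    occupancy; each drawn taxon receives one individual and the rest of
    the sample's reads are assigned multinomially with probability
    proportional to metacommunity relative abundance (column sums over
    the full analysis set).
    """
    values = table.counts.round().astype(np.int64).to_numpy()
    n_samples, n_taxa = values.shape
    occupancy = (values > 0).sum(axis=0).astype(float)
    abundance = values.sum(axis=0).astype(float)
    if occupancy.sum() == 0:
        raise InvalidInputError("empty table")
    occ_p = occupancy / occupancy.sum()
    nulls = np.zeros((n_samples, n_null, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        richness = int((values[s] > 0).sum())
        total = int(values[s].sum())
        if richness > n_taxa:
            raise InvalidInputError("sample richness exceeds taxon pool")
        for b in range(n_null):
            chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_p)
            counts = np.zeros(n_taxa, dtype=np.int64)
            counts[chosen] = 1
            remaining = total - richness
            if remaining > 0:
                w = abundance[chosen]
                if w.sum() == 0:
                    w = np.ones_like(w)
                counts[chosen] += rng.multinomial(remaining, w / w.sum())
            nulls[s, b] = counts
    return values, nulls


def _bray(x, y):
    denom = (x + y).sum()
    return np.abs(x - y).sum() / denom if denom > 0 else 0.0


def raup_crick_bray(
    table: CommunityTable, n_null: int = 999, seed: int = 0
) -> DistanceMatrix:
    """Bray-Curtis Raup-Crick index in [-1, 1] for every sample pair.

    RC compares the observed Bray-Curtis of a pair with its distribution
    over null community pairs that preserve each sample's richness and
    total abundance; ties count half.  Values near +1 mean the pair is
    more dissimilar than almost all null draws (turnover beyond the
    stochastic expectation), near -1 more similar.
    """
    rng = np.random.default_rng(seed)
    values, nulls = _null_communities(table, n_null, rng)
    n = values.shape[0]
    rc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs = _bray(values[i], values[j])
            null_bc = np.array([_bray(nulls[i, b], nulls[j, b]) for b in range(n_null)])
            less = (null_bc < obs - 1e-12).sum()
            ties = (np.abs(null_bc - obs) <= 1e-12).sum()
            rc_raw = (less + 0.5 * ties) / n_null
            rc[i, j] = rc[j, i] = (rc_raw - 0.5) * 2.0
    return DistanceMatrix(rc, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_processes(bnti: float, rc: float, legend_convention: bool = False) -> Process:
    """Five-way assembly-process classification from (βNTI, RC_Bray).

    Default sign convention: βNTI > +2 → heterogeneous selection (pairs
    more phylogenetically dissimilar than expected, i.e. divergent
    environments), βNTI < -2 → homogeneous selection.
    ``legend_convention=True`` swaps the two selection labels for
    compatibility with sources that print the inequalities the other way
    round.
    """
    if not (np.isfinite(bnti) and np.isfinite(rc)):
        raise InvalidInputError("bnti and rc must be finite")
    if bnti > 2:
        return (
            Process.HOMOGENEOUS_SELECTION if legend_convention else Process.HETEROGENEOUS_SELECTION
        )
    if bnti < -2:
        return (
            Process.HETEROGENEOUS_SELECTION if legend_convention else Process.HOMOGENEOUS_SELECTION
        )
    if rc > 0.95:
        return Process.DISPERSAL_LIMITATION
    if rc < -0.95:
        return Process.HOMOGENIZING_DISPERSAL
    return Process.UNDOMINATED


@dataclass
class AssemblyResult:
    """Per-pair βNTI / RC_Bray / process plus per-table summaries."""

    pairs: pd.DataFrame  # sample_i, sample_j, bnti, rc_bray, process
    process_fractions: dict
    fraction_stochastic: float  # |bnti| < 2
    fraction_deterministic: float  # |bnti| > 2


def assembly_analysis(
    table: CommunityTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    legend_convention: bool = False,
    on_degenerate: str = "raise",
) -> AssemblyResult:
    """βNTI + RC_Bray + process classification for every sample pair."""
    bnti = bnti_null(
        table, tree, n_null=n_null, seed=seed, abundance_weighted=abundance_weighted,
        on_degenerate=on_degenerate,
    )
    rc = raup_crick_bray(table, n_null=n_null, seed=seed + 1)
    ids = table.sample_ids
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = bnti[ids[i], ids[j]]
            r = rc[ids[i], ids[j]]
            proc = classify_processes(b, r, legend_convention=legend_convention)
            records.append((ids[i], ids[j], b, r, proc.value))
    pairs = pd.DataFrame(records, columns=["sample_i", "sample_j", "bnti", "rc_bray", "process"])
    fractions = {p.value: float((pairs.process == p.value).mean()) for p in Process}
    stoch = float((pairs.bnti.abs() < 2).mean())
    deter = float((pairs.bnti.abs() > 2).mean())
    return AssemblyResult(
        pairs=pairs,
        process_fractions=fractions,
        fraction_stochastic=stoch,
        fraction_deterministic=deter,
    )


# ---------------------------------------------------------------------------
# modified stochasticity ratio
# ---------------------------------------------------------------------------

@dataclass
class MSTResult:
    pairs: pd.DataFrame  # sample_i, sample_j, observed, expected, mst
    mean_mst: float


def mst_from_components(delta: float, expected: float, d_max: float = 1.0) -> float:
    """Piecewise MST: 1 at Δ=E, 0 at Δ∈{0, Dmax}; clipped to [0, 1]."""
    if expected >= d_max:
        raise DegenerateNullError("null expectation equals the maximum dissimilarity")
    if delta >= expected:
        v = (d_max - delta) / (d_max - expected)
    else:
        v = delta / expected if expected > 0 else 1.0
    return float(np.clip(v, 0.0, 1.0))


def mst_ratio(
    table: CommunityTable,
    group: list | None = None,
    n_null: int = 999,
    seed: int = 0,
) -> MSTResult:
    """Modified stochasticity ratio per pair within a sample group.

    Observed Bray-Curtis is compared with the mean Bray-Curtis of null
    community pairs from the same richness/abundance-preserving
    generator as the Raup-Crick index; MST near 1 means the observed
    dissimilarity matches the stochastic expectation.
    """
    sub = table if group is None else table.select_samples(group)
    if sub.n_samples < 3:
        raise InvalidInputError("group must have >= 3 samples")
    rng = np.random.default_rng(seed)
    values, nulls = _null_communities(sub, n_null, rng)
    ids = sub.sample_ids
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            obs = _bray(values[i], values[j])
            expected = float(
                np.mean([_bray(nulls[i, b], nulls[j, b]) for b in range(n_null)])
            )
            records.append((ids[i], ids[j], obs, expected, mst_from_components(obs, expected)))
    pairs = pd.DataFrame(records, columns=["sample_i", "sample_j", "observed", "expected", "mst"])
    return MSTResult(pairs=pairs, mean_mst=float(pairs.mst.mean()))
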