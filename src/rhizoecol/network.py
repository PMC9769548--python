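"""Interkingdom co-occurrence networks and stability metrics.

Correlations between taxa are inferred with SparCC, which works on
log-ratio variances to sidestep the compositional artefacts of
proportion data.  Edges pass a hard threshold on |r|; topology-level
stability is summarized by robustness to node removal, natural
connectivity (a spectral measure), vulnerability (largest relative loss
of global efficiency from a single deletion), Guimerà–Amaral Zi/Pi node
roles, and sample-level cohesion (abundance-weighted null-corrected
connectedness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from scipy.special import logsumexp

from .containers import CommunityTable
from .errors import (
    InsufficientTaxaError,
    InvalidArgumentError,
    InvalidInputError,
    UndefinedVulnerabilityError,
)

log = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.6
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _log_ratio_variance(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of log(x_i / x_j)."""
    logx = np.log(fractions)
    cov = np.cov(logx, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(t: np.ndarray, excluded: set) -> np.ndarray:
    """Solve basis variances under the sparsity assumption, honouring exclusions."""
    n = t.shape[0]
    m = np.ones((n, n))
    np.fill_diagonal(m, n - 1)
    t_eff = t.copy()
    for i, j in excluded:
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = t_eff[j, i] = 0.0
    omega = np.linalg.solve(m, t_eff.sum(axis=1))
    omega = np.maximum(omega, 1e-10)
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def _sparcc_single(fractions, exclusion_threshold, max_exclusion_iter):
    t = _log_ratio_variance(fractions)
    n = t.shape[0]
    excluded: set = set()
    rho = _basis_correlations(t, excluded)
    for _ in range(max_exclusion_iter):
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # refuse to over-exclude: keep the system well conditioned
        if len(excluded) >= n * (n - 3) // 2:
            break
        excluded.add((min(i, j), max(i, j)))
        rho = _basis_correlations(t, excluded)
    return rho


def sparcc_correlation(
    table: CommunityTable,
    n_resample: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_iter: int = 10,
    seed: int = 0,
    prevalence: float = 0.25,
) -> pd.DataFrame:
    """SparCC correlation matrix over taxa (median across resamples).

    Counts are first filtered to taxa present in at least ``prevalence``
    of samples, then per resample converted to fractions by a Dirichlet
    posterior draw with pseudocount 1.  Basis variances are solved from
    the log-ratio variance system under the sparsity assumption, with
    iterative exclusion of the strongest correlated pair.
    """
    filtered = table.filter_prevalence(prevalence)
    if filtered.n_taxa < 4:
        raise InsufficientTaxaError("SparCC needs >= 4 taxa after the prevalence filter")
    if filtered.n_samples < 10:
        log.warning("sparcc_correlation: only %d samples", filtered.n_samples)
    counts = filtered.values()
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_resample, filtered.n_taxa, filtered.n_taxa))
    for b in range(n_resample):
        fractions = np.vstack([rng.dirichlet(row + 1.0) for row in counts])
        estimates[b] = _sparcc_single(fractions, exclusion_threshold, max_exclusion_iter)
    rho = np.median(estimates, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=filtered.taxon_ids, columns=filtered.taxon_ids)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    graph: nx.Graph  # node attrs: kingdom; edge attrs: weight, sign
    isolated: list  # taxa passing no edge threshold

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, weight=None)


def build_network(
    corr: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    kingdom: pd.Series | None = None,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into an undirected signed graph.

    An edge is kept iff |r| > ``r_threshold``; nodes left without edges
    are dropped from the graph but reported as ``isolated``.
    """
    if not np.allclose(corr.values, corr.values.T, atol=1e-8):
        raise InvalidInputError("correlation matrix must be symmetric")
    taxa = list(corr.index)
    g = nx.Graph()
    values = corr.values
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = values[i, j]
            if abs(r) > r_threshold:
                g.add_edge(taxa[i], taxa[j], weight=float(r), sign="+" if r > 0 else "-")
    isolated = [t for t in taxa if t not in g]
    for node in g.nodes:
        g.nodes[node]["kingdom"] = (
            str(kingdom.loc[node]) if kingdom is not None else "bacteria"
        )
    return CorrelationNetwork(graph=g, isolated=isolated)


# ---------------------------------------------------------------------------
# modules and node roles
# ---------------------------------------------------------------------------

@dataclass
class NodeRole:
    module: int
    zi: float
    pi: float
    role: str


def node_roles(net: CorrelationNetwork, seed: int = 0) -> pd.DataFrame:
    """Zi/Pi node roles from a greedy-modularity partition.

    zi is the within-module degree z-score, pi the participation
    coefficient ``1 - Σ_m (k_im / k_i)²``.  Roles follow the classical
    cutoffs: module hub (zi > 2.5, pi <= 0.62), connector (zi <= 2.5,
    pi > 0.62), network hub (both exceeded), peripheral otherwise.
    Modules are detected on the unweighted graph; ties in the
    agglomeration are broken deterministically by node id.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        return pd.DataFrame(columns=["module", "zi", "pi", "role"])
    # relabel to sorted order for deterministic tie-breaks
    communities = greedy_modularity_communities(g)
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c[0]))
    module_of = {}
    for mid, members in enumerate(communities):
        for node in members:
            module_of[node] = mid
    records = {}
    for mid, members in enumerate(communities):
        within = np.array(
            [sum(1 for nb in g.neighbors(v) if module_of[nb] == mid) for v in members],
            dtype=float,
        )
        mean, sd = within.mean(), within.std(ddof=0)
        for v, k_own in zip(members, within):
            zi = 0.0 if sd == 0 else (k_own - mean) / sd
            k_total = g.degree(v)
            per_module: dict = {}
            for nb in g.neighbors(v):
                per_module[module_of[nb]] = per_module.get(module_of[nb], 0) + 1
            pi = 1.0 - sum((k / k_total) ** 2 for k in per_module.values())
            if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
                role = "network_hub"
            elif zi > ZI_THRESHOLD:
                role = "module_hub"
            elif pi > PI_THRESHOLD:
                role = "connector"
            else:
                role = "peripheral"
            records[v] = NodeRole(module=mid, zi=float(zi), pi=float(pi), role=role)
    df = pd.DataFrame(
        {
            "module": {v: r.module for v, r in records.items()},
            "zi": {v: r.zi for v, r in records.items()},
            "pi": {v: r.pi for v, r in records.items()},
            "role": {v: r.role for v, r in records.items()},
        }
    )
    return df.loc[sorted(df.index)]


# ---------------------------------------------------------------------------
# robustness to node removal
# ---------------------------------------------------------------------------

def _secondary_extinction(g: nx.Graph) -> nx.Graph:
    """Iteratively delete nodes left without edges."""
    g = g.copy()
    while True:
        lonely = [v for v in g.nodes if g.degree(v) == 0]
        if not lonely:
            return g
        g.remove_nodes_from(lonely)


def robustness_removal(
    net: CorrelationNetwork,
    strategy: str = "random_fraction",
    fraction: float = 0.5,
    n_hubs: int = 10,
    reps: int = 100,
    seed: int = 0,
    roles: pd.DataFrame | None = None,
) -> dict:
    """Proportion of taxa remaining after node removal + secondary extinction.

    ``random_fraction`` removes ``fraction`` of the nodes uniformly at
    random (averaged over ``reps``); ``targeted_hubs`` removes the
    ``n_hubs`` highest-zi module/network hubs (all of them, with a
    warning, if fewer exist).
    """
    g = net.graph
    n0 = g.number_of_nodes()
    if n0 == 0:
        raise InvalidInputError("network is empty")
    if strategy == "random_fraction":
        if not 0 < fraction < 1:
            raise InvalidArgumentError("fraction must be in (0, 1)")
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes)
        k = int(round(fraction * n0))
        values = []
        for _ in range(reps):
            drop = rng.choice(n0, size=k, replace=False)
            h = g.copy()
            h.remove_nodes_from([nodes[i] for i in drop])
            h = _secondary_extinction(h)
            values.append(h.number_of_nodes() / n0)
        return {"mean": float(np.mean(values)), "values": values}
    if strategy == "targeted_hubs":
        if roles is None:
            roles = node_roles(net, seed=seed)
        hubs = roles[roles.role.isin(["module_hub", "network_hub"])].sort_values(
            "zi", ascending=False
        )
        if len(hubs) < n_hubs:
            log.warning(
                "robustness_removal: only %d hubs available (< %d requested); removing all",
                len(hubs),
                n_hubs,
            )
        drop = list(hubs.index[:n_hubs])
        h = g.copy()
        h.remove_nodes_from(drop)
        h = _secondary_extinction(h)
        value = h.number_of_nodes() / n0
        return {"mean": float(value), "values": [float(value)], "removed_hubs": drop}
    raise InvalidArgumentError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# spectral stability
# ---------------------------------------------------------------------------

def natural_connectivity(graph_or_adjacency) -> float:
    """Natural connectivity: ln of the mean eigenvalue exponential.

    λ̄ = ln( (1/n) Σ_i exp(λ_i) ) over the eigenvalues of the unweighted
    adjacency matrix; computed with a log-sum-exp for stability.
    """
    if isinstance(graph_or_adjacency, nx.Graph):
        a = nx.to_numpy_array(graph_or_adjacency, weight=None)
    else:
        a = np.asarray(graph_or_adjacency, dtype=float)
    n = a.shape[0]
    if n == 0:
        raise InvalidInputError("empty graph")
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


def natural_connectivity_curve(
    net: CorrelationNetwork,
    removal_fractions=None,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean natural connectivity after random removal of node fractions."""
    if net.n_nodes == 0:
        raise InvalidInputError("network is empty")
    if removal_fractions is None:
        removal_fractions = np.linspace(0.0, 0.8, 9)
    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    n0 = len(nodes)
    rows = []
    for f in removal_fractions:
        k = int(round(f * n0))
        if k >= n0:
            log.warning("natural_connectivity_curve: truncating at fraction %.2f", f)
            break
        values = []
        for _ in range(reps):
            drop = rng.choice(n0, size=k, replace=False)
            h = net.graph.copy()
            h.remove_nodes_from([nodes[i] for i in drop])
            values.append(natural_connectivity(h))
        rows.append({"fraction_removed": float(f), "natural_connectivity": float(np.mean(values))})
    return pd.DataFrame(rows)


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path length; disconnected pairs contribute 0."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if dist > 0:
                total += 1.0 / dist
    return total / (n * (n - 1))


def vulnerability_index(net: CorrelationNetwork) -> float:
    """Largest relative drop in global efficiency from deleting one node."""
    g = net.graph
    if g.number_of_nodes() < 3:
        raise InvalidInputError("need >= 3 nodes")
    e0 = global_efficiency(g)
    if e0 == 0:
        raise UndefinedVulnerabilityError("global efficiency is zero")
    worst = -np.inf
    for v in sorted(g.nodes):
        h = g.copy()
        h.remove_node(v)
        worst = max(worst, (e0 - global_efficiency(h)) / e0)
    return float(worst)


# ---------------------------------------------------------------------------
# cohesion
# ---------------------------------------------------------------------------

@dataclass
class CohesionResult:
    connectedness: pd.DataFrame  # per taxon: positive, negative
    cohesion: pd.DataFrame  # per sample: positive (>=0), negative (<=0)


def cohesion_metrics(table: CommunityTable, n_null: int = 200, seed: int = 0) -> CohesionResult:
    """Null-corrected connectedness per taxon and cohesion per sample.

    Observed pairwise Pearson correlations of relative abundances are
    corrected by subtracting their mean over ``n_null`` taxon-shuffled
    tables (each taxon's values permuted independently across samples).
    A taxon's positive (negative) connectedness is the mean of the
    positive (negative) parts of its corrected correlations over all
    other taxa; a sample's cohesion is the abundance-weighted sum of
    connectedness values.
    """
    if table.n_samples < 10:
        log.warning("cohesion_metrics: only %d samples", table.n_samples)
    rel = table.relative_abundance().to_numpy()
    n_samples, n_taxa = rel.shape
    constant = rel.std(axis=0) == 0
    if constant.any():
        log.warning("cohesion_metrics: %d constant taxa; correlations set to 0", constant.sum())

    def corr(matrix):
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(matrix, rowvar=False)
        c = np.nan_to_num(c, nan=0.0)
        np.fill_diagonal(c, 0.0)
        return c

    obs = corr(rel)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(n_null):
        shuffled = np.empty_like(rel)
        for t in range(n_taxa):
            shuffled[:, t] = rel[rng.permutation(n_samples), t]
        null_sum += corr(shuffled)
    corrected = obs - null_sum / n_null
    np.fill_diagonal(corrected, 0.0)
    pos = np.where(corrected > 0, corrected, 0.0).sum(axis=1) / (n_taxa - 1)
    neg = np.where(corrected < 0, corrected, 0.0).sum(axis=1) / (n_taxa - 1)
    connectedness = pd.DataFrame(
        {"positive": pos, "negative": neg}, index=table.taxon_ids
    )
    cohesion = pd.DataFrame(
        {"positive": rel @ pos, "negative": rel @ neg}, index=table.sample_ids
    )
    return CohesionResult(connectedness=connectedness, cohesion=cohesion)


# ---------------------------------------------------------------------------
# edge partition
# ---------------------------------------------------------------------------

def edge_partition(net: CorrelationNetwork) -> dict:
    """Count edges by kingdom pair and sign: B+/B-, F+/F-, BF+/BF-.

    Edges touching a node labelled ``other`` go to a residual bin with a
    warning; bins always sum to the total edge count.
    """
    bins = {"B+": 0, "B-": 0, "F+": 0, "F-": 0, "BF+": 0, "BF-": 0, "other": 0}
    for u, v, attrs in net.graph.edges(data=True):
        ku = net.graph.nodes[u].get("kingdom", "other")
        kv = net.graph.nodes[v].get("kingdom", "other")
        sign = attrs["sign"]
        if "other" in (ku, kv):
            bins["other"] += 1
            continue
        if ku == kv:
            key = ("B" if ku == "bacteria" else "F") + sign
        else:
            key = "BF" + sign
        bins[key] += 1
    if bins["other"]:
        log.warning("edge_partition: %d edges involve kingdom 'other'", bins["other"])
    return bins
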