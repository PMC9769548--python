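"""Synthetic community generators with known ground truth.

Every downstream stage of the package (diversity, assembly null models,
neutral-model fitting, compositional networks, source apportionment) is
exercised against data produced here, where the generating parameters —
immigration rate, selection strength, basis correlations, mixing
proportions — are known exactly.

The neutral generator implements the zero-sum Moran (death–birth) process
underlying Hubbell-style neutral theory: at each event one individual
dies and is replaced either by an immigrant drawn from the metacommunity
relative-abundance profile (probability ``m``) or by the offspring of a
local individual (probability ``1 − m``).  Local communities are
initialized from the analytic stationary distribution of this process —
a Dirichlet-multinomial with concentration ``θ·p`` where
``θ = m(N−1)/(1−m)`` — so that short runs already sample the
immigration–drift equilibrium the Sloan neutral model describes, and the
subsequent Moran events verify the dynamics rather than burn them in.

Selection communities evolve a niche optimum per taxon by Brownian
motion along the phylogeny (variance proportional to branch length, root
trait 0), giving the phylogenetically conserved niches that nearest-taxon
indices are designed to detect; sampling weights are Gaussian filters of
the taxon trait around each sample's environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable
from .errors import InvalidArgumentError

DEFAULT_SEED = 0


def _rng(seed):
    return np.random.default_rng(DEFAULT_SEED if seed is None else seed)


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class NeutralSimParams:
    """Parameters of the zero-sum neutral (Moran) community simulator."""

    metacommunity_profile: np.ndarray
    local_size: int = 1000
    migration_rate: float = 0.1
    n_samples: int = 50
    n_generations: int = 5
    seed: int = DEFAULT_SEED
    init: str = "stationary"  # or "metacommunity"

    def __post_init__(self):
        p = np.asarray(self.metacommunity_profile, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("metacommunity_profile must be non-negative and sum to 1")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise InvalidArgumentError("migration_rate must lie in [0, 1]")
        if self.local_size < 1 or self.n_samples < 1 or self.n_generations < 0:
            raise InvalidArgumentError("local_size, n_samples >= 1; n_generations >= 0")
        self.metacommunity_profile = p


@dataclass
class SelectionSimParams:
    """Parameters of the environmental-selection simulator."""

    tree: TreeNode
    env_values: np.ndarray
    niche_conservatism: float = 1.0  # Brownian-motion rate per unit branch length
    selection_strength: float = 10.0
    depth: int = 2000
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        env = np.asarray(self.env_values, dtype=float)
        if not np.isfinite(env).all():
            raise InvalidArgumentError("env_values must be finite")
        if self.selection_strength < 0:
            raise InvalidArgumentError("selection_strength must be >= 0")
        if self.depth < 1:
            raise InvalidArgumentError("depth must be >= 1")
        if self.tree.count(tips=True) < 8:
            raise InvalidArgumentError("tree must have >= 8 leaves")
        self.env_values = env


@dataclass
class SourceSinkSpec:
    """A sink community that is a known mixture of source profiles.

    ``mixing_proportions`` has one entry per known source plus a final
    entry for the unknown source, whose profile is ``unknown_profile``.
    """

    source_profiles: list
    mixing_proportions: np.ndarray
    unknown_profile: np.ndarray | None = None
    sink_depth: int = 50_000
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        self.source_profiles = [np.asarray(p, dtype=float) for p in self.source_profiles]
        for p in self.source_profiles:
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError("every source profile must sum to 1")
        pi = np.asarray(self.mixing_proportions, dtype=float)
        if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("mixing_proportions must be non-negative and sum to 1")
        n_components = len(self.source_profiles) + (1 if self.unknown_profile is not None else 0)
        if len(pi) != n_components:
            raise InvalidArgumentError(
                "mixing_proportions must have one entry per source (+1 for the unknown profile)"
            )
        if self.unknown_profile is not None:
            u = np.asarray(self.unknown_profile, dtype=float)
            if (u < 0).any() or abs(u.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError("unknown_profile must sum to 1")
            self.unknown_profile = u
        if self.sink_depth < 1:
            raise InvalidArgumentError("sink_depth must be >= 1")
        self.mixing_proportions = pi


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_taxa: int, seed: int = DEFAULT_SEED) -> TreeNode:
    """Random rooted binary tree with exponential branch lengths.

    Leaves are labelled ``T0 .. T{n-1}`` — the taxon identifiers used by
    every simulator in this module.  Built by random pairwise joins
    (each join picks two subtrees uniformly), which yields a Yule-like
    topology; all branch lengths are strictly positive.
    """
    if n_taxa < 2:
        raise InvalidArgumentError("n_taxa must be >= 2")
    rng = _rng(seed)
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.exponential(1.0)) + 1e-3
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0)) + 1e-3
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# neutral assembly
# ---------------------------------------------------------------------------

def _moran_events(individuals, profile_cdf, m, n_events, rng):
    """Run ``n_events`` single-death replacements in place."""
    n = individuals.shape[0]
    death = rng.integers(0, n, n_events)
    immigrant = rng.random(n_events) < m
    parent = rng.integers(0, n, n_events)
    pool = np.searchsorted(profile_cdf, rng.random(n_events))
    for e in range(n_events):
        if immigrant[e]:
            individuals[death[e]] = pool[e]
        else:
            individuals[death[e]] = individuals[parent[e]]


def _stationary_counts(profile, n, m, rng):
    k = profile.shape[0]
    if m >= 1.0:
        return rng.multinomial(n, profile)
    if m <= 0.0:
        # theta -> 0: community fixed on a single taxon drawn from the pool
        taxon = rng.choice(k, p=profile)
        counts = np.zeros(k, dtype=np.int64)
        counts[taxon] = n
        return counts
    theta = m * (n - 1) / (1.0 - m)
    alpha = np.maximum(theta * profile, 1e-12)
    p_local = rng.dirichlet(alpha)
    return rng.multinomial(n, p_local)


def simulate_neutral_metacommunity(
    params: NeutralSimParams, initial_counts: np.ndarray | None = None
) -> CommunityTable:
    """Local communities assembled from a metacommunity by drift + immigration.

    Each of ``n_samples`` communities holds exactly ``local_size``
    individuals and is evolved by ``local_size * n_generations`` Moran
    events.  The ground-truth migration rate and community size are
    recorded in the returned table's ``meta``.

    Parameters
    ----------
    initial_counts
        Optional (n_samples, n_taxa) integer array overriding the default
        stationary initialization (e.g. monodominant communities).
    """
    p = params.metacommunity_profile
    rng = _rng(params.seed)
    cdf = np.cumsum(p)
    n = params.local_size
    rows = []
    for s in range(params.n_samples):
        if initial_counts is not None:
            counts = np.asarray(initial_counts[s], dtype=np.int64)
            if counts.sum() != n:
                raise InvalidArgumentError("initial_counts rows must sum to local_size")
        else:
            counts = _stationary_counts(p, n, params.migration_rate, rng)
        individuals = np.repeat(np.arange(p.shape[0]), counts)
        _moran_events(individuals, cdf, params.migration_rate, n * params.n_generations, rng)
        rows.append(np.bincount(individuals, minlength=p.shape[0]))
    counts = pd.DataFrame(
        np.asarray(rows),
        index=[f"S{i}" for i in range(params.n_samples)],
        columns=[f"T{i}" for i in range(p.shape[0])],
    )
    return CommunityTable(
        counts,
        meta={"migration_rate": params.migration_rate, "local_size": n, "model": "neutral"},
    )


def lognormal_metacommunity(n_taxa: int, sigma: float = 1.0, seed: int = DEFAULT_SEED) -> np.ndarray:
    """A lognormal species-abundance metacommunity profile (sums to 1)."""
    rng = _rng(seed)
    a = rng.lognormal(0.0, sigma, n_taxa)
    return a / a.sum()


# ---------------------------------------------------------------------------
# environmental selection
# ---------------------------------------------------------------------------

def brownian_traits(tree: TreeNode, rate: float, rng) -> pd.Series:
    """Brownian-motion trait per tip, root trait 0, variance = rate * branch length."""
    trait = {id(tree): 0.0}
    tips = {}
    for node in tree.preorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        value = trait[id(node.parent)] + rng.normal(0.0, np.sqrt(max(rate * length, 0.0)))
        trait[id(node)] = value
        if node.is_tip():
            tips[node.name] = value
    return pd.Series(tips)


def simulate_selection_communities(params: SelectionSimParams) -> CommunityTable:
    """Communities filtered by environmental selection on conserved niches.

    Sampling weight of taxon *i* in sample *j* is
    ``base_i * exp(-selection_strength * (trait_i - env_j)^2)``; each
    sample is a multinomial draw of ``depth`` reads from its weights.
    ``selection_strength = 0`` removes filtering entirely.
    """
    rng = _rng(params.seed)
    traits = brownian_traits(params.tree, params.niche_conservatism, rng)
    taxa = list(traits.index)
    base = rng.lognormal(0.0, 1.0, len(taxa))
    env = params.env_values
    rows = []
    for e in env:
        w = base * np.exp(-params.selection_strength * (traits.values - e) ** 2)
        if w.sum() <= 0:
            w = base.copy()
        rows.append(rng.multinomial(params.depth, w / w.sum()))
    counts = pd.DataFrame(
        np.asarray(rows), index=[f"S{i}" for i in range(len(env))], columns=taxa
    )
    return CommunityTable(
        counts,
        meta={
            "model": "selection",
            "selection_strength": params.selection_strength,
            "env_values": np.asarray(env).tolist(),
            "traits": traits.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# compositional counts with known basis correlation
# ---------------------------------------------------------------------------

def simulate_compositional_counts(
    basis_corr: np.ndarray,
    depth: int,
    n_samples: int,
    seed: int = DEFAULT_SEED,
    log_sigma: float = 1.0,
    log_mean_spread: float = 0.0,
) -> CommunityTable:
    """Multinomial counts whose log-basis abundances have a known correlation.

    Log abundances are multivariate normal with the given correlation
    (scaled by ``log_sigma``), exponentiated, closed to proportions, and
    sampled multinomially at ``depth`` reads per sample.
    ``log_mean_spread`` > 0 draws per-taxon log-mean offsets from
    N(0, spread²), producing the uneven mean abundances (dominant taxa)
    that make closure artefacts visible in naive correlations.
    """
    c = np.asarray(basis_corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
        raise InvalidArgumentError("basis_corr must be square and symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise InvalidArgumentError("basis_corr must have unit diagonal")
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    try:
        chol = np.linalg.cholesky(c * log_sigma**2)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError("basis_corr must be positive-definite") from exc
    rng = _rng(seed)
    mu = rng.normal(0.0, log_mean_spread, c.shape[0]) if log_mean_spread > 0 else 0.0
    z = rng.standard_normal((n_samples, c.shape[0])) @ chol.T + mu
    x = np.exp(z)
    p = x / x.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, row) for row in p])
    df = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"T{i}" for i in range(c.shape[0])],
    )
    return CommunityTable(df, meta={"model": "compositional", "basis_corr": c})


# ---------------------------------------------------------------------------
# source-sink mixtures
# ---------------------------------------------------------------------------

def simulate_source_sink(spec: SourceSinkSpec) -> np.ndarray:
    """Sink counts drawn multinomially from a mixture of source profiles."""
    rng = _rng(spec.seed)
    profiles = list(spec.source_profiles)
    if spec.unknown_profile is not None:
        profiles = profiles + [spec.unknown_profile]
    mix = np.zeros_like(profiles[0])
    for pi, prof in zip(spec.mixing_proportions, profiles):
        mix += pi * prof
    mix = mix / mix.sum()
    return rng.multinomial(spec.sink_depth, mix)


# ---------------------------------------------------------------------------
# spatially structured communities (distance decay)
# ---------------------------------------------------------------------------

def simulate_distance_decay_communities(
    n_sites: int = 20,
    n_taxa: int = 60,
    span_degrees: float = 10.0,
    drift_sigma: float = 0.6,
    depth: int = 2000,
    seed: int = DEFAULT_SEED,
) -> CommunityTable:
    """Communities whose immigration sources drift along a spatial transect.

    Sites sit on a west–east transect; the site-specific metacommunity
    log-profile performs a Gaussian random walk between neighbouring
    sites, so nearby sites draw from similar pools and community
    similarity decays with geographic distance.
    """
    rng = _rng(seed)
    lons = np.linspace(0.0, span_degrees, n_sites)
    log_profile = rng.normal(0.0, 1.0, n_taxa)
    rows = []
    for _ in range(n_sites):
        p = np.exp(log_profile)
        p = p / p.sum()
        rows.append(rng.multinomial(depth, p))
        log_profile = log_profile + rng.normal(0.0, drift_sigma, n_taxa)
    counts = pd.DataFrame(
        np.asarray(rows),
        index=[f"S{i}" for i in range(n_sites)],
        columns=[f"T{i}" for i in range(n_taxa)],
    )
    coords = pd.DataFrame({"longitude": lons, "latitude": np.zeros(n_sites)}, index=counts.index)
    return CommunityTable(counts, coordinates=coords, meta={"model": "distance_decay"})
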