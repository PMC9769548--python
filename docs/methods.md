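# Methods

This note documents the models, null constructions, numerical choices
and known limitations behind each analysis stage, and what the
synthetic-data generators do and do not emulate.

## Synthetic generators

**Neutral assembly.** Local communities of exactly `N` individuals
follow a zero-sum Moran (death–birth) process: at each event one
individual, chosen uniformly, dies and is replaced by an immigrant drawn
from the metacommunity relative-abundance profile with probability `m`,
or by the offspring of a local individual otherwise. Each sample is run
for `N · n_generations` events (default `n_generations = 5`). Rather
than burning in from an arbitrary start (mixing takes ~`N/m` events at
small `m`), communities are initialized from the process' analytic
stationary law — a Dirichlet-multinomial with concentration
`θ·p`, `θ = m(N−1)/(1−m)` — so the Moran events verify the dynamics
instead of paying for equilibration. `m = 0` is an absorbing case
(monodominant communities stay monodominant); `m = 1` reduces to i.i.d.
multinomial draws from the pool. Callers may pass explicit initial
counts (e.g. monodominant) to study transients. Metacommunity profiles
default to lognormal species-abundance distributions (σ ≈ 1–2), the
shape typical of soil ASV tables.

**Environmental selection.** A niche optimum per taxon evolves by
Brownian motion along a simulated phylogeny (variance = rate × branch
length, root trait 0), so close relatives have similar optima — the
phylogenetic signal nearest-taxon indices assume. Sampling weight of
taxon *i* in sample *j* is `base_i · exp(−s (trait_i − env_j)²)`;
reads are multinomial. `s = 0` removes filtering.

**Compositional counts.** Log-basis abundances are multivariate normal
with a user-supplied correlation matrix (unit diagonal, positive
definite), optionally offset by per-taxon log-means
(`log_mean_spread`), exponentiated, closed to proportions, and sampled
multinomially. Uneven log-means create the dominant-taxon regime in
which closure artefacts corrupt naive correlations — the setting SparCC
is built for.

**Source/sink mixtures.** A sink is a single multinomial draw from
`Σ_k π_k · profile_k`, optionally including an unknown profile as the
last component.

**What the generators do not emulate:** sequencing error, chimeras,
PCR/primer bias, overdispersion beyond the multinomial, spatially
explicit dispersal kernels, and temporal dynamics. Tests passing on
these generators show the *statistics* behave as designed under their
own model assumptions, not that those assumptions hold in any given
soil data set.

## Assembly null models

**βMNTD/βNTI.** βMNTD(k,m) = 0.5·[Σ_i f_ik min_j d_ij + Σ_j f_jm
min_i d_ij] over patristic distances, abundance-weighted by default
(uniform weights available). The null shuffles taxon labels across all
tree tips (999 permutations by default, one permutation applied to all
pairs per iteration); βNTI is the z-score of the observed value. Taxa
are processed in sorted-id order so results do not depend on input
column order. If two samples have identical taxon membership, βMNTD is
0 under every relabelling and the z-score is undefined: the default is
an error, and `on_degenerate="zero"` (used by the pipeline) assigns
βNTI = 0, the natural value when the observation equals the null
exactly.

**RC_Bray.** For each sample the null generator preserves observed
richness and total reads: taxa are drawn without replacement with
probability ∝ occupancy, each drawn taxon is seeded with one
individual (so richness is exact), and the remaining reads are
distributed multinomially ∝ metacommunity relative abundance (column
sums over the full analysis set, not just the pair). RC is the
fraction of null pairs less dissimilar than observed (ties at half
weight), rescaled to [−1, 1].

**Classification.** |βNTI| > 2 → selection, with βNTI > +2 labelled
heterogeneous selection (pairs more dissimilar than expected, as under
divergent environments) and βNTI < −2 homogeneous selection; among the
rest, RC > 0.95 → dispersal limitation, RC < −0.95 → homogenizing
dispersal, else undominated. Boundary values (exactly 2 or 0.95) fall
on the non-selection/undominated side. Some sources print the two
selection inequalities the other way; `legend_convention=True` swaps
the selection labels only.

**MST.** With Δ the observed Bray-Curtis, E its mean under the RC null
generator and Dmax = 1: MST = (Dmax−Δ)/(Dmax−E) when Δ ≥ E, else Δ/E,
clipped to [0,1]; 1 means the observation matches the stochastic
expectation, 0 maximal departure.

## Neutral community model

`freq(p) = 1 − BetaCDF(1/N; Nmp, Nm(1−p))` with `N` the mean sample
total and detection limit `1/N`; `m` minimizes the sum of squared
frequency residuals (bounded scalar search on (1e-6, 1]). R² is
computed on frequencies; the 95% band uses Wilson binomial intervals
at the number of samples; taxa with frequency 0 or 1 are excluded
(uninformative for the fit).

**Known bias.** Occurrence-frequency fitting overestimates `m`: the
exact detection probability of a rare taxon, `P(count ≥ 1)` under the
beta-binomial, exceeds the beta-tail approximation `P(x > 1/N)` the
model uses (equivalent-m ratios of 1.2–1.8 at N = 1000 for p ≤ 0.005),
and the Moran stationary concentration `m(N−1)/(1−m)` differs from the
diffusion's `Nm` by a further `1/(1−m)`. Measured against the Moran
generator this yields median `m̂/m ≈ 1.25` at m = 0.05 and ≈ 1.5 at
m = 0.15, insensitive to the metacommunity profile. The package fits
the standard estimator rather than a debiased variant because
comparability with published `m` values is the point; recovered rates
should be read as upper bounds at larger `m`.

## Niche breadth

Levins B_i = 1/Σ_j q_ij² over each taxon's across-sample proportions;
Bcom is the mean over taxa present. The generalist/specialist null
preserves all sample totals and all taxon totals exactly by sampling
uniformly from the fixed-margins contingency-table distribution
(Patefield's algorithm via `scipy.stats.random_table`); independent
draws sidestep the poor mixing of incremental 2×2 unit swaps, which in
testing almost never moved mass out of concentrated taxa. Thresholds
are the percentile 2.5/97.5 bounds of the null breadth; taxa whose
null breadth never varies are neutral by definition.

## Networks

SparCC: per resample, counts (+pseudocount 1) are converted to
fractions by a Dirichlet posterior draw; basis variances solve the
log-ratio variance system under the sparsity assumption, with
iterative exclusion of the strongest pair (up to 10 iterations, stop
threshold 0.1); the estimate is the median over 20 resamples, clipped
to [−1,1]. Taxa are prevalence-filtered (≥ 25% of samples, configurable)
first. Edges require |r| > 0.6 with no additional significance filter.
Spectral and efficiency metrics use the unweighted adjacency. Modules
come from greedy modularity maximization with deterministic sorted-id
tie-breaks (chosen over Louvain for reproducibility); Zi/Pi cutoffs
are the classical 2.5/0.62. Robustness removes nodes (random fraction,
averaged over replicates, or the highest-zi module/network hubs) and
then iteratively deletes degree-0 nodes (secondary extinction = edge
loss only; no abundance cascade). Natural connectivity is computed by
log-sum-exp over the adjacency eigenvalues. Vulnerability is
`max_v (E − E_{G−v})/E` with disconnected pairs contributing 0 to
efficiency.

Cohesion: pairwise Pearson correlations of relative abundances are
corrected by subtracting their mean over taxon-shuffle nulls (each
taxon's values permuted independently across samples); a taxon's
positive (negative) connectedness is the sum of the positive (negative)
parts of its corrected correlations divided by the number of other
taxa — i.e. a mean over all other taxa of the signed part, which keeps
the null expectation near zero; per-sample cohesion is the
abundance-weighted sum. Constant taxa get zero correlations with a
warning.

## Source apportionment

The sink is a multinomial mixture over known source profiles
(pseudocount-1 smoothed) plus, optionally, one free unknown profile
initialized from the sink mass not explained by the known sources
(floor 1e-12). Standard EM: fractional read assignment (E), weight and
unknown-profile updates (M); the log-likelihood is checked
nondecreasing; convergence at 1e-8 absolute change or 1000 iterations.
Initialization is deterministic (uniform known weights, 0.1 unknown),
so results do not depend on the seed argument. With a single sink the
unknown component is identifiable only insofar as the sink deviates
from the span of the known sources; proportions for near-collinear
sources should be interpreted with care.

## Pipeline scale and defaults

Library defaults use 999 null iterations / 1000 permutations (the
conventional choices). The pipeline configuration defaults to 199/199
and a compact synthetic bundle (two kingdoms, 8 samples per
compartment, 60 + 25 taxa, depth 1000, BS assembled at m = 0.3 vs RS
at m = 0.1 on a shared transect), sized so a complete run finishes in
seconds while every stage still has resolvable signal; all stage seeds
derive from one master seed via `SeedSequence([master, crc32(name)])`.
Null-model resolution at 199 iterations limits RC/βNTI tail precision
to ~0.005/z-score granularity — adequate for the 0.95 and 2 thresholds
but worth raising for publication-grade analyses.

## Degenerate inputs and tie-breaks

Rarefaction drops (never pads) samples below depth. CSS errors on
all-zero samples. Chao1 uses the bias-corrected form, defined when no
doubletons exist. Bray-Curtis of two all-zero samples is an error.
Zero-variance within-module degree gives zi = 0 (all-peripheral
cliques). RC ties count half. The Mantel and distance-decay p-values
use the (count+1)/(permutations+1) estimator and are one-tailed
(enrichment for Mantel, decay for distance-decay).
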