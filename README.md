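# rhizoecol

Community-ecology inference for paired bulk-soil (BS) / rhizosphere (RS)
microbiome count tables — the statistical battery commonly applied to
amplicon (16S/ITS) ASV tables when asking *how* root-associated
communities assemble and interact:

- **Diversity & preprocessing** — rarefaction, cumulative-sum scaling
  (CSS), Chao1 richness, the bacteria/fungi richness equilibrium ratio,
  Bray-Curtis dissimilarity, Podani-family decomposition of Sørensen
  dissimilarity into replacement and richness-difference components,
  distance-decay regression, Mantel tests.
- **Assembly null models** — βMNTD and its standardized effect size
  βNTI against a tip-shuffling phylogenetic null; the Bray-Curtis
  Raup-Crick index (RC_Bray); the five-way process classification
  (heterogeneous/homogeneous selection, dispersal limitation,
  homogenizing dispersal, undominated); the modified stochasticity
  ratio (MST).
- **Neutral & niche** — the Sloan neutral community model
  (occurrence frequency = 1 − Beta(1/N; Nmp, Nm(1−p)), with migration
  rate *m* fitted by least squares), Levins niche breadth
  B = 1/Σqⱼ², and a fixed-margins permutation test classifying taxa as
  generalists or specialists.
- **Interkingdom networks** — SparCC compositional correlations,
  |r| > 0.6 edge thresholding, Guimerà–Amaral Zi/Pi node roles,
  robustness to random and hub-targeted node removal, natural
  connectivity ln((1/n)Σe^λᵢ), vulnerability (largest relative drop in
  global efficiency from one deletion), cohesion (abundance-weighted,
  null-corrected connectedness), and the B/F/BF edge partition.
- **Source apportionment** — an EM multinomial mixture estimating what
  fraction of a sink (rhizosphere) community derives from each candidate
  source (bulk soil) plus an unknown source.
- **Synthetic data** — generators with known ground truth for every
  stage: zero-sum neutral (Moran) assembly at known immigration rate,
  environmental selection on phylogenetically conserved (Brownian)
  niches, compositional counts with a known basis correlation, and
  known source/sink mixtures.

## Worked example

```python
import rhizoecol as rz

# neutral communities assembled at a known immigration rate
profile = rz.lognormal_metacommunity(150, sigma=2.0, seed=0)
table = rz.simulate_neutral_metacommunity(
    rz.NeutralSimParams(profile, local_size=1000, migration_rate=0.05,
                        n_samples=50, n_generations=2, seed=1)
)
fit = rz.fit_ncm(table)
print(f"m = {fit.m:.4f}  Nm = {fit.Nm:.1f}  R^2 = {fit.r_squared:.2f}")
print(fit.partition_fractions)
```

prints

```
m = 0.0601  Nm = 60.1  R^2 = 0.95
{'above': 0.05511811023622047, 'neutral': 0.8740157480314961, 'below': 0.07086614173228346}
```

The fitted migration rate tracks the simulated value 0.05 (occurrence-
frequency fitting overestimates *m* somewhat; see `docs/methods.md`),
the model explains ~95% of the variance in occurrence frequencies, and
~87% of taxa fall inside the 95% prediction band ("neutral"), the rest
occurring more ("above") or less ("below") often than predicted.

The full BS-vs-RS battery runs from the command line:

```sh
rhizoecol run-all --synthetic --seed 0 --out results/
```

which writes per-stage CSV/JSON artifacts (alpha diversity, beta
decomposition, βNTI/RC_Bray pair tables with process fractions, NCM
fits, niche strategies, a GraphML network with stability metrics,
cohesion, and source proportions) plus a machine-readable `report.json`.

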