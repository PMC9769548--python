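"""Sloan neutral community model and niche-breadth classification.

The Sloan model predicts each taxon's occurrence frequency (fraction of
samples in which it is detected) from its mean relative abundance ``p``:
with community size ``N`` (mean reads per sample), migration rate ``m``
and detection limit ``d = 1/N``,

    freq(p) = 1 - BetaCDF(d; N m p, N m (1 - p)).

``m`` is the only free parameter and is fitted by least squares on the
observed frequencies.  Levins niche breadth ``B = 1 / Σ_j q_j²`` (over a
taxon's across-sample proportions ``q``) measures how evenly a taxon
spreads over habitats; a margin-preserving permutation null classifies
taxa as generalists (observed B above the null 97.5th percentile),
specialists (below the 2.5th) or neutral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .containers import CommunityTable
from .errors import InvalidInputError, UnfittableModelError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NCMFit:
    m: float
    N: float
    Nm: float
    r_squared: float
    detection_limit: float
    taxa: pd.DataFrame  # taxon, p, freq_obs, freq_pred, lower, upper, partition
    partition_fractions: dict

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "N": self.N,
            "Nm": self.Nm,
            "r_squared": self.r_squared,
            "partition_fractions": self.partition_fractions,
        }


def predicted_frequency(p: np.ndarray, m: float, N: float, d: float) -> np.ndarray:
    """Sloan occurrence frequency: 1 - BetaCDF(d; Nmp, Nm(1-p))."""
    p = np.asarray(p, dtype=float)
    a = np.maximum(N * m * p, 1e-12)
    b = np.maximum(N * m * (1.0 - p), 1e-12)
    return stats.beta.sf(d, a, b)


def fit_ncm(table: CommunityTable) -> NCMFit:
    """Fit the Sloan neutral model to a count table.

    Taxa occurring in every sample or in none carry no information for
    the frequency fit and are excluded.  The 95% band around the
    predicted frequency uses Wilson binomial intervals at the number of
    samples; taxa outside the band are partitioned as above/below.
    """
    counts = table.counts.round().astype(np.int64)
    n_samples = counts.shape[0]
    if n_samples < 10:
        log.warning("fit_ncm: only %d samples; fit may be unstable", n_samples)
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if (totals == 0).any():
        raise InvalidInputError("all-zero sample in NCM input")
    N = float(totals.mean())
    d = 1.0 / N
    rel = counts.to_numpy(dtype=float) / totals[:, None]
    p = rel.mean(axis=0)
    freq = (counts.to_numpy() > 0).mean(axis=0)
    informative = (freq > 0) & (freq < 1)
    if not informative.any():
        raise UnfittableModelError("no taxon occurs in an intermediate number of samples")
    p_fit = p[informative]
    f_fit = freq[informative]

    def sse(m):
        return float(np.sum((f_fit - predicted_frequency(p_fit, m, N, d)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    m_hat = float(res.x)
    pred = predicted_frequency(p_fit, m_hat, N, d)
    ss_tot = float(np.sum((f_fit - f_fit.mean()) ** 2))
    r2 = 1.0 - res.fun / ss_tot if ss_tot > 0 else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lower, upper = proportion_confint(
            np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
        )
    partition = np.where(f_fit > upper, "above", np.where(f_fit < lower, "below", "neutral"))
    taxa = pd.DataFrame(
        {
            "taxon": np.asarray(table.taxon_ids)[informative],
            "p": p_fit,
            "freq_obs": f_fit,
            "freq_pred": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        }
    )
    fractions = {
        label: float((partition == label).mean()) for label in ("above", "neutral", "below")
    }
    return NCMFit(
        m=m_hat,
        N=N,
        Nm=N * m_hat,
        r_squared=float(r2),
        detection_limit=d,
        taxa=taxa,
        partition_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Levins niche breadth and generalist/specialist classification
# ---------------------------------------------------------------------------

@dataclass
class NicheBreadthResult:
    breadth: pd.Series  # per-taxon Levins B
    bcom: float
    strategy: pd.Series | None = None  # generalist / specialist / neutral
    strategy_fractions: dict | None = None


def levins_breadth(table: CommunityTable) -> NicheBreadthResult:
    """Levins breadth B_i = 1 / Σ_j q_ij² per taxon; Bcom = mean over taxa.

    q are each taxon's proportions across samples; taxa with zero total
    are excluded with a warning.  ``1 <= B <= n_samples``.
    """
    values = table.values()
    totals = values.sum(axis=0)
    if (totals == 0).any():
        dropped = [t for t, z in zip(table.taxon_ids, totals == 0) if z]
        log.warning("levins_breadth: excluding %d all-zero taxa", len(dropped))
    keep = totals > 0
    q = values[:, keep] / totals[keep]
    b = 1.0 / (q**2).sum(axis=0)
    breadth = pd.Series(b, index=np.asarray(table.taxon_ids)[keep], name="levins_B")
    return NicheBreadthResult(breadth=breadth, bcom=float(breadth.mean()))


def classify_niche_strategy(
    table: CommunityTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> NicheBreadthResult:
    """Generalist/specialist classification against a fixed-margins null.

    Null tables preserve every sample total and every taxon total and
    are drawn uniformly from that constraint set (Patefield's algorithm
    via :func:`scipy.stats.random_table`).  A taxon is a generalist if
    its observed Levins B exceeds the null 97.5th percentile, a
    specialist if below the 2.5th, neutral otherwise (including taxa
    whose null breadth never varies).
    """
    if n_perm < 100:
        log.warning("classify_niche_strategy: n_perm=%d is low; percentiles will be coarse", n_perm)
    observed = levins_breadth(table)
    values = table.counts.round().astype(np.int64).to_numpy()
    keep = values.sum(axis=0) > 0
    rng = np.random.default_rng(seed)
    null_dist = stats.random_table(values.sum(axis=1), values.sum(axis=0))
    draws = null_dist.rvs(n_perm, random_state=rng)
    null_b = np.empty((n_perm, int(keep.sum())))
    for it in range(n_perm):
        shuffled = draws[it]
        q = shuffled[:, keep] / shuffled[:, keep].sum(axis=0)
        null_b[it] = 1.0 / (q**2).sum(axis=0)
    lower = np.percentile(null_b, 2.5, axis=0)
    upper = np.percentile(null_b, 97.5, axis=0)
    monomorphic = null_b.std(axis=0) == 0
    obs = observed.breadth.to_numpy()
    labels = np.where(obs > upper, "generalist", np.where(obs < lower, "specialist", "neutral"))
    labels[monomorphic] = "neutral"
    strategy = pd.Series(labels, index=observed.breadth.index, name="strategy")
    fractions = {
        label: float((labels == label).mean())
        for label in ("generalist", "specialist", "neutral")
    }
    return NicheBreadthResult(
        breadth=observed.breadth,
        bcom=observed.bcom,
        strategy=strategy,
        strategy_fractions=fractions,
    )
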