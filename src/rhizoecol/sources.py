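"""Source apportionment of a sink community by an EM multinomial mixture.

A sink community (e.g. a rhizosphere sample) is modelled as a
multinomial mixture of candidate source profiles (e.g. bulk soil) plus,
optionally, a free "unknown" source profile estimated jointly with the
mixing weights.  The E-step assigns each sink read fractionally to the
components; the M-step updates the weights and the unknown profile.
The log-likelihood is nondecreasing across iterations (standard EM
guarantee), which is asserted at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NumericalFailureError

UNKNOWN_FLOOR = 1e-12


@dataclass
class SourceEstimate:
    proportions: np.ndarray  # one per known source (+1 for unknown if enabled)
    source_names: list
    log_likelihood: list  # per-iteration trace, nondecreasing
    n_iter: int
    unknown_profile: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {name: float(p) for name, p in zip(self.source_names, self.proportions)}


def em_source_apportionment(
    sink: np.ndarray,
    sources: list,
    unknown: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
    source_names: list | None = None,
) -> SourceEstimate:
    """Estimate the mixing proportions of a sink over source communities.

    Parameters
    ----------
    sink
        Count vector over the shared taxon set.
    sources
        List of count vectors over the same taxa; each is smoothed with
        pseudocount 1 and normalized to a profile.
    unknown
        If true, add a free component whose profile is initialized from
        the sink mass not explained by the known sources and re-estimated
        each M-step.
    seed
        Accepted for interface uniformity; the initialization is
        deterministic, so the result does not depend on it.

    Returns
    -------
    SourceEstimate with proportions summing to 1 and the log-likelihood
    trace.
    """
    y = np.asarray(sink, dtype=float)
    if y.sum() <= 0:
        raise InvalidInputError("sink total must be positive")
    if (y < 0).any():
        raise InvalidInputError("sink counts must be non-negative")
    profiles = []
    for s in sources:
        s = np.asarray(s, dtype=float)
        if s.shape != y.shape:
            raise InvalidInputError("sources must share the sink's taxon indexing")
        if s.sum() <= 0:
            raise InvalidInputError("each source total must be positive")
        sm = s + 1.0
        profiles.append(sm / sm.sum())
    k = len(profiles)
    if k == 0:
        raise InvalidInputError("need at least one source")
    names = list(source_names) if source_names is not None else [f"source_{i}" for i in range(k)]
    n_total = y.sum()
    y_rel = y / n_total

    if unknown:
        mean_known = np.mean(profiles, axis=0)
        residual = np.maximum(y_rel - mean_known, UNKNOWN_FLOOR)
        u = residual / residual.sum()
        profiles = profiles + [u]
        names = names + ["unknown"]
        pi = np.full(k + 1, 0.9 / k)
        pi[-1] = 0.1
    else:
        pi = np.full(k, 1.0 / k)

    p = np.vstack(profiles)  # components x taxa
    trace = []
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mix = pi @ p  # per-taxon mixture probability
        mix = np.maximum(mix, UNKNOWN_FLOOR)
        ll = float(y @ np.log(mix))
        if not np.isfinite(ll):
            raise NumericalFailureError("non-finite log-likelihood")
        trace.append(ll)
        # E-step: fractional read assignment; M-step: weights (+ unknown profile)
        resp = (pi[:, None] * p) / mix[None, :]  # components x taxa
        weighted = resp * y[None, :]
        pi = weighted.sum(axis=1) / n_total
        pi = pi / pi.sum()
        if unknown:
            u_new = weighted[-1]
            if u_new.sum() > 0:
                u_new = np.maximum(u_new / u_new.sum(), UNKNOWN_FLOOR)
                p[-1] = u_new / u_new.sum()
        if ll - prev < tol and it > 1:
            break
        prev = ll
    return SourceEstimate(
        proportions=pi,
        source_names=names,
        log_likelihood=trace,
        n_iter=it,
        unknown_profile=p[-1].copy() if unknown else None,
    )
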