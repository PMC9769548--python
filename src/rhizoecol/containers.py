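"""In-memory containers for community data.

The central object is :class:`CommunityTable`, a thin validated wrapper
around a samples x taxa :class:`pandas.DataFrame` carrying per-taxon
kingdom labels, per-sample compartment labels (e.g. bulk soil ``BS`` vs
rhizosphere ``RS``) and optional sample coordinates.  Distance matrices
are represented with :class:`skbio.DistanceMatrix`; phylogenies with
:class:`skbio.TreeNode`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

KINGDOMS = ("bacteria", "fungi", "other")


@dataclass
class CommunityTable:
    """Samples x taxa abundance table with ecological annotations.

    Parameters
    ----------
    counts
        Non-negative numeric matrix; rows are samples, columns taxa.
    kingdom
        Per-taxon label in ``{"bacteria", "fungi", "other"}``. Defaults to
        ``"bacteria"`` for every taxon.
    compartment
        Per-sample label (e.g. ``"BS"``/``"RS"``). Defaults to ``"NA"``.
    coordinates
        Optional per-sample ``(longitude, latitude)`` in decimal degrees.
    """

    counts: pd.DataFrame
    kingdom: pd.Series | None = None
    compartment: pd.Series | None = None
    coordinates: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(np.asarray(self.counts))
        if isinstance(self.counts.index, pd.RangeIndex):
            self.counts.index = [f"S{i}" for i in range(self.counts.shape[0])]
        if isinstance(self.counts.columns, pd.RangeIndex):
            self.counts.columns = [f"T{i}" for i in range(self.counts.shape[1])]
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        if (self.counts.values < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise InvalidInputError("sample and taxon identifiers must be unique")
        if self.kingdom is None:
            self.kingdom = pd.Series("bacteria", index=self.counts.columns)
        else:
            self.kingdom = pd.Series(self.kingdom).reindex(self.counts.columns)
            if self.kingdom.isna().any():
                raise InvalidInputError("kingdom label missing for some taxa")
            bad = set(self.kingdom.unique()) - set(KINGDOMS)
            if bad:
                raise InvalidInputError(f"unknown kingdom labels: {bad}")
        if self.compartment is None:
            self.compartment = pd.Series("NA", index=self.counts.index)
        else:
            self.compartment = pd.Series(self.compartment).reindex(self.counts.index)
            if self.compartment.isna().any():
                raise InvalidInputError("compartment label missing for some samples")
        if self.coordinates is not None:
            self.coordinates = pd.DataFrame(self.coordinates).reindex(self.counts.index)
            if list(self.coordinates.columns[:2]) != ["longitude", "latitude"]:
                self.coordinates.columns = ["longitude", "latitude"]

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-closed proportions (each sample sums to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise InvalidInputError("cannot close all-zero samples to proportions")
        return self.counts.div(totals, axis=0)

    # -- subsetting ------------------------------------------------------
    def select_samples(self, sample_ids) -> "CommunityTable":
        ids = list(sample_ids)
        return CommunityTable(
            self.counts.loc[ids],
            kingdom=self.kingdom,
            compartment=self.compartment.loc[ids],
            coordinates=None if self.coordinates is None else self.coordinates.loc[ids],
            meta=dict(self.meta),
        )

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        ids = list(taxon_ids)
        return CommunityTable(
            self.counts[ids],
            kingdom=self.kingdom.loc[ids],
            compartment=self.compartment,
            coordinates=self.coordinates,
            meta=dict(self.meta),
        )

    def filter_prevalence(self, min_fraction: float) -> "CommunityTable":
        """Keep taxa present (count > 0) in at least ``min_fraction`` of samples."""
        prev = (self.counts > 0).mean(axis=0)
        return self.select_taxa(self.counts.columns[prev >= min_fraction])

    def by_compartment(self) -> dict[str, "CommunityTable"]:
        return {
            c: self.select_samples(self.compartment.index[self.compartment == c])
            for c in sorted(self.compartment.unique())
        }
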