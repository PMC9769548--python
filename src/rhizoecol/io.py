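"""File formats.

Count tables are tab-separated with taxa as rows and samples as columns
(first column = taxon id, header row = sample ids), the layout amplicon
pipelines commonly export.  Metadata is CSV with columns ``sample_id``,
``compartment`` and optional ``longitude``/``latitude``.  Trees are
newick (read with scikit-bio).  Labelled matrices are written as CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import CommunityTable
from .errors import InvalidInputError


def write_counts_tsv(table: CommunityTable, path) -> None:
    df = table.counts.T  # taxa rows x sample columns
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path, kingdom=None, compartment=None, coordinates=None) -> CommunityTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CommunityTable(df.T, kingdom=kingdom, compartment=compartment, coordinates=coordinates)


def write_metadata_csv(table: CommunityTable, path) -> None:
    meta = pd.DataFrame({"sample_id": table.sample_ids, "compartment": table.compartment.values})
    if table.coordinates is not None:
        meta["longitude"] = table.coordinates["longitude"].values
        meta["latitude"] = table.coordinates["latitude"].values
    meta.to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise InvalidInputError("metadata must have a sample_id column")
    return meta.set_index("sample_id")


def write_kingdom_csv(table: CommunityTable, path) -> None:
    pd.DataFrame({"taxon_id": table.taxon_ids, "kingdom": table.kingdom.values}).to_csv(
        path, index=False
    )


def read_kingdom_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    return df.set_index("taxon_id")["kingdom"]


def attach_metadata(table: CommunityTable, meta: pd.DataFrame) -> CommunityTable:
    """Attach compartment labels / coordinates from a metadata frame.

    Every sample in the table must appear in the metadata; extra metadata
    rows are ignored.
    """
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise InvalidInputError(f"samples absent from metadata: {missing}")
    compartment = meta.loc[table.sample_ids, "compartment"]
    coords = None
    if {"longitude", "latitude"} <= set(meta.columns):
        coords = meta.loc[table.sample_ids, ["longitude", "latitude"]]
    return CommunityTable(
        table.counts, kingdom=table.kingdom, compartment=compartment, coordinates=coords,
        meta=dict(table.meta),
    )


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.values, ids=list(df.index))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
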