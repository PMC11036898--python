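"""Readers and writers for the pipeline's on-disk formats.

Count tables are TSV with ASVs as rows, samples as columns and a first
column ``ASV_ID`` (BIOM is supported when the ``biom`` package is
importable); metadata is CSV indexed by sample id; trees are Newick;
distance matrices are square TSV with matching id header row/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import CountTable

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_taxonomy",
]


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table (``tsv`` or ``biom``) and validate it."""
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col="ASV_ID")
        except ValueError as exc:
            raise ValueError(f"malformed count table {path}: {exc}") from exc
        return CountTable(df.T)
    if format == "biom":
        try:
            import biom
        except ImportError as exc:  # pragma: no cover - present with scikit-bio
            raise ImportError("BIOM support requires the biom-format package") from exc
        table = biom.load_table(str(path))
        df = pd.DataFrame(
            table.matrix_data.toarray().T,
            index=list(table.ids("sample")),
            columns=list(table.ids("observation")),
        )
        return CountTable(df)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(counts: CountTable, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = counts.data.T
        out.index.name = "ASV_ID"
        out.to_csv(path, sep="\t")
        return
    if format == "biom":
        import biom

        table = biom.Table(
            counts.data.T.to_numpy(), counts.asv_ids, counts.sample_ids
        )
        with biom.util.biom_open(str(path), "w") as fh:
            table.to_hdf5(fh, "eimbiome")
        return
    raise ValueError(f"unknown count-table format {format!r}")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    for col in ("is_negative_control", "surgery"):
        if col in meta.columns:
            meta[col] = meta[col].astype(bool)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path)


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; duplicate leaves are rejected.

    Missing branch lengths are set to 0 (the tree still loads, but
    UniFrac then ignores those branches).
    """
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf label(s) in tree: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(float), list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t"
    )


def read_taxonomy(path) -> pd.DataFrame:
    """ASV taxonomy TSV with an ``ASV_ID`` column and rank columns."""
    tax = pd.read_csv(path, sep="\t")
    if "ASV_ID" not in tax.columns:
        raise ValueError("taxonomy file must contain an ASV_ID column")
    return tax.set_index("ASV_ID")
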