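"""Readers and writers for the plain-text dialects the pipeline consumes.

Formats: tab-separated OTU tables (taxa-as-rows, the common amplicon dialect,
or samples-as-rows; ``#`` comment lines ignored), Newick trees, and CSV sample
metadata.  Writers mirror readers so a written file re-reads bit-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CommunityTable, PhyloTree, SampleFrame

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_samples",
    "write_samples",
]


def read_community_table(path, orientation: str = "auto") -> CommunityTable:
    """Read a TSV count table.

    Parameters
    ----------
    path : str or path-like
    orientation : {"auto", "taxa_rows", "samples_rows"}
        How to interpret rows.  ``auto`` assumes taxa-as-rows unless row ids
        look like sample ids (fewer rows than columns is used as a weak hint).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"empty community table: {path}")
    try:
        body = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric entry {v!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r}"
                    ) from exc
        raise
    if np.any(body < 0):
        i, j = np.argwhere(body < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation not in ("auto", "taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        orientation = "taxa_rows" if df.shape[0] >= df.shape[1] else "samples_rows"
    if orientation == "taxa_rows":
        df = df.T
    return CommunityTable(
        df.to_numpy(dtype=float),
        [str(s) for s in df.index],
        [str(t) for t in df.columns],
    )


def write_community_table(table: CommunityTable, path, orientation: str = "taxa_rows"):
    df = table.to_frame()
    if orientation == "taxa_rows":
        df = df.T
        df.index.name = "taxon_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_newick(path)


def write_newick(tree: PhyloTree, path):
    tree.tree.write(path, format="newick")


def read_samples(path, table: CommunityTable | None = None) -> SampleFrame:
    """Read the CSV metadata/environment table; validate against a table."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    frame = SampleFrame(df)
    if table is not None:
        frame.check_against(table)
    return frame


def write_samples(frame: SampleFrame, path):
    out = frame.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
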