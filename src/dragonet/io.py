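"""Reading omics tables, sample alignment, and result serialization.

TSV/CSV tables carry a header row of feature names and a first column of
sample IDs. All numeric output is serialized with 12 significant digits,
so write/read round-trips are lossless at that precision.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import PairedOmicsData

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "feature_a", "layer_a", "feature_b", "layer_b", "block",
    "partial_correlation", "p_value", "q_value",
]
_FLOAT_FMT = "%.12g"


def read_omics_table(path, delimiter: str = "\t", samples_in_rows: bool = True) -> pd.DataFrame:
    """Read a samples x features table (header row, sample-ID first column).

    Set ``samples_in_rows=False`` for transposed files (features in rows);
    the returned frame always has samples in rows. Non-numeric cells and
    duplicate feature names are rejected with the offending location.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, keep_default_na=False, na_values=[])
    if not samples_in_rows:
        df = df.T
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric cell in {path}: row {bad!r}, column {col!r}")
        if df[col].isna().any():
            bad = df[df[col].isna()].index[0]
            raise ValueError(f"missing value in {path}: row {bad!r}, column {col!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate feature name in {path}: {dup!r}")
    return df.astype(float)


def align_samples(table1: pd.DataFrame, table2: pd.DataFrame) -> PairedOmicsData:
    """Inner-join two tables on sample IDs, preserving table1's order."""
    ids1 = table1.index.astype(str)
    ids2 = set(table2.index.astype(str))
    shared = [s for s in ids1 if s in ids2]
    dropped = (len(table1) - len(shared)) + (len(table2) - len(shared))
    if not shared:
        raise ValueError("no shared sample IDs between the two layers")
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    if dropped:
        logger.warning("dropped %d unmatched sample(s) during alignment", dropped)
    t1 = table1.loc[table1.index.astype(str).isin(set(shared))]
    t2 = table2.copy()
    t2.index = t2.index.astype(str)
    t2 = t2.loc[[s for s in shared]]
    return PairedOmicsData(
        X1=t1.to_numpy(dtype=float),
        X2=t2.to_numpy(dtype=float),
        sample_ids=shared,
        feature_ids_1=list(map(str, table1.columns)),
        feature_ids_2=list(map(str, table2.columns)),
    )


def write_dataset(data: PairedOmicsData, path1, path2, delimiter: str = "\t"):
    """Write the two layers as TSV tables (sample IDs in the first column)."""
    for X, ids, path in (
        (data.X1, data.feature_ids_1, path1),
        (data.X2, data.feature_ids_2, path2),
    ):
        pd.DataFrame(X, index=data.sample_ids, columns=ids).to_csv(
            path, sep=delimiter, float_format=_FLOAT_FMT, index_label="sample_id"
        )


def write_truth_edges(truth, path, delimiter: str = "\t"):
    """Write a ground-truth graph as a (node_a, node_b, weight) edge list."""
    p1 = truth.p1
    iu, ju = np.nonzero(np.triu(truth.adjacency, 1))
    names = [f"L1:V{k}" for k in range(p1)] + [f"L2:V{k}" for k in range(truth.p - p1)]
    df = pd.DataFrame(
        {
            "node_a": [names[i] for i in iu],
            "node_b": [names[j] for j in ju],
            "weight": truth.theta[iu, ju],
        }
    )
    df.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT, index=False)


def write_edge_table(edges: pd.DataFrame, path, fdr_threshold: float = 1.0, delimiter: str = "\t"):
    """Write the edge table, optionally keeping only q < fdr_threshold rows.

    Row order is deterministic: ascending (q, p, feature names).
    """
    out = edges.loc[edges["q_value"] < fdr_threshold, EDGE_COLUMNS] if fdr_threshold < 1.0 \
        else edges[EDGE_COLUMNS]
    out = out.sort_values(["q_value", "p_value", "feature_a", "feature_b"], kind="mergesort")
    out.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT, index=False)


def read_edge_table(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)


def to_graphml(edges: pd.DataFrame, path, fdr_threshold: float = 0.05):
    """Export the thresholded network as GraphML (node attr: layer;
    edge attrs: partial_correlation, p, q)."""
    import networkx as nx

    sub = edges[edges["q_value"] < fdr_threshold]
    g = nx.Graph()
    for row in sub.itertuples(index=False):
        g.add_node(row.feature_a, layer=int(row.layer_a))
        g.add_node(row.feature_b, layer=int(row.layer_b))
        g.add_edge(
            row.feature_a,
            row.feature_b,
            partial_correlation=float(row.partial_correlation),
            p=float(row.p_value),
            q=float(row.q_value),
        )
    nx.write_graphml(g, path)
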