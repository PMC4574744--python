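"""Expression-matrix loading, probe collapsing and gene filtering.

The expression container is a plain :class:`pandas.DataFrame` with gene (or
probe) identifiers as the index and sample identifiers as columns, holding
non-negative values on a linear MAS5-like scale.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "validate_expression",
    "collapse_probes",
    "filter_genes",
]


def validate_expression(X: pd.DataFrame) -> pd.DataFrame:
    if X.index.has_duplicates:
        raise ValueError("duplicate gene/probe identifiers")
    if X.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    values = X.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression values must be numeric")
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    return X


def read_expression(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a genes-x-samples delimited text matrix.

    Accepts plain TSV/CSV with a header row of sample ids and the first
    column holding gene/probe ids, and tolerates GCT 1.2-style files (a
    ``#1.2`` version line, a dimensions line, and a Description column).
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        drop = [c for c in df.columns if c.lower() == "description"]
        df = df.drop(columns=drop)
    else:
        if sep is None:
            sep = "," if first.count(",") > first.count("\t") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_expression(df)


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping[str, str],
    method: str = "max_mean",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    The retained row is the probe with maximal mean expression across samples
    (``method="max_mean"``, default) or maximal interquartile range
    (``method="max_iqr"``); ties break on the lexicographically smaller probe
    id, so the choice is deterministic.  Probes without a gene mapping are
    dropped (their count is recorded in ``result.attrs["n_unmapped"]``).
    Values are copied, never averaged or otherwise combined.
    """
    if method not in ("max_mean", "max_iqr"):
        raise ValueError(f"unknown collapse method: {method!r}")
    validate_expression(probe_matrix)
    mapped = [p for p in probe_matrix.index if p in probe_map]
    n_unmapped = len(probe_matrix.index) - len(mapped)
    if not mapped:
        raise ValueError("no probes could be mapped to genes")
    sub = probe_matrix.loc[mapped]
    if method == "max_mean":
        score = sub.mean(axis=1)
    else:
        q = np.quantile(sub.to_numpy(), [0.25, 0.75], axis=1)
        score = pd.Series(q[1] - q[0], index=sub.index)

    order = pd.DataFrame(
        {
            "probe": list(mapped),
            "gene": [probe_map[p] for p in mapped],
            "score": score.loc[mapped].to_numpy(),
        }
    )
    # per gene: highest score wins, ties to the lexicographically smaller probe
    order = order.sort_values(
        ["gene", "score", "probe"], ascending=[True, False, True], kind="mergesort"
    )
    best = order.drop_duplicates("gene", keep="first").set_index("probe")
    result = sub.loc[best.index].copy()
    result.index = pd.Index(best["gene"].to_numpy(), name="gene")
    result = result.sort_index()
    result.attrs["n_unmapped"] = n_unmapped
    return result


def filter_genes(
    X: pd.DataFrame, pct75_min: float = 250.0, iqr_min: float = 500.0
) -> pd.DataFrame:
    """Drop low-expression and low-dynamic-range genes.

    A gene is retained iff its 75th percentile across samples is at least
    ``pct75_min`` and its interquartile range is at least ``iqr_min``
    (quantiles by linear interpolation between order statistics).  Gene
    order is preserved.
    """
    if X.shape[1] < 4:
        raise ValueError("gene filtering needs at least 4 samples")
    values = X.to_numpy(dtype=float)
    q25, q75 = np.quantile(values, [0.25, 0.75], axis=1)
    keep = (q75 >= pct75_min) & ((q75 - q25) >= iqr_min)
    if not keep.any():
        raise ValueError(
            "no genes survive the expression/dynamic-range filters "
            f"(75th pct >= {pct75_min}, IQR >= {iqr_min})"
        )
    return X.loc[keep]
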