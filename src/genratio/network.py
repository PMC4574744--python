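"""Ratio-network construction and leave-one-gene-out importance.

The significant, positively-oriented ratios form a directed graph: an edge
numerator -> denominator means the pair's ratio is elevated in sensitive
samples.  A gene's degree counts the significant ratios it participates in;
its positivity is the fraction of those in which it is the numerator — 1
marks a putative positive regulator of response, 0 a negative one.  Gene
importance is measured by rerunning cross-validation with the gene removed
from the hypothesis set, on the same fold partition, and recording the AUC
drop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model import GrepConfig, _coerce_labels, cross_validate

__all__ = [
    "build_ratio_network",
    "network_node_table",
    "write_edge_list",
    "read_edge_list",
    "GeneImportance",
    "gene_elimination_importance",
]


def build_ratio_network(
    significant_ratios: Sequence[tuple[str, str]],
    model_ratios: Sequence[tuple[str, str]] = (),
    t_stats: Sequence[float] | None = None,
) -> nx.DiGraph:
    """Directed graph of positively-oriented significant ratios.

    Node attributes: ``degree`` (ratios containing the gene) and
    ``positivity`` (numerator fraction).  Edge attributes: ``in_model``
    (ratio used by the classifier) and optionally ``t``.
    """
    ratios = [tuple(r) for r in significant_ratios]
    if any(a == b for a, b in ratios):
        raise ValueError("self-ratio encountered; ratios must pair distinct genes")
    if t_stats is not None and any(t < 0 for t in t_stats):
        raise ValueError(
            "negative t: ratios must be positively oriented before network construction"
        )
    model_set = {tuple(r) for r in model_ratios}
    unmatched = model_set - set(ratios)
    if unmatched:
        raise ValueError(f"model ratios not among significant ratios: {sorted(unmatched)}")
    G = nx.DiGraph()
    num_count: dict[str, int] = {}
    den_count: dict[str, int] = {}
    for i, (num, den) in enumerate(ratios):
        attrs = {"in_model": (num, den) in model_set}
        if t_stats is not None:
            attrs["t"] = float(t_stats[i])
        G.add_edge(num, den, **attrs)
        num_count[num] = num_count.get(num, 0) + 1
        den_count[den] = den_count.get(den, 0) + 1
    for gene in G.nodes:
        n_num = num_count.get(gene, 0)
        n_den = den_count.get(gene, 0)
        G.nodes[gene]["degree"] = n_num + n_den
        G.nodes[gene]["positivity"] = n_num / (n_num + n_den)
    return G


def network_node_table(G: nx.DiGraph) -> pd.DataFrame:
    return (
        pd.DataFrame(
            [
                {"gene": g, "degree": d["degree"], "positivity": d["positivity"]}
                for g, d in G.nodes(data=True)
            ]
        )
        .sort_values(["degree", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


def write_edge_list(G: nx.DiGraph, path: str) -> None:
    """Delimited edge list: gene_num, gene_den, in_model[, t]."""
    rows = []
    for num, den, d in G.edges(data=True):
        row = {"gene_num": num, "gene_den": den, "in_model": int(d.get("in_model", False))}
        if "t" in d:
            row["t"] = d["t"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    ratios = list(zip(df["gene_num"].astype(str), df["gene_den"].astype(str)))
    model = [r for r, m in zip(ratios, df["in_model"]) if m]
    t = df["t"].to_list() if "t" in df.columns else None
    return build_ratio_network(ratios, model, t)


@dataclass
class GeneImportance:
    gene: str
    auc_full: float
    auc_without: float
    delta: float  # auc_full - auc_without; positive = gene helps
    fold_deltas: np.ndarray
    z: float  # delta over the SD of fold-level deltas (0 when all deltas are 0)


def _fold_z(delta: float, fold_deltas: np.ndarray) -> float:
    sd = float(np.std(fold_deltas, ddof=1)) if fold_deltas.size > 1 else 0.0
    if sd == 0.0:
        return 0.0 if delta == 0.0 else float(np.sign(delta) * np.inf)
    return float(delta / sd)


def gene_elimination_importance(
    X: pd.DataFrame,
    labels: Sequence,
    hypothesis_genes: Sequence[str],
    config: GrepConfig | None = None,
    k: int = 5,
    genes_to_test: Sequence[str] | None = None,
) -> list[GeneImportance]:
    """AUC cost of removing each hypothesis gene, on a fixed fold partition.

    One cross-validation of the full pipeline runs per reduced gene set; the
    folds (and all seeds) are identical across runs so deltas reflect gene
    removal rather than partition noise.  ``genes_to_test`` restricts the
    scan to a subset (the full scan is linear in the gene-set size).
    """
    config = config or GrepConfig()
    hypothesis_genes = list(hypothesis_genes)
    if len(hypothesis_genes) < 3:
        raise ValueError("need at least 3 hypothesis genes")
    y = _coerce_labels(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.zeros(y.size), y))

    full = cross_validate(X, y, hypothesis_genes, config, folds=folds)
    full_fold_auc = np.array(
        [m.auc if m.auc is not None else np.nan for m in full.per_fold]
    )
    out = []
    for gene in genes_to_test if genes_to_test is not None else hypothesis_genes:
        reduced = [g for g in hypothesis_genes if g != gene]
        rep = cross_validate(X, y, reduced, config, folds=folds)
        red_fold_auc = np.array(
            [m.auc if m.auc is not None else np.nan for m in rep.per_fold]
        )
        fold_deltas = full_fold_auc - red_fold_auc
        delta = float(full.pooled.auc - rep.pooled.auc)
        out.append(
            GeneImportance(
                gene=gene,
                auc_full=float(full.pooled.auc),
                auc_without=float(rep.pooled.auc),
                delta=delta,
                fold_deltas=fold_deltas,
                z=_fold_z(delta, fold_deltas[~np.isnan(fold_deltas)]),
            )
        )
    return out
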