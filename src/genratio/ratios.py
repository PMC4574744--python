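"""Pairwise log-ratio features and permutation-based selection.

The central feature space: for a chosen gene set, every unordered gene pair
becomes one feature whose per-sample value is

    log((x_num + c) / (x_den + c))

with a pseudocount ``c`` damping noise at low expression.  Features are
ranked by a two-sample t statistic (sensitive minus insensitive), with
significance from sample-label permutations and a plug-in permutation FDR
(expected null exceedances over observed exceedances, made monotone).
Selected features are re-oriented so that higher ratio values associate with
sensitivity (t > 0).

Because a per-sample scale factor multiplies numerator and denominator
alike, log-ratios with c=0 are exactly invariant to per-sample rescaling —
the property that lets a fitted model transfer across platforms without
renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatioSelectionConfig",
    "RatioSet",
    "compute_log_ratios",
    "welch_t",
    "pooled_t",
    "ratio_t_stats",
    "permutation_significance",
    "select_significant",
]


@dataclass(frozen=True)
class RatioSelectionConfig:
    """Knobs of the ratio-selection stage.

    pseudocount: expression units added to numerator and denominator
        (default 32, well below the MAS5 baseline of 150).
    n_permutations: sample-label permutations for p/q estimation.
    fdr_cutoff: permutation-FDR threshold for significance.
    equal_var: pooled-variance t instead of the Welch default.
    pooled_p: count permutation exceedances across the whole feature family
        instead of per feature (finer p resolution than 1/(B+1)).
    """

    pseudocount: float = 32.0
    n_permutations: int = 100
    fdr_cutoff: float = 0.1
    equal_var: bool = False
    pooled_p: bool = False
    seed: int = 0


@dataclass
class RatioSet:
    """A bank of oriented log-ratio features over common samples.

    ``values[i, s]`` is the log-ratio of pair ``pairs[i] = (num, den)`` in
    sample ``s``.  Statistics are populated by the association stage.
    """

    pairs: list[tuple[str, str]]
    values: np.ndarray  # (n_features, n_samples)
    sample_ids: list[str]
    pseudocount: float
    t_stat: np.ndarray | None = None
    p_value: np.ndarray | None = None
    q_value: np.ndarray | None = None
    oriented_positive: bool = False
    skipped_genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_num": [p[0] for p in self.pairs],
                "gene_den": [p[1] for p in self.pairs],
            }
        )
        for name, arr in (
            ("t", self.t_stat),
            ("p", self.p_value),
            ("q", self.q_value),
        ):
            if arr is not None:
                df[name] = arr
        return df

    def subset(self, idx: np.ndarray) -> "RatioSet":
        idx = np.asarray(idx)
        return replace(
            self,
            pairs=[self.pairs[i] for i in idx],
            values=self.values[idx],
            t_stat=None if self.t_stat is None else self.t_stat[idx],
            p_value=None if self.p_value is None else self.p_value[idx],
            q_value=None if self.q_value is None else self.q_value[idx],
        )


def compute_log_ratios(
    X: pd.DataFrame, gene_set: Sequence[str], pseudocount: float = 32.0
) -> RatioSet:
    """Log-ratio features for every unordered pair of available genes.

    Pairs are canonically oriented by lexicographic gene order before any
    association testing; genes absent from ``X`` are skipped and recorded.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    available = [g for g in dict.fromkeys(gene_set) if g in X.index]
    skipped = [g for g in dict.fromkeys(gene_set) if g not in X.index]
    if len(available) < 2:
        raise ValueError("need at least 2 genes present in the matrix")
    available = sorted(available)
    logx = np.log(X.loc[available].to_numpy(dtype=float) + pseudocount)
    pos = {g: i for i, g in enumerate(available)}
    pairs = list(combinations(available, 2))
    num_idx = np.fromiter((pos[a] for a, _ in pairs), dtype=int)
    den_idx = np.fromiter((pos[b] for _, b in pairs), dtype=int)
    values = logx[num_idx] - logx[den_idx]
    return RatioSet(
        pairs=pairs,
        values=values,
        sample_ids=[str(s) for s in X.columns],
        pseudocount=pseudocount,
        skipped_genes=skipped,
    )


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "sensitive").astype(int) if "sensitive" in set(y) else y.astype(int)
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1 or sensitive/insensitive)")
    return y


def welch_t(values: np.ndarray, group_matrix: np.ndarray) -> np.ndarray:
    """Welch t for each feature row against each 0/1 label column.

    ``values`` is (F, S); ``group_matrix`` is (S, B) of 0/1 indicators for
    the positive class, giving a (F, B) matrix of t statistics (positive
    class minus negative class).  Features with zero variance in both
    groups get t = 0.
    """
    g = np.asarray(group_matrix, dtype=float)
    n1 = g.sum(axis=0)
    n0 = g.shape[0] - n1
    if np.any(n1 < 2) or np.any(n0 < 2):
        raise ValueError("each class needs at least 2 samples")
    s1 = values @ g
    sq1 = (values**2) @ g
    s_tot = values.sum(axis=1, keepdims=True)
    sq_tot = (values**2).sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m0 = (s_tot - s1) / n0
    v1 = (sq1 - n1 * m1**2) / (n1 - 1)
    v0 = ((sq_tot - sq1) - n0 * m0**2) / (n0 - 1)
    v1 = np.maximum(v1, 0.0)
    v0 = np.maximum(v0, 0.0)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
    t[se2 == 0] = 0.0
    return t


def pooled_t(values: np.ndarray, group_matrix: np.ndarray) -> np.ndarray:
    """Student (pooled-variance) analogue of :func:`welch_t`."""
    g = np.asarray(group_matrix, dtype=float)
    n1 = g.sum(axis=0)
    n0 = g.shape[0] - n1
    if np.any(n1 < 2) or np.any(n0 < 2):
        raise ValueError("each class needs at least 2 samples")
    s1 = values @ g
    sq1 = (values**2) @ g
    s_tot = values.sum(axis=1, keepdims=True)
    sq_tot = (values**2).sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m0 = (s_tot - s1) / n0
    ss1 = np.maximum(sq1 - n1 * m1**2, 0.0)
    ss0 = np.maximum((sq_tot - sq1) - n0 * m0**2, 0.0)
    sp2 = (ss1 + ss0) / (n1 + n0 - 2)
    se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
    t[se2 == 0] = 0.0
    return t


def ratio_t_stats(
    ratios: RatioSet, labels: Sequence, equal_var: bool = False
) -> np.ndarray:
    """Two-sample t per ratio (sensitive minus insensitive), stored in place."""
    y = _as_binary(labels)[:, None]
    stat = pooled_t if equal_var else welch_t
    t = stat(ratios.values, y)[:, 0]
    ratios.t_stat = t
    return t


def _permutation_q(t_obs_abs: np.ndarray, t_perm_abs: np.ndarray) -> np.ndarray:
    """Plug-in permutation FDR: E[null exceedances] / observed exceedances.

    For each observed |t| threshold, the expected number of null statistics
    at or above it (mean over permutations, pooled across features) is
    divided by the observed count; the result is clipped to [0, 1] and made
    monotone non-increasing in |t|.
    """
    order = np.argsort(-t_obs_abs, kind="mergesort")
    sorted_abs = t_obs_abs[order]
    flat = np.sort(t_perm_abs.ravel())
    B = t_perm_abs.shape[1]
    # null exceedances at each observed threshold, averaged over permutations
    n_null = (flat.size - np.searchsorted(flat, sorted_abs, side="left")) / B
    n_obs = np.arange(1, sorted_abs.size + 1, dtype=float)
    q_sorted = np.clip(n_null / n_obs, 0.0, 1.0)
    # monotone: a larger |t| can never have a larger q
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def permutation_significance(
    ratios: RatioSet, labels: Sequence, cfg: RatioSelectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p- and q-values for every ratio feature.

    Sample labels are permuted jointly across all features, preserving the
    inter-gene correlation structure.  p-values use per-feature exceedance
    counting with +1 smoothing by default (``cfg.pooled_p`` pools counts
    across the family for finer resolution); q-values come from the plug-in
    permutation FDR.  Results are stored on ``ratios`` and returned.
    """
    if cfg.n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    y = _as_binary(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("labels are degenerate (single class)")
    stat = pooled_t if cfg.equal_var else welch_t
    t_obs = stat(ratios.values, y[:, None])[:, 0]
    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_permutations
    perm_cols = np.empty((y.size, B), dtype=float)
    for b in range(B):
        perm_cols[:, b] = rng.permutation(y)
    t_perm = stat(ratios.values, perm_cols)

    abs_obs = np.abs(t_obs)
    abs_perm = np.abs(t_perm)
    if cfg.pooled_p:
        flat = np.sort(abs_perm.ravel())
        exceed = flat.size - np.searchsorted(flat, abs_obs, side="left")
        p = (1.0 + exceed) / (1.0 + flat.size)
    else:
        exceed = (abs_perm >= abs_obs[:, None]).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + B)
    q = _permutation_q(abs_obs, abs_perm)

    ratios.t_stat = t_obs
    ratios.p_value = p
    ratios.q_value = q
    return p, q


def select_significant(ratios: RatioSet, fdr_cutoff: float = 0.1) -> RatioSet:
    """Keep features with q below the cutoff, oriented positively.

    Retained pairs are flipped where needed so the numerator gene is the one
    elevated in sensitive samples (t > 0); flipping negates values and t and
    leaves p and q untouched.  An empty selection is returned as an empty
    :class:`RatioSet` (downstream stages treat it as "no signal").
    """
    if ratios.q_value is None:
        raise ValueError("q-values not populated; run permutation_significance")
    keep = np.flatnonzero(ratios.q_value < fdr_cutoff)
    out = ratios.subset(keep)
    flip = out.t_stat < 0
    out.values = out.values.copy()
    out.values[flip] *= -1.0
    out.t_stat = np.abs(out.t_stat)
    out.pairs = [
        (den, num) if f else (num, den)
        for (num, den), f in zip(out.pairs, flip)
    ]
    out.oriented_positive = True
    return out
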