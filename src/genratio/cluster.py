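"""Exemplar clustering of correlated ratio features by affinity propagation.

Significant ratios are often heavily redundant (many pairs share a gene or
track the same underlying program), so one representative per correlated
cluster is used as the classifier feature.  Similarity is the Pearson
correlation of per-sample log-ratio vectors; clustering is affinity
propagation (responsibility/availability message passing) with a
deterministic lowest-index tie-break and an all-singletons fallback when the
messages fail to settle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RatioClusterSet",
    "ratio_similarity",
    "affinity_propagation",
    "select_exemplars",
    "cluster_report",
]


@dataclass
class RatioClusterSet:
    labels: np.ndarray  # cluster assignment per point: index of its exemplar
    exemplars: np.ndarray  # sorted unique exemplar indices
    similarity: np.ndarray
    preference: float
    damping: float
    converged: bool
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def ratio_similarity(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of feature value vectors.

    Zero-variance features get similarity 0 against everything (their
    correlation is undefined); the diagonal is set to 0 and never used as a
    preference.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 features")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples per feature")
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(values)
    degenerate = sd == 0
    S[degenerate, :] = 0.0
    S[:, degenerate] = 0.0
    S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, 0.0)
    return S


def affinity_propagation(
    similarity: np.ndarray,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
) -> RatioClusterSet:
    """Affinity propagation on a precomputed similarity matrix.

    ``preference`` defaults to the median off-diagonal similarity.  The run
    stops once the exemplar set is unchanged for ``convergence_window``
    consecutive iterations; if that never happens within ``max_iter``, every
    point becomes its own exemplar (no merging) and ``converged`` is False.
    Ties in exemplar competition resolve to the lowest feature index.
    """
    S = np.array(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity contains non-finite values")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("similarity must be symmetric")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    n = S.shape[0]
    if n == 1:
        return RatioClusterSet(
            labels=np.zeros(1, dtype=int),
            exemplars=np.zeros(1, dtype=int),
            similarity=S,
            preference=0.0,
            damping=damping,
            converged=True,
            n_iter=0,
        )
    off = S[~np.eye(n, dtype=bool)]
    if preference is None:
        preference = float(np.median(off))
    # deterministic symmetry-breaking: an index-ordered tilt ~1e-10 of the
    # similarity scale resolves exemplar ties toward the lowest index and
    # prevents oscillation on exactly symmetric inputs
    scale = max(float(np.max(np.abs(off), initial=0.0)), abs(preference), 1e-12)
    np.fill_diagonal(S, preference + 1e-10 * scale * np.arange(n, 0, -1))

    R = np.zeros_like(S)
    A = np.zeros_like(S)
    idx = np.arange(n)
    stable = 0
    last_exemplars: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        max1_idx = np.argmax(AS, axis=1)
        max1 = AS[idx, max1_idx]
        AS[idx, max1_idx] = -np.inf
        max2 = AS.max(axis=1)
        R_new = S - max1[:, None]
        R_new[idx, max1_idx] = S[idx, max1_idx] - max2
        R = damping * R + (1.0 - damping) * R_new
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        A_new = np.minimum(0.0, col[None, :] - Rp)
        np.fill_diagonal(A_new, col - Rp.diagonal())
        A = damping * A + (1.0 - damping) * A_new

        exemplars = np.flatnonzero(np.diag(A + R) > 0)
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars):
            stable += 1
        else:
            stable = 0
        last_exemplars = exemplars
        if stable >= convergence_window and len(exemplars) > 0:
            converged = True
            break

    if not converged or last_exemplars is None or len(last_exemplars) == 0:
        labels = idx.copy()
        return RatioClusterSet(
            labels=labels,
            exemplars=idx.copy(),
            similarity=similarity,
            preference=preference,
            damping=damping,
            converged=False,
            n_iter=it,
        )

    exemplars = last_exemplars
    # assign each point to its most similar exemplar (ties -> lowest index,
    # argmax returns the first maximum); exemplars assign to themselves
    sim_to_ex = S[:, exemplars]
    labels = exemplars[np.argmax(sim_to_ex, axis=1)]
    labels[exemplars] = exemplars
    return RatioClusterSet(
        labels=labels,
        exemplars=np.sort(exemplars),
        similarity=similarity,
        preference=preference,
        damping=damping,
        converged=True,
        n_iter=it,
    )


def select_exemplars(clusters: RatioClusterSet, t_stat: np.ndarray | None = None) -> np.ndarray:
    """Exemplar feature indices, ordered by descending |t| when given."""
    exemplars = clusters.exemplars
    if t_stat is not None:
        order = np.argsort(-np.abs(np.asarray(t_stat)[exemplars]), kind="mergesort")
        exemplars = exemplars[order]
    return exemplars


def cluster_report(clusters: RatioClusterSet) -> "pd.DataFrame":
    """Per-feature table: cluster id, exemplar flag, similarity to exemplar."""
    import pandas as pd

    labels = clusters.labels
    sim = np.asarray(clusters.similarity, dtype=float)
    n = labels.size
    sim_to_ex = np.array(
        [1.0 if labels[i] == i else sim[i, labels[i]] for i in range(n)]
    )
    return pd.DataFrame(
        {
            "feature": np.arange(n),
            "cluster_id": labels,
            "is_exemplar": labels == np.arange(n),
            "similarity_to_exemplar": sim_to_ex,
        }
    )
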