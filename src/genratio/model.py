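"""End-to-end ratio-classifier orchestration: fit, predict, cross-validate.

The full pipeline is

    gene filters -> pairwise log-ratios -> t + permutation significance
    -> FDR selection -> affinity-propagation exemplars -> logistic regression

and a fitted model carries everything needed to score new samples from raw
non-negative expression values — gene pairs, logistic coefficients, the
pseudocount — with no renormalization of the incoming matrix.  Because the
features are within-sample ratios, predictions are insensitive to per-sample
scale (exactly so at pseudocount 0), which is what makes the model portable
across platforms.

Cross-validation refits every stage (filters included) inside each training
fold, so reported out-of-fold metrics carry no selection leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cluster import affinity_propagation, ratio_similarity, select_exemplars
from .expression import filter_genes
from .metrics import Metrics, compute_metrics
from .ratios import (
    RatioSelectionConfig,
    compute_log_ratios,
    permutation_significance,
    select_significant,
)

__all__ = [
    "GrepConfig",
    "GrepModel",
    "PredictionResult",
    "CVReport",
    "fit_grep",
    "predict",
    "cross_validate",
    "screen_split_evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GrepConfig:
    """All tunables of the ratio-classifier pipeline."""

    pseudocount: float = 32.0
    n_permutations: int = 100
    fdr_cutoff: float = 0.1
    pct75_min: float = 250.0
    iqr_min: float = 500.0
    equal_var: bool = False
    pooled_p: bool = False
    damping: float = 0.9
    max_iter: int = 1000
    convergence_window: int = 50
    preference: float | None = None
    l2_c: float = 1.0  # inverse L2 strength of the logistic stage
    threshold: float = 0.5
    apply_gene_filters: bool = True
    seed: int = 0

    def ratio_config(self, seed: int | None = None) -> RatioSelectionConfig:
        return RatioSelectionConfig(
            pseudocount=self.pseudocount,
            n_permutations=self.n_permutations,
            fdr_cutoff=self.fdr_cutoff,
            equal_var=self.equal_var,
            pooled_p=self.pooled_p,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class GrepModel:
    """A fitted ratio classifier, self-contained and serializable."""

    ratios: list[tuple[str, str]]  # oriented (numerator, denominator)
    coef: np.ndarray
    intercept: float
    pseudocount: float
    log_base: str = "e"
    threshold: float = 0.5
    seed: int = 0
    no_signal: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.ratios:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "format": "genratio-model",
            "version": 1,
            "ratios": [list(r) for r in self.ratios],
            "coef": [float(c) for c in np.asarray(self.coef).ravel()],
            "intercept": float(self.intercept),
            "pseudocount": float(self.pseudocount),
            "log_base": self.log_base,
            "threshold": float(self.threshold),
            "seed": int(self.seed),
            "no_signal": bool(self.no_signal),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrepModel":
        return cls(
            ratios=[tuple(r) for r in d["ratios"]],
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            pseudocount=float(d["pseudocount"]),
            log_base=d.get("log_base", "e"),
            threshold=float(d.get("threshold", 0.5)),
            seed=int(d.get("seed", 0)),
            no_signal=bool(d.get("no_signal", False)),
            metadata=d.get("metadata", {}),
        )


@dataclass
class PredictionResult:
    sample_id: str
    probability: float
    call: str  # "sensitive" | "insensitive"


@dataclass
class CVReport:
    fold_assignments: np.ndarray  # test-fold index per sample
    oof_probabilities: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    pooled: Metrics
    per_fold: list[Metrics]

    @property
    def auc(self) -> float | None:
        return self.pooled.auc

    @property
    def ppv(self) -> float | None:
        return self.pooled.ppv


def _coerce_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "sensitive").astype(int)
    return y.astype(int)


def _ratio_values(
    X: pd.DataFrame, ratios: Sequence[tuple[str, str]], pseudocount: float
) -> np.ndarray:
    missing = sorted({g for pair in ratios for g in pair} - set(X.index))
    if missing:
        raise KeyError(f"model genes missing from matrix: {missing}")
    vals = X.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("expression values must be non-negative")
    pos = {g: i for i, g in enumerate(X.index)}
    logx = np.log(vals + pseudocount)
    out = np.empty((len(ratios), X.shape[1]))
    for i, (num, den) in enumerate(ratios):
        out[i] = logx[pos[num]] - logx[pos[den]]
    return out


def fit_grep(
    X: pd.DataFrame,
    labels: Sequence,
    hypothesis_genes: Sequence[str],
    config: GrepConfig | None = None,
) -> GrepModel:
    """Fit the full ratio-classifier pipeline on a training matrix.

    ``labels`` are binary (1/"sensitive" vs 0/"insensitive"; intermediate
    lines are excluded upstream).  When no ratio survives FDR selection the
    returned model is intercept-only with ``no_signal=True`` and predicts
    the training prevalence for every sample.
    """
    config = config or GrepConfig()
    if len(list(hypothesis_genes)) == 0:
        raise ValueError("hypothesis gene set is empty")
    y = _coerce_labels(labels)
    if X.shape[1] != y.size:
        raise ValueError("labels length must match sample count")

    Xf = filter_genes(X, config.pct75_min, config.iqr_min) if config.apply_gene_filters else X
    genes = [g for g in hypothesis_genes if g in Xf.index]
    prevalence = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))

    def _no_signal(reason: str) -> GrepModel:
        return GrepModel(
            ratios=[],
            coef=np.array([]),
            intercept=float(np.log(prevalence / (1 - prevalence))),
            pseudocount=config.pseudocount,
            threshold=config.threshold,
            seed=config.seed,
            no_signal=True,
            metadata={"reason": reason, "n_train": int(y.size)},
        )

    if len(genes) < 2:
        return _no_signal("fewer than 2 hypothesis genes survive filtering")

    ratios = compute_log_ratios(Xf, genes, config.pseudocount)
    permutation_significance(ratios, y, config.ratio_config())
    selected = select_significant(ratios, config.fdr_cutoff)
    if len(selected) == 0:
        return _no_signal("no ratios significant at the FDR cutoff")

    if len(selected) == 1:
        exemplar_idx = np.array([0])
        ap_converged = True
    else:
        S = ratio_similarity(selected.values)
        clusters = affinity_propagation(
            S,
            preference=config.preference,
            damping=config.damping,
            max_iter=config.max_iter,
            convergence_window=config.convergence_window,
        )
        exemplar_idx = select_exemplars(clusters, selected.t_stat)
        ap_converged = clusters.converged

    exemplars = selected.subset(exemplar_idx)
    clf = LogisticRegression(C=config.l2_c, solver="lbfgs", max_iter=2000)
    clf.fit(exemplars.values.T, y)

    model = GrepModel(
        ratios=list(exemplars.pairs),
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        pseudocount=config.pseudocount,
        threshold=config.threshold,
        seed=config.seed,
        metadata={
            "n_train": int(y.size),
            "n_genes_filtered": int(Xf.shape[0]),
            "n_hypothesis_genes_used": len(genes),
            "n_candidate_ratios": len(ratios),
            "n_significant_ratios": len(selected),
            "n_exemplars": len(exemplars),
            "ap_converged": bool(ap_converged),
            "gene_filters": {
                "applied": config.apply_gene_filters,
                "pct75_min": config.pct75_min,
                "iqr_min": config.iqr_min,
            },
            "exemplar_t": [float(t) for t in exemplars.t_stat],
        },
    )
    # training probabilities recorded through the same code path predict uses
    model.metadata["train_sample_ids"] = [str(s) for s in X.columns]
    model.metadata["train_probabilities"] = [
        float(p) for p in _probabilities(model, X)
    ]
    return model


def _probabilities(model: GrepModel, X: pd.DataFrame) -> np.ndarray:
    if model.no_signal or len(model.ratios) == 0:
        return np.full(X.shape[1], float(expit(model.intercept)))
    values = _ratio_values(X, model.ratios, model.pseudocount)
    return expit(model.intercept + model.coef @ values)


def predict(model: GrepModel, X_new: pd.DataFrame) -> list[PredictionResult]:
    """Score new samples with a fitted model — no rescaling of ``X_new``.

    Every model gene must be present; negative expression is rejected.
    """
    prob = _probabilities(model, X_new)
    return [
        PredictionResult(
            sample_id=str(s),
            probability=float(p),
            call="sensitive" if p > model.threshold else "insensitive",
        )
        for s, p in zip(X_new.columns, prob)
    ]


def cross_validate(
    X: pd.DataFrame,
    labels: Sequence,
    hypothesis_genes: Sequence[str],
    config: GrepConfig | None = None,
    k: int = 5,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the whole pipeline.

    Gene filtering, ratio selection, clustering and the logistic fit are all
    redone inside each training fold; metrics are computed on out-of-fold
    probabilities only.  ``folds`` accepts a precomputed list of
    (train_idx, test_idx) pairs so repeated analyses (e.g. gene-elimination
    scans) can share one partition.
    """
    config = config or GrepConfig()
    y = _coerce_labels(labels)
    class_counts = np.bincount(y, minlength=2)
    if folds is None:
        if class_counts.min() < k:
            raise ValueError(
                f"smallest class has {class_counts.min()} samples; cannot stratify {k} folds"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
        folds = list(skf.split(np.zeros(y.size), y))

    oof = np.full(y.size, np.nan)
    assignment = np.full(y.size, -1, dtype=int)
    per_fold: list[Metrics] = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        model = fit_grep(X.iloc[:, train_idx], y[train_idx], hypothesis_genes, config)
        prob = _probabilities(model, X.iloc[:, test_idx])
        oof[test_idx] = prob
        assignment[test_idx] = fold_id
        per_fold.append(compute_metrics(prob, y[test_idx], config.threshold))
    if np.isnan(oof).any():
        raise RuntimeError("incomplete fold cover: some samples never tested")
    pooled = compute_metrics(oof, y, config.threshold)
    return CVReport(
        fold_assignments=assignment,
        oof_probabilities=oof,
        labels=y,
        sample_ids=[str(s) for s in X.columns],
        pooled=pooled,
        per_fold=per_fold,
    )


def screen_split_evaluate(
    X: pd.DataFrame,
    labels: Sequence,
    hypothesis_genes: Sequence[str],
    train_samples: Sequence[str],
    test_samples: Sequence[str],
    config: GrepConfig | None = None,
) -> tuple[GrepModel, Metrics]:
    """Train on one screen's samples, test on another's, dropping overlap.

    Samples present in both sets are removed from the test side so the
    evaluation is fully independent of training.
    """
    config = config or GrepConfig()
    train = [s for s in train_samples if s in X.columns]
    test = [s for s in test_samples if s in X.columns and s not in set(train)]
    if not test:
        raise ValueError("test set is empty after removing shared samples")
    y = pd.Series(_coerce_labels(labels), index=[str(c) for c in X.columns])
    model = fit_grep(X[train], y[train].to_numpy(), hypothesis_genes, config)
    prob = _probabilities(model, X[test])
    return model, compute_metrics(prob, y[test].to_numpy(), config.threshold)


def save_model(model: GrepModel, path: str) -> None:
    """Write a model as a self-contained structured text document (JSON)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")


def load_model(path: str) -> GrepModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "genratio-model":
        raise ValueError("not a genratio model file")
    return GrepModel.from_dict(d)
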