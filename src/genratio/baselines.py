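"""Comparator classifiers and simulations that contextualize the ratio model.

Implements the standard analyses a ratio classifier is judged against:
per-feature differential association (t-test / Fisher + Benjamini-Hochberg),
the fixed 2-gene above-the-medians rule, single-gene-feature variants of the
full pipeline (the ablation suite), random-gene-set controls, and a
downsampling simulation of how stably a gene ranks in differential analysis
at reduced cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import fisher_exact, ttest_ind
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .cluster import affinity_propagation, ratio_similarity, select_exemplars
from .expression import filter_genes
from .metrics import Metrics, compute_metrics
from .model import GrepConfig, _coerce_labels, _probabilities, fit_grep
from .ratios import (
    RatioSet,
    compute_log_ratios,
    permutation_significance,
    select_significant,
)

__all__ = [
    "FeatureAssociation",
    "differential_association",
    "two_gene_classifier",
    "TwoGeneModel",
    "fit_variant",
    "variant_probabilities",
    "cross_validate_variant",
    "ablation_suite",
    "random_geneset_control",
    "downsampling_rank_simulation",
]

PIPELINE_VARIANTS = (
    "grep",
    "gene_select_gene_classify_all",
    "gene_select_gene_classify_hypothesis",
    "ratio_select_gene_classify",
)


@dataclass
class FeatureAssociation:
    feature_id: str
    feature_kind: str  # expression | copy_number | mutation | lineage
    statistic: float
    p_value: float
    bh_fdr: float
    flagged_constant: bool = False


def differential_association(
    features: pd.DataFrame,
    labels: Sequence,
    kinds: str | Sequence[str] = "expression",
) -> list[FeatureAssociation]:
    """Per-feature association with the binary labels, BH-corrected.

    Numeric feature kinds (expression, copy_number) get a Student t-test;
    binary kinds (mutation, lineage) get Fisher's exact test on the 2x2
    table.  ``features`` is features x samples.  Constant features get
    p = 1 and a flag.  Results are sorted by p.
    """
    y = _coerce_labels(labels)
    if isinstance(kinds, str):
        kinds = [kinds] * features.shape[0]
    if len(kinds) != features.shape[0]:
        raise ValueError("one kind per feature required")
    stats, ps, flags = [], [], []
    vals = features.to_numpy(dtype=float)
    for row, kind in zip(vals, kinds):
        if np.all(row == row[0]):
            stats.append(0.0)
            ps.append(1.0)
            flags.append(True)
            continue
        if kind in ("mutation", "lineage"):
            a = int(((row != 0) & (y == 1)).sum())
            b = int(((row != 0) & (y == 0)).sum())
            c = int(((row == 0) & (y == 1)).sum())
            d = int(((row == 0) & (y == 0)).sum())
            odds, p = fisher_exact([[a, b], [c, d]])
            stats.append(float(odds) if np.isfinite(odds) else np.inf)
            ps.append(float(p))
        else:
            t, p = ttest_ind(row[y == 1], row[y == 0], equal_var=True)
            stats.append(float(t))
            ps.append(float(p))
        flags.append(False)
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    out = [
        FeatureAssociation(
            feature_id=str(fid),
            feature_kind=kind,
            statistic=s,
            p_value=p,
            bh_fdr=float(qv),
            flagged_constant=fl,
        )
        for fid, kind, s, p, qv, fl in zip(features.index, kinds, stats, ps, q, flags)
    ]
    return sorted(out, key=lambda r: r.p_value)


@dataclass
class TwoGeneModel:
    """Fixed 2-gene rule: sensitive iff both genes exceed their medians.

    Medians come from the training samples.  The continuous score used for
    ROC ranking is min(x_a - median_a, x_b - median_b): it induces the same
    binary call at 0 and a total order (a reconstruction — the original rule
    is purely binary).
    """

    gene_a: str
    gene_b: str
    median_a: float
    median_b: float


def _two_gene_scores(model: TwoGeneModel, X: pd.DataFrame) -> np.ndarray:
    for g in (model.gene_a, model.gene_b):
        if g not in X.index:
            raise KeyError(f"gene missing from matrix: {g}")
    a = X.loc[model.gene_a].to_numpy(dtype=float) - model.median_a
    b = X.loc[model.gene_b].to_numpy(dtype=float) - model.median_b
    return np.minimum(a, b)


def two_gene_classifier(
    X_train: pd.DataFrame,
    labels_train: Sequence,
    gene_a: str = "TNFRSF10B",
    gene_b: str = "CASP8",
    X_test: pd.DataFrame | None = None,
    labels_test: Sequence | None = None,
) -> tuple[TwoGeneModel, pd.DataFrame, Metrics]:
    """Fit and evaluate the 2-gene above-the-medians classifier.

    Without a test set, evaluation is on the training samples (the rule has
    no tunable parameters beyond the two medians).  Returns the model, a
    per-sample table of score/call, and the metrics.  The score feeds the
    ROC through a probability-like squashing that preserves its order.
    """
    model = TwoGeneModel(
        gene_a=gene_a,
        gene_b=gene_b,
        median_a=float(X_train.loc[gene_a].median()),
        median_b=float(X_train.loc[gene_b].median()),
    )
    X_eval = X_train if X_test is None else X_test
    y_eval = _coerce_labels(labels_train if labels_test is None else labels_test)
    score = _two_gene_scores(model, X_eval)
    # strictly-above-both-medians call; score 0 sits exactly on a median
    prob_like = expit(score)
    calls = score > 0
    table = pd.DataFrame(
        {
            "sample_id": [str(s) for s in X_eval.columns],
            "score": score,
            "call": np.where(calls, "sensitive", "insensitive"),
        }
    )
    metrics = compute_metrics(prob_like, y_eval, threshold=0.5)
    return model, table, metrics


def fit_variant(
    X: pd.DataFrame,
    labels: Sequence,
    genes: Sequence[str],
    config: GrepConfig | None = None,
    selection_space: str = "ratio",
    classifier_space: str = "ratio",
) -> dict:
    """Fit one pipeline variant, swapping the feature space of single stages.

    ``selection_space`` picks what the t-test/permutation-FDR/clustering
    stage operates on (pairwise log-ratios or single-gene log-expression);
    ``classifier_space`` picks what the logistic stage sees.  With
    ratio/ratio this is exactly the full pipeline; gene/gene is the standard
    single-gene expression classifier; ratio/gene selects via ratios but
    classifies on the genes appearing in selected ratios.
    """
    config = config or GrepConfig()
    if (selection_space, classifier_space) == ("ratio", "ratio"):
        model = fit_grep(X, labels, genes, config)
        return {"kind": "grep", "model": model}
    y = _coerce_labels(labels)
    Xf = filter_genes(X, config.pct75_min, config.iqr_min) if config.apply_gene_filters else X
    avail = [g for g in genes if g in Xf.index]
    prevalence = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    fallback = {
        "kind": f"{selection_space}_select_{classifier_space}_classify",
        "no_signal": True,
        "intercept": float(np.log(prevalence / (1 - prevalence))),
        "pseudocount": config.pseudocount,
    }
    if len(avail) < 2:
        return fallback

    if selection_space == "gene":
        feats = RatioSet(
            pairs=[(g, "") for g in avail],
            values=np.log(Xf.loc[avail].to_numpy(dtype=float) + config.pseudocount),
            sample_ids=[str(s) for s in X.columns],
            pseudocount=config.pseudocount,
        )
    else:
        feats = compute_log_ratios(Xf, avail, config.pseudocount)
    permutation_significance(feats, y, config.ratio_config())
    # single-gene features keep both orientations meaningful, so select on q
    # without re-orienting gene features
    keep = np.flatnonzero(feats.q_value < config.fdr_cutoff)
    if keep.size == 0:
        return fallback
    if selection_space == "ratio":
        selected = select_significant(feats, config.fdr_cutoff)
    else:
        selected = feats.subset(keep)

    # cluster in the selection feature space, exactly as the full pipeline does
    if len(selected) == 1:
        ex_idx = np.array([0])
    else:
        S = ratio_similarity(selected.values)
        clusters = affinity_propagation(
            S, config.preference, config.damping, config.max_iter, config.convergence_window
        )
        ex_idx = select_exemplars(clusters, selected.t_stat)
    exemplars = selected.subset(ex_idx)

    if classifier_space == "gene":
        # swap only the classifier's feature space: the genes appearing in
        # the exemplar features, as single-gene log expression
        sel_genes = sorted({g for pair in exemplars.pairs for g in pair if g})
        features = np.log(Xf.loc[sel_genes].to_numpy(dtype=float) + config.pseudocount)
        feature_names: list = sel_genes
    elif classifier_space == "ratio":
        if selection_space == "gene":
            raise ValueError("gene selection with ratio classification is not defined")
        features = exemplars.values
        feature_names = exemplars.pairs
    else:
        raise ValueError(f"unknown classifier space: {classifier_space!r}")

    clf = LogisticRegression(C=config.l2_c, solver="lbfgs", max_iter=2000)
    clf.fit(features.T, y)
    return {
        "kind": f"{selection_space}_select_{classifier_space}_classify",
        "no_signal": False,
        "selection_space": selection_space,
        "classifier_space": classifier_space,
        "feature_names": feature_names,
        "coef": clf.coef_.ravel().copy(),
        "intercept": float(clf.intercept_[0]),
        "pseudocount": config.pseudocount,
    }


def variant_probabilities(fit: dict, X: pd.DataFrame) -> np.ndarray:
    """Probability scores of a :func:`fit_variant` result on new samples."""
    if fit.get("kind") == "grep":
        return _probabilities(fit["model"], X)
    if fit.get("no_signal"):
        return np.full(X.shape[1], float(expit(fit["intercept"])))
    c = fit["pseudocount"]
    names = fit["feature_names"]
    if fit["classifier_space"] == "gene":
        values = np.log(X.loc[list(names)].to_numpy(dtype=float) + c)
    else:
        logx = np.log(X.to_numpy(dtype=float) + c)
        pos = {g: i for i, g in enumerate(X.index)}
        values = np.stack([logx[pos[a]] - logx[pos[b]] for a, b in names])
    return expit(fit["intercept"] + fit["coef"] @ values)


def cross_validate_variant(
    X: pd.DataFrame,
    labels: Sequence,
    genes: Sequence[str],
    config: GrepConfig | None = None,
    selection_space: str = "ratio",
    classifier_space: str = "ratio",
    k: int = 5,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[Metrics, list[Metrics], np.ndarray]:
    """Stratified k-fold CV of one pipeline variant (all stages refit per fold)."""
    config = config or GrepConfig()
    y = _coerce_labels(labels)
    if folds is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
        folds = list(skf.split(np.zeros(y.size), y))
    oof = np.full(y.size, np.nan)
    per_fold = []
    for train_idx, test_idx in folds:
        fit = fit_variant(
            X.iloc[:, train_idx], y[train_idx], genes, config,
            selection_space, classifier_space,
        )
        prob = variant_probabilities(fit, X.iloc[:, test_idx])
        oof[test_idx] = prob
        per_fold.append(compute_metrics(prob, y[test_idx], config.threshold))
    pooled = compute_metrics(oof, y, config.threshold)
    return pooled, per_fold, oof


def _fold_ci(per_fold: list[Metrics], attr: str) -> tuple[float, float]:
    vals = np.array([getattr(m, attr) for m in per_fold if getattr(m, attr) is not None])
    if vals.size == 0:
        return (np.nan, np.nan)
    half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
    return (float(vals.mean() - half), float(vals.mean() + half))


def ablation_suite(
    X: pd.DataFrame,
    labels: Sequence,
    hypothesis_genes: Sequence[str],
    config: GrepConfig | None = None,
    k: int = 5,
    two_gene_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """CV comparison of the full model against its stage-swap ablations.

    Five rows: the full ratio pipeline; single-gene selection+classification
    over all genes and over the hypothesis set; ratio selection with
    single-gene classification; and the fixed 2-gene median rule (genes
    given explicitly, or the two top-ranked hypothesis genes by t-test).
    Confidence intervals come from fold dispersion.
    """
    config = config or GrepConfig()
    y = _coerce_labels(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.zeros(y.size), y))
    all_genes = [str(g) for g in X.index]

    spec = [
        ("grep", hypothesis_genes, "ratio", "ratio"),
        ("gene_select_gene_classify_all", all_genes, "gene", "gene"),
        ("gene_select_gene_classify_hypothesis", hypothesis_genes, "gene", "gene"),
        ("ratio_select_gene_classify", hypothesis_genes, "ratio", "gene"),
    ]
    rows = []
    for name, genes, sel, clf_space in spec:
        pooled, per_fold, _ = cross_validate_variant(
            X, y, genes, config, sel, clf_space, folds=folds
        )
        lo, hi = _fold_ci(per_fold, "auc")
        rows.append(
            {
                "model": name,
                "auc": pooled.auc,
                "ppv": pooled.ppv,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
            }
        )

    if two_gene_pair is None:
        assoc = differential_association(
            X.loc[[g for g in hypothesis_genes if g in X.index]], y
        )
        two_gene_pair = (assoc[0].feature_id, assoc[1].feature_id)
    oof = np.full(y.size, np.nan)
    per_fold = []
    for train_idx, test_idx in folds:
        _, _, m = two_gene_classifier(
            X.iloc[:, train_idx], y[train_idx], *two_gene_pair,
            X_test=X.iloc[:, test_idx], labels_test=y[test_idx],
        )
        per_fold.append(m)
        model = TwoGeneModel(
            two_gene_pair[0], two_gene_pair[1],
            float(X.iloc[:, train_idx].loc[two_gene_pair[0]].median()),
            float(X.iloc[:, train_idx].loc[two_gene_pair[1]].median()),
        )
        oof[test_idx] = expit(_two_gene_scores(model, X.iloc[:, test_idx]))
    pooled = compute_metrics(oof, y, 0.5)
    lo, hi = _fold_ci(per_fold, "auc")
    rows.append(
        {
            "model": "two_gene",
            "auc": pooled.auc,
            "ppv": pooled.ppv,
            "auc_ci_low": lo,
            "auc_ci_high": hi,
        }
    )
    return pd.DataFrame(rows)


def random_geneset_control(
    X: pd.DataFrame,
    labels: Sequence,
    set_size: int,
    n_sets: int = 100,
    config: GrepConfig | None = None,
    k: int = 5,
    exclude_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Full-pipeline CV AUC over random gene sets of a fixed size.

    Each set is drawn without replacement from the gene universe (optionally
    excluding known signal genes); per set the whole pipeline is refit under
    CV and the out-of-fold confusion table is tested against prevalence with
    Fisher's exact test.  Returns one row per set with auc, ppv and the
    better-than-random p-value.
    """
    config = config or GrepConfig()
    y = _coerce_labels(labels)
    pool = [g for g in X.index.astype(str) if g not in set(exclude_genes)]
    if set_size > len(pool):
        raise ValueError("set_size exceeds available genes")
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n_sets):
        genes = list(rng.choice(pool, size=set_size, replace=False))
        sub_cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
        pooled, _, oof = cross_validate_variant(X, y, genes, sub_cfg, k=k)
        pred = oof > config.threshold
        table = [
            [int((pred & (y == 1)).sum()), int((pred & (y == 0)).sum())],
            [int((~pred & (y == 1)).sum()), int((~pred & (y == 0)).sum())],
        ]
        _, p = fisher_exact(table, alternative="greater")
        rows.append(
            {"set_index": i, "auc": pooled.auc, "ppv": pooled.ppv, "p_vs_random": float(p)}
        )
    return pd.DataFrame(rows, columns=["set_index", "auc", "ppv", "p_vs_random"])


def downsampling_rank_simulation(
    X: pd.DataFrame,
    labels: Sequence,
    gene: str,
    subset_sizes: Sequence[int] = (100, 200),
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """How stably one gene ranks in all-gene differential analysis at small n.

    Per replicate a label-stratified subsample (without replacement) is
    drawn, a Student t-test is run on every gene, and the target gene's rank
    by p plus its nominal significance are recorded.  Returns per-size mean
    rank and fraction of replicates with p < 0.05.
    """
    if gene not in X.index:
        raise KeyError(f"gene missing from matrix: {gene}")
    y = _coerce_labels(labels)
    rng = np.random.default_rng(seed)
    vals = X.to_numpy(dtype=float)
    gi = list(X.index).index(gene)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    out = []
    for size in subset_sizes:
        if size > y.size:
            raise ValueError(f"subset size {size} exceeds sample count {y.size}")
        n_pos = max(2, int(round(size * pos_idx.size / y.size)))
        n_neg = size - n_pos
        ranks, sig = [], []
        for _ in range(n_reps):
            take = np.concatenate(
                [
                    rng.choice(pos_idx, size=n_pos, replace=False),
                    rng.choice(neg_idx, size=n_neg, replace=False),
                ]
            )
            sub = vals[:, take]
            ys = y[take]
            t, p = ttest_ind(sub[:, ys == 1], sub[:, ys == 0], axis=1, equal_var=True)
            p = np.where(np.isnan(p), 1.0, p)
            order = np.argsort(p, kind="mergesort")
            rank = int(np.flatnonzero(order == gi)[0]) + 1
            ranks.append(rank)
            sig.append(p[gi] < 0.05)
        out.append(
            {
                "subset_size": int(size),
                "mean_rank": float(np.mean(ranks)),
                "fraction_significant": float(np.mean(sig)),
            }
        )
    return pd.DataFrame(out)
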