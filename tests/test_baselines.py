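"""Comparator classifiers, BH correction, ablation suite, simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from genratio.baselines import (
    ablation_suite,
    differential_association,
    downsampling_rank_simulation,
    random_geneset_control,
    two_gene_classifier,
)
from genratio.model import GrepConfig
from genratio.simulate import SyntheticConfig, generate_expression


def bh_step_up(p):
    """Reference Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestDifferentialAssociation:
    def test_constant_feature_flagged_p_one(self):
        X = pd.DataFrame(
            [[5.0] * 6, [1, 2, 3, 4, 5, 6]], index=["flat", "var"], columns=list("abcdef")
        )
        res = differential_association(X, [1, 1, 1, 0, 0, 0])
        flat = next(r for r in res if r.feature_id == "flat")
        assert flat.p_value == 1.0 and flat.flagged_constant

    def test_bh_hand_example(self):
        # BH on {0.01, 0.02, 0.03} with m=3 -> all 0.03
        np.testing.assert_allclose(bh_step_up([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_matches_reference_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(2, 40))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, bh_step_up(p), atol=1e-12)

    def test_fisher_on_mutation_matches_hypergeometric(self):
        y = np.array([1] * 10 + [0] * 20)
        mut = np.array([1] * 7 + [0] * 3 + [1] * 4 + [0] * 16)
        X = pd.DataFrame([mut], index=["mut"], columns=[f"s{i}" for i in range(30)])
        res = differential_association(X, y, kinds=["mutation"])
        # two-sided Fisher from scipy; sanity-check one tail bound
        a, b, c, d = 7, 4, 3, 16
        tail = sum(
            hypergeom.pmf(k, a + b + c + d, a + c, a + b) for k in range(a, min(a + c, a + b) + 1)
        )
        assert res[0].p_value >= tail - 1e-12

    def test_ranking_by_p(self, planted_dataset):
        d = planted_dataset
        res = differential_association(d.X.iloc[:20], d.labels)
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)


class TestTwoGeneClassifier:
    def _matrix(self, a, b):
        X = np.vstack([a, b])
        return pd.DataFrame(
            X, index=["GA", "GB"], columns=[f"s{i}" for i in range(len(a))]
        )

    def test_boundary_sample_at_medians_is_insensitive(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        X = self._matrix(a, a)
        _, table, _ = two_gene_classifier(X, [0, 0, 1, 1], "GA", "GB")
        med_idx = np.argmin(np.abs(a - np.median(a)))
        # scores at or below zero are called insensitive (strict inequality)
        assert (table.score <= 0).sum() >= 2
        assert all(
            row.call == "insensitive" for _, row in table.iterrows() if row.score <= 0
        )

    def test_oracle_aligned_data_gives_ppv_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, 40)
        b = rng.uniform(0, 100, 40)
        y = ((a > np.median(a)) & (b > np.median(b))).astype(int)
        _, _, m = two_gene_classifier(self._matrix(a, b), y, "GA", "GB")
        assert m.ppv == 1.0

    def test_random_labels_ppv_near_prevalence(self):
        rng = np.random.default_rng(2)
        ppvs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.uniform(0, 100, 200)
            b = r.uniform(0, 100, 200)
            y = (r.random(200) < 0.3).astype(int)
            _, _, m = two_gene_classifier(self._matrix(a, b), y, "GA", "GB")
            if m.ppv is not None:
                ppvs.append(m.ppv)
        assert np.mean(ppvs) == pytest.approx(0.3, abs=0.05)

    def test_missing_gene_raises(self, planted_dataset):
        with pytest.raises(KeyError):
            two_gene_classifier(planted_dataset.X, planted_dataset.labels, "NOPE", "G0000")


@pytest.fixture(scope="module")
def suite():
    cfg = SyntheticConfig(
        n_samples=200, n_genes=80, hypothesis_set_size=24, n_true_ratios=3,
        effect_size=2.0, per_sample_scale_range=(0.02, 50.0), seed=2,
    )
    d = generate_expression(cfg)
    return ablation_suite(d.X, d.labels, d.hypothesis_genes, GrepConfig(seed=2))


class TestAblationSuite:
    def test_suite_has_five_models(self, suite):
        assert len(suite) == 5
        assert set(suite.model) == {
            "grep",
            "gene_select_gene_classify_all",
            "gene_select_gene_classify_hypothesis",
            "ratio_select_gene_classify",
            "two_gene",
        }

    def test_ratio_models_beat_gene_models_under_scale_confounding(self, suite):
        t = suite.set_index("model")
        assert t.loc["grep", "auc"] > t.loc["gene_select_gene_classify_all", "auc"] + 0.1
        assert (
            t.loc["grep", "auc"]
            > t.loc["gene_select_gene_classify_hypothesis", "auc"] + 0.1
        )

    def test_confidence_intervals_bracket_estimate(self, suite):
        for _, row in suite.iterrows():
            if not np.isnan(row.auc_ci_low):
                assert row.auc_ci_low <= row.auc_ci_high


class TestRandomGeneSets:
    def test_zero_sets_empty_output(self, planted_dataset):
        d = planted_dataset
        out = random_geneset_control(d.X, d.labels, set_size=10, n_sets=0)
        assert len(out) == 0

    def test_signal_free_sets_center_at_chance(self, planted_dataset):
        d = planted_dataset
        signal = {g for pair in d.true_ratios for g in pair}
        out = random_geneset_control(
            d.X, d.labels, set_size=10, n_sets=5,
            config=GrepConfig(seed=0), exclude_genes=sorted(signal),
        )
        assert np.mean(out.auc) == pytest.approx(0.5, abs=0.08)
        assert (out.p_vs_random < 0.05).mean() <= 0.4


class TestDownsampling:
    def test_full_subset_ranks_strong_gene_first(self):
        cfg = SyntheticConfig(
            n_samples=150, n_genes=60, hypothesis_set_size=10,
            signal="single_gene", effect_size=4.0,
            per_sample_scale_range=(1.0, 1.0), seed=3,
        )
        d = generate_expression(cfg)
        out = downsampling_rank_simulation(
            d.X, d.labels, "G0000", subset_sizes=[150], n_reps=3, seed=0
        )
        assert out.mean_rank.iloc[0] == 1.0
        assert out.fraction_significant.iloc[0] == 1.0

    def test_null_gene_calibrated(self):
        cfg = SyntheticConfig(
            n_samples=200, n_genes=40, hypothesis_set_size=10, signal="none",
            per_sample_scale_range=(1.0, 1.0), seed=4,
        )
        d = generate_expression(cfg)
        out = downsampling_rank_simulation(
            d.X, d.labels, "G0010", subset_sizes=[100], n_reps=40, seed=1
        )
        assert out.fraction_significant.iloc[0] <= 0.2

    def test_power_non_decreasing_in_subset_size(self):
        cfg = SyntheticConfig(
            n_samples=300, n_genes=40, hypothesis_set_size=10,
            signal="single_gene", effect_size=1.0,
            per_sample_scale_range=(1.0, 1.0), seed=5,
        )
        d = generate_expression(cfg)
        out = downsampling_rank_simulation(
            d.X, d.labels, "G0000", subset_sizes=[60, 240], n_reps=25, seed=2
        )
        assert (
            out.fraction_significant.iloc[1]
            >= out.fraction_significant.iloc[0] - 0.15
        )

    def test_absent_gene_rejected(self, planted_dataset):
        with pytest.raises(KeyError):
            downsampling_rank_simulation(
                planted_dataset.X, planted_dataset.labels, "NOPE"
            )
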