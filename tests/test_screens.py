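"""Screen processing: curve fitting, calls, consensus, enrichment, xenografts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from genratio.screens import (
    CONFLICT,
    INSENSITIVE,
    INTERMEDIATE,
    SENSITIVE,
    DoseResponse,
    call_sensitivity,
    consensus_call,
    fit_dose_response,
    in_vivo_response,
    lineage_enrichment,
    read_dose_response,
    sigmoid_inhibition,
)
from genratio.simulate import default_dose_grid

GRID = default_dose_grid()


def _noiseless_curve(a_max, ec50, hill=1.0):
    return DoseResponse("line", "screen", GRID, sigmoid_inhibition(GRID, a_max, ec50, hill))


class TestDoseResponseFit:
    def test_recovers_known_parameters(self):
        fit = fit_dose_response(_noiseless_curve(80.0, 1e-10, 1.0))
        assert fit.converged
        assert fit.a_max == pytest.approx(80.0, rel=0.01)
        assert fit.ec50 == pytest.approx(1e-10, rel=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_over_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(55, 95)
        ec50 = np.exp(rng.uniform(np.log(GRID[1]), np.log(GRID[-2])))
        hill = rng.uniform(0.7, 2.0)
        fit = fit_dose_response(_noiseless_curve(a, ec50, hill))
        assert fit.a_max == pytest.approx(a, rel=0.01)
        assert fit.ec50 == pytest.approx(ec50, rel=0.05)

    def test_flat_curve_gives_zero_amax_and_max_dose_ic50(self):
        curve = DoseResponse("line", "screen", GRID, np.zeros_like(GRID))
        fit = fit_dose_response(curve)
        assert fit.a_max == pytest.approx(0.0, abs=1e-6)
        assert fit.ic50 == GRID[-1]

    def test_low_plateau_pins_ic50_at_max_dose(self):
        # a plateau below 50% inhibition never crosses the IC50 level
        fit = fit_dose_response(_noiseless_curve(40.0, 1e-10))
        assert fit.a_max == pytest.approx(40.0, rel=0.01)
        assert fit.ic50 == GRID[-1]

    def test_ic50_never_exceeds_max_tested_dose(self):
        fit = fit_dose_response(_noiseless_curve(55.0, GRID[-2], hill=0.8))
        assert fit.ic50 <= GRID[-1]

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            DoseResponse("l", "s", GRID[:2], np.zeros(2))

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            DoseResponse("l", "s", GRID[::-1], np.zeros_like(GRID))


class TestSensitivityCall:
    @pytest.mark.parametrize(
        "a_max,expected",
        [
            (75.0, SENSITIVE),
            (40.0, INSENSITIVE),
            (60.0, INTERMEDIATE),
            (70.0, SENSITIVE),  # boundary taken inclusively
            (50.0, INSENSITIVE),
            (50.0001, INTERMEDIATE),
        ],
    )
    def test_threshold_rule(self, a_max, expected):
        assert call_sensitivity(a_max) == expected

    @given(st.floats(-10, 110), st.floats(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_amax(self, a_max, bump):
        order = {INSENSITIVE: 0, INTERMEDIATE: 1, SENSITIVE: 2}
        assert order[call_sensitivity(a_max + bump)] >= order[call_sensitivity(a_max)]


class TestConsensus:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([SENSITIVE, SENSITIVE, INSENSITIVE], SENSITIVE),
            ([SENSITIVE, INSENSITIVE], CONFLICT),
            ([INTERMEDIATE], INTERMEDIATE),
            ([SENSITIVE, INSENSITIVE, INTERMEDIATE], CONFLICT),
            ([INSENSITIVE, INSENSITIVE, INSENSITIVE], INSENSITIVE),
        ],
    )
    def test_majority_rule(self, calls, expected):
        assert consensus_call(calls).call == expected

    @given(
        st.lists(
            st.sampled_from([SENSITIVE, INTERMEDIATE, INSENSITIVE]),
            min_size=1,
            max_size=7,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_order_invariant_and_majority_duplication_idempotent(self, calls, rnd):
        base = consensus_call(calls).call
        shuffled = list(calls)
        rnd.shuffle(shuffled)
        assert consensus_call(shuffled).call == base
        if base != CONFLICT:
            # duplicating the winning call cannot change the outcome
            assert consensus_call(calls + [base]).call == base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_call([])


def brute_force_fisher_greater(a, b, c, d):
    """One-sided (enrichment) Fisher p by hypergeometric tail enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    return sum(
        hypergeom.pmf(k, N, K, n) for k in range(a, min(K, n) + 1)
    )


class TestLineageEnrichment:
    def _consensus(self, calls):
        from genratio.screens import ConsensusCall

        return [
            ConsensusCall(cell_line_id=f"L{i}", call=c, n_screens=1)
            for i, c in enumerate(calls)
        ]

    def test_p_matches_hypergeometric_tail(self):
        # lineage: 8 sensitive / 2 insensitive; rest: 20 / 70
        calls = [SENSITIVE] * 8 + [INSENSITIVE] * 2 + [SENSITIVE] * 20 + [INSENSITIVE] * 70
        lineages = {f"L{i}": ("panc" if i < 10 else "other") for i in range(100)}
        res = lineage_enrichment(self._consensus(calls), lineages, min_n=10)
        row = res[res.lineage == "panc"].iloc[0]
        assert row.p_sensitive == pytest.approx(
            brute_force_fisher_greater(8, 2, 20, 70), rel=1e-10
        )

    def test_no_enrichment_is_not_significant(self):
        calls = ([SENSITIVE] * 2 + [INSENSITIVE] * 8) + ([SENSITIVE] * 18 + [INSENSITIVE] * 72)
        lineages = {f"L{i}": ("panc" if i < 10 else "other") for i in range(100)}
        res = lineage_enrichment(self._consensus(calls), lineages, min_n=10)
        assert res[res.lineage == "panc"].p_sensitive.iloc[0] > 0.3

    def test_concentrated_sensitivity_is_significant(self):
        calls = [SENSITIVE] * 10 + [INSENSITIVE] * 90
        lineages = {f"L{i}": ("panc" if i < 10 else "other") for i in range(100)}
        res = lineage_enrichment(self._consensus(calls), lineages, min_n=10)
        assert res[res.lineage == "panc"].p_sensitive.iloc[0] < 0.05

    def test_small_lineages_excluded(self):
        calls = [SENSITIVE] * 5 + [INSENSITIVE] * 20
        lineages = {f"L{i}": ("tiny" if i < 5 else "big") for i in range(25)}
        res = lineage_enrichment(self._consensus(calls), lineages, min_n=10)
        assert "tiny" not in set(res.lineage)


class TestInVivoResponse:
    def test_growing_tumor_t_over_c(self):
        r = in_vivo_response("m", 100, 150, 100, 300)
        assert r.t_over_c == pytest.approx(25.0)
        assert r.regression is None
        assert not r.responder

    def test_shrinking_tumor_regression(self):
        r = in_vivo_response("m", 200, 150, 100, 300)
        assert r.t_over_c is None
        assert r.regression == pytest.approx(-25.0)
        assert r.responder

    def test_stasis_is_responder(self):
        r = in_vivo_response("m", 100, 100, 100, 300)
        assert r.t_over_c == pytest.approx(0.0)
        assert r.responder

    def test_no_control_growth_flagged(self):
        r = in_vivo_response("m", 100, 150, 300, 250)
        assert not r.valid
        assert r.t_over_c is None


def test_read_dose_response_averages_replicates(tmp_path):
    rows = []
    for rep, offset in ((0, -5.0), (1, 5.0)):
        for d, inh in zip(GRID, sigmoid_inhibition(GRID, 80, 1e-10, 1.0)):
            rows.append(("L1", "scr", d, inh + offset, rep))
    path = tmp_path / "dr.tsv"
    pd.DataFrame(
        rows, columns=["cell_line_id", "screen_id", "dose", "inhibition", "replicate"]
    ).to_csv(path, sep="\t", index=False)
    curves = read_dose_response(str(path))
    assert len(curves) == 1
    # +5/-5 offsets cancel in the per-dose mean
    np.testing.assert_allclose(
        curves[0].inhibition, sigmoid_inhibition(GRID, 80, 1e-10, 1.0), atol=1e-9
    )
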