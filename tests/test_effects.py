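"""Worksheet statistics: contrasts, change-in-mean, s, error limits, decision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evopt.design import attach_cycle, build_worksheet
from evopt.effects import (
    Decision,
    EffectsError,
    EffectsReport,
    ErrorLimits,
    build_report,
    change_in_mean,
    decide,
    error_limits,
    estimate_sd,
    interaction_effect,
    main_effect,
    per_run_averages,
    per_run_differences,
)
from tests.conftest import PHASE1_FACTORS

# Printed phase-I rows (2 dp).
PRINTED_AVERAGES = [398.03, 144.45, 49.38, 93.74, 144.10, 398.47, 195.13, 114.85, 106.97, 104.91]
PRINTED_DIFFERENCES = [16.28, 29.04, -1.49, -9.89, 18.48, 28.63, -11.62, -14.33, 6.57, -11.23]


def brute_force_contrast(responses, ws, signs_of):
    """Oracle: mean over + runs minus mean over - runs, via explicit subsets."""
    plus = [responses[i] for i, r in enumerate(ws.runs) if signs_of(r.coded) > 0]
    minus = [responses[i] for i, r in enumerate(ws.runs) if signs_of(r.coded) < 0]
    return float(np.mean(plus) - np.mean(minus))


class TestWorksheetArithmetic:
    def test_averages_match_printed_rows(self, table4_ws):
        avg = per_run_averages(table4_ws)
        assert avg == pytest.approx(PRINTED_AVERAGES, abs=0.00501)

    def test_differences_match_printed_rows(self, table4_ws):
        diff = per_run_differences(table4_ws, 0, 1)
        assert diff == pytest.approx(PRINTED_DIFFERENCES, abs=0.00501)

    def test_single_cycle_average_is_that_cycle(self):
        ws = attach_cycle(build_worksheet(PHASE1_FACTORS), np.arange(10.0))
        assert per_run_averages(ws) == pytest.approx(np.arange(10.0))

    def test_same_cycle_difference_is_zero(self, table4_ws):
        assert per_run_differences(table4_ws, 1, 1) == pytest.approx(np.zeros(10))

    def test_invalid_cycle_index_rejected(self, table4_ws):
        with pytest.raises(EffectsError, match="cycle index"):
            per_run_differences(table4_ws, 0, 2)

    def test_empty_worksheet_rejected(self):
        with pytest.raises(EffectsError, match="no cycles"):
            per_run_averages(build_worksheet(PHASE1_FACTORS))


class TestContrasts:
    # Derived oracles on the printed cycle-1 responses (the published
    # effect values do not follow from the worksheet under its run coding;
    # the standard 2^3 contrast is the auditable definition used here).
    @pytest.mark.parametrize("factor, expected", [("T", 31.78), ("P", 6.22), ("R", -21.86)])
    def test_main_effects_cycle1(self, table4_ws, factor, expected):
        c1 = table4_ws.responses()[0]
        assert main_effect(c1, table4_ws, factor) == pytest.approx(expected, abs=0.00501)

    def test_interaction_tp_cycle1(self, table4_ws):
        c1 = table4_ws.responses()[0]
        assert interaction_effect(c1, table4_ws, "TP") == pytest.approx(65.58, abs=0.00501)

    def test_constant_responses_have_zero_effects(self, table4_ws):
        const = np.full(10, 123.4)
        for f in ("T", "P", "R"):
            assert main_effect(const, table4_ws, f) == 0.0
        for p in ("TP", "TR", "PR"):
            assert interaction_effect(const, table4_ws, p) == 0.0

    def test_unknown_factor_rejected(self, table4_ws):
        c1 = table4_ws.responses()[0]
        with pytest.raises(EffectsError):
            main_effect(c1, table4_ws, "Q")
        with pytest.raises(EffectsError):
            interaction_effect(c1, table4_ws, "TQ")

    @settings(max_examples=30, deadline=None)
    @given(responses=st.lists(st.floats(0, 500), min_size=10, max_size=10))
    def test_contrast_equals_brute_force_subsets(self, responses):
        ws = build_worksheet(PHASE1_FACTORS)
        for name, col in (("T", 0), ("P", 1), ("R", 2)):
            oracle = brute_force_contrast(responses, ws, lambda c, col=col: c[col])
            assert main_effect(responses, ws, name) == pytest.approx(oracle, abs=1e-9)
        for name, (a, b) in (("TP", (0, 1)), ("TR", (0, 2)), ("PR", (1, 2))):
            oracle = brute_force_contrast(responses, ws, lambda c, a=a, b=b: c[a] * c[b])
            assert interaction_effect(responses, ws, name) == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0.1, 5),
        b=st.floats(-50, 50),
        seed=st.integers(0, 2**16),
    )
    def test_affine_equivariance(self, a, b, seed):
        """responses -> a*responses + b scales every effect by a."""
        ws = build_worksheet(PHASE1_FACTORS)
        r = np.random.default_rng(seed).uniform(0, 400, 10)
        for f in ("T", "P", "R"):
            assert main_effect(a * r + b, ws, f) == pytest.approx(a * main_effect(r, ws, f), rel=1e-9, abs=1e-9)
        assert change_in_mean(a * r + b, ws) == pytest.approx(a * change_in_mean(r, ws), rel=1e-9, abs=1e-9)


class TestChangeInMean:
    def test_cycle2_matches_printed(self, table4_ws):
        c2 = table4_ws.responses()[1]
        assert change_in_mean(c2, table4_ws) == pytest.approx(-214.54, abs=0.00501)

    def test_cycle1_within_published_rounding(self, table4_ws):
        # recomputation gives -231.95; the published table prints -231.94
        c1 = table4_ws.responses()[0]
        assert change_in_mean(c1, table4_ws) == pytest.approx(-231.94, abs=0.02)

    def test_equal_responses_give_zero(self, table4_ws):
        assert change_in_mean(np.full(10, 7.0), table4_ws) == 0.0


class TestStandardDeviation:
    def test_fixed_returns_supplied_value(self, table4_ws):
        assert estimate_sd(table4_ws, "fixed", fixed=100.65) == 100.65

    def test_pooled_matches_hand_computation(self, table4_ws):
        d = np.asarray(PRINTED_DIFFERENCES)
        oracle = float(np.sqrt((d**2).sum() / 20.0))
        assert estimate_sd(table4_ws, "pooled") == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(12.00, abs=0.00501)

    def test_identical_cycles_give_zero(self):
        ws = build_worksheet(PHASE1_FACTORS)
        row = np.linspace(50, 400, 10)
        ws = attach_cycle(attach_cycle(ws, row), row)
        assert estimate_sd(ws, "pooled") == 0.0
        assert estimate_sd(ws, "range") == 0.0

    def test_range_method_uses_tabulated_factor(self, table4_ws):
        d = np.asarray(PRINTED_DIFFERENCES)
        assert estimate_sd(table4_ws, "range") == pytest.approx(0.23 * (d.max() - d.min()), abs=1e-9)

    def test_data_driven_methods_need_two_cycles(self):
        ws = attach_cycle(build_worksheet(PHASE1_FACTORS), np.full(10, 1.0))
        with pytest.raises(EffectsError, match="2 cycles"):
            estimate_sd(ws, "pooled")


class TestErrorLimits:
    @pytest.mark.parametrize(
        "s, printed",
        [
            (100.65, (142.32, 101.04, 89.68)),  # cycle I column
            (93.03, (131.54, 93.40, 82.89)),  # cycle II column
        ],
    )
    def test_printed_limits_at_n2(self, s, printed):
        lim = error_limits(s, 2)
        assert lim.for_average == pytest.approx(printed[0], abs=0.05)
        assert lim.for_effects == pytest.approx(printed[1], abs=0.5)
        assert lim.for_change_in_mean == pytest.approx(printed[2], abs=0.5)

    def test_zero_s_gives_zero_limits(self):
        lim = error_limits(0.0, 3)
        assert (lim.for_average, lim.for_effects, lim.for_change_in_mean) == (0, 0, 0)

    @settings(max_examples=30, deadline=None)
    @given(s=st.floats(0.01, 500), k=st.floats(0.1, 10), n=st.integers(1, 9))
    def test_homogeneous_in_s_and_decreasing_in_n(self, s, k, n):
        lim, lim_k, lim_n = error_limits(s, n), error_limits(k * s, n), error_limits(s, n + 1)
        for field in ("for_average", "for_effects", "for_change_in_mean"):
            assert getattr(lim_k, field) == pytest.approx(k * getattr(lim, field), rel=1e-9)
            assert getattr(lim_n, field) < getattr(lim, field)


def _report(effects, cim, s=100.0, n=2):
    t, p, r, tp, tr, pr = effects
    return EffectsReport(
        per_run_average=tuple(np.zeros(10)),
        per_run_difference=tuple(np.zeros(10)),
        effect_T=t, effect_P=p, effect_R=r,
        effect_TP=tp, effect_TR=tr, effect_PR=pr,
        change_in_mean=cim, s=s, n_cycles=n,
    )


class TestDecision:
    def test_published_effects_yield_optimum_reached(self):
        # the published cycle-I effects column fed verbatim
        report = _report((-26.05, 11.70, 30.50, 13.22, 34.59, 61.39), -231.94, s=100.65)
        limits = ErrorLimits(142.32, 101.04, 89.68)
        decision = decide(report, limits)
        assert decision.verdict == "optimum_reached"
        assert decision.shift_direction == {"T": 0, "P": 0, "R": 0}

    def test_effect_equal_to_limit_is_not_significant(self):
        report = _report((101.04, 0, 0, 0, 0, 0), 0.0)
        decision = decide(report, ErrorLimits(142.32, 101.04, 89.68))
        assert decision.verdict == "continue_cycles"

    def test_strong_effect_triggers_shift_with_direction(self):
        report = _report((250.0, -120.0, 0, 0, 0, 0), -300.0)
        decision = decide(report, ErrorLimits(142.32, 101.04, 89.68))
        assert decision.verdict == "shift"
        assert decision.shift_direction == {"T": 1, "P": -1, "R": 0}

    def test_small_cim_means_continue(self):
        report = _report((1, 1, 1, 1, 1, 1), -10.0)
        assert decide(report, ErrorLimits(142.32, 101.04, 89.68)).verdict == "continue_cycles"

    def test_relabelling_factors_permutes_directions(self):
        effects = (250.0, -120.0, 30.0, 0, 0, 0)
        limits = ErrorLimits(142.32, 101.04, 89.68)
        base = decide(_report(effects, 0.0), limits)
        # swap T and P everywhere: directions must swap identically
        swapped = decide(_report((-120.0, 250.0, 30.0, 0, 0, 0), 0.0), limits)
        assert swapped.shift_direction == {
            "T": base.shift_direction["P"],
            "P": base.shift_direction["T"],
            "R": base.shift_direction["R"],
        }


class TestBuildReport:
    def test_report_on_averages(self, table4_ws):
        rep = build_report(table4_ws, sd_method="fixed", sd=100.65)
        assert rep.n_cycles == 2
        assert rep.s == 100.65
        assert rep.per_run_average == pytest.approx(PRINTED_AVERAGES, abs=0.00501)
        avg = np.asarray(rep.per_run_average)
        assert rep.effect_T == pytest.approx(main_effect(avg, table4_ws, "T"))

    def test_report_decision_chain_reaches_optimum(self, table4_ws):
        """Full chain on the published worksheet: no effect beats its limit."""
        c1 = table4_ws.responses()[0]
        rep = build_report(table4_ws, responses=c1, sd_method="fixed", sd=100.65)
        limits = error_limits(rep.s, rep.n_cycles)
        assert decide(rep, limits).verdict == "optimum_reached"
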