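"""Dwell-time fits, corrections, classification, and rate estimators."""

import numpy as np
import pytest

from slipfret import (DwellSet, classify_trace, collect_dwells, correct_rate,
                      fit_dwell_exponential, fraction_reaching_state,
                      transition_frequency, transition_rate)
from slipfret.inference import Dwell, GaussianStateModel, IdealizedTrace
from slipfret.kinetics import (DwellFitError, deadtime_correct,
                               fit_event_exponential)


def model4():
    return GaussianStateModel([("PRE", 0.8, 0.1, 0.25),
                               ("A/P*", 0.6, 0.1, 0.25),
                               ("CHI", 0.4, 0.1, 0.25),
                               ("P/P", 0.2, 0.1, 0.25)])


def ideal_from(spec, dt=0.033):
    dwells, start = [], 0
    means = {"PRE": 0.8, "A/P*": 0.6, "CHI": 0.4, "P/P": 0.2}
    for lbl, n in spec:
        dwells.append(Dwell(lbl, start, n, means[lbl]))
        start += n
    return IdealizedTrace(dwells, dt, start)


class TestDwellFit:
    def test_unit_rate_recovery(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(1.0, 5000)
        ds = DwellSet("s", None, times, np.zeros(5000, bool))
        est = fit_dwell_exponential(ds, 0.033, n_boot=200, seed=1)
        assert est.k_obs == pytest.approx(1.0, abs=0.05)
        assert est.ci[0] < 1.0 < est.ci[1]

    def test_fast_fluctuation_rate_recovery(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(1 / 2.6, 2000)
        times = times[times >= 0.033]
        ds = DwellSet("s", None, times, np.zeros(times.size, bool))
        est = fit_dwell_exponential(ds, 0.033, n_boot=0)
        assert est.k_obs == pytest.approx(2.6, abs=0.15)

    def test_degenerate_distribution_rejected(self):
        ds = DwellSet("s", None, np.full(100, 0.33), np.zeros(100, bool))
        with pytest.raises(DwellFitError, match="degenerate"):
            fit_dwell_exponential(ds, 0.033, n_boot=0)

    def test_too_few_dwells_rejected(self):
        ds = DwellSet("s", None, np.ones(5), np.zeros(5, bool))
        with pytest.raises(DwellFitError, match=">= 20"):
            fit_dwell_exponential(ds, 0.033, n_boot=0)

    def test_censored_dwells_never_enter_fit(self):
        rng = np.random.default_rng(3)
        good = rng.exponential(1.0, 1000)
        junk = np.full(1000, 50.0)  # censored tail that would wreck the fit
        ds = DwellSet("s", None, np.r_[good, junk],
                      np.r_[np.zeros(1000, bool), np.ones(1000, bool)])
        est = fit_dwell_exponential(ds, 0.033, n_boot=0)
        assert est.k_obs == pytest.approx(1.0, abs=0.1)
        assert est.n == 1000

    def test_event_fit_matches_mle_efficiency(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(1 / 0.9, 300)
        est = fit_event_exponential(times, 0.033, n_boot=0)
        assert est.k_obs == pytest.approx(0.9, abs=0.15)


class TestCorrectRate:
    def test_standard_correction_arithmetic(self):
        assert correct_rate(0.26, 0.03, 33.0) == pytest.approx(
            0.26 - 0.03 - 1 / 33, abs=1e-12)
        assert correct_rate(0.26, 0.03, 33.0) == pytest.approx(0.1997,
                                                               abs=1e-4)

    def test_identity_without_losses(self):
        assert correct_rate(1.5, 0.0, 1e12) == pytest.approx(1.5)

    def test_below_resolution_goes_negative(self):
        assert correct_rate(0.05, 0.03, 33.0) == pytest.approx(-0.0103,
                                                               abs=1e-4)

    def test_linear_and_order_independent(self):
        k = 0.7
        a = correct_rate(correct_rate(k, 0.03, 1e12), 0.0, 33.0)
        b = correct_rate(correct_rate(k, 0.0, 33.0), 0.03, 1e12)
        assert a == pytest.approx(b)
        assert a == pytest.approx(correct_rate(k, 0.03, 33.0))


class TestDeadtimeCorrect:
    def test_no_excursions_missed_is_near_identity(self):
        # slow excursions: essentially nothing shorter than the dead time
        assert deadtime_correct(1.0, 0.01, 0.066) == pytest.approx(1.0,
                                                                   rel=0.01)

    def test_correction_raises_rate(self):
        assert deadtime_correct(1.6, 3.0, 0.1) > 1.6

    def test_runaway_correction_falls_back(self):
        assert deadtime_correct(5.0, 50.0, 0.1) == 5.0


class TestTransitionRate:
    def test_zero_events_gives_nd_result(self, wt_slow_analysis):
        est = transition_rate(wt_slow_analysis["ideals"], "P/P", "PRE",
                              n_boot=0)
        assert est.nd
        assert not np.isfinite(est.k_obs)

    def test_recovers_generating_rate(self, wt_slow_analysis):
        est = transition_rate(wt_slow_analysis["ideals"], "CHI", "A/P*",
                              n_boot=0)
        assert est.k_corrected == pytest.approx(2.6, abs=0.8)
        assert est.n > 100


class TestClassifyTrace:
    def test_single_switch_is_direct(self):
        ideal = ideal_from([("PRE", 50), ("P/P", 100)])
        assert classify_trace(ideal, model4()).label == "direct"

    def test_chi_fluctuations_are_chi_sampling(self):
        ideal = ideal_from([("PRE", 30), ("CHI", 20), ("P/P", 15),
                            ("CHI", 10), ("P/P", 120)])
        tc = classify_trace(ideal, model4())
        assert tc.label == "chi_sampling"
        assert tc.sync_frame == 30

    def test_pre_fluctuations_only_is_no_translocation(self):
        ideal = ideal_from([("PRE", 40), ("A/P*", 30), ("PRE", 40),
                            ("A/P*", 50)])
        assert classify_trace(ideal, model4()).label == "no_translocation"

    def test_single_frame_chi_artifact_not_sampling(self):
        ideal = ideal_from([("PRE", 50), ("CHI", 1), ("P/P", 100)])
        assert classify_trace(ideal, model4()).label == "direct"


class TestFrequenciesAndFractions:
    def test_transition_frequency_both_normalizations(self):
        ideal = ideal_from([("PRE", 5), ("A/P*", 5)] * 3 + [("PRE", 5)])
        freq = transition_frequency([ideal])
        assert freq[("PRE", "A/P*")]["fraction"] == pytest.approx(0.5)
        assert freq[("A/P*", "PRE")]["fraction"] == pytest.approx(0.5)
        assert freq[("PRE", "A/P*")]["per_trace"] == pytest.approx(3.0)

    def test_no_transitions_is_an_error(self):
        with pytest.raises(ValueError):
            transition_frequency([ideal_from([("PRE", 50)])])

    def test_all_terminal_fraction_is_one(self):
        ideals = [ideal_from([("PRE", 20), ("P/P", 50)]) for _ in range(5)]
        frac, (lo, hi), n = fraction_reaching_state(ideals, "P/P")
        assert frac == 1.0 and n == 5
        assert lo < 1.0 <= hi + 1e-12


def test_collect_dwells_marks_last_dwell_censored(wt_slow_analysis):
    ds = collect_dwells(wt_slow_analysis["ideals"], "P/P")
    # every trace's trailing dwell is censored; many traces end in P/P
    assert ds.censored.sum() > 0
    directed = collect_dwells(wt_slow_analysis["ideals"], "P/P", "CHI")
    assert not directed.censored.any()
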