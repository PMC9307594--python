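"""Bleed-through correction, FRET computation, events, selection."""

import numpy as np
import pytest

from slipfret import (FluorescenceTrace, KineticScheme, PhotophysicsModel,
                      compute_fret, correct_bleedthrough, detect_events,
                      process_trace, select_trace, select_traces,
                      simulate_ensemble, truncate)
from slipfret.processing import TraceEvent
from slipfret.schemes import ModeMixture


def flat_trace(donor, acceptor, n=100, dt=0.033):
    return FluorescenceTrace(np.full(n, float(donor)),
                             np.full(n, float(acceptor)), dt)


class TestBleedthrough:
    def test_zero_beta_is_identity(self):
        tr = flat_trace(870, 243.1)
        out = correct_bleedthrough(tr, 0.0)
        np.testing.assert_array_equal(out.acceptor, tr.acceptor)

    def test_arithmetic(self):
        out = correct_bleedthrough(flat_trace(870, 243.1), 0.13)
        np.testing.assert_allclose(out.acceptor, 130.0, atol=1e-9)
        np.testing.assert_allclose(out.donor, 870.0)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            correct_bleedthrough(flat_trace(1, 1), 1.0)


class TestComputeFret:
    def test_low_and_high_fret(self):
        assert compute_fret(flat_trace(800, 200)).efficiency[0] == \
            pytest.approx(0.2)
        assert compute_fret(flat_trace(200, 800)).efficiency[0] == \
            pytest.approx(0.8)

    def test_low_intensity_frames_masked(self):
        donor = np.full(50, 500.0)
        donor[30:] = 5.0
        tr = FluorescenceTrace(donor, np.full(50, 5.0), 0.033)
        ft = compute_fret(tr, min_total=50)
        assert ft.truncation_frame == 30
        assert ft.n_valid == 30

    def test_all_invalid_flagged_empty(self):
        ft = compute_fret(flat_trace(1.0, 1.0), min_total=50)
        assert ft.is_empty
        assert ft.meta.get("empty")


class TestNoiselessRoundTrip:
    def test_state_means_reproduced_exactly(self, noiseless_photo):
        scheme = KineticScheme(
            "clean", [("hi", 0.8, 0.0), ("lo", 0.2, 0.0)],
            [[0, 0.5], [0.5, 0]])
        photo = PhotophysicsModel(k_pb_donor=0.0, bleedthrough_beta=0.13,
                                  noise_sd=0.0, background_sd=1e-12)
        traces, manifest = simulate_ensemble(
            ModeMixture([(scheme, 1.0)]), 3, photo, 10.0, 0.033, seed=5)
        for tr, rec in zip(traces, manifest["traces"]):
            ft = compute_fret(correct_bleedthrough(tr, 0.13), min_total=50)
            # away from mid-frame transitions every frame sits on a mean
            on_state = np.isin(np.round(ft.valid_values(), 6), [0.2, 0.8])
            assert on_state.mean() > 0.9
            err = np.min(np.abs(ft.valid_values()[on_state][:, None] -
                                np.array([0.2, 0.8])[None, :]), axis=1)
            assert np.all(err < 1e-9)


class TestDetectEvents:
    def test_injected_donor_bleach_found(self):
        rng = np.random.default_rng(0)
        donor = np.concatenate([np.full(400, 600.0), np.zeros(600)])
        acceptor = np.concatenate([np.full(400, 400.0), np.zeros(600)])
        tr = FluorescenceTrace(donor + rng.normal(0, 10, 1000),
                               acceptor + rng.normal(0, 10, 1000), 0.033)
        events = detect_events(tr)
        bleach = [e for e in events if e.kind == "donor_bleach"]
        assert bleach and abs(bleach[0].frame - 400) <= 2

    def test_constant_trace_has_no_events(self):
        assert detect_events(flat_trace(600, 400)) == []

    def test_acceptor_loss_with_dequench(self):
        donor = np.concatenate([np.full(200, 500.0), np.full(300, 1000.0)])
        acceptor = np.concatenate([np.full(200, 500.0), np.zeros(300)])
        tr = FluorescenceTrace(donor, acceptor, 0.033)
        events = detect_events(tr)
        loss = [e for e in events if e.kind == "acceptor_loss"]
        assert loss and abs(loss[0].frame - 200) <= 2

    def test_blink_has_recovery(self):
        donor = np.full(300, 400.0)
        acceptor = np.full(300, 600.0)
        acceptor[100:110] = 0.0
        donor[100:110] = 1000.0
        tr = FluorescenceTrace(donor, acceptor, 0.033)
        kinds = {e.kind for e in detect_events(tr)}
        assert "blink" in kinds


class TestSelection:
    def test_clean_single_molecule_ensemble_mostly_accepted(self):
        mix = ModeMixture([(KineticScheme(
            "flip", [("hi", 0.8, 0.1), ("lo", 0.2, 0.1)],
            [[0, 1.0], [1.0, 0]]), 1.0)])
        traces, _ = simulate_ensemble(mix, 60, PhotophysicsModel(), 33.0,
                                      0.033, seed=3)
        kept, reports = select_traces(traces)
        assert len(kept) / len(traces) >= 0.95
        assert all(r.anticorrelation_r < -0.3 for r in reports if r.accepted)

    def test_two_molecule_composites_rejected(self):
        mix = ModeMixture([(KineticScheme(
            "flip", [("hi", 0.8, 0.1), ("lo", 0.2, 0.1)],
            [[0, 1.0], [1.0, 0]]), 1.0)])
        traces, _ = simulate_ensemble(mix, 60, PhotophysicsModel(), 33.0,
                                      0.033, seed=9)
        composites = [
            FluorescenceTrace(a.donor + b.donor, a.acceptor + b.acceptor,
                              a.frame_interval)
            for a, b in zip(traces[::2], traces[1::2])]
        kept, reports = select_traces(traces[:40] + composites)
        n_comp_kept = sum(r.accepted for r in reports[40:])
        assert n_comp_kept / len(composites) <= 0.05

    def test_donor_only_trace_rejected(self):
        rng = np.random.default_rng(2)
        tr = FluorescenceTrace(1000 + rng.normal(0, 10, 200),
                               rng.normal(0, 10, 200), 0.033)
        rep = select_trace(tr)
        assert not rep.accepted
        assert "no_anticorrelation" in rep.reasons

    def test_short_trace_rejected(self):
        rep = select_trace(flat_trace(500, 500, n=5))
        assert rep.reasons == ["too_short"]


class TestTruncate:
    def test_no_events_leaves_trace_unchanged(self):
        ft = compute_fret(flat_trace(600, 400))
        out = truncate(ft, [])
        assert out.truncation_reason == "none"
        assert out.n_valid == ft.n_valid

    def test_earliest_event_wins(self):
        ft = compute_fret(flat_trace(600, 400, n=1000))
        events = [TraceEvent("blink", 200, "low"),
                  TraceEvent("donor_bleach", 600, "high")]
        out = truncate(ft, events)
        assert out.truncation_frame == 200
        assert out.truncation_reason == "blink"

    def test_event_at_zero_flags_empty(self):
        ft = compute_fret(flat_trace(600, 400))
        out = truncate(ft, [TraceEvent("donor_bleach", 0, "high")])
        assert out.is_empty

    def test_no_invalid_frame_inside_prefix(self):
        ft = compute_fret(flat_trace(600, 400, n=500))
        out = truncate(ft, [TraceEvent("donor_bleach", 123, "high")])
        assert out.valid_mask[:out.truncation_frame].all()
        assert not out.valid_mask[out.truncation_frame:].any()


def test_process_trace_truncates_at_dissociation(photo):
    from slipfret import make_preset
    traces, manifest = simulate_ensemble(
        make_preset("deac_wt_nonslippery"), 20, photo, 33.0, 0.033, seed=21)
    hits = 0
    for tr in traces:
        t_diss = tr.meta["t_dissociation"]
        t_bleach = tr.meta["t_donor_bleach"] or np.inf
        if t_diss is None or t_diss > 30 or t_bleach < t_diss:
            continue
        ft = process_trace(tr, photo)
        if abs(ft.truncation_frame * 0.033 - t_diss) < 0.2:
            hits += 1
            assert ft.truncation_reason == "acceptor_bleach"
    assert hits >= 10
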