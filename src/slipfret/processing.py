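"""Conversion of raw two-channel intensity traces into validated FRET traces.

Processing order follows standard TIRF practice: correct donor-to-acceptor
bleed-through, detect photophysical events (donor bleach, acceptor loss,
blinking), select single-molecule anti-correlated traces, compute the FRET
efficiency E = FI_A / (FI_D + FI_A), and truncate each trace at the first
event so that only the photophysically clean prefix enters the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import FluorescenceTrace, PhotophysicsModel

__all__ = [
    "FretTrace",
    "SelectionReport",
    "TraceEvent",
    "correct_bleedthrough",
    "compute_fret",
    "detect_events",
    "select_trace",
    "select_traces",
    "truncate",
    "process_trace",
]

# A channel is considered lost once it sits in the background band
# (mean +- 3 s.d.) for at least this many consecutive frames; 5 frames
# (165 ms at 33 ms/frame) rejects shot-noise excursions.
LOSS_RUN_FRAMES = 5
ANTICORRELATION_MAX = -0.3
INTENSITY_BAND = (0.5, 1.5)
MIN_FRAMES = 10


@dataclass
class FretTrace:
    """Per-frame FRET efficiency with a single valid prefix.

    Frames at and beyond ``truncation_frame`` are invalid (photobleach,
    blink, or insufficient total intensity at the trace tail); within the
    prefix, frames whose total intensity fell below the threshold are
    also masked invalid.
    """

    efficiency: np.ndarray
    valid_mask: np.ndarray
    frame_interval: float
    truncation_frame: int
    truncation_reason: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.efficiency.shape != self.valid_mask.shape:
            raise ValueError("efficiency and valid_mask must align")
        if np.any(self.valid_mask[self.truncation_frame:]):
            raise ValueError("valid frames must lie before truncation_frame")

    @property
    def n_frames(self):
        return self.efficiency.size

    @property
    def n_valid(self):
        return int(self.valid_mask.sum())

    @property
    def is_empty(self):
        return self.n_valid == 0

    def valid_values(self):
        return self.efficiency[self.valid_mask]


@dataclass(frozen=True)
class TraceEvent:
    kind: str        # donor_bleach | acceptor_loss | blink
    frame: int
    confidence: str  # high | low


@dataclass
class SelectionReport:
    accepted: bool
    reasons: list
    anticorrelation_r: float
    n_bleach_steps_donor: int

    def __post_init__(self):
        if self.accepted and self.reasons:
            raise ValueError("accepted traces must carry no rejection reasons")


def correct_bleedthrough(trace, beta):
    """Subtract donor bleed-through from the acceptor channel.

    ``acceptor' = acceptor - beta * donor``; single application contract
    (not idempotent).
    """
    if not 0 <= beta < 1:
        raise ValueError("beta must be in [0, 1)")
    out = FluorescenceTrace(
        trace.donor.copy(),
        trace.acceptor - beta * trace.donor,
        trace.frame_interval,
        meta=dict(trace.meta),
    )
    out.meta["bleedthrough_corrected"] = beta
    return out


def compute_fret(trace, min_total=50.0):
    """FRET efficiency per frame, masking frames of insufficient intensity.

    E = acceptor / (donor + acceptor) where the summed intensity is at
    least ``min_total`` (default: background mean + 5 background s.d. at
    the default photophysics); other frames are marked invalid.  Values
    are softly clipped to [-0.2, 1.2].
    """
    total = trace.total()
    ok = total >= min_total
    e = np.zeros(trace.n_frames)
    e[ok] = trace.acceptor[ok] / total[ok]
    e = np.clip(e, -0.2, 1.2)
    # Valid frames must form a prefix: stop at the first invalid frame.
    if ok.all():
        cut = trace.n_frames
    else:
        cut = int(np.argmin(ok))
    mask = np.zeros(trace.n_frames, dtype=bool)
    mask[:cut] = True
    ft = FretTrace(e, mask, trace.frame_interval, truncation_frame=cut,
                   truncation_reason="none" if cut == trace.n_frames else "low_signal",
                   meta=dict(trace.meta))
    if ft.is_empty:
        ft.meta["empty"] = True
    return ft


def _runs(mask):
    """Yield (start, length) of runs of True in a boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e - s)


def _smooth(channel, size=LOSS_RUN_FRAMES):
    """Running median; suppresses single-frame noise pops that would
    otherwise split a bleached segment into several runs."""
    from scipy.ndimage import median_filter
    return median_filter(channel, size=size, mode="nearest")


def _close_gaps(mask, gap=LOSS_RUN_FRAMES):
    """Fill sub-threshold gaps inside True runs (background-noise
    crossings shorter than the event run length must not split a
    bleached segment)."""
    from scipy.ndimage import binary_closing
    padded = np.pad(mask, gap, mode="edge")
    closed = binary_closing(padded, structure=np.ones(gap, dtype=bool))
    return closed[gap:-gap]


def detect_events(trace, photo=None, min_run=LOSS_RUN_FRAMES):
    """Detect donor-bleach, acceptor-loss and blink candidate frames.

    Run-length thresholding against the background band
    ``background_mean +- 3 * background_sd``:

    * both channels in band for >= ``min_run`` frames through the end of
      the trace -> ``donor_bleach`` (transient with recovery -> ``blink``);
    * acceptor in band while the donor stays high (anti-correlated rise,
      covering both acceptor bleach and reporter dissociation) ->
      ``acceptor_loss`` (transient -> ``blink``).
    """
    if photo is None:
        photo = PhotophysicsModel()
    hi = photo.background_mean + 3 * photo.background_sd
    don = _smooth(trace.donor)
    acc = _smooth(trace.acceptor)
    don_low = don <= hi
    acc_low = acc <= hi
    don_high = don >= 0.5 * (photo.i_total - photo.background_mean)

    events = []
    both_low = _close_gaps(don_low & acc_low)
    acc_low = _close_gaps(acc_low)
    for start, length in _runs(both_low):
        if length < min_run:
            continue
        if start + length >= trace.n_frames:
            events.append(TraceEvent("donor_bleach", start,
                                     "high" if length >= 2 * min_run else "low"))
        else:
            events.append(TraceEvent("blink", start, "low"))
    acc_only = acc_low & don_high
    for start, length in _runs(acc_only):
        if length < min_run:
            continue
        end = start + length
        # Recovery of the acceptor afterwards marks a blink instead.
        recovered = end < trace.n_frames and not acc_low[end]
        kind = "blink" if recovered else "acceptor_loss"
        events.append(TraceEvent(kind, start,
                                 "high" if length >= 2 * min_run else "low"))
    events.sort(key=lambda ev: ev.frame)
    return events


def _donor_bleach_steps(trace, photo):
    """Count bleach steps as decrements of the apparent molecule count.

    The summed two-channel intensity is FRET-independent (the donor and
    acceptor anticorrelate exactly), so ``round(total / i_total)``
    tracks the number of emitting molecules; a single molecule shows at
    most one downward step, a doublet two.
    """
    total = _smooth(trace.total(), size=2 * LOSS_RUN_FRAMES + 1)
    count = np.round((total - photo.background_mean) /
                     photo.i_total).astype(int)
    count = np.maximum(count, 0)
    steps = 0
    prev = count[0]
    run_val, run_len = prev, 0
    for v in count[1:]:
        if v == run_val:
            run_len += 1
        else:
            run_val, run_len = v, 1
        if run_len == LOSS_RUN_FRAMES and run_val < prev:
            steps += prev - run_val
            prev = run_val
        elif run_len == LOSS_RUN_FRAMES and run_val > prev:
            prev = run_val
    return steps


def _initial_total(trace, n_frames=20):
    """Median summed intensity over the first frames (pre any loss)."""
    total = _smooth(trace.total())
    return float(np.median(total[:min(n_frames, trace.n_frames)]))


def select_trace(trace, photo=None, ensemble_median_total=None):
    """Single-molecule selection of one trace.

    Accepts a trace iff (i) the frame-to-frame donor vs acceptor intensity
    *changes* are anti-correlated (Pearson r <= -0.3; first differences
    avoid baseline-driven spurious correlation), (ii) the donor shows at
    most one bleach step (>= 2 steps indicate multiple molecules), and
    (iii) the pre-bleach total intensity lies within the single-molecule
    band 0.5-1.5x the ensemble median (skipped when no median is given).
    """
    if photo is None:
        photo = PhotophysicsModel()
    reasons = []
    if trace.n_frames < MIN_FRAMES:
        return SelectionReport(False, ["too_short"], np.nan, 0)

    events = detect_events(trace, photo)
    first_end = min((ev.frame for ev in events), default=trace.n_frames)
    pre = slice(0, max(first_end, 0))

    n_steps = _donor_bleach_steps(trace, photo)
    if n_steps > 1:
        reasons.append("multiple_bleach_steps")

    d = np.diff(trace.donor[pre])
    a = np.diff(trace.acceptor[pre])
    if d.size < MIN_FRAMES - 1:
        # event at/near frame 0 (e.g. no acceptor from the start):
        # judge anticorrelation on the whole trace instead
        d = np.diff(trace.donor)
        a = np.diff(trace.acceptor)
    if np.std(d) == 0 or np.std(a) == 0:
        r = np.nan
        reasons.append("no_anticorrelation")
    else:
        r = float(np.corrcoef(d, a)[0, 1])
        if not r <= ANTICORRELATION_MAX:
            reasons.append("no_anticorrelation")

    if ensemble_median_total is not None:
        med = _initial_total(trace)
        lo, hi_band = INTENSITY_BAND
        if not lo * ensemble_median_total <= med <= hi_band * ensemble_median_total:
            reasons.append("intensity_band")

    return SelectionReport(not reasons, reasons, r, n_steps)


def select_traces(traces, photo=None):
    """Select an ensemble; the intensity band uses the ensemble median.

    Returns (accepted traces, list of SelectionReport aligned with input).
    """
    if photo is None:
        photo = PhotophysicsModel()
    medians = [_initial_total(tr) for tr in traces if tr.n_frames >= MIN_FRAMES]
    ens_median = float(np.median(medians)) if medians else None
    reports = [select_trace(tr, photo, ens_median) for tr in traces]
    kept = [tr for tr, rep in zip(traces, reports) if rep.accepted]
    return kept, reports


def truncate(fret, events):
    """Cut the valid prefix one frame before the earliest event.

    ``events`` must be sorted by frame.  With no events the trace is
    returned unchanged (reason ``none``); an event at frame 0 yields an
    empty, flagged trace.
    """
    if not events:
        return fret
    frames = [ev.frame for ev in events]
    if frames != sorted(frames):
        raise ValueError("events must be sorted by frame")
    ev = events[0]
    cut = min(ev.frame, fret.truncation_frame)
    mask = fret.valid_mask.copy()
    mask[cut:] = False
    reason = {"donor_bleach": "donor_bleach", "acceptor_loss": "acceptor_bleach",
              "blink": "blink"}.get(ev.kind, ev.kind)
    out = FretTrace(fret.efficiency.copy(), mask, fret.frame_interval,
                    truncation_frame=cut, truncation_reason=reason,
                    meta=dict(fret.meta))
    out.meta["truncation_event"] = ev.kind
    if out.is_empty:
        out.meta["empty"] = True
    return out


def process_trace(trace, photo=None, beta=None, min_total=None):
    """Bleed-through correction -> event detection -> FRET -> truncation."""
    if photo is None:
        photo = PhotophysicsModel()
    if beta is None:
        beta = photo.bleedthrough_beta
    if min_total is None:
        min_total = photo.background_mean + 5 * photo.background_sd
    corrected = correct_bleedthrough(trace, beta)
    # Events are detected on the corrected channels: uncorrected, the
    # acceptor of a dissociated/acceptor-bleached molecule still carries
    # beta * i_total of donor bleed-through and never reaches background.
    events = detect_events(corrected, photo)
    fret = compute_fret(corrected, min_total=min_total)
    return truncate(fret, events)
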