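"""Dwell-time kinetics from idealized trajectories.

Dwell times of each FRET state are collected from the filtered idealized
trajectories; their empirical survival curve is fitted to a single
exponential ``y = y0 + A exp(-t/tau)`` (decay rate k = 1/tau).  Observed
rates are corrected for dye photobleaching and the finite observation
window, ``k_corrected = k_observed - k_photobleach - 1/T``.

Because the dwell time of a Markov state is exponential in its *total*
exit rate regardless of the destination, per-edge transition rates
k(i -> j) are estimated as the corrected dwell decay multiplied by the
observed branching fraction n_ij / n_i (the standard per-edge maximum
likelihood estimator).

Survival-curve fitting is used rather than binned-histogram fitting
(bin-free, stable at small n); single-frame dwells are excluded as
camera-limited, and dwells cut short by trace truncation are censored
and never enter the fits — their loss is exactly what the
``-k_photobleach - 1/T`` correction compensates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "DwellSet",
    "RateEstimate",
    "TraceClass",
    "DwellFitError",
    "collect_dwells",
    "fit_dwell_exponential",
    "correct_rate",
    "deadtime_correct",
    "transition_rate",
    "classify_trace",
    "translocation_rate",
    "dissociation_rate",
    "head_swivel_rate",
    "photobleach_rate",
    "transition_frequency",
    "fraction_reaching_state",
]

DEFAULT_K_PB = 0.03      # 1/s, combined dye photobleaching constant
DEFAULT_T_OBS = 33.0     # s, observation window (100 s variant available)
MIN_DWELLS = 20
STABLE_POST_FRAMES = 10
SYNC_THRESHOLD = 0.5


class DwellFitError(RuntimeError):
    pass


@dataclass
class DwellSet:
    """Dwell times (s) in one state, optionally destination-resolved."""

    state: str
    to_state: str | None
    dwell_times: np.ndarray
    censored: np.ndarray
    n_traces: int = 0

    def __post_init__(self):
        self.dwell_times = np.asarray(self.dwell_times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.dwell_times.shape != self.censored.shape:
            raise ValueError("dwell_times and censored must align")
        if np.any(self.dwell_times <= 0):
            raise ValueError("dwell times must be > 0")
        if self.to_state is not None and np.any(self.censored):
            raise ValueError("destination-resolved dwells cannot be censored")

    @property
    def uncensored_times(self):
        return self.dwell_times[~self.censored]

    @property
    def n_uncensored(self):
        return int((~self.censored).sum())


@dataclass
class RateEstimate:
    """Exponential-fit rate with photobleaching correction.

    ``nd`` marks a result where the number of events fell below the fit
    floor (too few fluctuations to calculate a rate); ``below_resolution``
    marks a corrected rate at or below zero, i.e. limited by
    photobleaching; ``lower_bound`` marks camera-limited (one-frame)
    processes reported as k >= 1/frame_interval.
    """

    label: str
    k_obs: float = np.nan
    k_corrected: float = np.nan
    tau: float = np.nan
    y0: float = np.nan
    A: float = np.nan
    r_squared: float = np.nan
    N: int = 0
    n: int = 0
    ci: tuple = (np.nan, np.nan)
    nd: bool = False
    below_resolution: bool = False
    lower_bound: bool = False
    extra: dict = field(default_factory=dict)

    def to_row(self):
        return {
            "label": self.label, "k_obs": self.k_obs,
            "k_corrected": self.k_corrected, "tau": self.tau,
            "r_squared": self.r_squared, "N": self.N, "n": self.n,
            "ci_low": self.ci[0], "ci_high": self.ci[1],
            "nd": self.nd, "below_resolution": self.below_resolution,
            "lower_bound": self.lower_bound,
        }


@dataclass
class TraceClass:
    label: str                      # direct | chi_sampling | no_translocation
    sync_frame: int | None = None
    post_entry_frame: int | None = None


def collect_dwells(ideals, state, to_state=None):
    """Collect dwell times in *state* across idealized traces.

    The final dwell of every trace ends at truncation, not at a
    transition, and is flagged censored.  With ``to_state`` given only
    dwells terminating in a transition to that state are kept (these are
    uncensored by construction).
    """
    times, cens = [], []
    n_traces = 0
    for ideal in ideals:
        seen = False
        for i, d in enumerate(ideal.dwells):
            if d.label != state:
                continue
            last = i == len(ideal.dwells) - 1
            if to_state is not None:
                if last or ideal.dwells[i + 1].label != to_state:
                    continue
            seen = True
            times.append(d.n_frames * ideal.frame_interval)
            cens.append(last)
        if seen:
            n_traces += 1
    return DwellSet(state, to_state, np.array(times), np.array(cens, dtype=bool),
                    n_traces=n_traces)


def _survival_points(times, frame_interval):
    """Empirical survival S(j*dt) at observed frame multiples, j >= 2.

    Evaluating at the observed dwell values (not every frame multiple)
    keeps the point density proportional to the data, so the sparse far
    tail cannot dominate the least-squares fit; the first bin
    (single-frame dwells) is camera-limited and excluded.
    """
    frames = np.maximum(np.round(times / frame_interval).astype(int), 1)
    j = np.unique(frames)
    j = j[j >= 2]
    s = np.array([(frames >= jj).mean() for jj in j])
    return j * frame_interval, s


def fit_dwell_exponential(dwells, frame_interval, min_dwells=MIN_DWELLS,
                          n_boot=1000, seed=0, label=None, s_min=0.05):
    """Fit ``y = y0 + A exp(-t/tau)`` to the dwell survival curve.

    Only uncensored dwells enter; the survival curve is evaluated at
    frame multiples with single-frame dwells excluded, and points where
    the survival has dropped below ``s_min`` are discarded (the sparse
    far tail carries large relative noise and any contamination by
    rare merged dwells).  Returns a :class:`RateEstimate` with
    ``k_obs = 1/tau`` and a seeded bootstrap 95% CI (the correction
    shift is applied downstream).
    """
    times = dwells.uncensored_times if isinstance(dwells, DwellSet) else np.asarray(dwells, float)
    if times.size < min_dwells:
        raise DwellFitError(
            f"need >= {min_dwells} uncensored dwells, got {times.size}")

    def _fit(ts):
        t, s = _survival_points(ts, frame_interval)
        keep = s >= s_min
        if keep.sum() >= 4:
            t, s = t[keep], s[keep]
        if t.size < 4 or np.unique(s).size < 3:
            raise DwellFitError(
                "degenerate dwell distribution: survival curve has too few "
                "distinct points for an exponential fit")
        # y0 absorbs the (small) finite-window offset; for dwells short
        # against the window it is near zero, and leaving it unbounded
        # lets the fit trade offset against slope on noisy tails.
        # Points carry their binomial standard errors (weighted LS).
        p0 = (0.0, 1.0, max(float(np.mean(ts)), frame_interval))
        sig = np.sqrt(np.clip(s * (1.0 - s), 1e-6, None) / ts.size)
        popt, _ = optimize.curve_fit(
            lambda tt, y0, A, tau: y0 + A * np.exp(-tt / tau),
            t, s, p0=p0, sigma=sig,
            bounds=([-0.05, 0.0, frame_interval / 100],
                    [0.05, 10.0, 1e6]), maxfev=10000)
        resid = s - (popt[0] + popt[1] * np.exp(-t / popt[2]))
        ss_tot = np.sum((s - s.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else np.nan
        return popt, r2

    popt, r2 = _fit(times)
    y0, A, tau = popt

    ks = []
    if n_boot:
        rng = np.random.default_rng(seed)
        for _ in range(n_boot):
            resample = rng.choice(times, size=times.size, replace=True)
            try:
                p, _ = _fit(resample)
                ks.append(1.0 / p[2])
            except (DwellFitError, RuntimeError):
                continue
    ci = (float(np.percentile(ks, 2.5)), float(np.percentile(ks, 97.5))) \
        if len(ks) >= 100 else (np.nan, np.nan)

    return RateEstimate(
        label=label or (f"{dwells.state}->{dwells.to_state}"
                        if isinstance(dwells, DwellSet) and dwells.to_state
                        else getattr(dwells, "state", "dwell")),
        k_obs=1.0 / tau, tau=tau, y0=y0, A=A, r_squared=r2,
        N=getattr(dwells, "n_traces", 0), n=int(times.size), ci=ci)


def fit_event_exponential(times, frame_interval, min_events=MIN_DWELLS,
                          n_boot=1000, seed=0, label="events", s_min=0.02,
                          n_traces=0):
    """One-parameter exponential fit to terminal event times.

    For first-passage quantities with one event per trace (dissociation,
    sync-to-POST times), the survival curve is anchored at its first
    well-measured point and only the decay rate is free,
    ``S(t) = S(t0) exp(-k (t - t0))`` — near the efficiency of the
    maximum-likelihood estimate, where the generic three-parameter form
    carries about twice the sampling error.  Single-frame events are
    excluded as camera-limited.
    """
    times = np.asarray(times, dtype=float)
    if times.size < min_events:
        raise DwellFitError(
            f"need >= {min_events} events, got {times.size}")

    def _fit(ts):
        t, s = _survival_points(ts, frame_interval)
        keep = s >= s_min
        if keep.sum() >= 3:
            t, s = t[keep], s[keep]
        if t.size < 3 or np.unique(s).size < 2:
            raise DwellFitError("degenerate event-time distribution")
        t0, s0 = t[0], s[0]
        sig = np.sqrt(np.clip(s * (1.0 - s), 1e-6, None) / ts.size)
        popt, _ = optimize.curve_fit(
            lambda tt, k: s0 * np.exp(-k * (tt - t0)), t, s,
            p0=(1.0 / max(np.mean(ts), frame_interval),), sigma=sig,
            bounds=(1e-6, 1e4), maxfev=10000)
        k = float(popt[0])
        resid = s - s0 * np.exp(-k * (t - t0))
        ss_tot = np.sum((s - s.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else np.nan
        return k, s0 * np.exp(k * t0), r2

    k, A, r2 = _fit(times)
    ks = []
    if n_boot:
        rng = np.random.default_rng(seed)
        for _ in range(n_boot):
            try:
                ks.append(_fit(rng.choice(times, size=times.size,
                                          replace=True))[0])
            except (DwellFitError, RuntimeError):
                continue
    ci = (float(np.percentile(ks, 2.5)), float(np.percentile(ks, 97.5))) \
        if len(ks) >= 100 else (np.nan, np.nan)
    return RateEstimate(label=label, k_obs=k, tau=1.0 / k, y0=0.0, A=A,
                        r_squared=r2, N=n_traces or int(times.size),
                        n=int(times.size), ci=ci)


def correct_rate(k_obs, k_pb=DEFAULT_K_PB, T=DEFAULT_T_OBS):
    """Photobleaching / observation-window correction.

    ``k_corrected = k_observed - k_photobleach - 1/T``.  May be <= 0, in
    which case the rate is limited by photobleaching (flag downstream).
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    return k_obs - k_pb - 1.0 / T


def _apply_correction(est, k_pb, T):
    est.k_corrected = correct_rate(est.k_obs, k_pb, T)
    est.below_resolution = est.k_corrected <= 0
    if np.isfinite(est.ci[0]):
        est.ci = (correct_rate(est.ci[0], k_pb, T),
                  correct_rate(est.ci[1], k_pb, T))
    return est


# Effective idealizer dead times (camera frames), characterized on
# simulated traces at the standard noise level (state s.d. 0.1).  For a
# hidden two-state alternation a visit needs ~1 interior frame beyond
# its two camera-integrated boundary frames to be called reliably; in a
# multi-state network part of the sub-dead-time excursions terminate at
# a *different* observable level and are therefore not lost, reducing
# the effective dead time.
DEAD_FRAMES_TWO_STATE = 2.5
DEAD_FRAMES_NETWORK = 2.0


def deadtime_correct(k_obs, k_excursion_obs, tau_d, max_factor=2.0):
    """Missed-event (dead-time) correction of a dwell decay rate.

    Excursions to neighbouring states shorter than the idealizer dead
    time ``tau_d`` go undetected and merge flanking dwells, inflating
    the observed dwell:

        E[T_obs] = E[T]/p + (1/p - 1) E[T_exc | T_exc < tau_d],

    with ``p = exp(-k_exc tau_d)`` the detection probability of one
    excursion.  Inverting with the *observed* excursion decay
    ``k_excursion_obs`` is deliberately one-sided (no joint iteration):
    it under-corrects slightly but is unconditionally stable.  The
    corrected rate is capped at ``max_factor`` times the observed one;
    beyond that the premise (modest event loss) no longer holds and the
    observed rate is returned unchanged.
    """
    p = np.exp(-k_excursion_obs * tau_d)
    e_short = 1.0 / k_excursion_obs - tau_d * p / (1.0 - p)
    e_true = p / k_obs - (1.0 - p) * e_short
    if e_true <= 0:
        return k_obs
    k = 1.0 / e_true
    if not np.isfinite(k) or k > max_factor * k_obs:
        return k_obs
    return k


def transition_rate(ideals, from_state, to_state, k_pb=DEFAULT_K_PB,
                    T=DEFAULT_T_OBS, min_transitions=MIN_DWELLS,
                    n_boot=1000, seed=0, dead_frames=DEAD_FRAMES_NETWORK):
    """Corrected per-edge transition rate k(from_state -> to_state).

    The decay of all uncensored ``from_state`` dwells gives the total
    exit rate; it is corrected for undetected sub-dead-time excursions
    (which merge flanking dwells; the excursion-state dwell decay is
    measured from the data and the two rates solved jointly, see
    :func:`_deadtime_fixed_point`), then for photobleaching and the
    observation window, and finally multiplied by the observed
    branching fraction into ``to_state``.  Returns an explicit "n.d."
    result when fewer than ``min_transitions`` such transitions exist.
    """
    all_dwells = collect_dwells(ideals, from_state)
    directed = collect_dwells(ideals, from_state, to_state)
    n_ij = directed.n_uncensored
    label = f"{from_state}->{to_state}"
    if n_ij < min_transitions or all_dwells.n_uncensored < min_transitions:
        return RateEstimate(label=label, N=all_dwells.n_traces, n=n_ij, nd=True)

    frame_interval = ideals[0].frame_interval
    est = fit_dwell_exponential(all_dwells, frame_interval,
                                min_dwells=min_transitions,
                                n_boot=n_boot, seed=seed, label=label)

    if dead_frames:
        # Excursion dwells: the dwells immediately following an exit
        # from `from_state`, pooled over destinations.
        exc_times = []
        for ideal in ideals:
            for i, d in enumerate(ideal.dwells[:-1]):
                if d.label == from_state:
                    if i + 1 < len(ideal.dwells) - 1:  # uncensored
                        exc_times.append(
                            ideal.dwells[i + 1].n_frames * frame_interval)
        if len(exc_times) >= min_transitions:
            nb = DwellSet("excursion", None, np.array(exc_times),
                          np.zeros(len(exc_times), bool))
            k_nb_obs = fit_dwell_exponential(nb, frame_interval,
                                             min_dwells=min_transitions,
                                             n_boot=0).k_obs
            tau_d = dead_frames * frame_interval
            k_corr = deadtime_correct(est.k_obs, k_nb_obs, tau_d)
            if np.isfinite(est.ci[0]) and est.k_obs > 0:
                scale = k_corr / est.k_obs
                est.ci = (est.ci[0] * scale, est.ci[1] * scale)
            est.extra.update({"k_obs_deadtime_uncorrected": est.k_obs,
                              "k_excursion_obs": k_nb_obs})
            est.k_obs = k_corr
            est.tau = 1.0 / k_corr

    branching = n_ij / all_dwells.n_uncensored
    est = _apply_correction(est, k_pb, T)
    est.k_corrected *= branching
    est.ci = tuple(c * branching for c in est.ci)
    est.n = n_ij
    est.extra["branching"] = branching
    est.extra["k_exit_corrected"] = est.k_corrected / branching
    return est


def _sync_frame(ideal, threshold=SYNC_THRESHOLD):
    """First frame of the first dwell whose idealized mean is below threshold."""
    for d in ideal.dwells:
        if d.mean < threshold:
            return d.start_frame
    return None


BLIP_MAX_FRAMES = 5
STABLE_POST_OCCUPANCY = 0.9


def _stable_post_entry(ideal, post_state, stable_frames=STABLE_POST_FRAMES,
                       blip_max=BLIP_MAX_FRAMES,
                       min_occupancy=STABLE_POST_OCCUPANCY):
    """Frame of the last transition into the long-lived POST state.

    The POST entry is the start of the earliest POST dwell from which
    the trace remains essentially in POST until truncation: the suffix
    must be at least ``stable_frames`` long, occupy POST for at least
    ``min_occupancy`` of its frames, and contain no excursion of
    ``blip_max`` frames or more (short excursions at this noise level
    are indistinguishable from misassigned frames).  Returns None when
    no such entry exists.
    """
    dwells = ideal.dwells
    for i, d in enumerate(dwells):
        if d.label != post_state:
            continue
        suffix = dwells[i:]
        total = sum(s.n_frames for s in suffix)
        # A non-final entry must be followed by a long-enough stable
        # stretch; a trailing POST dwell cut short by truncation counts
        # (the requirement is capped at the trace end).
        if total < stable_frames and i < len(dwells) - 1:
            continue
        post_frames = sum(s.n_frames for s in suffix
                          if s.label == post_state)
        if post_frames / total < min_occupancy:
            continue
        if any(s.label != post_state and s.n_frames >= blip_max
               for s in suffix):
            continue
        return d.start_frame
    return None


CHI_MIN_FRAMES = 5


def classify_trace(ideal, model, chi_state="CHI", post_state=None,
                   sync_threshold=SYNC_THRESHOLD,
                   stable_frames=STABLE_POST_FRAMES,
                   chi_min_frames=CHI_MIN_FRAMES):
    """Classify one filtered idealized trace.

    ``chi_sampling`` — resolvable occupancy of the CHI state at or after
    the synchronization point, at least ``chi_min_frames`` frames in
    total (165 ms at the default frame time, mirroring the event-
    detection run length): a one-frame CHI visit during a PRE-to-POST
    jump is the camera-integration artifact of a mid-frame transition,
    and isolated misassigned frames occur at a few percent per frame at
    this noise level.  ``direct`` — the trace reaches a stable POST
    state without such CHI occupancy; ``no_translocation`` otherwise.
    """
    if post_state is None:
        post_state = model.labels[int(np.argmin(model.means))]
    sync = _sync_frame(ideal, sync_threshold)
    post_entry = _stable_post_entry(ideal, post_state, stable_frames) \
        if ideal.dwells else None
    if sync is None:
        return TraceClass("no_translocation", None, post_entry)
    chi_frames = sum(d.n_frames for d in ideal.dwells
                     if d.label == chi_state and d.start_frame >= sync)
    has_chi = chi_frames >= chi_min_frames
    if has_chi:
        return TraceClass("chi_sampling", sync, post_entry)
    if post_entry is not None:
        return TraceClass("direct", sync, post_entry)
    return TraceClass("no_translocation", sync, post_entry)


def translocation_rate(ideals, model, post_state=None,
                       sync_threshold=SYNC_THRESHOLD,
                       stable_frames=STABLE_POST_FRAMES,
                       k_pb=DEFAULT_K_PB, T=DEFAULT_T_OBS,
                       min_events=MIN_DWELLS, n_boot=1000, seed=0):
    """Overall translocation rate k_TL.

    Per trace: time from the synchronization point (first idealized value
    below the threshold) to the last transition into the POST state
    (start of the final, stable POST dwell); the time distribution is
    fitted to an exponential and corrected.  Traces never reaching a
    stable POST are excluded (count reported); traces translocating
    within one frame are camera-limited and reported separately — if they
    dominate, the estimate is the lower bound 1/frame_interval.
    """
    if post_state is None:
        post_state = model.labels[int(np.argmin(model.means))]
    frame_interval = ideals[0].frame_interval
    times = []
    n_instant = 0
    n_no_post = 0
    for ideal in ideals:
        tc = classify_trace(ideal, model, post_state=post_state,
                            sync_threshold=sync_threshold,
                            stable_frames=stable_frames)
        if tc.sync_frame is None or tc.post_entry_frame is None:
            n_no_post += 1
            continue
        df = tc.post_entry_frame - tc.sync_frame
        if df <= 1:
            n_instant += 1
        else:
            times.append(df * frame_interval)
    times = np.array(times)
    label = "k_TL"
    extra = {"n_instantaneous": n_instant, "n_excluded_no_post": n_no_post,
             "n_resolved": int(times.size)}

    if n_instant > times.size:
        # Camera-limited: translocation completes within one frame.
        est = RateEstimate(label=label, k_obs=1.0 / frame_interval,
                           k_corrected=1.0 / frame_interval,
                           tau=frame_interval, N=n_instant + times.size,
                           n=n_instant, lower_bound=True, extra=extra)
        return est
    if times.size < min_events:
        raise DwellFitError(
            f"only {times.size} resolved translocation events "
            f"(>= {min_events} required)")
    est = fit_event_exponential(times, frame_interval, min_events=min_events,
                                n_boot=n_boot, seed=seed, label=label)
    est.extra.update(extra)
    # Anchored event-time fits condition on the observed events, so the
    # finite-window 1/T term does not apply; only the photobleaching
    # competition inflates the observed rate.
    return _apply_correction(est, k_pb, np.inf)


def dissociation_rate(ideals, e_state="E", k_pb=DEFAULT_K_PB, T=DEFAULT_T_OBS,
                      min_events=MIN_DWELLS, n_boot=1000, seed=0):
    """E-site dissociation rate of the deacylated-tRNA reporter.

    The dwell runs from the first entry into the E state to the loss of
    the acceptor signal (trace truncation by ``acceptor_bleach``, which
    covers both dissociation and acceptor photobleaching — the k_pb
    subtraction separates the two statistically).  Traces ending for any
    other reason are censored.  Only k_pb is subtracted: the anchored
    event-time fit conditions on the observed events and carries no
    finite-window bias for the 1/T term to compensate.
    """
    times, cens = [], []
    n_traces = 0
    for ideal in ideals:
        entry = None
        for d in ideal.dwells:
            if d.label == e_state:
                entry = d.start_frame
                break
        if entry is None:
            continue
        n_traces += 1
        dt = (ideal.n_valid - entry) * ideal.frame_interval
        if dt <= 0:
            continue
        times.append(dt)
        cens.append(ideal.meta.get("truncation_reason") != "acceptor_bleach")
    ds = DwellSet(e_state, None, np.array(times), np.array(cens, dtype=bool),
                  n_traces=n_traces)
    if ds.n_uncensored < min_events:
        return RateEstimate(label="k_off", N=n_traces, n=ds.n_uncensored,
                            nd=True)
    est = fit_event_exponential(ds.uncensored_times, ideals[0].frame_interval,
                                min_events=min_events, n_boot=n_boot,
                                seed=seed, label="k_off", n_traces=n_traces)
    return _apply_correction(est, k_pb, np.inf)


def head_swivel_rate(ideals, s_state="S", n_state="N", k_pb=DEFAULT_K_PB,
                     T=DEFAULT_T_OBS, dead_frames=DEAD_FRAMES_TWO_STATE,
                     min_events=MIN_DWELLS, n_boot=1000, seed=0):
    """Back-swiveling rate k_S->N from the final S dwell of each trace.

    The last S dwell that terminates in a transition to the long-lived
    N state is fitted to an exponential.  Because N visits shorter than
    the detection dead time (``dead_frames`` camera frames) go
    unnoticed and merge consecutive S dwells, the apparent S dwell is
    inflated; the standard two-state missed-event correction
    (single-channel kinetics) is applied:

        E[T_obs] = E[T_S]/p + (1/p - 1) E[T_N | T_N < tau_d],

    with p = exp(-k_N tau_d) the probability that an N visit is
    detectable and k_N estimated from the observed N dwells.  The
    photobleaching/observation-window correction is applied last.
    """
    frame_interval = ideals[0].frame_interval
    tau_d = dead_frames * frame_interval

    final_s = []
    for ideal in ideals:
        s_idx = [i for i, d in enumerate(ideal.dwells) if d.label == s_state]
        if not s_idx:
            continue
        i = s_idx[-1]
        if i < len(ideal.dwells) - 1 and ideal.dwells[i + 1].label == n_state:
            final_s.append(ideal.dwells[i].n_frames * frame_interval)
    if len(final_s) < min_events:
        return RateEstimate(label="k_S->N", N=len(final_s), n=len(final_s),
                            nd=True)
    # One terminal event per trace: the anchored one-parameter fit has
    # near-MLE efficiency (see fit_event_exponential).
    est = fit_event_exponential(np.array(final_s), frame_interval,
                                min_events=min_events, n_boot=n_boot,
                                seed=seed, label="k_S->N",
                                n_traces=len(final_s))

    # Missed-event correction using the N-dwell decay.
    n_dwells = collect_dwells(ideals, n_state)
    k_dead = est.k_obs
    if n_dwells.n_uncensored >= min_events:
        k_n_obs = fit_dwell_exponential(n_dwells, frame_interval,
                                        min_dwells=min_events,
                                        n_boot=0).k_obs
        k_dead = deadtime_correct(est.k_obs, k_n_obs, tau_d)
        est.extra.update({"k_n_obs": k_n_obs,
                          "p_detect": float(np.exp(-k_n_obs * tau_d)),
                          "k_uncorrected_deadtime": est.k_obs})
    est.k_obs = k_dead
    est.tau = 1.0 / k_dead
    if np.isfinite(est.ci[0]) and est.extra.get("k_uncorrected_deadtime"):
        scale = k_dead / est.extra["k_uncorrected_deadtime"]
        est.ci = (est.ci[0] * scale, est.ci[1] * scale)
    # anchored event-time fit: no finite-window bias, k_pb only
    return _apply_correction(est, k_pb, np.inf)


def photobleach_rate(traces, photo=None, min_events=100, label="k_pb"):
    """Photobleaching rate constant from detected donor-bleach times.

    Bleach frames are found with the event detector; because bleach
    times span the whole observation window, the survival curve is
    fitted to the exact window-truncated exponential
    ``S(t) = (exp(-k t) - exp(-k T)) / (1 - exp(-k T))`` — a
    one-parameter fit that stays well-conditioned where the generic
    ``y0 + A exp(-t/tau)`` form becomes degenerate (k*T ~ 1).
    No photobleaching correction applies: this *is* the bleach rate.
    """
    from .processing import detect_events
    from .simulate import PhotophysicsModel

    if photo is None:
        photo = PhotophysicsModel()
    frame_interval = traces[0].frame_interval
    T = traces[0].n_frames * frame_interval
    times = []
    for tr in traces:
        events = [ev for ev in detect_events(tr, photo)
                  if ev.kind == "donor_bleach"]
        if events and events[0].frame > 0:
            times.append(events[0].frame * frame_interval)
    times = np.array(times)
    if times.size < min_events:
        raise DwellFitError(
            f"only {times.size} bleach events (>= {min_events} required)")

    t, s = _survival_points(times, frame_interval)

    def model(tt, k):
        return (np.exp(-k * tt) - np.exp(-k * T)) / (1.0 - np.exp(-k * T))

    popt, _ = optimize.curve_fit(model, t, s, p0=(1.0 / times.mean(),),
                                 bounds=(1e-6, 1e3), maxfev=10000)
    k = float(popt[0])
    resid = s - model(t, k)
    ss_tot = np.sum((s - s.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else np.nan
    return RateEstimate(label=label, k_obs=k, k_corrected=k, tau=1.0 / k,
                        y0=-np.exp(-k * T) / (1 - np.exp(-k * T)),
                        A=1.0 / (1 - np.exp(-k * T)), r_squared=r2,
                        N=len(traces), n=int(times.size),
                        extra={"window_s": T})


def transition_frequency(ideals, sync_threshold=None):
    """Transition frequencies per ordered state pair, both normalizations.

    Returns a dict ``pair -> {"n", "fraction", "per_trace"}`` where
    ``fraction`` is the share of all transitions (number of transitions
    between two states divided by the total number of transitions) and
    ``per_trace`` the mean number of such transitions per trace.  With
    ``sync_threshold`` given, only the post-synchronization part of each
    trace is counted.
    """
    counts = {}
    n_traces = 0
    total = 0
    for ideal in ideals:
        start = 0
        if sync_threshold is not None:
            s = _sync_frame(ideal, sync_threshold)
            if s is None:
                continue
            start = s
        n_traces += 1
        for a, b, frame in ideal.transitions:
            if frame < start:
                continue
            counts[(a, b)] = counts.get((a, b), 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no transitions found")
    return {
        pair: {"n": n, "fraction": n / total, "per_trace": n / n_traces}
        for pair, n in sorted(counts.items(), key=lambda kv: -kv[1])
    }


def fraction_reaching_state(ideals, target_state, window=None):
    """Fraction of traces whose final filtered dwell is ``target_state``.

    ``window`` (s) restricts the judgement to dwells starting within the
    window.  Returns (fraction, (wilson_low, wilson_high), n_traces).
    """
    from statsmodels.stats.proportion import proportion_confint

    n = 0
    hits = 0
    for ideal in ideals:
        if not ideal.dwells:
            continue
        dwells = ideal.dwells
        if window is not None:
            horizon = window / ideal.frame_interval
            dwells = [d for d in dwells if d.start_frame < horizon]
            if not dwells:
                continue
        n += 1
        if dwells[-1].label == target_state:
            hits += 1
    if n == 0:
        return np.nan, (np.nan, np.nan), 0
    lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
    return hits / n, (float(lo), float(hi)), n
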