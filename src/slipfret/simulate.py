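"""Camera-level rendering of latent state paths into two-channel traces.

The emission model inverts the FRET definition E = FI_A / (FI_D + FI_A):
given a per-frame effective FRET value, the true acceptor intensity is
``i_total * E`` and the true donor intensity ``i_total * (1 - E)``.  The
observed acceptor additionally receives a fraction ``beta`` of the donor
signal (spectral bleed-through), and both channels carry Gaussian
background.  The per-frame effective FRET is the exact time-occupancy
weighted average of the state means over the camera integration window
(so a transition occurring mid-frame produces a single intermediate-level
frame), plus one Gaussian noise term of the state's s.d. which carries
the full composite (conformational + shot) noise observed in real traces.

Photophysics:

* donor photobleaching (time ~ Exp(k_pb_donor)) sends both channels to
  background for the rest of the trace;
* acceptor photobleaching, or entry into a terminal scheme state
  (reporter dissociation), sends the acceptor to background and the
  donor to the full single-molecule intensity (dequenching);
* optional acceptor blinking is a reversible dark state with
  exponential on/off kinetics (disabled by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schemes import KineticScheme, ModeMixture, StatePath, sample_path

__all__ = [
    "PhotophysicsModel",
    "FluorescenceTrace",
    "render",
    "simulate_ensemble",
]


@dataclass(frozen=True)
class PhotophysicsModel:
    """Dye and detection parameters for trace rendering.

    Defaults reproduce the standard experimental conditions: a combined
    dye photobleaching constant of 0.03 1/s (modelled entirely in the
    donor channel, so that acceptor-signal loss on reporter-dissociation
    schemes is attributable to dissociation alone), donor-to-acceptor
    bleed-through 0.13, a total single-molecule intensity of 1000 counts
    and background noise of 10 counts.  ``noise_sd`` is additional
    per-channel detector noise; it defaults to 0 because the composite
    FRET-domain noise is already carried by the state s.d.
    """

    k_pb_donor: float = 0.03
    k_pb_acceptor: float = 0.0
    bleedthrough_beta: float = 0.13
    i_total: float = 1000.0
    noise_sd: float = 0.0
    background_mean: float = 0.0
    background_sd: float = 10.0
    blink_on_rate: float = 0.0   # dark -> emitting
    blink_off_rate: float = 0.0  # emitting -> dark

    def __post_init__(self):
        for name in ("k_pb_donor", "k_pb_acceptor", "noise_sd",
                     "background_sd", "blink_on_rate", "blink_off_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.bleedthrough_beta < 1:
            raise ValueError("bleedthrough_beta must be in [0, 1)")
        if self.i_total <= self.background_mean + 3 * self.background_sd:
            raise ValueError("i_total must exceed background_mean + 3*background_sd")

    def to_dict(self):
        return {k: float(getattr(self, k)) for k in (
            "k_pb_donor", "k_pb_acceptor", "bleedthrough_beta", "i_total",
            "noise_sd", "background_mean", "background_sd",
            "blink_on_rate", "blink_off_rate")}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class FluorescenceTrace:
    """Per-frame donor/acceptor intensities of one molecule.

    ``meta`` holds simulation ground truth when available: the scheme and
    component name, per-trace seed, the latent :class:`StatePath`, and
    donor-bleach / acceptor-loss event times.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be equal-length 1-d series")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self):
        return self.donor.size

    @property
    def times(self):
        return np.arange(self.n_frames) * self.frame_interval

    def total(self):
        return self.donor + self.acceptor


def _frame_fret_means(path, state_means, frame_interval, n_frames):
    """Exact occupancy-weighted mean FRET per frame, plus occupancy masks.

    Returns (values, occupied) where ``occupied[f]`` is the fraction of
    frame f during which a FRET signal exists (before any terminal entry
    and before the path runs out).
    """
    values = np.zeros(n_frames)
    occupied = np.zeros(n_frames)
    dt = frame_interval
    for lbl, t0, t1 in path.dwells:
        mu = state_means[lbl]
        f0 = int(np.floor(t0 / dt))
        f1 = min(int(np.ceil(t1 / dt)), n_frames)
        if f0 >= n_frames:
            break
        idx = np.arange(f0, f1)
        lo = np.maximum(idx * dt, t0)
        hi = np.minimum((idx + 1) * dt, t1)
        w = np.clip(hi - lo, 0.0, None) / dt
        values[idx] += mu * w
        occupied[idx] += w
    nz = occupied > 0
    values[nz] = values[nz] / occupied[nz]
    return values, occupied


def render(path, photo, frame_interval, n_frames, seed, state_sds=None,
           state_means=None):
    """Render a latent :class:`StatePath` into a :class:`FluorescenceTrace`.

    Parameters
    ----------
    path : StatePath
    photo : PhotophysicsModel
    frame_interval : float
        Camera frame time in seconds.
    n_frames : int
        Number of frames; if shorter than the path duration the trace is
        simply truncated at ``n_frames`` (documented behaviour).
    seed : int or numpy.random.Generator
    state_means, state_sds : dict, optional
        label -> FRET mean / s.d.  Required when the path does not come
        from a scheme simulated through :func:`simulate_ensemble`; there
        they are filled from the scheme automatically.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if state_means is None or state_sds is None:
        raise ValueError("state_means and state_sds are required")

    e_frame, occupied = _frame_fret_means(path, state_means, frame_interval, n_frames)
    t_frame = np.arange(n_frames) * frame_interval

    # Composite per-frame FRET noise at the (occupancy-weighted) state s.d.
    sd_frame = np.zeros(n_frames)
    if state_sds:
        sdv, _ = _frame_fret_means(path, state_sds, frame_interval, n_frames)
        sd_frame = sdv
    noisy_e = e_frame + rng.normal(0.0, 1.0, n_frames) * sd_frame

    # Event times ------------------------------------------------------
    t_donor_bleach = (rng.exponential(1.0 / photo.k_pb_donor)
                      if photo.k_pb_donor > 0 else np.inf)
    t_acc_bleach = (rng.exponential(1.0 / photo.k_pb_acceptor)
                    if photo.k_pb_acceptor > 0 else np.inf)
    t_terminal = path.terminal_time if path.terminated else np.inf
    # Signal also ends where the path itself ends (shorter than window).
    t_path_end = path.duration if not path.terminated else np.inf
    t_acc_loss = min(t_acc_bleach, t_terminal)

    acc_true = photo.i_total * noisy_e
    don_true = photo.i_total * (1.0 - noisy_e)

    # Acceptor loss: acceptor to background, donor dequenched to i_total.
    lost = t_frame >= t_acc_loss
    acc_true[lost] = 0.0
    don_true[lost] = photo.i_total

    # Optional acceptor blinking (reversible dark state).
    if photo.blink_off_rate > 0 and photo.blink_on_rate > 0:
        dark = np.zeros(n_frames, dtype=bool)
        t, is_dark = 0.0, False
        t_end = n_frames * frame_interval
        while t < t_end:
            rate = photo.blink_on_rate if is_dark else photo.blink_off_rate
            dt_ev = rng.exponential(1.0 / rate)
            if is_dark:
                f0 = int(t / frame_interval)
                f1 = min(int(np.ceil((t + dt_ev) / frame_interval)), n_frames)
                dark[f0:f1] = True
            t += dt_ev
            is_dark = not is_dark
        dark &= ~lost
        acc_true[dark] = 0.0
        don_true[dark] = photo.i_total

    # Donor bleach kills both channels.
    dead = t_frame >= t_donor_bleach
    acc_true[dead] = 0.0
    don_true[dead] = 0.0
    # Frames past the end of a (short) path carry no signal either.
    ended = t_frame >= t_path_end
    acc_true[ended] = 0.0
    don_true[ended] = 0.0

    acc_obs = acc_true + photo.bleedthrough_beta * don_true
    don_obs = don_true
    if photo.noise_sd > 0:
        acc_obs = acc_obs + rng.normal(0.0, photo.noise_sd, n_frames)
        don_obs = don_obs + rng.normal(0.0, photo.noise_sd, n_frames)
    acc_obs = acc_obs + photo.background_mean + rng.normal(0.0, photo.background_sd, n_frames)
    don_obs = don_obs + photo.background_mean + rng.normal(0.0, photo.background_sd, n_frames)

    meta = {
        "scheme": path.scheme_name,
        "path": path,
        "t_donor_bleach": None if not np.isfinite(t_donor_bleach) else float(t_donor_bleach),
        "t_acceptor_bleach": None if not np.isfinite(t_acc_bleach) else float(t_acc_bleach),
        "t_dissociation": None if not np.isfinite(t_terminal) else float(t_terminal),
    }
    return FluorescenceTrace(don_obs, acc_obs, frame_interval, meta=meta)


def _scheme_emission_maps(scheme):
    means = {s.label: s.fret_mean for s in scheme.states}
    sds = {s.label: (0.0 if scheme.is_terminal(s.label) else s.fret_sd)
           for s in scheme.states}
    return means, sds


def simulate_ensemble(mixture, n_traces, photo, t_max, frame_interval, seed):
    """Simulate an ensemble of traces from a mode mixture.

    Each trace draws its mixture component by weight; per-trace seeds are
    spawned deterministically from the master seed, so a fixed seed gives
    a bit-identical ensemble and manifest.

    Returns
    -------
    traces : list of FluorescenceTrace
    manifest : dict
        Ground truth: mixture definition, photophysics, per-trace
        component, seed, and event times.
    """
    if isinstance(mixture, KineticScheme):
        mixture = ModeMixture([(mixture, 1.0)])
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = np.random.SeedSequence(seed)
    comp_rng = np.random.default_rng(master.spawn(1)[0])
    comp_idx = comp_rng.choice(len(mixture.components), size=n_traces,
                               p=mixture.weights)
    child_seqs = master.spawn(n_traces + 1)[1:]

    n_frames = int(round(t_max / frame_interval))
    traces = []
    records = []
    for t_i in range(n_traces):
        c = mixture.components[int(comp_idx[t_i])]
        rng = np.random.default_rng(child_seqs[t_i])
        path = sample_path(c.scheme, t_max, rng)
        means, sds = _scheme_emission_maps(c.scheme)
        trace = render(path, photo, frame_interval, n_frames, rng,
                       state_sds=sds, state_means=means)
        trace.meta.update({
            "trace_id": t_i,
            "component": c.label,
            "mixture": mixture.name,
        })
        traces.append(trace)
        records.append({
            "trace_id": t_i,
            "component": c.label,
            "t_donor_bleach": trace.meta["t_donor_bleach"],
            "t_acceptor_bleach": trace.meta["t_acceptor_bleach"],
            "t_dissociation": trace.meta["t_dissociation"],
            "path": path.to_jsonable(),
        })
    manifest = {
        "mixture": mixture.to_dict(),
        "photophysics": photo.to_dict(),
        "n_traces": int(n_traces),
        "t_max": float(t_max),
        "frame_interval": float(frame_interval),
        "seed": int(seed),
        "traces": records,
    }
    return traces, manifest
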