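"""Synchronized ensembles, contour grids, and the slow-fraction regression.

Traces are aligned at a kinetic event (synchronization), e.g. the first
idealized FRET value below 0.5 for the peptidyl-tRNA reporter, or the
last entry into the swiveled (S) state for the head reporter.  From the
aligned matrix, time-resolved occupancy contours and post-synchronization
histograms are built; the fraction of slow traces per condition is
regressed against the biochemical frameshifting efficiency by OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import Histogram
from .kinetics import _sync_frame

__all__ = [
    "SyncRule",
    "SyncEnsemble",
    "RegressionResult",
    "synchronize",
    "contour",
    "post_sync_histogram",
    "linear_fit",
    "plot_contour",
]


@dataclass(frozen=True)
class SyncRule:
    """Synchronization rule: ``first_below(x)`` or ``last_entry(state)``.

    ``first_below`` aligns at the first frame whose idealized mean lies
    below a FRET threshold; ``last_entry`` aligns at the first frame of
    the last dwell in a named state.  The alternative reading of the
    trace-alignment prescription — first idealized value below (lowest
    PRE-state mean - 0.1) — is expressed as ``first_below`` with that
    derived threshold.
    """

    kind: str
    value: float | str

    def __post_init__(self):
        if self.kind not in ("first_below", "last_entry"):
            raise ValueError("rule must be first_below or last_entry")

    def sync_frame(self, ideal):
        if self.kind == "first_below":
            return _sync_frame(ideal, float(self.value))
        frame = None
        for d in ideal.dwells:
            if d.label == self.value:
                frame = d.start_frame
        return frame


@dataclass
class SyncEnsemble:
    """FRET values aligned at each trace's synchronization event.

    ``aligned[i, j]`` is trace i's FRET at offset ``offsets[j]`` frames
    from its sync event; frames outside a trace's span are NaN.
    """

    aligned: np.ndarray
    offsets: np.ndarray
    frame_interval: float
    sync_rule: SyncRule
    n_included: int
    n_excluded: int
    excluded_reasons: dict = field(default_factory=dict)


def synchronize(ideals, frets, rule):
    """Align traces at the frames selected by *rule*.

    ``ideals`` provide the sync events, ``frets`` the raw FRET values
    (pairs aligned by position).  Traces without the event are excluded
    and counted.  The result is invariant to trace ordering up to row
    permutation.
    """
    if len(ideals) != len(frets):
        raise ValueError("ideals and frets must align")
    rows = []
    syncs = []
    n_excluded = 0
    for ideal, fret in zip(ideals, frets):
        s = rule.sync_frame(ideal)
        if s is None or fret.n_valid == 0:
            n_excluded += 1
            continue
        rows.append(fret.efficiency[:fret.n_valid])
        syncs.append(s)
    if not rows:
        raise ValueError("no traces qualify for the synchronization rule")
    pre = max(syncs)
    post = max(len(r) - s for r, s in zip(rows, syncs))
    offsets = np.arange(-pre, post)
    aligned = np.full((len(rows), offsets.size), np.nan)
    for i, (r, s) in enumerate(zip(rows, syncs)):
        aligned[i, pre - s:pre - s + len(r)] = r
    return SyncEnsemble(aligned, offsets, frets[0].frame_interval, rule,
                        n_included=len(rows), n_excluded=n_excluded,
                        excluded_reasons={"no_sync_event": n_excluded})


def contour(sync, t_range, fret_bins=None):
    """Time-resolved FRET occupancy grid, column-normalized by n_included.

    Parameters
    ----------
    sync : SyncEnsemble
    t_range : (t_min, t_max)
        Time window in seconds relative to the sync point.
    fret_bins : array_like, optional
        FRET bin edges (default 0.02-wide bins over [-0.1, 1.1]).

    Returns
    -------
    grid : (n_fret_bins, n_time_cols) ndarray
        ``grid[:, j].sum()`` equals (frames present in column j) /
        n_included, i.e. column mass <= 1 with missing frames reducing it.
    t_centers, fret_edges
    """
    if fret_bins is None:
        fret_bins = np.arange(-0.1, 1.1 + 1e-9, 0.02)
    fret_bins = np.asarray(fret_bins, dtype=float)
    t_min, t_max = t_range
    dt = sync.frame_interval
    cols = np.flatnonzero((sync.offsets * dt >= t_min) &
                          (sync.offsets * dt < t_max))
    if cols.size == 0:
        raise ValueError("empty time range")
    grid = np.zeros((fret_bins.size - 1, cols.size))
    clipped = np.clip(sync.aligned, fret_bins[0], fret_bins[-1] - 1e-12)
    for j, c in enumerate(cols):
        col = clipped[:, c]
        col = col[np.isfinite(col)]
        if col.size:
            counts, _ = np.histogram(col, bins=fret_bins)
            grid[:, j] = counts / sync.n_included
    return grid, sync.offsets[cols] * dt, fret_bins


def post_sync_histogram(sync, bin_width=0.02, range_=(-0.1, 1.1)):
    """Histogram of all FRET values at and after the sync point."""
    post = sync.aligned[:, sync.offsets >= 0]
    vals = post[np.isfinite(post)]
    if vals.size == 0:
        raise ValueError("no post-synchronization frames")
    n_bins = int(round((range_[1] - range_[0]) / bin_width))
    counts, edges = np.histogram(vals, bins=n_bins, range=range_)
    return Histogram(edges, counts, int(counts.sum()))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float

    def __post_init__(self):
        if not (np.isnan(self.r_squared) or 0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def linear_fit(x, y):
    """Ordinary least squares y = slope*x + intercept with slope s.e.

    Used for the frameshifting-efficiency vs slow-fraction correlation;
    requires >= 3 points and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=float(res.rsquared), slope_se=float(res.bse[1]))


def plot_contour(sync, t_range, ax=None, smooth_sigma=0.0, **imshow_kw):
    """Render a contour grid with matplotlib (smoothing is plot-only)."""
    import matplotlib.pyplot as plt

    grid, t, edges = contour(sync, t_range)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter
        grid = gaussian_filter(grid, smooth_sigma)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid, origin="lower", aspect="auto",
                   extent=[t[0], t[-1], edges[0], edges[-1]],
                   cmap=imshow_kw.pop("cmap", "viridis"), **imshow_kw)
    ax.set_xlabel("time from synchronization (s)")
    ax.set_ylabel("FRET")
    return ax, im
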