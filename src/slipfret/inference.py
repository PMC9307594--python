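"""Global FRET state model and per-trace HMM idealization.

The state model is fitted once per ensemble: all valid FRET frames are
pooled into a histogram which is fitted to a sum of Gaussians, yielding
the state means, s.d. and occupancies.  Each trace is then idealized with
a Gaussian-emission hidden Markov model (maximum-likelihood EM; state
count either fixed or selected per trace by the Bayesian information
criterion) and decoded with the Viterbi algorithm.  Finally, FRET changes
smaller than the state s.d. are not considered transitions and are
removed by merging dwells (the sub-s.d. transition filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Histogram",
    "GaussianStateModel",
    "HmmFit",
    "IdealizedTrace",
    "pooled_histogram",
    "fit_gaussian_sum",
    "fit_hmm",
    "idealize",
    "filter_small_transitions",
    "idealize_trace",
]

HIST_RANGE = (-0.1, 1.1)
DEFAULT_BIN_WIDTH = 0.02
SIGMA_FLOOR = 0.02


@dataclass
class Histogram:
    """FRET histogram over pooled valid frames."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if int(self.counts.sum()) != int(self.n_samples):
            raise ValueError("counts must sum to n_samples")

    @property
    def centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self):
        return np.diff(self.bin_edges)

    def density(self):
        if self.n_samples == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / (self.n_samples * self.widths)


@dataclass(frozen=True)
class GaussianState:
    label: str
    mu: float
    sigma: float
    weight: float


class GaussianStateModel:
    """Sum-of-Gaussians FRET state model (means sorted descending)."""

    def __init__(self, components, residual_norm=None):
        comps = []
        for c in components:
            comps.append(c if isinstance(c, GaussianState) else GaussianState(*c))
        comps.sort(key=lambda c: -c.mu)
        mus = [c.mu for c in comps]
        if len(set(np.round(mus, 9))) != len(mus):
            raise ValueError("state means must be unique")
        if any(c.sigma <= 0 for c in comps):
            raise ValueError("state s.d. must be > 0")
        w = sum(c.weight for c in comps)
        if abs(w - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        self.components = tuple(comps)
        self.residual_norm = residual_norm

    @classmethod
    def from_mixture(cls, mixture, weights=None):
        """Build the model from a mode mixture's emitting FRET levels."""
        states = mixture.fret_states()
        if weights is None:
            weights = [1.0 / len(states)] * len(states)
        return cls([(lbl, mu, sd, w)
                    for (lbl, mu, sd), w in zip(states, weights)])

    def __len__(self):
        return len(self.components)

    @property
    def labels(self):
        return tuple(c.label for c in self.components)

    @property
    def means(self):
        return np.array([c.mu for c in self.components])

    @property
    def sigmas(self):
        return np.array([c.sigma for c in self.components])

    @property
    def weights(self):
        return np.array([c.weight for c in self.components])

    def state(self, label):
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no state {label!r}")

    def nearest_label(self, value):
        return self.labels[int(np.argmin(np.abs(self.means - value)))]

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.weight * stats.norm.pdf(x, c.mu, c.sigma)
        return out

    def __repr__(self):
        parts = ", ".join(
            f"{c.label}: {c.mu:.3f}+-{c.sigma:.3f} (w={c.weight:.2f})"
            for c in self.components)
        return f"GaussianStateModel({parts})"


def pooled_histogram(traces, bin_width=DEFAULT_BIN_WIDTH, range_=HIST_RANGE):
    """Histogram of all valid FRET frames over an ensemble of FretTraces.

    Frames outside the histogram range (rare noise outliers) are
    dropped, not piled into the edge bins — an edge spike would bias
    any subsequent Gaussian-sum fit.
    """
    values = [tr.valid_values() for tr in traces if tr.n_valid]
    if not values:
        raise ValueError("no valid frames in input traces")
    pooled = np.concatenate(values)
    n_bins = int(round((range_[1] - range_[0]) / bin_width))
    counts, edges = np.histogram(pooled, bins=n_bins, range=range_)
    return Histogram(edges, counts, int(counts.sum()))


def _kmeans_1d(values, k, weights=None, n_iter=50):
    """Deterministic 1-d weighted k-means (quantile-seeded Lloyd)."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    qs = np.linspace(0, 1, 2 * k + 1)[1::2]
    order = np.argsort(values)
    cw = np.cumsum(weights[order]) / weights.sum()
    centers = np.array([values[order][np.searchsorted(cw, q)] for q in qs])
    centers = np.unique(centers)
    while centers.size < k:  # degenerate seeding: spread over range
        centers = np.unique(np.append(centers, centers.max() + 0.05))
    for _ in range(n_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            m = assign == j
            if weights[m].sum() > 0:
                new[j] = np.average(values[m], weights=weights[m])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def _weighted_em_1d(centers, weights, mu0, sd0=0.08, n_iter=2000, tol=1e-12,
                    tied=True):
    """EM for a 1-d Gaussian mixture on binned data (deterministic).

    Treats each bin center as a point with multiplicity ``weights``.
    With ``tied=True`` all components share one s.d. — the appropriate
    model when every FRET state carries the same composite noise width,
    and the regularisation that removes the weight-vs-width degeneracy
    along which the free mixture likelihood drifts when components
    overlap at ~2 s.d. separation.
    """
    k = len(mu0)
    mu = np.asarray(mu0, dtype=float).copy()
    sd = np.full(k, sd0)
    w = np.full(k, 1.0 / k)
    weights = weights / weights.sum()
    prev = -np.inf
    for _ in range(n_iter):
        dens = np.array([wj * stats.norm.pdf(centers, m, s)
                         for wj, m, s in zip(w, mu, sd)])
        tot = dens.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(weights * np.log(tot)))
        resp = dens / tot
        var_acc = 0.0
        for j in range(k):
            rj = resp[j] * weights
            nj = rj.sum()
            if nj <= 1e-12:
                continue
            w[j] = nj
            mu[j] = float(np.sum(rj * centers) / nj)
            var = float(np.sum(rj * (centers - mu[j]) ** 2))
            if tied:
                var_acc += var
            else:
                sd[j] = max(np.sqrt(var / nj), 0.005)
        w = w / w.sum()
        if tied:
            sd[:] = max(np.sqrt(var_acc), 0.005)
        if abs(ll - prev) < tol:
            break
        prev = ll
    return w, mu, sd


class GaussianSumFitError(RuntimeError):
    def __init__(self, message, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}


def fit_gaussian_sum(hist, k, init=None, max_iter=2000, tied_sigma=True):
    """Fit a k-component Gaussian sum to a FRET histogram.

    The mixture ``sum_k w_k N(mu_k, sigma_k)`` is fitted to the binned
    data by maximum likelihood (EM with the bin counts as multiplicities
    of the bin centers), which is deterministic for a fixed
    initialisation and free of the spurious optima that a plain
    nonlinear least-squares descent on the bin densities falls into
    when components overlap.  By default all components share one s.d.
    (``tied_sigma``): every FRET state carries the same composite noise
    width, and the tie removes the weight-vs-width drift direction of
    the free mixture likelihood at ~2 s.d. component separation.  Means
    are initialised from ``init`` when given, otherwise by a weighted
    1-d k-means on the bin centers.

    Returns a :class:`GaussianStateModel` whose ``residual_norm``
    carries the 2-norm of the residual between the fitted density and
    the histogram densities (the fit-quality metric); states are
    labelled ``s1..sk`` by descending mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if hist.n_samples == 0:
        raise ValueError("histogram is empty")
    x = hist.centers
    y = hist.density()
    occupied = y > 0
    if init is not None:
        seed_mu = np.sort(np.asarray(init, dtype=float))
        if seed_mu.size != k:
            raise ValueError("init must provide one mean per component")
    else:
        seed_mu = _kmeans_1d(x[occupied], k, weights=y[occupied])
    w, mu, sd = _weighted_em_1d(x, hist.counts.astype(float) + 1e-12,
                                seed_mu, n_iter=max_iter, tied=tied_sigma)
    if not np.all(np.isfinite(mu)) or w.sum() <= 0:
        raise GaussianSumFitError(
            "Gaussian-sum fit collapsed",
            diagnostics={"weights": w.tolist(), "means": mu.tolist()})
    w = w / w.sum()
    model = np.zeros_like(x)
    for j in range(k):
        model += w[j] * stats.norm.pdf(x, mu[j], sd[j])
    residual_norm = float(np.linalg.norm(model - y))
    # duplicate means (collapsed components) cannot form a state model
    mu_adj = mu.copy()
    for j in range(1, k):
        order = np.argsort(mu_adj)
        for a, b in zip(order, order[1:]):
            if abs(mu_adj[a] - mu_adj[b]) < 1e-9:
                mu_adj[b] += 1e-6
    order = np.argsort(-mu_adj)
    comps = [(f"s{r+1}", float(mu_adj[j]), float(sd[j]), float(w[j]))
             for r, j in enumerate(order)]
    return GaussianStateModel(comps, residual_norm=residual_norm)


# --------------------------------------------------------------------------
# HMM idealization
# --------------------------------------------------------------------------

@dataclass
class HmmFit:
    """Converged Gaussian-emission HMM for one trace."""

    means: np.ndarray
    sigmas: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    bic: float
    n_states: int
    converged: bool
    state_labels: tuple = ()   # mapping to global model labels (nearest mean)
    n_frames: int = 0


TRANSMAT_DIAG0 = 0.85


def _sanitize_hmm(hmm, k, fallback_means):
    """Repair EM degeneracies (empty states leave NaN rows/params)."""
    sp = hmm.startprob_
    if not np.all(np.isfinite(sp)) or abs(sp.sum() - 1.0) > 1e-6:
        hmm.startprob_ = np.full(k, 1.0 / k)
    tm = hmm.transmat_
    bad = ~np.isfinite(tm).all(axis=1) | (np.abs(tm.sum(axis=1) - 1.0) > 1e-6)
    if bad.any():
        tm = tm.copy()
        tm[bad] = 1.0 / k
        hmm.transmat_ = tm
    if not np.all(np.isfinite(hmm.means_)):
        m = hmm.means_.copy()
        fb = np.asarray(fallback_means, dtype=float).reshape(-1, 1)
        m[~np.isfinite(m)] = fb[~np.isfinite(m)]
        hmm.means_ = m
    cv = hmm.covars_.reshape(k, -1)
    if not np.all(np.isfinite(cv)) or np.any(cv <= 0):
        cv = np.where(np.isfinite(cv) & (cv > 0), cv, SIGMA_FLOOR ** 2)
        hmm.covars_ = cv[:, 0].reshape(-1, 1)


def _fit_hmm_fixed_k(values, k, init_means, init_sigmas, tol, max_iter,
                     transmat_diag=TRANSMAT_DIAG0, fix_emissions=False):
    import logging

    from hmmlearn.hmm import GaussianHMM
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    hmm = GaussianHMM(
        n_components=k, covariance_type="diag",
        min_covar=SIGMA_FLOOR ** 2, tol=tol, n_iter=max_iter,
        init_params="", params="st" if fix_emissions else "stmc",
        random_state=0,
    )
    hmm.startprob_ = np.full(k, 1.0 / k)
    trans = np.full((k, k), (1.0 - transmat_diag) / max(k - 1, 1))
    np.fill_diagonal(trans, transmat_diag if k > 1 else 1.0)
    hmm.transmat_ = trans
    hmm.means_ = np.asarray(init_means, dtype=float).reshape(-1, 1)
    hmm.covars_ = np.maximum(np.asarray(init_sigmas, dtype=float) ** 2,
                             SIGMA_FLOOR ** 2).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            hmm.fit(values)
        except ValueError:
            pass
        _sanitize_hmm(hmm, k, init_means)
        logl = float(hmm.score(values))
    return hmm, logl


def fit_hmm(fret, model=None, k_range=None, tol=1e-6, max_iter=1000):
    """Fit a Gaussian-emission HMM to one FRET trace by EM.

    When the candidate state count matches the global ``model``, the
    emission parameters are taken from the model and held fixed while EM
    learns the per-trace dynamics (start and transition probabilities) —
    per-trace emission refitting at this noise level only destabilises a
    trusted state model.  For other state counts the emissions are
    initialised from a deterministic 1-d k-means of the trace values and
    refined by EM (s.d. bounded below at 0.02).  With ``k_range`` given,
    one HMM is fitted per candidate state count and the winner chosen by
    BIC.  Fitted states are mapped back to the global model labels by
    nearest mean when a model is supplied.
    """
    values = fret.valid_values().reshape(-1, 1)
    if values.shape[0] < 10:
        raise ValueError("need >= 10 valid frames to fit an HMM")

    if k_range is None:
        if model is None:
            raise ValueError("provide a GaussianStateModel or a k_range")
        ks = [len(model)]
    else:
        ks = sorted(int(k) for k in k_range)

    fits = []
    n = values.shape[0]
    for k in ks:
        fixed = model is not None and k == len(model)
        if fixed:
            mu0, sd0 = model.means, np.maximum(model.sigmas, 0.05)
        else:
            mu0 = _kmeans_1d(values[:, 0], k)
            sd0 = np.full(k, 0.1)
        hmm, logl = _fit_hmm_fixed_k(values, k, mu0, sd0, tol, max_iter,
                                     fix_emissions=fixed)
        p = (k - 1) + k * (k - 1) + (0 if fixed else 2 * k)
        bic = -2.0 * logl + p * np.log(n)
        fits.append((bic, k, hmm, logl))
    bic, k, hmm, logl = min(fits, key=lambda t: t[0])

    means = hmm.means_[:, 0].copy()
    sigmas = np.sqrt(hmm.covars_.reshape(k, -1)[:, 0])
    # Degenerate components: s.d. at the floor with < 2 assigned frames.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = hmm.predict(values)
    counts = np.bincount(path, minlength=k)
    for j in range(k):
        if 0 < counts[j] < 2 and sigmas[j] <= SIGMA_FLOOR * 1.01:
            warnings.warn(
                f"HMM component {j} degenerate (sigma at floor, "
                f"{counts[j]} frame); pruned from reporting", RuntimeWarning)
    labels = (tuple(model.nearest_label(m) for m in means)
              if model is not None else tuple(f"s{j+1}" for j in range(k)))
    fit = HmmFit(means=means, sigmas=sigmas, transmat=hmm.transmat_.copy(),
                 startprob=hmm.startprob_.copy(), log_likelihood=logl,
                 bic=float(bic), n_states=k,
                 converged=bool(hmm.monitor_.converged),
                 state_labels=labels, n_frames=n)
    fit._hmm = hmm
    return fit


@dataclass
class Dwell:
    label: str
    start_frame: int
    n_frames: int
    mean: float


@dataclass
class IdealizedTrace:
    """Discrete state path of one trace over its valid prefix."""

    dwells: list                      # list of Dwell, partitioning the prefix
    frame_interval: float
    n_valid: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = 0
        for d in self.dwells:
            if d.start_frame != f or d.n_frames <= 0:
                raise ValueError("dwells must partition the valid prefix")
            f += d.n_frames
        if self.dwells and f != self.n_valid:
            raise ValueError("dwells must cover exactly the valid prefix")
        for a, b in zip(self.dwells, self.dwells[1:]):
            if a.label == b.label:
                raise ValueError("consecutive dwells must differ in state")

    @property
    def state_seq(self):
        """Per-frame dwell index over the valid prefix."""
        out = np.empty(self.n_valid, dtype=int)
        for i, d in enumerate(self.dwells):
            out[d.start_frame:d.start_frame + d.n_frames] = i
        return out

    @property
    def frame_labels(self):
        out = np.empty(self.n_valid, dtype=object)
        for d in self.dwells:
            out[d.start_frame:d.start_frame + d.n_frames] = d.label
        return out

    @property
    def transitions(self):
        """(from_label, to_label, frame of arrival) for each state change."""
        out = []
        for a, b in zip(self.dwells, self.dwells[1:]):
            out.append((a.label, b.label, b.start_frame))
        return out

    @property
    def n_transitions(self):
        return max(len(self.dwells) - 1, 0)

    def duration(self):
        return self.n_valid * self.frame_interval


def _dwells_from_labels(labels, means_by_label):
    dwells = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            dwells.append(Dwell(labels[start], start, i - start,
                                means_by_label[labels[start]]))
            start = i
    return dwells


def idealize(fit, fret, decode="posterior"):
    """Decode a fitted HMM into an IdealizedTrace.

    ``decode="posterior"`` (default) takes the per-frame maximum of the
    smoothed state posterior, which recovers short dwells at camera-
    limited fluctuation rates more completely than the joint most
    probable path; ``decode="viterbi"`` gives the classic Viterbi path.
    """
    values = fret.valid_values().reshape(-1, 1)
    meta = dict(fret.meta)
    meta["truncation_reason"] = fret.truncation_reason
    if values.shape[0] == 0:
        return IdealizedTrace([], fret.frame_interval, 0, meta=meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if decode == "viterbi":
            path = fit._hmm.predict(values)
        elif decode == "posterior":
            path = np.argmax(fit._hmm.predict_proba(values), axis=1)
        else:
            raise ValueError("decode must be 'posterior' or 'viterbi'")
    labels = [fit.state_labels[j] for j in path]
    # Components mapped to the same global label merge into one dwell state.
    means = {lbl: float(m) for lbl, m in zip(fit.state_labels, fit.means)}
    dwells = _dwells_from_labels(labels, means)
    return IdealizedTrace(dwells, fret.frame_interval, values.shape[0],
                          meta=meta)


def filter_small_transitions(ideal, model):
    """Remove idealized transitions smaller than the state s.d.

    A transition with ``|mu_from - mu_to| < max(sigma_from, sigma_to)``
    cannot be distinguished from noise; it is removed by relabelling the
    shorter of its two flanking dwells to the longer one's state (on a
    tie, the later dwell merges into the earlier) and merging equal-label
    runs.  Iterates until no sub-threshold transitions remain; idempotent
    and never increases the transition count.
    """
    if not ideal.dwells:
        return ideal

    def mu(lbl):
        return model.state(lbl).mu

    def sd(lbl):
        return model.state(lbl).sigma

    dwells = [[d.label, d.n_frames] for d in ideal.dwells]
    changed = True
    while changed:
        changed = False
        for i in range(len(dwells) - 1):
            a, b = dwells[i], dwells[i + 1]
            if abs(mu(a[0]) - mu(b[0])) < max(sd(a[0]), sd(b[0])):
                if b[1] > a[1]:
                    a[0] = b[0]       # earlier (shorter) dwell absorbed
                else:
                    b[0] = a[0]       # later dwell absorbed (ties -> earlier)
                # merge equal-label runs
                merged = []
                for lbl, n in dwells:
                    if merged and merged[-1][0] == lbl:
                        merged[-1][1] += n
                    else:
                        merged.append([lbl, n])
                dwells = merged
                changed = True
                break

    out = []
    start = 0
    for lbl, n in dwells:
        out.append(Dwell(lbl, start, n, mu(lbl)))
        start += n
    return IdealizedTrace(out, ideal.frame_interval, ideal.n_valid,
                          meta=dict(ideal.meta))


def idealize_trace(fret, model, k_range=None, tol=1e-6, max_iter=1000,
                   decode="posterior"):
    """Convenience: HMM fit + decode + sub-s.d. filter for one trace."""
    fit = fit_hmm(fret, model=model, k_range=k_range, tol=tol,
                  max_iter=max_iter)
    return filter_small_transitions(idealize(fit, fret, decode=decode), model)
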