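"""Continuous-time Markov schemes for smFRET trajectory simulation.

A :class:`KineticScheme` is a labelled continuous-time Markov chain whose
states carry FRET emission parameters (mean, s.d.).  Trajectories are
realised with the Gillespie algorithm (:func:`sample_path`): the dwell in
state *i* is exponential with rate ``sum_j k[i][j]`` and the successor is
drawn with probability ``k[i][j] / sum_j k[i][j]``.  Terminal states (for
example tRNA dissociation, which ends the FRET signal) absorb the path.

Several schemes mixed with fixed weights form a :class:`ModeMixture`,
e.g. the fast/slow translocation modes of a ribosome population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SchemeState",
    "KineticScheme",
    "ModeMixture",
    "StatePath",
    "sample_path",
    "mean_first_passage_time",
]

_ATOL = 1e-9


@dataclass(frozen=True)
class SchemeState:
    """One state of a kinetic scheme.

    Parameters
    ----------
    label : str
        State name (e.g. ``"CHI"``).
    fret_mean : float
        Mean FRET efficiency emitted while in the state, dimensionless.
    fret_sd : float
        Standard deviation of the emitted FRET efficiency.  The default
        0.1 is the composite (conformational + shot noise) width of a
        FRET state observed in TIRF traces of single ribosomes.
    """

    label: str
    fret_mean: float
    fret_sd: float = 0.1


class KineticScheme:
    """Labelled CTMC with FRET emission parameters.

    Parameters
    ----------
    name : str
        Scheme identifier.
    states : sequence of SchemeState or (label, mean[, sd]) tuples
    rates : (n, n) array_like
        Off-diagonal entries ``rates[i, j]`` are transition rates i -> j
        in 1/s; the diagonal is ignored.  All off-diagonal entries must
        be non-negative.
    initial_probs : array_like, optional
        Per-state start probabilities (default: all mass on state 0).
    terminal_states : set of str, optional
        Labels whose entry ends the FRET signal (e.g. ``"dissociated"``).
        Terminal states must have no outgoing rates.
    """

    def __init__(self, name, states, rates, initial_probs=None,
                 terminal_states=()):
        self.name = str(name)
        parsed = []
        for s in states:
            if isinstance(s, SchemeState):
                parsed.append(s)
            else:
                parsed.append(SchemeState(*s))
        self.states = tuple(parsed)
        n = len(self.states)
        if n == 0:
            raise ValueError("scheme needs at least one state")
        self.labels = tuple(s.label for s in self.states)
        if len(set(self.labels)) != n:
            raise ValueError("state labels must be unique")

        rates = np.asarray(rates, dtype=float)
        if rates.shape != (n, n):
            raise ValueError(f"rates must be ({n}, {n}), got {rates.shape}")
        off = rates[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        self.rates = rates.copy()
        np.fill_diagonal(self.rates, 0.0)

        if initial_probs is None:
            initial_probs = np.zeros(n)
            initial_probs[0] = 1.0
        initial_probs = np.asarray(initial_probs, dtype=float)
        if initial_probs.shape != (n,) or np.any(initial_probs < 0):
            raise ValueError("initial_probs must be a length-n non-negative vector")
        if abs(initial_probs.sum() - 1.0) > _ATOL:
            raise ValueError("initial_probs must sum to 1")
        self.initial_probs = initial_probs

        self.terminal_states = frozenset(terminal_states)
        unknown = self.terminal_states - set(self.labels)
        if unknown:
            raise ValueError(f"unknown terminal states: {sorted(unknown)}")
        for lbl in self.terminal_states:
            i = self.index(lbl)
            if self.rates[i].sum() > 0:
                raise ValueError(f"terminal state {lbl!r} has outgoing rates")

        # Emitting states with distinct means must be separated by more
        # than the larger s.d., otherwise they are not resolvable states.
        emit = [s for s in self.states if s.label not in self.terminal_states]
        means = sorted({round(s.fret_mean, 9) for s in emit})
        for a, b in zip(means, means[1:]):
            sd = max(s.fret_sd for s in emit
                     if round(s.fret_mean, 9) in (a, b))
            if 0 < b - a <= sd:
                raise ValueError(
                    f"FRET means {a} and {b} closer than the state s.d. {sd}")

    # -- introspection -------------------------------------------------
    @property
    def n_states(self):
        return len(self.states)

    def index(self, label):
        """Index of the state named *label*."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no state {label!r} in scheme {self.name!r}") from None

    def exit_rate(self, label):
        """Total exit rate (1/s) out of the state named *label*."""
        return float(self.rates[self.index(label)].sum())

    def fret_mean(self, label):
        return self.states[self.index(label)].fret_mean

    def is_terminal(self, label):
        return label in self.terminal_states

    def with_rate(self, from_label, to_label, value):
        """Return a copy of the scheme with one rate replaced."""
        rates = self.rates.copy()
        rates[self.index(from_label), self.index(to_label)] = float(value)
        return KineticScheme(self.name, self.states, rates,
                             self.initial_probs, self.terminal_states)

    def to_dict(self):
        return {
            "name": self.name,
            "states": [[s.label, s.fret_mean, s.fret_sd] for s in self.states],
            "rates": self.rates.tolist(),
            "initial_probs": self.initial_probs.tolist(),
            "terminal_states": sorted(self.terminal_states),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["name"], [tuple(s) for s in d["states"]],
                   d["rates"], d["initial_probs"], d["terminal_states"])

    def __repr__(self):
        return (f"KineticScheme({self.name!r}, states={self.labels}, "
                f"terminal={sorted(self.terminal_states)})")


@dataclass(frozen=True)
class MixtureComponent:
    scheme: KineticScheme
    weight: float
    label: str = ""


class ModeMixture:
    """Weighted mixture of kinetic schemes (e.g. fast/slow modes).

    Parameters
    ----------
    components : sequence of (KineticScheme, weight) or (scheme, weight, label)
    name : str, optional
    """

    def __init__(self, components, name=""):
        comps = []
        for c in components:
            if isinstance(c, MixtureComponent):
                comps.append(c)
            else:
                scheme, weight = c[0], float(c[1])
                label = c[2] if len(c) > 2 else scheme.name
                comps.append(MixtureComponent(scheme, weight, label))
        if not comps:
            raise ValueError("mixture needs at least one component")
        w = np.array([c.weight for c in comps])
        if np.any(w < 0) or abs(w.sum() - 1.0) > _ATOL:
            raise ValueError("component weights must be >= 0 and sum to 1")
        self.components = tuple(comps)
        self.name = name or comps[0].scheme.name

    @property
    def weights(self):
        return np.array([c.weight for c in self.components])

    @property
    def labels(self):
        return tuple(c.label for c in self.components)

    def component(self, label):
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no component {label!r} in mixture {self.name!r}")

    def pure(self, label):
        """Single-component mixture containing only the named component."""
        c = self.component(label)
        return ModeMixture([(c.scheme, 1.0, c.label)],
                           name=f"{self.name}:{label}")

    def fret_states(self):
        """Unique emitting (label, mean, sd) across components, mean-descending.

        When several components reuse a FRET level the first label
        encountered wins; levels are considered equal within 1e-6.
        """
        out = []
        for c in self.components:
            for s in c.scheme.states:
                if c.scheme.is_terminal(s.label):
                    continue
                if not any(abs(s.fret_mean - m) < 1e-6 for _, m, _ in out):
                    out.append((s.label, s.fret_mean, s.fret_sd))
        out.sort(key=lambda t: -t[1])
        return out

    def to_dict(self):
        return {
            "name": self.name,
            "components": [
                {"label": c.label, "weight": c.weight,
                 "scheme": c.scheme.to_dict()}
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            [(KineticScheme.from_dict(c["scheme"]), c["weight"], c["label"])
             for c in d["components"]],
            name=d.get("name", ""),
        )

    def __repr__(self):
        parts = ", ".join(f"{c.label}:{c.weight:g}" for c in self.components)
        return f"ModeMixture({self.name!r}, [{parts}])"


@dataclass
class StatePath:
    """Latent state trajectory: contiguous dwells (label, t_start, t_end)."""

    dwells: list  # list of (label, t_start, t_end)
    duration: float
    scheme_name: str = ""
    terminated: bool = False  # ended by entering a terminal state
    terminal_time: float | None = None
    terminal_label: str | None = None

    def __post_init__(self):
        t = 0.0
        for lbl, t0, t1 in self.dwells:
            if not (abs(t0 - t) <= 1e-9 and t1 > t0):
                raise ValueError("dwells must be contiguous with t_end > t_start")
            t = t1
        if self.dwells and not self.terminated:
            if abs(self.dwells[-1][2] - self.duration) > 1e-9:
                raise ValueError("last dwell must end at the path duration")

    def state_at(self, t):
        """State label occupied at time *t* (None if past a terminal entry)."""
        for lbl, t0, t1 in self.dwells:
            if t0 <= t < t1:
                return lbl
        return self.terminal_label if self.terminated else None

    def first_entry(self, label):
        for lbl, t0, _ in self.dwells:
            if lbl == label:
                return t0
        return None

    def last_entry(self, label):
        out = None
        for lbl, t0, _ in self.dwells:
            if lbl == label:
                out = t0
        return out

    def to_jsonable(self):
        return {
            "dwells": [[lbl, float(t0), float(t1)] for lbl, t0, t1 in self.dwells],
            "duration": float(self.duration),
            "scheme_name": self.scheme_name,
            "terminated": self.terminated,
            "terminal_time": self.terminal_time,
            "terminal_label": self.terminal_label,
        }


def sample_path(scheme, t_max, seed):
    """Gillespie realisation of *scheme* up to ``t_max`` seconds.

    The path ends at ``t_max`` or on entry into a terminal state,
    whichever comes first.  A non-terminal state with zero outgoing
    rates simply holds until ``t_max``.

    Parameters
    ----------
    scheme : KineticScheme
    t_max : float
        Maximum path duration in seconds.
    seed : int or numpy.random.Generator

    Returns
    -------
    StatePath
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Precomputed per-state totals and successor CDFs (cached on the scheme).
    cache = getattr(scheme, "_gillespie_cache", None)
    if cache is None:
        k_tots = scheme.rates.sum(axis=1)
        cdfs = np.cumsum(scheme.rates, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cdfs = np.where(k_tots[:, None] > 0, cdfs / k_tots[:, None], 0.0)
        init_cdf = np.cumsum(scheme.initial_probs)
        cache = (k_tots, cdfs, init_cdf)
        scheme._gillespie_cache = cache
    k_tots, cdfs, init_cdf = cache

    i = int(np.searchsorted(init_cdf, rng.random(), side="right"))
    i = min(i, scheme.n_states - 1)
    t = 0.0
    dwells = []
    terminated = False
    terminal_time = None
    terminal_label = None
    while t < t_max:
        label = scheme.labels[i]
        if scheme.is_terminal(label):
            terminated = True
            terminal_time = t
            terminal_label = label
            break
        k_tot = k_tots[i]
        if k_tot <= 0:
            dwells.append((label, t, t_max))
            t = t_max
            break
        dt = rng.exponential(1.0 / k_tot)
        t_end = min(t + dt, t_max)
        dwells.append((label, t, t_end))
        if t + dt >= t_max:
            t = t_max
            break
        t = t_end
        i = int(np.searchsorted(cdfs[i], rng.random(), side="right"))
        i = min(i, scheme.n_states - 1)
    duration = terminal_time if terminated else min(t, t_max)
    return StatePath(dwells=dwells, duration=duration, scheme_name=scheme.name,
                     terminated=terminated, terminal_time=terminal_time,
                     terminal_label=terminal_label)


def mean_first_passage_time(scheme, from_label, to_label):
    """Expected hitting time (s) of *to_label* starting from *from_label*.

    Solves the linear system ``tau_i = (1 + sum_j k_ij tau_j) / k_i`` over
    transient states; raises if the target is unreachable.
    """
    n = scheme.n_states
    target = scheme.index(to_label)
    others = [i for i in range(n) if i != target]
    A = np.zeros((len(others), len(others)))
    b = np.ones(len(others))
    for r, i in enumerate(others):
        k_tot = scheme.rates[i].sum()
        if k_tot <= 0:
            raise ValueError(
                f"state {scheme.labels[i]!r} is absorbing; target unreachable")
        A[r, r] = k_tot
        for c, j in enumerate(others):
            A[r, c] -= scheme.rates[i, j]
    tau = np.linalg.solve(A, b)
    return float(tau[others.index(scheme.index(from_label))])
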