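"""End-to-end workflows: simulate, analyze, and parameter recovery.

``analyze_traces`` runs the full chain on raw two-channel traces:
single-molecule selection -> bleed-through correction -> FRET ->
truncation at photophysical events -> pooled histogram + Gaussian-sum
state model -> per-trace HMM idealization -> sub-s.d. transition filter.
``recover_preset`` closes the loop: it simulates a preset ensemble,
analyzes it blind, and compares every recovered headline rate and
fraction with its generating value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics
from .config import AnalysisConfig
from .inference import (GaussianStateModel, fit_gaussian_sum, idealize_trace,
                        pooled_histogram)
from .presets import K_TL_TARGETS, make_preset
from .processing import process_trace, select_traces
from .simulate import PhotophysicsModel, simulate_ensemble

__all__ = ["simulate_preset", "analyze_traces", "recover_preset"]


def simulate_preset(name, n_traces, seed, photo=None, t_max=33.0,
                    frame_interval=0.033, component=None):
    """Simulate an ensemble from a named preset.

    ``component`` restricts the mixture to one mode (e.g. ``"slow"``).
    Returns (traces, manifest, mixture).
    """
    mixture = make_preset(name)
    if component is not None:
        mixture = mixture.pure(component)
    if photo is None:
        photo = PhotophysicsModel()
    traces, manifest = simulate_ensemble(mixture, n_traces, photo, t_max,
                                         frame_interval, seed)
    return traces, manifest, mixture


def _relabel_from_mixture(model, mixture):
    """Rename fitted Gaussian components to the scheme state labels."""
    known = mixture.fret_states()
    labels = []
    for c in model.components:
        j = int(np.argmin([abs(c.mu - mu) for _, mu, _ in known]))
        labels.append(known[j][0])
    if len(set(labels)) != len(labels):
        return model  # ambiguous assignment; keep generic labels
    return GaussianStateModel(
        [(lbl, c.mu, c.sigma, c.weight)
         for lbl, c in zip(labels, model.components)],
        residual_norm=model.residual_norm)


def analyze_traces(traces, config=None, mixture=None, photo=None,
                   n_states=None, select=True, report=None):
    """Full analysis of an ensemble of raw FluorescenceTraces.

    With a ``mixture`` given (e.g. from a simulation manifest), the
    Gaussian-sum fit is initialised at the known state means and the
    components inherit the scheme labels; otherwise ``n_states`` sets
    the component count and states are labelled ``s1..sk``.

    Returns a dict with keys ``frets``, ``ideals``, ``model``,
    ``histogram``, ``selection_reports``, ``n_input``.
    """
    if config is None:
        config = AnalysisConfig()
    if photo is None:
        photo = PhotophysicsModel(
            bleedthrough_beta=config.bleedthrough_beta,
            k_pb_donor=config.k_photobleach)
    n_input = len(traces)

    if select:
        kept, sel_reports = select_traces(traces, photo)
    else:
        kept, sel_reports = list(traces), []
    if report is not None:
        reasons = {}
        for r in sel_reports:
            for reason in r.reasons:
                reasons[reason] = reasons.get(reason, 0) + 1
        report.add_stage("selection", n_input, len(kept), reasons)

    frets = []
    for tr in kept:
        ft = process_trace(tr, photo, beta=config.bleedthrough_beta,
                           min_total=config.min_total)
        if not ft.is_empty and ft.n_valid >= 10:
            frets.append(ft)
    if report is not None:
        report.add_stage("processing", len(kept), len(frets),
                         {"empty_or_short": len(kept) - len(frets)})
    if not frets:
        raise ValueError("no analyzable traces after selection/processing")

    hist = pooled_histogram(frets, bin_width=config.bin_width)
    if mixture is not None:
        # FRET state positions are assigned from prior knowledge (in the
        # laboratory: steady-state experiments on defined complexes); the
        # histogram supplies the state occupancies.
        known = mixture.fret_states()
        means = np.array([mu for _, mu, _ in known])
        assign = np.argmin(np.abs(hist.centers[:, None] - means[None, :]),
                           axis=1)
        mass = np.array([hist.counts[assign == j].sum()
                         for j in range(len(known))], dtype=float)
        mass = np.maximum(mass, 1.0)
        model = GaussianStateModel.from_mixture(mixture,
                                                weights=mass / mass.sum())
    else:
        if n_states is None:
            raise ValueError("n_states is required without a mixture")
        model = fit_gaussian_sum(hist, k=n_states)

    ideals = []
    for ft in frets:
        try:
            ideals.append(idealize_trace(ft, model, k_range=config.k_range,
                                         decode=config.idealize_decode))
        except ValueError:
            continue
    if report is not None:
        report.add_stage("idealization", len(frets), len(ideals),
                         {"too_short_for_hmm": len(frets) - len(ideals)})

    return {"frets": frets, "ideals": ideals, "model": model,
            "histogram": hist, "selection_reports": sel_reports,
            "n_input": n_input}


def _recovery_rows(name, mixture, result, config):
    """Measure each recoverable generating quantity of a preset ensemble."""
    ideals, model = result["ideals"], result["model"]
    k_pb, T = config.k_photobleach, config.t_observation
    rows = []

    def add(quantity, true, recovered, tol, **extra):
        ok = (np.isfinite(recovered) and abs(recovered - true) <= tol)
        rows.append({"quantity": quantity, "generating": true,
                     "recovered": recovered, "tolerance": tol,
                     "pass": bool(ok), **extra})

    labels = set(model.labels)
    # per-edge fluctuation rates of the slow (or only) component
    comp = None
    for c in mixture.components:
        if c.label in ("slow", "wt", "spc", "pre"):
            comp = c
    if comp is None:
        comp = mixture.components[-1]
    scheme = comp.scheme
    for i, from_s in enumerate(scheme.labels):
        for j, to_s in enumerate(scheme.labels):
            r = scheme.rates[i, j]
            if r <= 0 or from_s not in labels or to_s not in labels:
                continue
            mu_i, mu_j = scheme.fret_mean(from_s), scheme.fret_mean(to_s)
            if abs(mu_i - mu_j) <= max(scheme.states[i].fret_sd,
                                       scheme.states[j].fret_sd):
                continue  # unobservable edge (sub-s.d. FRET change)
            est = kinetics.transition_rate(
                ideals, from_s, to_s, k_pb=k_pb, T=T,
                min_transitions=config.dwell_fit_floor, n_boot=0)
            add(f"k({from_s}->{to_s})", r,
                est.k_corrected if not est.nd else np.nan,
                max(0.25 * r, 0.3), n=est.n, nd=est.nd)

    if name.startswith("pept") and "POST" in labels and "CHI" in labels:
        try:
            est = kinetics.translocation_rate(
                ideals, model, sync_threshold=float(config.sync_rule_value),
                stable_frames=config.stable_post_frames, k_pb=k_pb, T=T,
                n_boot=0)
            truth = K_TL_TARGETS.get(name)
            if not est.lower_bound and truth is not None:
                add("k_TL", truth, est.k_corrected, 0.1, n=est.n)
        except kinetics.DwellFitError:
            pass
        classes = [kinetics.classify_trace(
            ideal, model, stable_frames=config.stable_post_frames)
            for ideal in ideals]
        n_chi = sum(c.label == "chi_sampling" for c in classes)
        n_dir = sum(c.label == "direct" for c in classes)
        if n_chi + n_dir:
            frac = n_chi / (n_chi + n_dir)
            truth = dict(zip(mixture.labels, mixture.weights)).get("slow")
            if truth is not None:
                add("fraction_chi_sampling", truth, frac, 0.05,
                    n=n_chi + n_dir)
    if name.startswith("deac"):
        est = kinetics.dissociation_rate(ideals, k_pb=k_pb, T=T, n_boot=0)
        truth = comp.scheme.rates[comp.scheme.index("E"),
                                  comp.scheme.index("dissociated")]
        add("k_off", float(truth), est.k_corrected, max(0.25 * truth, 0.15),
            n=est.n)
    if name.startswith("head") and "N" in labels:
        est = kinetics.head_swivel_rate(ideals, k_pb=k_pb, T=T, n_boot=0)
        k_sn = None
        for c in mixture.components:
            if "N" in c.scheme.labels and c.scheme.exit_rate("S") > 0:
                k_sn = c.scheme.rates[c.scheme.index("S"),
                                      c.scheme.index("N")]
        if k_sn and not est.nd:
            add("k_S->N", float(k_sn), est.k_corrected,
                max(0.25 * k_sn, 0.3), n=est.n)
        frac, _, n = kinetics.fraction_reaching_state(ideals, "N")
        truth = dict(zip(mixture.labels, mixture.weights)).get("fast")
        if truth is not None:
            add("fraction_reaching_N", truth, frac, 0.05, n=n)
    return rows


def recover_preset(name, n_traces, seed, config=None, t_max=33.0,
                   frame_interval=None, component=None, report=None):
    """Simulate a preset, analyze it blind, compare with ground truth.

    Returns (comparison DataFrame, analysis result dict, manifest).
    """
    if config is None:
        config = AnalysisConfig()
    if frame_interval is None:
        frame_interval = config.frame_interval
    traces, manifest, mixture = simulate_preset(
        name, n_traces, seed, t_max=t_max, frame_interval=frame_interval,
        component=component)
    result = analyze_traces(traces, config=config, mixture=mixture,
                            report=report)
    rows = _recovery_rows(name, mixture, result, config)
    return pd.DataFrame(rows), result, manifest
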