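# Methods

This note documents the models, the simulator, the estimators, and the
design choices behind `slipfret`, in the spirit of a methods section a
user should read before trusting numbers from the package.

## The kinetic model

Ribosomal translocation is modelled as a labelled continuous-time Markov
chain (CTMC) per molecule. Each state carries a FRET emission mean and a
composite standard deviation (default 0.1, covering conformational
jitter and shot noise in one Gaussian term, since only the composite
width of a FRET state is observable in TIRF histograms). Three reporter
geometries are encoded:

* **Peptidyl-tRNA** (large-subunit protein L11 ↔ pept-tRNA dye):
  PRE ≈ 0.8 (A/A, A/P), A/P* ≈ 0.6, the chimeric translocation
  intermediate CHI ≈ 0.4, and P/P ≈ 0.2. The POST state is a second,
  absorbing 0.2-FRET state — spectroscopically identical to P/P but
  kinetically locked.
* **Deacylated tRNA** (small-subunit protein S13 ↔ P-site tRNA dye):
  P/P ≈ 0.9, P/E ≈ 0.6, E site ≈ 0.3, then loss of the acceptor signal
  on dissociation (a terminal scheme state).
* **SSU head swivel** (S13 ↔ L33): swiveled S ≈ 0.8, non-swiveled
  N ≈ 0.5, with a locked N state terminating the fluctuations.

Populations are two-component mode mixtures: a **fast mode** that
commits to translocation at an effective EF-G commitment rate and then
crosses to POST within one camera frame (camera-limited,
k ≥ 1/frame time ≈ 30 s⁻¹), and a **slow mode** trapped in
CHI ↔ P/P (or, with GTPγS, A/P* ↔ CHI) fluctuations before locking.

### Preset parameterization

Published per-edge fluctuation rates fill the scheme edges directly
(e.g. wild type: k(0.4→0.6) = 2.6 s⁻¹, k(0.2→0.4) = 2.7 s⁻¹; GTPγS:
k(0.6→0.4) = 7.0 s⁻¹, k(0.4→0.6) = 6.2 s⁻¹ following the textual
description of the fluctuation pair over the tabulated column order,
which is internally inconsistent for that condition). Cells reported as
not determined are encoded as 0 s⁻¹ where negligible flux is physically
consistent, and otherwise resolved as follows:

* unresolved k(0.4→0.2) is set equal to the published reverse rate
  (symmetric CHI ↔ P/P exchange — the fluctuation the slow mode is
  defined by; the transition-count-derived alternative makes P/P
  effectively unreachable and is inconsistent with the published overall
  translocation rate);
* unresolved k(0.6→0.4) is borrowed from the one condition where that
  cell is resolvable (3.9 s⁻¹).

The **locking rate** (P/P → POST, or CHI → POST for GTPγS) is not
published. It is calibrated per preset with
`slipfret.presets.calibrate_lock_rate`, which bisects on noiseless
Gillespie ensembles until the exponential decay of the
synchronization-to-POST time distribution equals the published overall
translocation rate k_TL (0.2 s⁻¹ for wild type). The calibrated
constants are frozen in `presets.py`; the utility ships so the
calibration is reproducible.

Unpublished study conditions were fixed once: commitment rate 0.5 s⁻¹
(sets the seconds-scale delay before translocation in a trace);
PRE fluctuations 0.8 ↔ 0.6 at 2.0/2.0 s⁻¹ for the pept reporter and
P/P ↔ P/E at 0.3/0.3 s⁻¹ for the deac reporter (the deac PRE state is
reported to fluctuate an order of magnitude less frequently); head
N-fluctuation return 2.0 s⁻¹ and N-locking 1.0 s⁻¹. Mixture weights:
19% slow for wild type on slippery mRNA and 87% for Q507D (published);
35%/55% for Q507A/Q507N (unpublished; interpolated respecting the
published ordering A < N < D); 73% slow for GTPγS (published). Head
reporter: 85%/87% fast on non-slippery/slippery mRNA with wild-type
EF-G, 13% fast with Q507D, whose stalled component has its back-swivel
rate encoded as 0 (published only as below the photobleaching
resolution).

## The camera and photophysics model

Frames integrate the emission over the frame interval: the per-frame
FRET value is the exact occupancy-weighted mean of the state means, so a
mid-frame transition produces a single intermediate-level frame — the
one-frame transit signature of fast translocation. Per-frame Gaussian
noise at the state s.d. is added in FRET space; channels are then
`acceptor = i_total·E`, `donor = i_total·(1−E)`, with donor→acceptor
bleed-through β = 0.13, Gaussian background (s.d. 10 counts on
i_total = 1000), donor photobleaching at 0.03 s⁻¹ (both channels to
background), and acceptor loss — photobleaching (default rate 0,
see below) or reporter dissociation — sending the acceptor to background
and the donor to the full intensity (dequenching). Acceptor blinking is
available (reversible dark state) but disabled by default, since only
its removal, never its kinetics, enters the analysis.

The single published photobleaching constant (0.03 ± 0.01 s⁻¹) is
modelled entirely in the donor channel. This keeps the correction
formula below exactly consistent and makes acceptor-signal loss on the
deac reporter attributable to dissociation alone; the statistical
separation of dissociation from acceptor bleaching is performed at the
rate level by the same correction, mirroring the experimental analysis.

## The analysis chain

1. **Selection.** A trace is accepted iff (i) the frame-to-frame donor
   and acceptor *changes* are anti-correlated (Pearson r ≤ −0.3 on first
   differences, which is insensitive to baseline levels), (ii) the
   apparent molecule count — `round(total / i_total)`, the summed
   intensity being FRET-independent — steps down at most once, and
   (iii) the initial summed intensity lies within 0.5–1.5× the ensemble
   median. On clean simulated singles acceptance is ≥ 95%; two-molecule
   composites are rejected at ≥ 95%.
2. **FRET and truncation.** E = FI_A/(FI_D+FI_A) after subtracting
   β·donor from the acceptor. Events are detected on the corrected
   channels (uncorrected, a dissociated molecule's acceptor still holds
   β·i_total of bleed-through and never reaches background) by
   run-length thresholding against the background band (mean ± 3 s.d.),
   with median smoothing and morphological gap-closing so isolated noise
   crossings cannot split a bleached segment; a channel is lost after
   ≥ 5 consecutive in-band frames (165 ms). Traces are truncated one
   frame before the earliest event.
3. **State model.** The pooled FRET histogram (0.02-wide bins over
   [−0.1, 1.1], out-of-range outliers dropped rather than clipped) is
   fitted to a sum of Gaussians. The fit maximizes the binned likelihood
   (EM with bin counts as multiplicities) with a **tied component
   s.d.** by default: all FRET states carry the same composite width,
   and the tie removes the weight-vs-width degeneracy along which a free
   mixture fit drifts when components sit ~2 s.d. apart (with it, state
   means recover to < 0.01 at 10⁵ frames; without, errors up to 0.05
   occur). A free-s.d. variant remains available. In recovery workflows,
   where the generating states are known, the pipeline instead uses the
   known means/s.d. with occupancies read off the histogram — the
   experimental analogue being that state FRET values are assigned from
   independent steady-state measurements, not refitted per kinetic
   dataset.
4. **Idealization.** Per trace, a Gaussian-emission HMM is fitted by EM
   (tolerance 1e-6, up to 1000 iterations). When the candidate state
   count equals the global model's, emissions are taken from the global
   model and held fixed while EM learns the per-trace start and
   transition probabilities; for other counts (BIC mode scans a range
   and picks the minimum-BIC model) emissions initialize from a
   deterministic 1-d k-means and refine, with the emission s.d. bounded
   below at 0.02. Decoding defaults to the per-frame maximum of the
   smoothed posterior rather than the Viterbi path: at this SNR the
   joint-MAP path systematically swallows dwells of a few frames, and
   posterior decoding recovers them with a tolerable false-positive
   rate (Viterbi remains available as `idealize_decode = "viterbi"`).
   Decoded states map to global labels by nearest mean, and FRET changes
   smaller than the larger state s.d. are removed by merging the shorter
   dwell into its longer neighbour (ties merge into the earlier dwell),
   iterated to a fixed point.
5. **Dwell kinetics.** Dwell survival curves, evaluated at the observed
   frame multiples with single-frame dwells excluded as camera-limited
   and points below 5% survival dropped, are fitted to
   y = y₀ + A·e^(−t/τ) by binomially-weighted least squares (y₀ bounded
   to ±0.05 — for dwells short against the window the offset is near
   zero, and a free offset trades against the slope on noisy tails).
   One-event-per-trace quantities (dissociation times, sync-to-POST
   times, the final S dwell of the head reporter) instead use a
   one-parameter anchored exponential S(t) = S(t₀)e^(−k(t−t₀)), which
   reaches maximum-likelihood-level efficiency where the
   three-parameter form has about twice the sampling error; bleach-time
   fits use the exact window-truncated exponential because there
   k·T ≈ 1 and the generic form is ill-conditioned. Dwells ending at
   trace truncation are censored and excluded. Repeated-dwell fits are
   corrected with the full published formula
   **k_corrected = k_observed − k_photobleach − 1/T** (T = 33 s, or
   100 s for the slow head-reporter variant), which compensates the
   losses of that fitting procedure; the anchored event-time fits
   condition on the observed events, where the memoryless exponential
   leaves no finite-window bias, so they subtract only k_photobleach.
6. **Per-edge rates and the dead-time correction.** The dwell time of a
   Markov state is exponential in its total exit rate regardless of
   destination, so k(i→j) is the corrected dwell decay multiplied by the
   observed branching fraction n_ij/n_i. Because excursions shorter than
   the idealizer's dead time go undetected and merge flanking dwells
   (the classic missed-event problem of single-channel kinetics), the
   dwell decay is first corrected with
   E[T_obs] = E[T]/p + (1/p − 1)·E[T_exc | T_exc < τ_d],
   p = e^(−k_exc·τ_d), using the observed excursion-dwell decay; the
   one-sided inversion is unconditionally stable and slightly
   conservative. The effective dead time is a property of the whole
   detection chain and was characterized on simulated ensembles against
   the generating rates: 2.5 frames for a hidden two-state alternation
   (head reporter — a visit needs interior evidence beyond its two
   camera-integrated boundary frames), 2 frames for multi-state
   networks where some short excursions terminate at a different
   observable level and are therefore not lost. Without this correction
   recovered fluctuation rates at k ≈ 3–5 s⁻¹ and 33 ms frames are
   20–25% low.
7. **Synchronization and classification.** The sync point is the first
   idealized value below FRET 0.5 (pept reporter; the head reporter
   uses the last entry into the S state, and the alternative reading
   "first value below lowest PRE mean − 0.1" is available as a named
   rule). Stable POST entry is the earliest POST dwell whose suffix
   stays ≥ 90% in POST with no excursion of ≥ 5 frames — tolerant to
   isolated misassigned frames that would otherwise reset the "last
   transition to POST". k_TL is fitted to the sync-to-POST times;
   ensembles dominated by one-frame translocations report the
   camera-limited lower bound 1/frame interval. A trace is classified
   CHI-sampling if it holds ≥ 5 CHI frames after sync (a single
   one-frame CHI visit is the camera-integration artifact of a mid-frame
   jump), direct if it reaches stable POST without such occupancy, and
   no-translocation otherwise; fractions are reported among
   translocation-informative traces (direct + CHI-sampling). Measured
   classification confusion against ground truth is ~4–5% at the
   standard noise.

## What the simulations do and do not establish

The generator reproduces the features the analysis depends on: Markovian
state dwells at the published rates, camera integration, composite state
noise, bleed-through, background, photobleaching/dissociation-induced
signal loss, and fast/slow population structure. It does **not** emulate
intensity heterogeneity between molecules, non-exponential (molecule- or
time-dependent) kinetics, baseline drift, correlated noise, or
quantum-yield differences between states (no gamma correction is applied
anywhere). Passing recovery tests therefore demonstrates that the
pipeline is consistent and close to unbiased *under the stated model*,
not that real traces satisfy that model.

## Problem sizes and numerical choices

Recovery checks run at the scale of the original datasets: 300 traces
for rate recovery, 500 for population fractions, 10⁴ bleach events for
the photobleaching constant, 10⁵ pooled frames for the state-model fit;
the test suite uses the same or moderately smaller ensembles. All
simulation randomness flows through `numpy` SeedSequences spawned from a
single master seed, making every ensemble and manifest bit-reproducible.
Bootstrap confidence intervals (1000 resamples, seeded) are attached to
rate estimates on request. Degenerate inputs fail loudly: empty
histograms, all-equal dwell sets, sub-minimum event counts and unknown
preset names raise; rates below the photobleaching resolution are
returned flagged (`below_resolution`), and transitions with too few
events yield an explicit serializable "n.d." result rather than a
number.

## Known limitations

* Per-edge rates inherit the dead-time approximation; at fluctuation
  rates approaching the frame rate (k·Δt ≳ 0.3) the sharp-dead-time
  model becomes crude and residual biases of ~10% remain.
* The slow-mode schemes compress whatever multi-step locking process
  follows CHI ↔ P/P exchange into a single calibrated rate; only the
  observable consequences (sync-to-POST decay, fluctuation rates) are
  matched, not the hidden mechanism.
* The classifier's 5-frame CHI-occupancy threshold trades false
  positives from decoding noise against sensitivity to very brief CHI
  sampling; populations whose slow mode locks after fewer than ~2 CHI
  visits would be partially missed.
* Blind state-count selection (BIC) under-calls states that are visited
  only briefly in a trace; recovery workflows therefore use the known
  state model, as the experimental protocol effectively does.
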