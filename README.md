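# slipfret

Simulation and kinetic analysis of single-molecule FRET (smFRET)
trajectories of translating ribosomes, built around the question of how
ribosomes lose the reading frame on slippery mRNA: during EF-G-catalyzed
translocation a fraction of ribosomes switches from a fast, accurate mode
(PRE → POST within one camera frame) to a slow, frameshifting-prone mode
in which peptidyl-tRNA is trapped fluctuating between the chimeric (CHI)
translocation intermediate and the P/P state before locking into POST.

The package is aimed at single-molecule biophysicists who want a fully
ground-truthed version of this kind of two-color TIRF analysis: every
stage — from camera-level trace synthesis to the final rate table — can
be validated by parameter recovery against the generating kinetic scheme.

## What it does

**Simulation** (`slipfret.schemes`, `slipfret.simulate`, `slipfret.presets`)

* Kinetic schemes are labelled continuous-time Markov chains with FRET
  emission parameters; trajectories are Gillespie realizations, and
  ribosome populations are fast/slow mode mixtures.
* Documented presets encode the published state assignments and rates for
  three reporters: peptidyl-tRNA (FRET 0.8 / 0.6 / 0.4 / 0.2),
  deacylated tRNA (0.9 / 0.6 / 0.3 / loss on dissociation), and the SSU
  head swivel (S = 0.8, N = 0.5), for wild-type EF-G, the
  frameshifting-promoting Q507 mutants, GTPγS and spectinomycin.
* The camera model integrates state occupancy over each frame (a
  mid-frame transition yields one intermediate-level frame), adds the
  composite state noise (s.d. 0.1 FRET), donor→acceptor bleed-through
  (β = 0.13), Gaussian background, donor photobleaching
  (k_pb = 0.03 s⁻¹) and acceptor loss with donor dequenching.

**Analysis** (`slipfret.processing`, `slipfret.inference`,
`slipfret.kinetics`, `slipfret.views`)

* FRET efficiency E = FI_A / (FI_D + FI_A) after bleed-through
  correction; single-molecule selection (anti-correlation of channel
  changes, one bleach step, intensity band); trace truncation at
  photobleaching / blinking events.
* Global state model as a Gaussian sum fitted to the pooled FRET
  histogram; per-trace idealization with a Gaussian-emission hidden
  Markov model (state count fixed or per-trace by BIC) and the sub-s.d.
  transition filter.
* Dwell-time kinetics: survival-curve exponential fits
  (y = y₀ + A·e^(−t/τ), k = 1/τ), the photobleaching/observation-window
  correction **k_corrected = k_observed − k_photobleach − 1/T**, per-edge
  transition rates via branching fractions with a missed-event
  (dead-time) correction, overall translocation rate k_TL from
  synchronization to the last POST entry, E-site dissociation and head
  back-swiveling rates, trace classification
  (direct / CHI-sampling / no translocation), transition frequencies,
  synchronized contour ensembles, and the slow-fraction vs
  frameshifting-efficiency OLS regression.

## Worked example

Simulate 200 wild-type slippery-mRNA peptidyl-tRNA traces (81% fast /
19% slow mode), analyze them blind, and recover the slow-mode kinetics:

```python
import slipfret as sf
from slipfret.config import AnalysisConfig

cfg = AnalysisConfig(hmm_mode="fixed", n_boot=200)
traces, manifest, mixture = sf.simulate_preset("pept_wt_slippery", 200, seed=42)
result = sf.analyze_traces(traces, config=cfg, mixture=mixture)
print("state model:", result["model"])

classes = [sf.classify_trace(i, result["model"]) for i in result["ideals"]]
n_chi = sum(c.label == "chi_sampling" for c in classes)
n_dir = sum(c.label == "direct" for c in classes)
print(f"CHI-sampling fraction: {100 * n_chi / (n_chi + n_dir):.1f}% "
      f"({n_chi}/{n_chi + n_dir} translocating traces)")

slow_tr, _, slow_mix = sf.simulate_preset("pept_wt_slippery", 200, seed=43,
                                          component="slow")
slow = sf.analyze_traces(slow_tr, config=cfg, mixture=slow_mix)
est = sf.transition_rate(slow["ideals"], "CHI", "A/P*", n_boot=200)
print(f"k(CHI -> A/P*) = {est.k_corrected:.2f} 1/s "
      f"(95% CI {est.ci[0]:.2f}-{est.ci[1]:.2f}, n = {est.n} transitions)")
ktl = sf.translocation_rate(slow["ideals"], slow["model"], n_boot=200)
print(f"k_TL = {ktl.k_corrected:.3f} 1/s (n = {ktl.n} traces)")
```

Output:

```
state model: GaussianStateModel(PRE: 0.800+-0.100 (w=0.05), A/P*: 0.600+-0.100 (w=0.04), CHI: 0.400+-0.100 (w=0.16), POST: 0.200+-0.100 (w=0.74))
CHI-sampling fraction: 21.5% (41/191 translocating traces)
k(CHI -> A/P*) = 2.64 1/s (95% CI 2.37-2.93, n = 546 transitions)
k_TL = 0.252 1/s (n = 158 traces)
```

The CHI-sampling fraction recovers the generating 19% slow-mode weight
within its binomial uncertainty; the CHI → A/P* fluctuation rate and the
overall translocation rate recover their generating values (2.6 s⁻¹ and
0.2 s⁻¹ — the published wild-type slow-mode kinetics used by the
preset).

## Command line

```bash
slipfret simulate --preset pept_wt_slippery --n 300 --seed 1 --out ens/
slipfret analyze  --in ens/ --out analysis/
slipfret recover  --preset deac_wt_nonslippery --n 300 --seed 1 --out rec/
```

`simulate` writes one delimited text file per trace plus a YAML manifest
with the full ground truth; `analyze` runs the selection → FRET →
idealization → kinetics chain and writes a run report; `recover` closes
the loop and emits a table comparing every recovered rate and fraction
with its generating value.

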