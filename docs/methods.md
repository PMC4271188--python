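# Methods

## The measurement this package models

A proton-coupled oligopeptide transporter (POT family) reconstituted into
liposomes symports n protons with m peptides per cycle,

    n H+(out) + m Pep(out)  <=>  n H+(in) + m Pep(in).

Because the peptide is electrically neutral, each cycle moves n elementary
charges, and the coupled reaction has a single equilibrium (reversal)
potential that depends only on the gradients and on n/m — not on any
kinetic detail:

    ΔΨ_rev = s · [ (pH_in − pH_out) − (m/n) · log10([Pep]_in/[Pep]_out) ],

with ΔΨ = Ψ_in − Ψ_out (outside at ground) and s the Nernstian slope in
mV/decade. Clamping the voltage with a potassium gradient plus valinomycin
and watching whether the lumen acidifies (inward proton flux) or
alkalinizes (outward) at a series of voltages brackets n. The lumen pH is
read out with trapped pyranine: the 460 nm / 415 nm excitation ratio
(emission 510 nm), normalized to the first reading (F_R), falls on
acidification.

Rearranging the same relation at ΔΨ = 0 gives the equilibrium accumulation

    [Pep]_in/[Pep]_out = ([H+]_out/[H+]_in)^(n/m),

so two substrates with different coupling accumulate to steady-state levels
differing by a factor of 10^(Δn) per pH unit of gradient — the basis of the
radiolabel-uptake contrast between di- and tri-peptides.

## Thermodynamic core (`pepflux.thermo`)

* The slope defaults to exactly 60 mV/decade, which reproduces the round
  target voltages of the assay design (−40 mV for 3:1, −30 mV for 4:1,
  −24/−20 mV for 5:1/6:1 under a 100-fold inward peptide gradient). An
  "exact" mode computes RT·ln10/F from temperature (59.82 mV at 301.5 K,
  within 0.3% of 60).
* Stoichiometries are positive integers (n, m); the estimator reports n at
  m = 1, which is the only case the assay design varies.
* Sign convention is fixed everywhere: Ψ_in − Ψ_out, outside ground;
  negative-inside voltages drive peptide/proton uptake against the peptide
  gradient.
* Units: mM, mV, seconds, pH units. Concentrations are used in place of
  activities.
* The model counts total protons moved per cycle; it is agnostic about
  whether a proton crosses through the transporter or rides on the peptide.

## Assay simulator (`pepflux.simulate`)

The simulator is the package's synthetic-data generator. It emulates the
fluorescence experiment, not any particular microscopic rate theory:

* **Flux law.** J_H = n · turnover_rate · sat([Pep]_out) · (ΔΨ_rev − ΔΨ),
  with J_pep = J_H·m/n strictly coupled and sat a Michaelis term with
  apparent midpoints of 10 µM (di-Ala) and 125 µM (tri-Ala). Linear
  response in the displacement from equilibrium is the weakest kinetic
  assumption that preserves the exact zero-flux voltage, which is the only
  feature the downstream inference uses. The reversal potential is
  recomputed from the evolving state at every step, so the simulator and
  the closed form agree at equilibrium by construction of the physics, not
  by sharing code paths (the bisection oracle test checks this agreement
  numerically).
* **Voltage clamp.** Valinomycin is an ideal K+ clamp: from the event
  onward ΔΨ equals the K+ Nernst potential of the protocol's gradient, and
  bath K+ is treated as undepleted. Before the event the membrane has
  negligible conductance, so any electrogenic flux would self-arrest on the
  membrane capacitance within milliseconds; the model represents this by
  freezing the state, reproducing the flat pre-valinomycin baseline.
* **Substrate gating.** Only di- and tri-peptides are transported; other
  lengths give identically zero transporter flux.
* **Buffering.** Lumen pH moves as dpH = −J_H/(β·v) with a lumped buffer
  capacity β = 5 mM/pH (a 5 mM Good's buffer near its pKa, dye included)
  and volume scale v = 1.
* **Leak.** An optional passive proton conductance
  leak·(E_H − ΔΨ) is available (default 0: tight vesicles).
* **Dye readout.** Pyranine is a single-site titration with pKa 7.2
  (literature value), ratio bounds 0.2–2.2 (arbitrary but configurable),
  against a constant 415 nm reference channel of 100 a.u. Gaussian noise of
  sd = noise_sd × 100 a.u. is added independently per channel per sample;
  the default noise_sd = 0.01 ratio units gives traces with the visual
  jitter of clean cuvette recordings. Noise is the only stochastic element
  and is fully seeded.
* **Integration.** Fixed-step classical RK4 with ten sub-steps per 0.5 s
  sampling interval; halving the step changes 60 s readouts by < 1e−6 pH
  units. Peptide pools carry a positivity floor of 1e−9 × [Pep]_out(0):
  under extreme export drives the internal pool collapses toward a tiny
  quasi-equilibrium faster than any fixed step resolves, and the floor
  (through the log in the reversal potential) keeps fluxes finite while
  preserving the flux direction. In the near-reversal regime the assay
  operates in, the floor is never reached. A finite-bath switch
  (`external_volume_ratio`) allows external peptide depletion; the default
  is an infinite bath, appropriate for a ~1 ml cuvette against ~µl of
  vesicle lumen.
* **Default protocol.** 70 s runs sampled at 0.5 s, valinomycin at 10 s,
  three replicates. Replicates share the deterministic kinetics and differ
  only in seeded measurement noise (spawned from the protocol seed), so
  reruns are bit-identical.

What the generator does **not** emulate: vesicle size heterogeneity, dye
leakage or photobleaching, baseline drift, valinomycin insertion kinetics,
finite K+ pools, or charged substrates. Passing recovery tests therefore
demonstrate that the inference logic is correct under the stated model, not
that real traces are this well behaved.

## Trace processing (`pepflux.traces`)

F_R = f460/f415 elementwise; normalization divides by the first reading
(idempotent, scale-invariant). Window statistics take each replicate's mean
F_R over 55–65 s (both endpoints included — the convention chosen here) and
report the across-replicate mean and SEM (n−1 SD over √n; a single
replicate reports SEM 0 with a warning). Replicates must share a sampling
grid; no interpolation is attempted.

## Inference (`pepflux.inference`)

* **Classification.** A window mean below 1 − k·σ_baseline is called
  acidification, above 1 + k·σ_baseline alkalinization, otherwise no net
  flux; k = 2 by default and σ_baseline is the SD of the normalized
  pre-valinomycin samples pooled across replicates. This is the
  quantitative surrogate for judging traces against the F_R = 1 line.
* **Bracketing.** Directional calls are hard constraints (a candidate n
  must put its reversal potential strictly above every acidification
  voltage and strictly below every alkalinization voltage); no-net-flux
  calls are soft: they nominate candidates within ±2 mV but exclude
  nothing, because at realistic noise a few mV of genuine drive is
  indistinguishable from zero. A unique nomination among the surviving
  candidates becomes the point estimate; the bracket spans the surviving
  set; `ambiguous` is raised whenever the data do not pin a single n.
  Voltage-inconsistent patterns (acidification above an alkalinization)
  raise an error rather than vote, since direction must be monotone in
  voltage under any fixed coupling.
* **Candidates** default to n = 1…10, covering 1:1 through 6:1 with
  margin. This soft/hard split is what makes the closely spaced 5:1 vs 6:1
  reversal potentials (−24 vs −20 mV under the standard gradient) degrade
  gracefully into an explicit ambiguity at high noise instead of a wrong
  point estimate.
* **Recovery harness.** For a substrate with known true coupling, the
  harness designs the voltage series (true n and its neighbours by
  default), simulates three replicates per voltage, processes, classifies,
  infers, and reports the fraction of seeds whose bracket contains the
  truth and the fraction flagged ambiguous. 100 seeds run in a few seconds.

## Uptake (`pepflux.uptake`)

Counts-to-amount conversion uses 2.22×10^12 dpm/Ci: pmol =
cpm / efficiency / (specific activity in dpm/pmol). Presets carry the
3H-di-alanine (30 Ci/mmol, 45% efficiency) and 14C-tri-alanine
(55 mCi/mmol, 98%) calibrations.

The uptake simulation runs the same linear flux law at a clamped voltage
(zero for symmetric 75 mM K+) with fixed, strongly buffered pH on both
faces and a saturating, undepleted external peptide, integrating internal
peptide with LSODA (the approach to a 10^n-fold accumulation is slow and
stiffens a fixed-step scheme; runs to the plateau use long nominal
durations, ~1e8 s by default, which the adaptive solver crosses in a few
hundred steps). The plateau lands on the closed-form accumulation ratio to
well under 1%. Absolute pmol values scale with an assumed lumen volume
(default 1 µl) and are illustrative; the quantitative content is the ratio
law and the di-vs-tri contrast, which hold across randomized liposome
parameters.

## Problem sizes used in the shipped checks

Oracle agreement uses 20 randomized gradient conditions with n drawn from
1–6 (bisection to 0.01 mV on 20 s noise-free runs). Recovery uses 100 seeds
per scenario, three voltages per run, three replicates per voltage, 70 s
traces at 0.5 s sampling. Uptake checks use n ∈ {3, 4, 5} plus ten
randomized parameter draws. These sizes give Monte-Carlo fractions with
~±0.05 resolution and run in seconds on one core.

## Known limitations

* The linear flux law has no rate-limiting turnover ceiling; far from
  equilibrium the absolute flux magnitudes are not meaningful, only their
  sign and zero crossing.
* The classifier threshold scales with estimated baseline noise; traces
  with drift or non-Gaussian noise would need a different threshold model.
* m > 1 peptides per cycle is supported in the thermodynamics and the
  simulator but the estimator reports n at m = 1.
* No Bayesian posterior over n; the bracket-plus-flag output mirrors how
  the voltage-series experiment is actually interpreted.
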