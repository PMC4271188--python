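# pepflux

Thermodynamic analysis and simulation of proton-coupled peptide transport
in proteoliposomes, built around the reversal-potential method for
measuring proton:peptide coupling stoichiometry.

## The problem

POT-family transporters (bacterial PepT homologues, mammalian PepT1/PepT2)
symport di- and tri-peptides with protons. How many protons move per
peptide is a thermodynamic quantity with real consequences — it sets how
steeply a pH gradient can concentrate substrate — but it cannot be read off
a structure. It can be read off an equilibrium: for the coupled reaction

    n H⁺(out) + m Pep(out) ⇌ n H⁺(in) + m Pep(in)

net flux vanishes at exactly one membrane voltage, the reversal potential

    ΔΨ_rev = 60·[ (pH_in − pH_out) − (m/n)·log₁₀([Pep]_in/[Pep]_out) ]  (mV),

with ΔΨ = Ψ_in − Ψ_out and 60 mV per decade. Clamp a series of voltages
with K⁺/valinomycin, watch whether the lumen (via the trapped pH dye
pyranine) acidifies or alkalinizes at each, and the voltage where flux
reverses brackets n. At zero voltage the same relation predicts the
equilibrium accumulation [Pep]_in/[Pep]_out = ([H⁺]_out/[H⁺]_in)ⁿ, testable
with radiolabelled substrate.

pepflux implements this entire analysis for simulated data: the closed-form
thermodynamics, a kinetic proteoliposome simulator emitting realistic
dual-channel pyranine traces, trace reduction to normalized F_R window
statistics, flux-direction classification and stoichiometry inference, and
the steady-state uptake model. It is aimed at people designing or
interpreting reversal-potential experiments on electrogenic transporters.

## Worked example

Plan the voltage series for a 100-fold inward peptide gradient (10 mM in,
0.1 mM out, pH 6.8 both sides, 120 mM internal K⁺), then run the full
simulate → process → classify → infer pipeline for a tri-peptide that truly
couples 3 protons:

```python
from pepflux import (AssayConditions, Stoichiometry, accumulation_ratio,
                     design_voltage_series, end_to_end_recovery)
from pepflux.simulate import tri_alanine

cond = AssayConditions(ph_in=6.8, ph_out=6.8, pep_in=10.0, pep_out=0.1)
for e in design_voltage_series(cond, [Stoichiometry(n) for n in (2, 3, 4)]):
    print(f"n={e.candidate.n_protons}:1  target {e.target_voltage:+.1f} mV"
          f"  K+_out {e.k_out_required:.2f} mM")

report = end_to_end_recovery(tri_alanine(3), cond, seeds=range(20))
print(f"recovered true n=3 in {report.n_recovered}/{report.n_runs} runs "
      f"(point estimate correct in {report.n_point_correct})")
est = report.estimates[0]
print(f"first estimate: bracket [{est.lower_n}, {est.upper_n}], "
      f"point n={est.point_n}, ambiguous={est.ambiguous}")
print(f"accumulation at 1 pH unit, n=3: "
      f"{accumulation_ratio(Stoichiometry(3), 6.5, 7.5):.0f}-fold")
```

Output:

```
n=2:1  target -60.0 mV  K+_out 12.00 mM
n=3:1  target -40.0 mV  K+_out 25.85 mM
n=4:1  target -30.0 mV  K+_out 37.95 mM
recovered true n=3 in 20/20 runs (point estimate correct in 20)
first estimate: bracket [3, 3], point n=3, ambiguous=False
accumulation at 1 pH unit, n=3: 1000-fold
```

Reading this: a 2:1 coupling would reverse at −60 mV, 3:1 at −40 mV, 4:1 at
−30 mV, and each voltage is clamped by diluting external K⁺ to the listed
concentration before adding valinomycin. Simulated runs at those three
voltages show acidification at −60 mV, no net flux at −40 mV and
alkalinization at −30 mV, so the inference returns n = 3 in every seeded
repetition; and a 3-proton coupling lets one pH unit of gradient sustain a
1000-fold peptide accumulation at zero voltage.

A command-line interface wraps the same functions:

```bash
pepflux reversal --ph-in 6.8 --ph-out 6.8 --pep-in 10 --pep-out 0.1 --n 3
pepflux design   --ph-in 6.8 --ph-out 6.8 --pep-in 10 --pep-out 0.1 --candidates 2,3,4
pepflux simulate --protocol protocol.json --out traces.csv
pepflux infer    --summary summary.csv --ph-in 6.8 --ph-out 6.8 \
                 --pep-in 10 --pep-out 0.1 --baseline-sd 0.02
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and limitations.

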