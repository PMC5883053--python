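# slowex

Quantitative analysis of **slow conformational exchange** in proteins
from NMR observables, built around the dynamics-vs-catalysis question
in cyclophilin A (CypA) rescue-mutant studies: directed-evolution
mutations that restore activity to a crippled enzyme do so by
*accelerating* the interconversion between a major and a weakly
populated minor conformation, and the conversion rate tracks catalytic
efficiency.

The package is for NMR spectroscopists and methods developers who need
a tested, scriptable re-implementation of that analysis chain:

* **CEST** (chemical exchange saturation transfer): Bloch–McConnell
  forward models and staged fitting — noise estimation from profile
  baselines, a no-exchange screen, per-residue two-site fits,
  clustering of (k_ex, p_B) to count exchange processes, global
  two-site and linear three-site fits with topology comparison
  (B↔A↔C vs A↔B↔C vs A↔C↔B), inclusion rules (|Δω| ≥ 1 ppm, F-test
  improvement, Monte-Carlo consistency) and Monte-Carlo uncertainties.
* **CPMG relaxation dispersion**: pooled duplicate errors,
  Carver–Richards fits with F-test significance (p < 0.05), R2,inf
  from the three highest refocusing frequencies, and fast/slow regime
  calls from the temperature dependence of R_ex.
* **Binding titrations**: global dissociation constants from combined
  ¹H/¹⁵N chemical-shift perturbations via the exact single-site
  isotherm.
* **Enzyme kinetics**: single-exponential progress-curve rates,
  k_cat/K_M extraction, and the orthogonal-distance regression
  through the origin linking k_maj→min to catalytic efficiency.
* **Synthetic data**: generators with known ground truth that emulate
  the study's acquisition schedules and noise, so every stage is
  testable without access to raw spectra.

## The model in brief

Exchange between a major state A and minor state(s) B (and C) is
parameterized by k_ex = k_AB + k_BA and populations p_B (p_C), with
microscopic balance on every edge of the kinetic chain. CEST profiles
are computed by propagating the Bloch–McConnell equations for
(x, y, z) magnetization of every state under weak RF irradiation;
CPMG dispersions by the Carver–Richards expression. Downstream,

    k_maj->min = p_minor * k_ex         (rate of leaving A)
    ΔG = R T ln(p_minor / p_major)      (minor-state free energy)

and k_cat/K_M is regressed on k_maj→min through the origin with errors
on both axes. See `docs/methods.md` for assumptions and numerical
details.

## Worked example

Simulate a single-mutant-like two-site dataset (8 residues at two B1
fields, 0.5% intensity noise) and run the staged CEST analysis:

```python
from slowex import simulate, cest, kinetics

truth = simulate.make_scenario("S99T-like", n_residues_per_group=4, seed=3)
schedules = simulate.default_cest_schedules("S99T-like")
profiles = simulate.generate_cest_dataset(truth, schedules, seed=11)
shifts = {r: s.shift_ppm for r, s in truth.per_residue.items()}

out = cest.fit_cest_dataset(profiles, shifts,
                            cest.CESTFitOptions(mc_runs=100), seed=1)
ex, se = out.result.exchange, out.result.standard_errors
print(ex.topology.value, f"{ex.k_ex_AB:.1f}", f"{100 * ex.p_B:.2f}")
rate, rse = kinetics.major_to_minor_rate(ex.k_ex_AB, ex.p_B,
                                         se["mc_k_ex_AB"], se["mc_p_B"])
```

Output:

```
topology      : two_site_AB
k_ex          : 191.1 +/- 10.6 s^-1
p_B           : 1.22 +/- 0.03 %
chi2_red      : 0.97
k_maj->min    : 2.34 +/- 0.14 s^-1
dG            : -2.47 kcal/mol
```

The staged fit identifies a single two-site process, recovers the
generating parameters (truth: k_ex = 188.3 s⁻¹, p_B = 1.22%) within
one Monte-Carlo standard error, and converts them into the
major-to-minor conversion rate and minor-state free energy that feed
the catalysis correlation.

A command-line interface mirrors the library
(`slowex simulate | fit-cest | fit-cpmg | fit-kd | correlate | report`);
`slowex report --config pipeline.yaml --seed 1 --out results/` runs a
configured multi-stage pipeline with a complete inclusion/exclusion
audit log.

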