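# Methods

`slowex` quantifies slow (seconds-to-milliseconds) conformational
exchange in proteins from four kinds of NMR-adjacent observables and
links the extracted kinetics to enzyme catalysis. This note documents
the models, the numerical choices, and what the synthetic-data studies
do and do not demonstrate.

## Exchange models

A protein interconverting between a dominant state A and one or two
weakly populated states B (and C) is described by a first-order rate
matrix. Each pair of connected states is parameterized by the exchange
rate constant `k_ex = k_fwd + k_rev` and the equilibrium populations;
microscopic balance `k_i->j p_i = k_j->i p_j` holds on every edge, so
the configured populations are stationary by construction. Supported
topologies are two-site A↔B and the three linear three-site chains
(B↔A↔C, A↔B↔C, A↔C↔B). The triangular model, which would connect all
three states, is deliberately not implemented: it costs an extra rate
parameter that CEST data of ordinary quality cannot constrain. For the
label-symmetric B↔A↔C chain, fitted results are canonicalized so that
the higher-population minor state carries the B label.

The rate constant for leaving the major state, `k_maj->min = p_minor *
k_ex`, is the quantity correlated with catalytic efficiency, and
`ΔG = R T ln(p_minor / p_major)` converts a population into a
free-energy difference (negative when the minor state lies higher —
this sign convention is stated explicitly because the comparison with
simulation work is otherwise ambiguous).

## CEST forward model

Saturation-transfer profiles are computed by propagating the
Bloch–McConnell equations for in-phase ¹⁵N magnetization: three
components (x, y, z) per exchange state, giving 6×6 or 9×9 evolution
matrices that combine relaxation (R1, R2, minor-state excess ΔR2),
exchange, RF nutation (ω₁ = 2π·B1 about x) and per-state offset terms.
Assumptions, all standard for amide CEST under composite-pulse ¹H
decoupling:

* scalar couplings and anti-phase terms are neglected (in-phase
  approximation);
* longitudinal relaxation during the saturation delay decays toward
  zero rather than thermal equilibrium — the I/I0 normalization
  cancels the equilibrium term at the 0.4–0.5 s delays used here;
* minor states share one ΔR2 (constrained non-negative by default;
  configurable);
* the 180° pulses of the CPMG propagator are instantaneous and
  perfect.

The matrix exponential over the saturation delay is evaluated by
scaling-and-squaring with a truncated Taylor series applied to the
whole stack of per-offset matrices at a shared scaling power. Sharing
the (largest-norm) scaling power only deepens the scaling of
smaller-norm matrices, which tightens their series truncation error,
so the batched variant is conservative; it agrees with
`scipy.linalg.expm` at the 1e-12 level and with independent
adaptive ODE integration to better than 1e-6 in I/I0, while being
roughly two orders of magnitude faster per profile than per-matrix
library calls — the property that makes the Monte-Carlo analyses below
affordable.

## CPMG dispersion

Effective relaxation rates follow the analytical Carver–Richards
two-site expression; a brute-force numerical propagator (complex
transverse magnetization, explicit echo blocks) serves as its
independent cross-check and as the forward model for three-site truth
data. The two agree within 2% across ν_CPMG = 100–1000 Hz in the
slow- and fast-exchange regimes spanned by the study parameters
(populations ≤ ~4.5%); agreement degrades in deep intermediate
exchange at higher minor populations, a known property of the
Carver–Richards approximation.

Dispersion analysis fits a flat model (one parameter) and the two-site
model (four parameters) and calls exchange significant when the F-test
between them gives p < 0.05. The F statistic uses boundary-corrected
degrees of freedom (1, n−2): under the null hypothesis the exchange
timescale and shift difference are unidentified (the model collapses
to flat at zero amplitude), so the dispersion family absorbs about one
effective noise degree of freedom rather than three; the naive
(3, n−4) convention would test at ~0.4% actual size instead of the
nominal 5%. The correction is calibrated on flat-profile null
simulations (measured size ≈ 4.5%).
Measurement errors come from the pooled relative standard deviation of
duplicate points, `sqrt(Σ((a_i−b_i)/mean_i)² / (2 n_pairs))`, converted
to absolute units per point. R2,inf is the mean of the three highest
refocusing frequencies. The exchange contribution R_ex is reported as
the fitted dispersion evaluated at the lowest measured frequency minus
R2,inf — a smoothed version of the corresponding data difference.
Regime classification uses the temperature dependence of R_ex (it
grows with temperature for slow exchange, shrinks for fast exchange;
threshold 0.05 s⁻¹/K on the slope) with a dispersion-shape fallback
(half-quench frequency below 400 Hz indicates the slower regime).
Rates and populations from CPMG alone are not propagated downstream
for slow processes; the CEST fit is the quantitative source.

## Staged CEST inference

1. **Noise.** Per-profile σ of I/I0 from first differences of
   grid-adjacent, dip-free baseline points (robust median/MAD dip
   screening); differencing cancels slow baseline trends. Profiles
   with fewer than 50 baseline points fall back to a configurable
   floor (0.01) with a warning.
2. **No-exchange screen.** R1, R2, I0 fitted per residue; a residue is
   flagged as an exchange candidate when the upper-tail chi-square
   probability of its fit is below 0.05. On a flat baseline R1 and I0
   are nearly degenerate (only their product is pinned); this is
   harmless because the screen uses the fit quality, not R1 itself.
3. **Per-residue two-site fits.** (k_ex, p_B, Δω, R1, R2, ΔR2, I0)
   jointly across B1 fields, with Δω initialized from the deepest
   off-resonance residual dip and its sign flip. Fits pinned at
   parameter bounds, with |Δω| < 0.1 ppm, or whose exchange
   contribution never exceeds 3σ anywhere are marked unidentifiable.
   Transformed-parameter standard errors (log k_ex, logit p_B) are
   retained from the covariance matrix.
4. **Clustering.** Per-residue (log k_ex, logit p_B) estimates are
   clustered by deterministic 2-means with axes scaled by the median
   per-residue standard errors, so separations are measured in units
   of measurement error. The two-cluster solution is accepted only if
   (a) its explained-variance fraction exceeds the 95% quantile of the
   same statistic under a single-Gaussian null simulated at the
   observed sample size, (b) the centers are at least 8 error-units
   apart, and (c) both clusters have at least two members — a
   "process" supported by one residue is an outlying fit, not a
   second process. One cluster implies a single global two-site
   process; two imply a three-site analysis.
5. **Global fits.** Shared exchange parameters plus per-residue
   nuisance parameters, as bounded nonlinear least squares on
   log k_ex and logit p (positivity and population constraints without
   penalties), with block-sparse finite-difference Jacobians (the
   column-grouping keeps the per-iteration cost independent of residue
   count) and `x_scale='jac'`. Three-site fits add a χ²-triggered
   polish: residues whose contribution to χ²_red exceeds 1.3 are
   re-fitted with the global parameters fixed from a grid of
   alternative Δω starting values (sign flips and residual-dip
   candidates), then the global fit is repeated — when only one
   minor-state dip is visible, the other Δω start is genuinely
   ambiguous and this comparison-of-χ² procedure resolves it.
6. **Topology comparison.** The three linear chains are fitted from
   the cluster seeds (higher-population process seeding the A/B pair);
   chains within Δχ²_red = 0.1 are reported as indistinguishable, and
   B↔A↔C (independent processes) is selected unless another chain wins
   decisively.
7. **Inclusion rules.** A residue enters the final fit only if
   |Δω| ≥ 1 ppm (either process), the exchange model improves over
   no-exchange at p < 0.05 by F-test, and per-residue Monte-Carlo
   re-fits with floating k_ex/p_B are consistent: relative spread of
   k_ex below 50% and a unimodal sample (best two-class split explains
   < 80% of the variance — a two-class split of a Gaussian sample
   explains about 64%, of a genuinely bimodal one > 90%).
8. **Uncertainties.** Parametric Monte-Carlo: datasets re-drawn as
   best-fit model plus Gaussian noise at the estimated σ and fully
   re-fitted (500 runs by default; covariance-matrix errors are also
   reported and agree with the Monte-Carlo spread within a few
   percent). The re-fits use a bounded damped Gauss–Newton warm-started
   at the base solution; because the data enter the weighted residuals
   additively, the Jacobian is data-independent and is computed once
   per campaign, which makes the runs about an order of magnitude
   cheaper than independent trust-region fits while converging to the
   same optima (verified run-by-run against full re-fits).

## Binding titrations

Fast-exchange peak positions move by the protein bound fraction times
the saturation shift. The bound fraction is the exact single-site
quadratic in total concentrations (ligand depletion included; no
free≈total approximation). Combined shifts use
`sqrt(ΔδH² + (ΔδN/6.3)²)`; residues with maximal combined shift below
0.035 ppm are excluded. One K_D is shared across residues
(unweighted global least squares; per-residue saturation amplitudes
are nuisance parameters) and its standard error comes from the global
covariance scaled by the residual variance. The K_D ≈ K_M
identification used when converting efficiencies is a reporting
assumption carried as a label, never used in fitting.

## Enzyme assays and the correlation

Progress curves are fitted as single exponentials
`A(t) = A∞ − ΔA·exp(−k_obs t)`; curves spanning fewer than ~3
half-lives are flagged as extrapolated. Catalytic efficiency is
`(k_obs − k0)/[E]` averaged over concentrations and replicates
(mean ± sd), with the thermal background k0 from [E] = 0 triplicates.

The kinetics–catalysis correlation is an orthogonal distance
regression of k_cat/K_M on k_maj→min through the origin, weighted by
the uncertainties on both axes. χ²_red uses the orthogonal effective
variance `sy² + slope²·sx²` over n−1 degrees of freedom. The reported
adjusted R² is computed on the zero-intercept model with the
uncentered total sum of squares under the instrumental y-weights
1/sy²; with one parameter and n−1 degrees of freedom the adjustment
leaves R² unchanged. Wild-type protein is excluded from the
correlation: its conversion rate is not measurable by CEST.

## Synthetic data

The generator draws per-residue parameters from stylized but realistic
ranges — |Δω| ∈ [1, 5] ppm with random sign for exchanging residues,
R1 ∈ [1, 2] s⁻¹, R2 ∈ [8, 20] s⁻¹, ¹⁵N shifts in 108–128 ppm, ΔR2 = 0
— around the exchange parameters of the built-in scenarios (two-site
188.3 s⁻¹/1.22%; B↔A↔C 422.9/1.93% + 177.7/0.31% and 265.1/4.32% +
186.5/0.73%). Noise defaults: Gaussian sd 0.005 on I/I0, 0.3 s⁻¹ on
R2,eff, (0.002, 0.01) ppm on (¹H, ¹⁵N) positions, 0.002 AU on
absorbance. Acquisition schedules mirror the study conditions: B1
fields of 10.8–34.7 Hz with saturation delays of 0.4–0.5 s and 20–25 Hz
offset grids for CEST; an 11-point 100–1000 Hz grid with a 40 ms
constant-time period and duplicates at 200/800/1000 Hz for CPMG;
titrations at 0/1/3/5/9 mM ligand against 0.25 mM protein. Multi-
temperature CPMG scales k_ex by a configurable factor (default 1.8 per
+5 K; no activation energies are published, so this is a stylized
Arrhenius-like choice).

What the generator does **not** emulate: peak overlap, baseline
distortions, B1 inhomogeneity, scalar-coupling effects, temperature-
dependent populations, or non-Gaussian intensity noise. Passing
recovery studies therefore demonstrate the correctness and calibration
of the inference machinery, not robustness to every artifact of real
spectra.

## Simulation-study sizes

The validation studies (`slowex.validation`) default to reduced but
identifiable designs chosen so a full campaign runs in minutes on one
CPU: 4 residues (two-site) or 2 per group (three-site scenarios, with
groups sensing process 1, process 2, and both), 25 Hz offset grids over
a 102–133.5 ppm window matching where the synthetic shifts live, 20
replicates, and 100 Monte-Carlo runs per fit. Recovery is assessed per
global exchange parameter as the fraction of replicates whose estimate
lies within two Monte-Carlo standard errors of the truth; with four
jointly estimated parameters the per-parameter criterion is the
calibration-faithful one (joint coverage of four correlated intervals
is nominally ~85–90% even for a perfect fit). Intervals are formed on
the estimation scale (log k_ex, logit p) with parametric-bootstrap
bias correction: the Monte-Carlo refits are a parametric bootstrap, so
`mean(samples) − estimate` estimates the finite-sample bias and
`2·estimate − mean(samples)` the corrected value. Both refinements
matter at small designs — the curved k_ex/p likelihood ridge biases
raw estimates by a fraction of a standard error, and the sampling
distribution of a weakly identified rate (the 0.31%-populated second
process) is right-skewed, so uncorrected linear-scale intervals
under-cover by several percent.

## Known limitations

* The Carver–Richards expression (and hence CPMG fitting) assumes
  two-site exchange; three-site dispersions are only composed
  approximately (sum of independent contributions, good to ~10% when
  both processes are slow).
* The no-exchange screen can absorb small exchange contributions into
  an inflated R2 (broadened direct-saturation dip), so residues with
  |Δω| near 1 ppm and weak minor populations may escape flagging at
  coarse offset grids; the study-density grids keep this rare.
* Equilibrium recovery during the saturation delay and
  exchange-modulated minor-state R1 are not modeled (toggleable
  approximations would require a 1-augmented state space; at the
  delays and populations considered their effect is far below the
  noise floor).
* The unimodality heuristic for Monte-Carlo consistency is a
  variance-split rule, not a formal dip test; it is calibrated to
  separate clearly bimodal re-fit distributions from Gaussian ones.
* At the reduced validation designs, the most weakly identified
  quantity — the exchange rate of a ~0.3%-populated second process
  constrained by a handful of residues — can have a multimodal
  likelihood: distinct combinations of shift-difference signs and
  rates fit equally well within noise. Warm-started Monte-Carlo
  re-fits stay within one mode, so their spread understates the full
  uncertainty for that parameter and its nominal-coverage intervals
  run a few percent short. With study-sized residue counts (tens of
  residues per process) the modes resolve and the effect disappears.
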