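# Methods

This note records the models implemented in `formsim`, their assumptions,
the defaults and why they were chosen, what the synthetic data emulate, and
the numerical choices that affect results.

## Dissolution kinetics and similarity

Cumulative release is modeled as a weighted sum of two Weibull CDFs sharing
a plateau `fmax` (percent of label claim) and lag time (h):

    F(t) = fmax·[w1·(1−exp(−((t−lag)/scale1)^shape1))
               + (1−w1)·(1−exp(−((t−lag)/scale2)^shape2))]

This parameterization (Fmax, Weibscale 1/2, Weibshape 1/2, weight w1) is the
form used by gut-absorption simulators for "direct in vitro input" of XR
release data. Fitting is bounded multi-start nonlinear least squares
(shapes in [0.2, 5], scales in [0.05, 100] h, fmax in [0, 110]) because the
biphasic SSE surface is multimodal; the start grid is deterministic, so fits
are reproducible. Profiles with fewer than 7 points are fit with the reduced
single-phase model (w1 = 1) — in particular the two printed three-point
profiles, where three parameters (fmax, scale, shape) are exactly
identified. A profile of all zeros returns a degenerate fmax≈0 fit flagged
as such rather than an error.

The similarity factor is

    f2 = 50·log10(100·[1 + (1/n)·Σ(R_t − T_t)²]^(−1/2))

over the timepoints common to both profiles, truncated to at most one point
after both profiles exceed 85% released (the standard regulatory convention,
which prevents similarity inflation by post-plateau points). Identical
profiles give 100; a uniform 10-point difference gives 49.89, which rounds
to the 50 boundary. The bootstrap variant resamples vessels with replacement
within each arm (2000 draws by default), computes f2 on resampled mean
profiles, and reports a percentile interval; the 5th percentile is the
decision statistic, the usual conservative choice for f2 bootstraps.

## Box–Behnken response surfaces

The 3-factor design is the 12 edge midpoints (±1, ±1, 0 permutations) plus
center replicates; 5 centers give the canonical 17-run design and a
pure-error variance estimate. Models are fit by OLS on the full 10-term
quadratic **in actual percent-w/w units** — evaluating the published 1-h
model at the optimized composition (20, 20, 5)% reproduces the printed 22%
release only in actual units, so coded-unit fitting would be inconsistent
with the reported coefficients. Terms with p ≥ α (default 0.05) are pruned
and the model refit on the survivors; this per-term pruning (no stepwise
search) mirrors how sparse published coefficient sets are reported. Target
matching minimizes the summed squared deviation of per-timepoint predictions
over the factor box with multi-start L-BFGS-B from a deterministic grid.
Default factor bounds are 5–40% w/w per polymer (configurable); lactose
filler is reported as q.s. to a 750 mg tablet but is not a model factor.

## Matrix characterization

Hydration and erosion are the standard gravimetric ratios (both
scale-invariant in the weights). The gel-strength expression is implemented
as G = 0.0098·F/(x·rp) MPa with F in grams-force, x and rp in mm; 0.0098
converts gram-force to newtons. The published arithmetic for this quantity
is ambiguous, so an alternative reading that further normalizes by the probe
cross-section is selectable via the `variant` argument; the default
preserves the stated force-per-displacement semantics. The default probe
radius is 7.0 mm (the value quoted with the equation; note a 10 mm *diameter*
probe is described elsewhere for the same instrument — the equation's value
is used).

## Oral-absorption model

Nine sequential GI compartments (stomach, duodenum, jejunum 1–2, ileum 1–3,
caecum, ascending colon) with first-order transit at rate 1/transit-time.
Three luminal states per compartment: unreleased depot, released solid,
dissolved drug.

* **Release.** The formulation schedule is enforced through its hazard
  h(t) = g'(t)/(1−g(t)) applied to the depot (g = cumulative release
  fraction), so total release tracks the in vitro curve while the depot
  transits; the hazard is capped at 200/h for shape exponents < 1 near the
  lag. IR release is first-order with default 8/h (≥85% released within
  15 min). The approximation is exact while the depot remains in the tract;
  depot leaving the colon unreleased is counted as unabsorbed loss.
* **Dissolution/precipitation.** Released solid dissolves first-order
  (100/h) limited by the saturation solubility interpolated piecewise-
  linearly in pH between the measured points (31/47/52 mg/mL at pH
  2/4.5/6.8, clamped outside); supersaturation precipitates back at 100/h.
  At the 23 mg dose solubility never binds; the machinery matters only for
  dose-escalation studies. The salt solubilization factor reported with the
  pKa fit is carried in `DrugParams` for config fidelity but is not applied
  to the measured solubilities (it belongs to a pKa-based solubility model
  this package does not use, and multiplying measured saturation values by
  it would be unphysical).
* **Absorption.** Flux from dissolved drug with
  ka_i = 2·Peff·ASF_i/radius_i (cylindrical surface-to-volume), Peff in
  units of 1e-4 cm/s (default 3.1). ASF defaults: 0 in the stomach, 0.5 in
  the small intestine, 0.40 caecum, 0.20 ascending colon.
* **Elimination.** Absorbed drug enters a well-stirred liver (1.8 L)
  exchanging with the central compartment at hepatic blood flow 90 L/h, so
  first-pass and systemic clearance emerge from one mechanism. Metabolism is
  v = Σ SF·Vmax·Cu/(Km + Cu) on the unbound liver concentration
  (fu_b = fu_p/(B:P) = 0.04/0.78), with in vitro Vmax (ng/min/mg microsomal
  protein) scaled by MPPGL = 32 mg/g and 1800 g liver. Defaults: CYP2D6
  Vmax 125, Km 47 µM, SF 1.0 (the fitted value is not published; override in
  config when known); CYP3A4 Vmax 89, Km 44 µM, SF 5.0. At therapeutic
  exposure Cu ≪ Km, so kinetics are effectively linear; saturation appears
  only under large dose escalation.
* **Disposition.** A two-compartment model replaces full-body tissue
  partitioning (out of scope here): VBE conclusions rest on relative
  test/reference behavior, which survives lumping the tissues. Defaults
  Vc = 3.0 L/kg, k12 = k21 = 0.06/h, body weight 70 kg were calibrated —
  together with the ASF defaults above — so the IR simulation lands at
  Tmax ≈ 3.3 h and terminal half-life ≈ 71 h, consistent with published
  donepezil pharmacokinetics; absolute Cmax is plausible but not tuned to
  any study.

Integration uses LSODA with rtol 1e-8/atol 1e-10 on a fixed 0.05 h output
grid (0.1 h in the fast test configurations); halving the grid changes Cmax
and AUC by well under 0.5%. A mass-balance audit (lumen + body + eliminated
+ excreted vs dose) runs at every output time and any deviation beyond 0.1%
raises an integrity error; in practice the deviation is at solver precision
(~1e-12). AUC0–t is trapezoidal on the output grid; AUCinf adds
Clast/λz with λz from a terminal log-linear fit and is reported missing when
no negative terminal slope exists.

With the defaults, the IR form absorbs ~99% of dose, concentrated in the
duodenum/jejunum, while the XR (reference Weibull) form absorbs ~72% with
substantial caecal and colonic uptake — the qualitative XR/IR contrast the
model is meant to capture. These fractions are emergent, not fitted.

## Parameter sensitivity analysis

One-at-a-time multiplicative sweeps (default 0.25×–4× in 9 log-spaced steps,
center exactly 1.0) over: lag time, Fmax, both Weibull shapes and scales,
Peff, both CYP Vmax values, and stomach transit time. Sensitivity is the
elasticity d log(metric)/d log(parameter) by central difference at ±10%,
unitless by construction. The multiplier-1 row is the unperturbed baseline
simulation; sweep-point failures are recorded as missing rather than fatal.
Global (variance-based) indices are deliberately out of scope — the OAT
framing matches how such analyses are reported for this class of model.

## Virtual bioequivalence

Variability enters mechanistically: each subject gets a between-subject
(BSV) log-normal multiplier per parameter, drawn once, and an independent
within-subject (WSV) multiplier re-drawn per period — not post-hoc noise on
PK metrics. Multipliers have median 1 and CV = sqrt(exp(σ²)−1). The default
CV set (percent, BSV/WSV): CYP3A4 Vmax 15/15, CYP2D6 Vmax 15/15, stomach
transit 35/35, Peff 30/30, Weibull scales 5/5, shapes 5/5, Fmax 3.2/3.2.
The dissolution rows are in vitro variability of the administered
formulation and are applied to its Weibull parameters each period.

Trials are balanced two-sequence (TR/RT) two-period crossovers. Analysis is
on the log scale with the balanced 2×2 fixed-effects model: the
period-adjusted estimate is the mean of the two sequences' mean
within-subject differences, its standard error uses the pooled
within-sequence variance of those differences (df = n−2), and the 90% CI
corresponds to TOST at α = 0.05. With zero residual variance the CI
degenerates to the point estimate. A trial passes when both Cmax and AUC0–t
CIs lie within 80–125%. Pass counts over repeated trials (15 by default,
each with an independently drawn population from seed-derived streams) map
to risk: low ≥ 13/15, moderate 9–12/15, high < 9/15, generalized
proportionally. The sample-size stepper grows n until empirical power
(passing fraction) reaches the target, reusing each trial's max-n population
truncated to the current n (common random numbers) so the power curve is
monotone up to Monte-Carlo noise. The default VBE base configuration uses
the 72 h simulation horizon; AUC0–t is therefore AUC over 72 h. Populations
are demographically homogeneous (70 kg); demographic matching is out of
scope.

## Synthetic data

The generators stand in for unpublished raw data and external clinical
datasets; they are pure functions of (spec, seed).

* **BBD tables**: responses drawn from truth quadratics (default: the
  published retained-coefficient models for the four sampling times) plus
  Gaussian noise (σ = 1% released). Factor levels default to 10–30% for the
  two HPMC grades and 2–8% for NaCMC, centered on the optimized composition.
* **Dissolution profiles**: sampled from Weibull truth curves (default: the
  fits to the two printed three-point profiles) at 0.5/1/2.5/5/13 h with
  clipped, monotonized Gaussian noise (σ = 1%).
* **Clinical PK**: per-study "observed" data are re-simulations with
  log-normal perturbations (default CV 10%) of permeability, CYP capacities
  and gastric emptying; "predicted" is the unperturbed baseline. This
  exercises AFE validation logic; it cannot validate the model against real
  human data, and passing these tests shows internal consistency only.

None of the synthetic processes emulate inter-laboratory assay bias,
non-log-normal physiological variability, correlated parameter variation, or
fed-state physiology; conclusions from the test suite therefore do not
extend to those features of real datasets.

## Known limitations

* Tissue partitioning is lumped; absolute exposure magnitudes carry the
  calibration's uncertainty even though relative (T/R) conclusions are
  robust to it.
* No transporters, enterohepatic recycling, food effects, or regional
  permeability prediction; colonic ASF values are documented constants.
* The CYP2D6 scale factor defaults to 1.0 because no fitted value is
  published; users with clearance data should calibrate it in config.
* The f2 bootstrap assumes exchangeable vessels within an arm.
* Release scheduling by hazard treats release as location-independent;
  matrix tablets whose release rate depends on local hydrodynamics are not
  distinguished.
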