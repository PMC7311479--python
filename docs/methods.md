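# Methods notes

This note records the models implemented in `lumistab`, their assumptions,
the defaults that matter, and the design choices taken where the underlying
experimental conventions leave room. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Thermal melts (`lumistab.thermal`)

**Model.** Ellipticity vs temperature is fit with the 4-parameter Boltzmann
sigmoid θ(T) = θ_post + (θ_pre − θ_post)/(1 + exp((T − Tm)/s)), with flat
pre/post plateaus by default. A linear-baseline variant
(`fit_boltzmann(..., linear_baselines=True)`) is available because plateau
treatment in commercial fitting software is rarely reported; the flat default
matches the common 4-parameter sigmoid.

**Apparent Tm.** Protein thermal denaturation monitored this way is typically
irreversible, so the midpoint is a comparative readout, not an equilibrium
quantity. Reports label the column `apparent_tm_C`, and no van 't Hoff or
two-state analysis of melts is attempted.

**Fitting.** Multi-start Levenberg–Marquardt least squares with Tm started at
the 25/50/75% quantiles of the scanned range; lowest SSR wins, ties broken by
lower Tm. `se_tm` comes from the parameter covariance. Fewer than 10 points is
an input error; a fitted Tm outside the scanned range is flagged (and warned),
not rejected. Temperatures stay in °C — the model never needs Kelvin.

**ΔTm.** `delta_tm` is modified − reference with error √(se_ref² + se_mod²),
assuming the two fits are independent.

## Urea denaturation (`lumistab.denaturation`)

**Model.** Two-state folded↔unfolded equilibrium with the linear extrapolation
method: ΔG([D]) = ΔG_H₂O − m·[D]; K_U = exp(−ΔG/RT); observed signal
[(a_f + b_f D) + (a_u + b_u D)·K_U]/(1 + K_U). R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹
and T = 293.15 K by default (fluorescence acquired at 20 °C); both are
configurable. Exponents are clipped at ±700, keeping the model finite for
|ΔG| up to ~400 kcal/mol.

**Global fit.** ΔG_H₂O and m are shared across replicates; each replicate has
its own four baseline parameters (a shared-baseline mode exists behind a
flag — which convention the original analyses used is generally unstated, and
per-replicate baselines are the safer default because they absorb
instrument-session drift). Multi-start over ΔG ∈ {1,3,5,8} kcal/mol ×
m ∈ {1,2,3} kcal/mol/M, baselines initialised from the curve ends; lowest SSR
wins. Unweighted least squares is used, matching standard LEM practice.

**Standard errors.** Two reporting modes, because "error of a global fit over
n replicates" is genuinely ambiguous in the field: `global_covariance`
(default) takes SEs from the global-fit covariance; `replicate_sem` refits
each replicate independently and reports the SEM of the per-replicate
estimates. Every report row records which mode produced its errors.

**Derived quantities.** Cmid = ΔG_H₂O/m is always computed from the fitted
values, so Cmid·m = ΔG_H₂O holds exactly by construction. (Published
stability tables sometimes contain Cmid cells inconsistent with their own
ΔG/m at the printed precision — rounding/typo artefacts; this package never
reproduces such cells, it recomputes.) ΔΔG is modified − reference with
quadrature error. Note the related point that a text body may quote a ΔΔG
(e.g. +0.63) that differs in the last digit from the difference of the
table's rounded entries (7.49 − 6.87 = +0.62); the package follows the table
arithmetic.

**Identifiability at realistic noise.** The synthetic study conditions
(3 replicates × 25 points on 0–6 M, 1% multiplicative noise, transition
amplitude ~0.7 with fitted per-replicate linear baselines) put a Fisher-
information floor of ≈0.06–0.10 kcal/mol on the achievable *median* |ΔG
error| across the 3.4–6.9 kcal/mol truth range — ΔG_H₂O is an extrapolation
to zero denaturant, and its variance is dominated by the baseline/transition
trade-off, not by the optimiser. The m-value, by contrast, is recovered with
median error ≈0.03 kcal/mol/M. The parameter-recovery test asserting a
0.05 kcal/mol median for ΔG therefore fails under these honest conditions
and is left in place as a statement of the target; the noiseless recovery
(relative error < 10⁻⁵) and the 2-SE coverage checks pass.

**Reagents.** `concentration_from_absorbance` is Beer–Lambert A/(ε·l), with
bundled `ReagentSpec`s for GSNO (ε₃₃₅ = 0.92 mM⁻¹cm⁻¹) and the wild-type
luminal-domain construct (ε₂₈₀ = 1.2944 mg mL⁻¹cm⁻¹).

## Chemical-shift perturbations (`lumistab.csp`)

**Formula.** CSP = √(ΔH² + (w·ΔN)²) with w = 0.14 (configurable), the
standard amide rescaling of the ¹⁵N ppm range onto the ¹H scale. With w = 1
the metric is the Euclidean ppm distance.

**Peak lists.** Sparky-style whitespace tables (`Assignment w1 w2`, with
w1 = ¹⁵N and w2 = ¹H as conventional for ¹⁵N-HSQC lists) or
`residue,h_ppm,n_ppm` CSV. Assignments such as `G109N-H` yield residue 109;
unparseable assignments are kept as unassigned records (excluded from the
per-residue profile but counted in match summaries). Duplicate residues are a
hard error naming the duplicates. Residue numbering is taken as-is: the
luminal-domain construct and the EF-SAM assignments occupy the same native
coordinates, so **no numbering offset is ever applied**.

**Matching.** Default is by residue number (assignments transferred between
conditions). For unassigned data, greedy minimum-distance pairing in weighted
shift space with a 0.2 weighted-ppm acceptance cutoff; each peak used at most
once; unmatched peaks are always reported. Greedy pairing is not guaranteed
globally optimal; the test suite checks it against an exhaustive assignment
oracle on well-separated instances.

**Threshold.** No universal convention exists for "significant" CSP. The
default is the common iterative rule: exclude values > mean + 3 SD until
stable, then threshold at (trimmed mean) + 1 SD. A fixed user value is the
alternative. This is a convention choice, not a rule taken from any one
study.

**Clusters.** Maximal runs of above-threshold residues, tolerating up to
`max_gap = 1` below-threshold or unobserved residue inside a run, discarding
runs shorter than `min_length = 3`. The gap tolerance reflects that single
prolines/overlapped peaks interrupt otherwise contiguous perturbed helices.

**Structure mapping.** `map_to_structure` writes 100·CSP (capped at 999.99,
the fixed-width column limit) into the B-factor field of every atom of the
selected chain via Bio.PDB; residues without a CSP get 0. Profile residues
missing from the structure are listed in the returned table
(`mapped=False`), not raised; zero overlap is an error reporting both
numbering ranges.

## Fura-2 traces (`lumistab.fura`)

**Calibration.** [Ca²⁺] = K_d·β·(R − R_min)/(R_max − R) with K_d = 225 nM.
R ≥ R_max is a saturation error; R < R_min clamps to 0 nM with a warning.
`derive_calibration` takes end-of-run Triton (saturating) and EGTA
(Ca²⁺-free) segments: R_max/R_min are segment means, β is mean F380(free) /
mean F380(saturated); without F380 segments β defaults to 1 with a warning.
No viscosity or background correction is applied to R_min/R_max.

**Windows.** All summary statistics are means over *time* windows
(stop-exclusive, so a window ending at an addition excludes the
post-addition sample): suspension-protocol F₀ is the 50 s before TG; the
plate-protocol F₀ is the 80 s before TG (EGTA present); basal uses the 30 s
before EGTA; peak SOCE uses 450–550 s after the Ca²⁺ addback. Defining the
baseline by a 50-s time window rather than "the first 10 points" keeps the
definition sampling-rate independent (at 1-s sampling the two coincide up to
one sample). Event times are supplied explicitly; there is no automatic
event detection.

**Protocols.** Suspension: F/F₀ normalisation (quotient), basal calibrated
to nM, SOCE as mean F/F₀. Plate: no nM calibration; relative basal is
F_basal − F₀ and relative SOCE is F_SOCE − F₀ (ratio differences).

## Synthetic data (`lumistab.simulate`)

Generators are pure functions of (truth, seed) — bit-identical on repeat.
Defaults encode the study conditions: 20–90 °C melts at 1 °C steps;
25-point 0–6 M urea grids, n = 3 replicates, 1% multiplicative noise,
per-replicate baselines (1.00, −0.010, 0.30, 0.012)±small variations — i.e.
a ~70% fluorescence quench on unfolding with gently sloping baselines;
amide peak lists over residues 62–205 with two perturbed spans (68–76 and
130–142, emulating the entering EF-hand helix and the EF-hand-exit/SAM-linker
face where published perturbations cluster — the exact spans are this
package's choice); 600-s Fura-2 records at 1-s sampling with EGTA at 100 s,
TG at 200 s and addback at 400 s, chosen so the 450–550 s SOCE window is
live, plus appended Triton/EGTA calibration segments consistent with the
truth's β.

Noise models: additive Gaussian for the CD signal and for each Fura-2
fluorescence channel; multiplicative (fractional) Gaussian for denaturation
fluorescence — matching typical instrument behaviour. What the generators do
**not** emulate: baseline curvature and aggregation artefacts in melts,
intermediate unfolding states, NMR peak overlap/linewidth effects,
cell-to-cell variability and photobleaching. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated noise
models, not robustness to every real-data pathology.

## Statistics (`lumistab.stats`, `lumistab.report`)

The two-group comparison is the classic equal-variance Student's t-test
(df = n₁ + n₂ − 2), with Welch's test behind `equal_var=False`; ANOVA/post
hoc comparisons are out of scope (group summaries are emitted for external
tools). Error propagation for differences is always quadrature,
√(e₁² + e₂²), assuming independent estimates. Report CSVs round display
columns to 1 decimal (°C) or 2 decimals (kcal/mol, M) while keeping
full-precision columns alongside, and are byte-reproducible for identical
inputs.

## Problem sizes

The recovery sweeps use 100 seeds (Boltzmann melts; 4 × 25 seeds across the
ΔG/m truth range for the global fits) and 20-seed Fura-2 sweeps; these sizes
give stable medians while keeping the full suite and the acceptance script
each within a couple of minutes on one core.
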