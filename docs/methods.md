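# Methods

This note documents the models, statistical procedures, parameter choices
and numerical decisions behind `spinex`, and what the synthetic-data tests
do and do not establish about real data.

## Spin physics

### Conventions

All internal math is in angular frequency (rad/s); ppm appears only at the
interface. Frequencies live on the chemical-shift scale with a positive
¹⁵N Larmor frequency — the sign of the ¹⁵N gyromagnetic ratio is
irrelevant because only relative offsets enter the rotating-frame
equations. The static field is configured as the ¹⁵N Larmor frequency in
Hz (defaults 60.83 MHz for a 14.1 T instrument, 70.97 MHz for 16.4 T;
nominal values, since exact spectrometer frequencies are
instrument-specific). Default temperature 283.15 K (10 °C). The design is
nucleus-agnostic but only ¹⁵N defaults ship.

### Bloch–McConnell forward model

`bloch.build_evolution_matrix` assembles the 6×6 generator L of
dM/dt = L·M for (x, y, z) magnetization of both states: offset precession
at (Ω_GS, Ω_ES), nutation about +x at ω_SL, autorelaxation (−R₂
transverse, −R₁ longitudinal, shared between states — they are the same
spin), and exchange coupling (−k₁/+k₋₁ and +k₁/−k₋₁ on the diagonal-block
identities). The thermal-recovery (inhomogeneous) term is omitted: a
spin-lock experiment measures the decay of prepared magnetization, which
is exactly the homogeneous problem.

Initial condition: both states aligned along the population-averaged
effective field direction (sin θ̄, 0, cos θ̄), with magnitudes p_A and
p_B. This emulates an experiment whose alignment element rotates
equilibrium magnetization onto the effective field before locking; the
alignment element itself (and relaxation during it) is not simulated, a
documented assumption since acquisition schemes vary.

Propagation is by eigendecomposition of L (exp(Λt) in the eigenbasis),
with a scaling-and-squaring (`scipy.linalg.expm`) fallback when the
eigenvector matrix is ill-conditioned (condition number > 1e8); the two
routes agree to 1e−8 relative and both are cross-checked against an
independent RK45 integration in the tests.

`r1rho_numeric` extracts R₁ρ as the negative real part of the eigenvalue
of L whose eigenvector overlaps the population-averaged effective-field
direction most strongly. Ties near level crossings are resolved by that
overlap criterion rather than by smallest-real-part, which fails there. An
alternative route fits a monoexponential to the projection of the
simulated trace onto the lock direction; `method="both"` warns when the
two disagree by more than 5% (a regime where a monoexponential description
of the decay is breaking down).

### Closed-form rate and its validity

The fitting function is the Laguerre approximation of asymmetric two-site
exchange (Miloushev–Palmer form; written out in `laguerre.py` and the
README). Measured against the Bloch–McConnell eigenvalue rate over a grid
spanning p_B ∈ {0.5, 1, 3, 5}%, k_ex ∈ {100, 423, 1000, 2000} s⁻¹,
Δω ∈ {1.4, 2.0, 3.9, 4.3} ppm at 60.83 MHz, lock powers 100–2000 Hz and
offsets up to ±3.5× power:

- on-resonance: agreement ≤1% everywhere on the grid;
- off-resonance at powers ≥300 Hz: ≤1.3% everywhere;
- off-resonance at 100 Hz: ≤2% for p_B ≤ 1%; for p_B ≥ 3% in slow
  exchange (k_ex below |Δω| in rad/s) the deviation grows, reaching ~7% at
  the grid's extreme corner (p_B = 5%, k_ex = 100 s⁻¹, Δω = 4.3 ppm,
  lock near the minor-state resonance).

The acceptance suite asserts the ≤2% contract over the valid region and
separately pins the >2% deviation of the slow-exchange corner as the
documented validity boundary. The exchange-term denominator is guarded
against non-positivity; empirically (300k-sample random search over the
physical domain) it never goes non-positive for p_B < 0.5, so the guard is
defensive. During optimisation the vectorised evaluator floors the
denominator instead of raising so that wild trial steps are penalised
rather than fatal.

## Statistics

### Decay fitting

I(t) = I₀·exp(−R₁ρ·t) with R₁ρ ≥ 0. The amplitude is profiled out
analytically (variable projection), reducing the fit to a one-dimensional
search over the rate: coarse log-grid scan, then bisection on the
stationarity condition to machine precision, vectorised over arbitrary
batches of curves. Log-space fitting was rejected because noisy late-delay
intensities can reach zero or below. A flat curve fits to rate 0; a decay
too fast for the delay grid is flagged unconverged.

Monte-Carlo errors (default 50 iterations, seeded): synthetic curves =
best-fit curve + Gaussian noise, refit, σ = standard deviation of refit
rates. Parametric resampling (not residual bootstrap) because the delay
grids have only ~6 points. The noise scale is the per-point
`intensity_sigma` when the table carries one, otherwise the dof-corrected
residual standard deviation sqrt(RSS/(n−2)) — the unbiased choice; the
plain RMS would systematically underestimate σ by ~18% on 6-point grids.
The synthetic generator writes its true per-point sigmas into the tables
it emits, which keeps the Monte-Carlo errors calibrated under the
generator's heteroscedastic (relative) noise; with the fallback, MC sigmas
are accurate for homoscedastic noise and mildly conservative otherwise.
At the reference condition (R = 25 s⁻¹, 6 delays to 60 ms, 1% noise) the
MC sigma reproduces the analytic linearised-least-squares standard error
within a few percent.

### Global fitting

Weighted χ² = Σ[(R₁ρ_obs − R₁ρ_Laguerre)/σ]², minimised with
`scipy.optimize.least_squares` (trust-region reflective, bounds
p_B ∈ (1e−4, 0.3], k_ex ∈ [10, 1e5] s⁻¹, |Δω| ≤ 20 ppm, R₁ ∈ (0, 10],
R₂ ∈ (0, 100] s⁻¹). In global mode (p_B, k_ex) are shared and each residue
contributes its own (R₁, R₂, Δω); R₁ and R₂ are shared between the on- and
off-resonance data of a residue (single spin model — standard practice,
noted as an assumption). Points with σ = 0 receive the profile's median σ
with a warning (unit weights if all are zero).

The p_B–Δω correlation trough makes single-start fits unreliable, so the
fit multi-starts over k_ex ∈ {100, 400, 1600} s⁻¹ × p_B ∈ {0.005, 0.03,
0.10}, with |Δω| seeded per residue from the largest apparent exchange
contribution via the fast-exchange relation
Rex ≈ p_A p_B Δω² k_ex/(k_ex² + ω_eff²) and the sign seeded from the
off-resonance asymmetry (the exchange peak sits at offsets opposite in
sign to Δω), both signs tried. With on-resonance data only the sign of Δω
is unidentifiable; results carry an explicit `sign_indeterminate` flag.

Parameter errors: Monte-Carlo resampling of the R₁ρ points
(Gaussian at each point's σ, 50 iterations, seeded), refitting from the
best-fit solution; resampling happens at the R₁ρ level rather than the
underlying intensities (a choice; intensity-level resampling is available
by rerunning the decay stage). At least 80% of refits must converge.

### Dispersion screen

Per residue, the no-exchange model R₁cos²θ + R₂sin²θ (linear in the two
rates; solved by non-negative least squares) is compared with the
5-parameter two-state fit by an F-test with (3, n−5) degrees of freedom at
α = 0.05. Noiseless flat profiles return p = 1 by convention. Calibration
measured over 100 seeded replicates of the standard 42-condition design
with σ = 0.3 s⁻¹ point noise: type-I error ≈ 5% (≤10% asserted), power
against study-scale exchange (p_B ≈ 3%, Δω ≈ 4 ppm) ≥95%.

## Thermodynamics

ΔG = −RT ln(p/(1−p)) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 283.15 K
by default. Two conventions are exposed wherever rounding paths diverge
and are never silently reconciled: the equilibrium constant between two
minor states is p_a/p_b in "ratio" mode (default; gives 8 for 8%/1%) and
the exact odds ratio in "exact" mode (gives 8.61); free-energy ladders can
be built from raw populations (8%/1% → −1.21 kcal/mol) or from
one-decimal rounded ΔG values (1.4 − 2.5 → −1.1 kcal/mol). `ThermoState`
keeps population and ΔG exactly consistent by construction.

## Synthetic data

### Dispersion datasets

The standard condition design mirrors the study's acquisition: 12
log-spaced on-resonance powers 100–2000 Hz; off-resonance series at 3
log-spaced powers 100–300 Hz with 10 offsets each at ±(0.7–3.5)× power;
6 evenly spaced delays from 0 to 60 ms (three-way-junction construct) or
150 ms (isolated hairpin). Counts are configurable; these are the
defaults. Scenario truths carry the published globally fitted exchange
parameters and per-residue Δω values; R₁ = 2 s⁻¹ and R₂ = 16 s⁻¹ are
nominal imino ¹⁵N values at 10 °C (they are free fit parameters
downstream, so their exact values do not bias exchange-parameter
recovery). Default relative intensity noise is 2% (the study does not
report its noise level; 2% is typical of well-resolved 1D peak
intensities), applied as Gaussian noise proportional to the ideal
intensity, with the true per-point sigmas recorded in the tables.

Three generation modes: `fast` (analytic monoexponential at the
closed-form rate — truth lives in the model class being fitted, so
recovery tests probe the fitting machinery alone), `numeric`
(monoexponential at the Bloch–McConnell eigenvalue rate) and `full`
(projection of the simulated Bloch–McConnell trace). Recovery tests and
the acceptance script use `fast`; the oracle suite quantifies the
closed-form/numeric gap explicitly at the R₁ρ level (above), so the model
error is characterised rather than folded invisibly into recovery
statistics. Everything is byte-reproducible under a fixed seed.

### SHAPE datasets

The generator emulates a probed construct with a 5′ hairpin (4 bp stem +
6 nt loop used as the internal control), a 5 nt single-stranded buffer,
a user-specified core (paired/unpaired per condition) and a 10 nt 3′
single-stranded normalization reference. Reactivities are log-normal with
paired median 0.2 and unpaired median 1.0; the control loop is scaled by
0.96 (the published internal-control level). Noise has two components:
a per-replicate lane scale (log-sd 0.19), emulating loading/injection
differences between capillary runs, and per-position measurement noise
(log-sd 0.06); combined per-measurement spread ≈20%. The lane scale —
the dominant term — is exactly what normalization to the 3′ reference
removes, which is why the normalized internal-control ratio is much
tighter (sd ≈ 2–3%) than the raw noise, matching the published 0.96±0.05
behaviour. A single i.i.d. 20% per-position noise would be unrealistic
for capillary electrophoresis and would make the internal control far
noisier than reported.

### What passing tests do and do not show

The generators produce monoexponential decays with Gaussian noise and
independent log-normal reactivities. Real data additionally contain peak
overlap, baseline distortions, B₁ inhomogeneity, temperature drift,
off-resonance alignment imperfections, RT-stop artifacts beyond the
annotated ones, and correlated lane distortions. Passing recovery tests
therefore demonstrates that the estimation machinery is unbiased and
correctly calibrated under the stated noise model at the study's design
and parameter regime — not that those instrumental effects are handled.
Within scope, the two-state model itself is exact for the simulated data.

## Problem sizes

Recovery acceptance uses 20 seeded replicates per scenario of the full
pipeline (5 residues × 42 conditions × 6 delays, 50 MC iterations at both
stages); screen calibration uses 100 replicates per hypothesis; the
oracle grid has ~1.8k conditions. The full suite runs in ~4 minutes on
one CPU, the acceptance script in seconds.

## Known limitations

- Two-state exchange only; no three-site models, no temperature-dependent
  (van 't Hoff) analysis.
- No B₁-inhomogeneity averaging or relaxation during alignment elements.
- The chemical-shift context ellipses shipped with the package are an
  illustrative synthetic table with literature-scale values, not a curated
  database extraction; substitute your own reference table for real
  assignments (`chemshift.read_ellipse_table`).
- ¹⁵N-only transition-consistency scoring (dispersion-fitted Δω is ¹⁵N).
- SHAPE analysis starts at per-position reactivities; capillary-trace
  alignment and band quantification are upstream.
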