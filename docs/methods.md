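# Methods notes

This note records the models implemented in `lipidbank`, the conventions and
numerical choices behind them, what the synthetic fixtures do and do not
emulate, and the design decisions taken where more than one reasonable
reading existed.

## Metadata layer

A simulation entry is a `README.yaml` document with required keys `DOI`,
`TRJ`, `TPR`, `SOFTWARE`, `TEMPERATURE`, `COMPOSITION` (per molecule:
force-field residue name, mapping-table id, count) and `TIMELEFTOUT` (the
user-declared equilibration period in ns, discarded before every analysis).
Unknown keys are preserved verbatim rather than rejected: databank schemas
evolve and older readers must not break. Entry identifiers are the SHA-256
digest of the topology digest concatenated with the trajectory digest, in
that fixed order — deterministic, order-sensitive and collision-resistant.

Experiment matching follows fixed windows: every membrane molecule's molar
percentage within ±3 percentage units, temperature within ±2 K, identical
counterions whenever charged lipids are present, and hydration compared
exactly only when either side is below 25 waters per lipid (above that both
systems count as fully hydrated). Molar percentages are computed over
membrane molecules only (lipids, sterols, surfactants); water and ions are
handled by the hydration and counterion rules. Widening any window can only
add matches (monotonicity), which the tests assert.

Ranking sorts descending for order-parameter qualities (1 is perfect) and
ascending for the form-factor quality FF_q (0 is perfect); entries with
τ_rel > 1.3 are discarded before sorting and ties break lexicographically by
entry id so rankings are reproducible.

## Observables

**Order parameters.** S_CH = ⟨3cos²θ − 1⟩/2 with θ against the z axis.
The ensemble average is taken per lipid first (over frames), and the
reported mean, variance and SEM are computed over the per-lipid means — the
error bar thus reflects the assumption that individual lipids are the
independent samples of a fluid bilayer. With equal frame counts per lipid
the mean equals the pooled average over all (lipid, frame) samples, which is
tested. Explicit hydrogens are required; united-atom topologies without
reconstructed hydrogens are rejected with a clear error rather than silently
mishandled.

**Electron density and form factor.** Each frame is centred on the lipid
centre of mass (electron counts serve as weights when masses are absent), a
z histogram with 1/3 Å bins weighted by per-atom electron counts is averaged
over frames, and the solvent-subtracted contrast uses the solvent profile
completed to its bulk plateau — estimated from the outer 20% of the box —
inside the membrane core, so Δρ_e → 0 in bulk by construction. F(q) is
evaluated by the midpoint rule on the histogram grid over q ∈ [0, 1] Å⁻¹
with 0.005 Å⁻¹ spacing, integrating real and imaginary parts (no membrane
symmetry assumed). Midpoint quadrature on the 1/3 Å grid keeps the relative
RMS deviation from the analytic slab form factor below 0.5% over the full q
range. Because the contrast vanishes in bulk solvent, the minima locations
are independent of the box size, which the padding-invariance test checks.

**Area per lipid** is 2·⟨Lx·Ly⟩/N with N the total membrane molecule count,
i.e. the lateral area per molecule in one leaflet. Read literally as box
area over total molecule count the number would be half of the 42–74 Å²
scale on which fluid-bilayer areas are universally quoted, so the
per-leaflet convention is used and stated here explicitly.

**Thickness** is the distance between the two z where lipid and water
electron densities cross, linearly interpolated between bins; with noisy
profiles showing several sign changes per side, the outermost crossing on
each side is used. Exact grid-point touches count as crossings; all-zero
plateaus do not.

## Equilibration (PCA)

Lipid configurations of one type are centred and superposed onto their
average structure in two passes (superpose onto the raw-centred mean,
recompute the mean, superpose again) with Kabsch rotations; collinear mean
structures are rejected as degenerate. PCA pools all lipids of a type into
one covariance — the lipids sample the same conformational ensemble — and
the alternative (averaging per-lipid covariances) was considered and not
taken. The PC1 autocorrelation is computed per lipid, averaged, and its
decay time is the 1/e crossing with linear interpolation between lags; an
ACF that never falls below 1/e returns the series length with a
non-converged flag. The convergence time is 49 × the decay time; the
calibration constant 49 is fixed, not re-fitted, since its published
derivation is force-field independent and re-deriving it would require
reference trajectory archives. τ_rel divides by the analyzed simulation
length and is invariant under uniform time rescaling. Rigid molecules
(sterols, via a configurable blacklist) are excluded upstream.

## Quality evaluation

**Per bond.** P is the probability mass of the dof-1 Student's t (Cauchy)
distribution inside [S_exp − ΔS, S_exp + ΔS] around the simulated mean, with
scale √s/√n. The degrees of freedom are configurable; dof = 1 is the default
because normal or high-dof tails underflow double precision for badly-off
force fields, making scores incomparable exactly where comparison matters.
The CDF difference is taken in the order that yields a positive probability
(by symmetry of the t distribution the magnitude is unaffected). Bonds whose
simulation SEM exceeds the experimental error are excluded: artificially
slow dynamics would otherwise widen the distribution and reward the
simulation for being poorly converged. ΔS_exp defaults to 0.02 and no
attempt is made to estimate experimental errors beyond that.

**Fragments and systems.** P_frag is the mean of available bond
probabilities times the availability fraction F_frag, whose denominator is
*all* bonds of the fragment — experimentally uncovered and excluded bonds
both count against it. "total" covers every bond of the molecule, including
the glycerol backbone. System-level scores weight the per-lipid fragment
scores by molar fraction, renormalised over the lipids actually scored;
"tails" is the average of the acyl-chain scores of each lipid.

**Form factors.** Experimental intensities are placed on the simulation
scale with k_e, the weighted-least-squares proportionality coefficient with
experimental errors as weights. Both |F| curves are resampled onto a uniform
0.001 Å⁻¹ grid and smoothed with a Savitzky–Golay filter of window 31 points
and polynomial order 1. The window is expressed on the 0.001 Å⁻¹ grid
because the published even window of 30 points is invalid for the filter
(hence 31), and because a 31-point window applied directly to the package's
native 0.005 Å⁻¹ simulation grid would span an entire form-factor lobe and
erase the very minima being located. The first local minimum at
q > 0.1 Å⁻¹ is found as the first strict sign change of the smoothed finite
difference (ties broken toward smaller q) and refined with a three-point
parabolic fit; for the V-shaped zeros of oscillatory form factors the
moving-average smoothing is locally quadratic around the vertex, so the
parabolic refinement recovers sub-grid accuracy. FF_q = |q_min^sim −
q_min^exp| × 100 is invariant under positive rescaling of either curve.

## Transport

Leaflets are assigned from headgroup z relative to the per-frame midplane
(the lipid COM z); inside the 1 nm midplane buffer zone the previously
confirmed label is retained. A flip-flop is a change of the *confirmed*
leaflet, where confirmation requires 100 consecutive frames of residence
outside the zone on the new side. A plain endpoint check ("in the opposite
leaflet 100 frames after zone entry") was considered and rejected: it counts
the return leg of a sub-cutoff excursion as an event, violating both the
intended semantics and time-reversal symmetry of the count. Rates are
normalised per molecule and per time, events/(N·t), so single-molecule and
ensemble rates are commensurate; the zero-event upper limit is 1/(N·t) by
the same logic.

Permeation counting classifies each frame as lower bulk, slab, or upper bulk
(bulk = beyond the density-crossing thickness bounds) and counts transitions
between opposite bulk visits; rebounds do not count and the count is
invariant under time reversal and z-mirror. Permeability is P = r/(2 c_w)
with c_w = 33.3679 nm⁻³ and r in events per ns per nm², reported in μm/s.

Lateral diffusion fits the MSD slope over lags between 10% and 50% of the
trajectory (60 lag samples), D = slope/4; fits with R² < 0.9 or with
half-window slopes differing by more than 50% (a parabola fits a straight
line deceptively well over a short window) are flagged. Perpendicular
diffusion uses the Tanner harmonic combination with z_w = box height minus
bilayer thickness; the output never exceeds either limiting channel.
Arrhenius energies are the least-squares slope of ln P vs 1/T expressed in
units of k_B·T_ref with T_ref = 310 K, with the slope's standard error
propagated. Binned summaries weight by simulation length and report a
weighted SEM using the effective sample size (Σw)²/Σw²; bins below a minimum
total weight (e.g. 1 μs of data for permeation) are dropped.

## Regression

Features are molar fractions over eight classes — POPC, POPE, POPG, POPS,
CHOL explicitly; sphingomyelins, cardiolipins and PI lipids grouped by
headgroup regardless of acyl chains — normalised over lipids only; water,
ions, temperature and salt are deliberately not features. Training splits
80/20 by the given seed, selects hyperparameters by 5-fold cross-validated
grid search on the training split, records test-split RMSE/R², and by
default refits the selected estimator on the full dataset (`fit_on="train"`
keeps the training-split fit). Linear and ridge are first-class; tree,
forest, kNN, boosting, lasso and elastic-net plug in through the same
interface. Because fractions sum to one, individual linear coefficients are
collinear with the intercept and not identifiable; predictions and
coefficient *contrasts* are, and those are what the tests pin down exactly
on noiseless data. For cardiolipin-containing systems an auxiliary
per-two-chain area is reported by rescaling the molecular area with
2/⟨chains per molecule⟩ (cardiolipin has four acyl chains).

## Synthetic fixtures

Every generator draws from a stream derived from (seed, generator name), so
outputs are bit-reproducible and adding a fixture never shifts another's
stream. Ground truths are analytic: oriented C–H bonds at
θ = arccos√((2S+1)/3) give exactly the target S for every azimuth; the slab
profile has the closed-form factor 2Δρ sin(qd/2)/q; scripted z series
realise exact event counts under the detection rules; the OU series uses the
exact AR(1) discretisation so its ACF is exp(−lag/τ) at every lag; Brownian
walkers have per-axis step variance 2DΔt; regression tables follow a stated
affine law. The toy bilayer used by the mini-databank places oriented bond
pairs, a surface phosphorus, and scattered chain pseudo-atoms (electron
counts chosen to give ≈ 0.3 e/Å³ in the slab) with pseudo-water at bulk
electron density outside — its area per lipid, thickness and order
parameters are known by construction.

These fixtures are oracles for the computations, not physical membranes:
they have no realistic chain packing, no capillary undulations, no
electron-density fine structure, no genuinely slow collective modes, and
their noise models are Gaussian. Passing tests therefore demonstrate that
the calculators implement their definitions correctly and recover known
parameters at the stated tolerances — not that any particular force field
is accurate.

## Problem sizes and determinism

Default desk-scale sizes: oriented-bond ensembles of 50 lipids × 100 frames;
mini-databank entries of 36 lipids × 60 frames with ≈ 1900 pseudo-waters;
OU series of 10⁵ steps; 100–400 Brownian walkers × 10⁴ steps; regression
tables of 60–200 rows. At these sizes parameter recovery lands within a few
percent (τ and D within ~5–10% depending on seed), and the full test suite
and the acceptance script each run in well under a minute. All randomness
flows from explicit seeds; reported values are computed at run time, never
stored.

## Known limitations

- No hydrogen reconstruction for united-atom force fields; such inputs are
  rejected.
- Permeability is event-counting only; no solubility-diffusion estimate.
- The calibration k = 49 is adopted, not re-derived.
- Quality evaluation assumes a single fixed experimental error for order
  parameters.
- The mini-databank's form-factor agreement with its synthetic experiment is
  approximate (the toy bilayer is not a perfect slab), so end-to-end FF_q
  values are checked for validity, not for a specific magnitude.
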