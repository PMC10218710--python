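# Methods

## Scope

`sternmag` models a two-arm, double-blind Sternberg working-memory
experiment under weak audio-frequency magnetic exposure, end to end: trial
scheduling, synthetic reaction-time (RT) generation, the dissociation
regression with its derived exposure effects and group-homogeneity tests,
and magnetostatic dosimetry of the solenoid stimulators. It does not model
biophysical interaction mechanisms beyond the eddy-current power estimate,
induced electric-field spatial structure, audio signal synthesis, or any
interactive stimulus presentation.

## Trial scheduling

A session holds four test blocks, one per set size SZ = 1..4, of 12 trials
each (48 total): per block a memory set of SZ distinct letters is drawn from
the 9-letter target pool, probes are 6 targets (from the memory set) and 6
foils (from the disjoint 12-letter foil pool), and the target-flag sequence
is rejection-sampled (cap 10,000 attempts, deterministic given the seed)
until no more than three equal flags run consecutively. Design choices where
the protocol leaves room:

- The 24/24 target/foil split is enforced *within* each block (6/6). A
  balanced split per cell makes the target regressor orthogonal to the
  set-size and exposure regressors, which is what gives the clean
  decoupling properties tested in the suite.
- The run-length cap is enforced across block boundaries too (strictly
  stronger than per-block, still easily satisfiable).
- Block order is ascending SZ by default and configurable; one memory set
  is used per block (the most common Sternberg variant) with a flag to
  resample per trial.
- The letter pools are a seeded random partition of the fixed 21-consonant
  alphabet B C D F G H J K L M N P Q R S T V W X Y Z; the specific letters
  are irrelevant to the model, only the pool sizes and disjointness matter.
- Practice gating is a pure function: the count of practice attempts
  consumed before the first six *consecutive* error-free outcomes.

## RT generation

Trial RTs are drawn as

    RT* = β0 + β1·SZ + (β2 + β3·SZ)·EX + β4·TG + subject offset
          + drift·(trial index) + ε

with defaults β = (428.0, 19.4, −15.0, 6.3, −29.0) ms — the fitted
coefficients of the study design this emulates — and:

- `resid_sd` = 80 ms Gaussian trial noise. No empirical residual SD is
  available for this design; 80 ms is a typical trial-level dispersion for
  young-adult Sternberg RTs and is flagged as a stand-in in the config. An
  ex-Gaussian mode (centred exponential component, `exgauss_tau`) is
  available because empirical RT distributions are right-skewed; the
  default remains Gaussian.
- `subject_sd` = 0 by default: the analysis model is a pooled OLS
  regression with exchangeable residuals, and the default generator matches
  that model exactly so that nominal standard errors and confidence
  intervals are calibrated. Nonzero values are supported for robustness
  studies of clustering effects (nominal OLS inference is then
  anticonservative for between-subject terms — by design, that is what
  such a study would probe).
- Censoring: draws above the 1000 ms probe window become omissions with no
  recorded RT. With the default noise this makes omissions extremely rare;
  per-subject omission counts of ~1 seen in real cohorts are not separately
  modelled.
- Errors: Bernoulli with `p_error` = 0.15, independent of RT and of
  exposure (48 × 0.15 ≈ 7 errors per subject, matching the order observed
  in real cohorts). Because errors are RT-independent, excluding them does
  not bias the regression.
- `rt_floor` = 150 ms clamps non-physiological low draws; `practice_drift`
  defaults to 0 (a negative value emulates response acceleration from
  learning, which the linear model does not encode — robustness use only).

Subject profiles (age, body-mass index, 17 health ratings, 3 habit
variables) are Gaussian draws rounded to the reported precision, with both
groups sharing one distribution per variable, so homogeneity comparisons
behave as null tests.

What passing tests on these synthetics do **not** show: real RT data have
learning curvature across the session, right-skewed and heteroscedastic
noise, and subject-level clustering; the default generator has none of
these, so recovery and coverage results certify the estimation machinery,
not robustness to those features.

## Dissociation fitting

Both models are fit by OLS (via statsmodels) on correct-response rows; a
flag admits error-trial RTs, and omissions are always excluded. Standard
errors come from the unbiased residual variance and the inverse Gram
diagonal, p-values from the Student-t reference with n − k df. Degenerate
designs (single set size, single exposure level for the full model,
rank-deficiency, empty input) raise instead of returning nonsense. A
cell-mean mode fits per-cell means weighted by counts; under the balanced
design it reproduces the trial-level coefficients exactly.

Derived effects are pure arithmetic on the full-model coefficients:
ΔRT(SZ) = β2 + β3·SZ, scan ratio β3/β1 (error if β1 = 0), inflation
1 + β3/β1, and intercept change 100·|β2|/β0 percent.

Welch's unequal-variance t-test is computed from summary statistics with
the Welch–Satterthwaite df and a two-sided p; when both groups have zero
variance and equal means the comparison is reported degenerate with p = 1.
Two-sided p-values throughout, no multiple-testing correction (matching
the analysis style this emulates), and no pooled-variance mode.

## Dosimetry

- Constants and conventions: µ0 = 1.257e-6 H/m; millimetres in I/O, metres
  internally; z measured from the inner coil-edge plane into the head;
  right-handed frame.
- Drive: series RLC magnitude I = V/√(R² + (Lω − 1/Cω)²). The parasitic
  capacitance has no documented value and is absent by default (the term
  1/Cω → 0); at audio frequencies with a 4.7 mH coil the inductive branch
  dominates regardless. The drive voltage is likewise undocumented; the
  default is 0.5 V (typical line-level amplitude), so absolute field values
  are order-of-magnitude calibrated, not measured.
- Discretization: each solenoid is a helix sampled by midpoint-rule
  quadrature of the line integral — element midpoints lie exactly on the
  helix and Δl is the local tangent times the parameter step. This
  reproduces the loop-centre closed form exactly and agrees with the
  finite-solenoid on-axis closed form to well below 0.5% at 16
  segments/turn; accuracy improves monotonically as segments double.
- Geometry: two coaxial solenoids per side (four coils), inner edges at
  z = 0 and z = head width (140 mm default), wired in series with aiding
  polarity. The far side is constructed as the exact mirror image of the
  near side's segment set, which preserves the dipole sense and makes the
  |B| field mirror-symmetric about the mid-plane to machine precision.
  Whether the physical device used two or four coils is ambiguous; both are
  supported via `coils_per_side`.
- Evaluation: straight Biot–Savart superposition in free space (tissue
  µ ≈ µ0, no eddy back-reaction). Points within one wire radius
  (0.04 mm, AWG-40) of a current element are flagged invalid and returned
  as NaN. Chunked vectorized evaluation keeps temporaries near 100 MB; the
  default head grid (7 × 7 × 15 points at 10 mm spacing) evaluates in
  seconds on one core.
- Under the defaults the mid-head on-axis magnitude is ≈ 0.089 µT,
  within the 0.05–0.2 µT band expected for a ~0.1 µT stimulus; this is a
  soft check because the true drive voltage is unknown.
- Eddy power: P = π²B²d²f²/(6ρD) with slab thickness d = 0.01 m,
  resistivity ρ = 0.2 Ω·m (σ = 5 S/m would be cellular-scale; 0.5 S/m is
  the bulk value used), density D = 1000 kg/m³ → ≈ 8e-13 W/kg at 0.1 µT
  and 10 kHz.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence` spawns of a single
  seed; identical seed + config give byte-identical CSV/JSON outputs, and
  each run writes a manifest (seeds, config SHA-256, package versions)
  sufficient to re-run bit-identically.
- CSV outputs keep full float precision; rounding happens only in
  human-readable console summaries.
- Test problem sizes: the scheduler invariants are sampled over 1000
  seeded sessions; confidence-interval calibration uses 200 simulated
  cohorts of 65 × 48 trials; Monte-Carlo mean checks use 10–20k draws.
  These sizes put Monte-Carlo noise well below the tested tolerances while
  keeping the whole suite under a minute.

## Known limitations

- The linear model cannot reproduce learning curvature; per-cell means of
  real sessions will disagree with it even when the fit is correct.
- Omissions are produced only by censoring, so their default rate is ~0.
- Field maps assume ideal helix geometry and ignore lead wires, winding
  layers beyond the mean diameter, and tissue conductivity back-reaction.
- The eddy-power formula is a slab estimate, not a spatial solver; it is
  quadratic in everything and should be read as an order of magnitude.
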