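# Methods

This note records the models, conventions and numerical choices behind
melonopt, and what its validation does and does not establish.

## Trial data and phenology

A trial is a set of treatments, each a (plant spacing, pruning mode)
pair.  Spacing is constrained to 30–80 cm in 5 cm steps; pruning modes
are coded ordinally 1–4 (1V1F, 2V2F, 3V3F, 3V2F).  Stage durations use
the **inclusive endpoint convention**: `stage_duration(a, b) =
(b − a).days + 1`, so both endpoints count and a same-day stage lasts one
day.  This is the unique convention under which the bundled growth-period
table's two printed duration columns (fruit development and total growth
period, 20 integers) all follow from the printed stage dates; it implies
the additivity identity d(a,b) + d(b,c) = d(a,c) + 1.

Indicator cells of the form `2.79 ± 0.13a` are split into (mean, sd) and
trailing Duncan-type significance letters are stripped.  Dates parse from
ISO 8601 and the `YYYY/M/D` dialect and are written back as ISO 8601.
Of the ten treatment yields only two (T3 = 53.97, CK = 27.86 t·hm⁻²) are
bundled; the rest are explicit missing values and surrogate training
refuses to run until they are supplied (observed, supplementary, or
scenario-filled).

## Entropy-weight TOPSIS

For the a × b positive matrix X (a = 10 treatments, b = 9 indicators in
the bundled table):

* column Euclidean normalization Y_ij = X_ij / √(Σ_i X_ij²);
* proportions P_ij = Y_ij / Σ_i Y_ij (identical to X_ij / Σ_i X_ij);
* entropies H_j = −(1/ln a) Σ_i P_ij ln P_ij, weights
  ω_j = (1 − H_j)/(b − Σ_j H_j), which sum to 1 whenever some column is
  non-constant;
* weighted matrix, per-column max/min ideal vectors, Euclidean
  separations D_i±, and closeness C_i = D_i⁻/(D_i⁺ + D_i⁻).

**Weighting-stage convention.** Two positive rescalings of the columns
may feed the weighted matrix: the unit-norm matrix Y, or the column-mean
scaled matrix X_ij / mean_i(X_ij) = a·P_ij.  Entropy weights, the rank
order, and (to within 0.002 on the bundled table) the closeness values
are identical under both, because P is invariant to any per-column
positive rescaling.  The separations, however, differ by a uniform
factor ≈ √a·(mean/rms) per column; only the **mean-scaled** convention
reproduces the bundled reference ranking table digit-for-digit in all
three printed columns, so it is the default (`scaling="mean"`), with
`scaling="euclidean"` kept as an option.

All nine indicators are treated as benefit-type (ideals are plain column
maxima/minima); cost-type indicators are an extension point, not
supported in v1.  Rank ties are broken by input order and flagged — the
bundled table has none.  The `0·ln 0 := 0` guard in the entropy is
defensive only, unreachable for strictly positive input.  TOPSIS input is
the table of treatment means, matching the 10 × 9 evaluation dimensions;
replicate-level weighting was not attempted.

## Surrogate network

Topology 2→12→8→3: inputs are min-max encodings of spacing (over
[30, 80]) and the ordinal pruning code (over [1, 4]) to [−1, 1]; outputs
are (total growth period d, yield t·hm⁻², C_i), each min-max scaled to
[−1, 1] over the training targets and descaled exactly on prediction
(C_i additionally clamped to [0, 1] with a flag).  Hidden activations are
tanh, the output is linear — the conventional pairing for damped
second-order least-squares training.

Training is full-batch Levenberg–Marquardt: per epoch, the update solves
(JᵀJ + μI)δ = −Jᵀr with the residual Jacobian computed analytically by
backprop; μ starts at the configured rate (default 0.05), divides by 10
after an accepted step and multiplies by 10 after a rejected one, and
training stops at the MSE target (10⁻⁸), the epoch cap (2000), or when
damping exceeds 10¹⁰.  The 167 network parameters exceed the ≤ 132
residuals of a 44-point trial; the μI ridge keeps the normal equations
well-posed in this underdetermined regime.  Multiple seeded restarts
(default 10) are trained and the restart with the lowest validation
error kept.  Validation is a seeded 70/15/15 random split by default;
with n = 10 that degenerates to 8/1/1, so a leave-one-out mode
(`validation="loo"`) scores restarts by mean LOO prediction error and
refits the kept restart on all rows.  With a validation split, weights
at the epoch of minimum validation MSE are restored (early stopping,
patience 6).  Everything is a pure function of (dataset, config, seed).

## NSGA-II and selection

Genomes are (spacing index 0–10, pruning code 1–4) — feasible by
construction, so no constraint penalties exist.  Objectives are
(duration, −yield, −C_i), all minimized.  The algorithm is the standard
elitist scheme: fast non-dominated sorting, crowding distance (boundary
solutions infinite; zero-range objectives contribute nothing), binary
tournament on (rank, crowding), uniform per-gene crossover (p = 0.8 per
pair), per-gene random-reset mutation (p = 0.1), and (μ+λ) truncation at
population 100 for 100 generations.  Real-coded operators (SBX,
polynomial mutation) add nothing on an 11 × 4 grid, so uniform/reset
operators were chosen.  Duplicate genomes are allowed during evolution
— forbidding them on a 44-point space would change the algorithm — and
the reported front is genotypically deduplicated.  Because the grid is
exhaustive at desk scale, `brute_force_pareto` computes the exact
non-dominated set and certifies every evolved front in the tests.

Selection min-max normalizes each front objective to [0, 1] with 1 best
(duration inverted; zero-range objectives map to 1) before the weighted
sum, since equal weights on raw units would let yield (tens of t·hm⁻²)
swamp C_i (≤ 1); a raw-units mode remains behind a flag for sensitivity
analysis.  Ties are broken by shorter duration, then higher yield, then
higher C_i — the production-goal order (early maturity, high yield,
quality).  The selected solution is always a member of the front.

## Synthetic trials

Scenarios specify smooth response surfaces plus Gaussian replicate noise:

* duration: per-pruning base (defaults 101 / 108.5 / 118.3 / 118 d for
  1V1F / 2V2F / 3V3F / 3V2F, the observed means) plus an optional spacing
  slope (default 0 — spacing showed no duration effect);
* yield: strictly decreasing in spacing (default 0.35 t·hm⁻² per cm)
  from per-pruning bases at 55 cm (27.86 / 49.5 / 51.0 / 53.97 t·hm⁻²,
  anchored at the two observed yields), 3V2F highest;
* C_i: a logistic in spacing (steepness 0.08 cm⁻¹, per-pruning midpoints
  64 / 68 / 72 cm for 3V2F / 2V2F / 3V3F, 60 cm for 1V1F), which keeps
  targets strictly inside (0, 1) and rising with spacing, offsets ordered
  3V2F > 2V2F > 3V3F;
* the nine indicators: observed-scale bases with a gentle relative
  spacing slope and pruning offsets in the same order.

Replicate noise is independent Gaussian with sd = `noise_frac` × the
response's range over the design (default 3 %), averaged over
`replicates` draws (default 3); noise 0 returns the surface means
exactly.  The default design is the full factorial; the trial-like
scenario fixes the ten-treatment design (1V1F only at the 55 cm
control).  No treatment × replicate correlation, weather/soil process, or
growth-curve dynamics are emulated, so passing recovery tests show the
analysis chain is sound under its own assumptions — not that those
assumptions hold in any particular field.

`planted_optimum` applies the exhaustive-Pareto + weighted-sum rule to
the noiseless surfaces over the full 44-design grid.  End-to-end
recovery studies therefore use the full-grid scenario (44 treatments):
a surrogate trained only on 55–75 cm cannot be expected to rank
extrapolated designs at 30 or 80 cm, and the planted truth is defined
over the whole grid.

## Study sizes and tolerances

Library defaults are the full settings above.  Simulation studies in the
test suite use the package's desk-scale sizes: surrogate restarts 2,
epoch cap 150, GA generations 40 — at these sizes the trained network
already fits the smooth scenario surfaces to R > 0.99 and the evolved
front equals the exhaustive Pareto set.  The fifty-seed recovery study
runs at the generator defaults (3 % replicate noise) and requires ≥ 90 %
exact recovery of the planted optimum and all but at most one run within
one grid step.  Numerical tolerances: weights sum to 1 within 1e-12;
oracle equivalence of the TOPSIS pipeline to 1e-10; scaling round-trips
to 1e-12; reproduction of the bundled ranking table to its printed
precision (5e-4 on separations, 0.01 on closeness).

## Known limitations

* The surrogate extrapolates beyond the sampled spacing range whenever
  the trial design does not cover the grid; recommendations outside the
  sampled region inherit that uncertainty.
* Cost-type indicators, alternative MCDA schemes, continuous spacing and
  other multi-objective algorithms are out of scope.
* The decision stage's normalization is a modelling choice; with few or
  degenerate front solutions the equal-weight selection can be sensitive
  to front membership (the deterministic tie rule makes it reproducible,
  not robust).
* The two columns "soluble sugar content (mg/g)" and "soluble sugar (%)"
  in the bundled quality table are kept as two distinct indicators
  exactly as recorded, without renaming or merging.
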