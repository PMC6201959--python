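# Methods

This note documents the models and numerical procedures implemented in
`segmorph`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Problem setting

The package analyzes 2D outlines of repeated, bilaterally symmetric modules
(the motivating system is the calcified segments of a siphonous green
macroalga, sampled as locality → plant → segment → digitization replicate).
Each outline is captured by one fixed basal landmark plus equidistant
semilandmarks; in the default 90-point scheme, landmark 1 (basal node) and
landmark 46 lie on the symmetry axis and landmarks *i* and *92 − i* are
mirror pairs. Because the modules have no front/back differentiation, left
and right cannot be registered across plants (*side ambiguity*): directional
and fluctuating asymmetry are therefore only ever defined within a plant.

## Superimposition

Partial generalized Procrustes analysis: every configuration is centered,
scaled to unit centroid size, and rotated (proper rotations only) to the
iteratively re-estimated consensus. Convergence is declared when the
consensus moves less than 1e-7 between iterations (max 100; non-convergence
returns the best iterate with a warning and a flag). The consensus
orientation is fixed by rotating the symmetry axis (landmarks 1→46) to the
vertical with landmark 1 down, which makes PC signs and DA directions
reproducible run-to-run. Distances are tangent-space Procrustes distances:
aligned shapes are orthogonally projected onto the tangent plane at the
consensus pole and compared there. Reported "mean PD" is the mean distance
to the consensus (not mean pairwise distance).

## Semilandmark treatments

Three treatments are implemented and can be compared on the same data:

* **unslid** — semilandmarks treated as fixed points (their position is
  whatever the equidistant resampling produced);
* **min_pd** — each semilandmark slides independently along its tangent to
  the orthogonal projection of the corresponding consensus point. Points can
  slide past their neighbors on variable data; this known pathology is
  *detected* (a sign change in the along-curve direction of an edge) and
  counted in the diagnostics, never silently repaired;
* **min_be** — the sliding displacements of all semilandmarks of one
  configuration jointly minimize the thin-plate-spline bending energy of the
  deformation from the current consensus, a (k−1)-dimensional linear
  least-squares problem per configuration.

Tangents are symmetric neighbor chords p[i+1] − p[i−1], wrapping around the
closed outline through the fixed landmark; the fixed landmark itself never
slides. Sliding runs for 3 slide/re-superimpose cycles by default, with the
consensus (and bending-energy kernel) refreshed each cycle; a flag freezes
the initial consensus instead. The TPS kernel is U(r) = r² log r; bending
energies are internally consistent and only compared, never interpreted in
absolute units, so the constant-factor alternative r² log r² would change
nothing downstream.

Within every minBE slide step the total bending energy cannot increase
(t = 0 is feasible in the quadratic minimization); within every minPD step
no point moves farther from its consensus target (projection). Both
invariants are asserted in tests against brute-force grid searches.

## Symmetry decomposition

Object symmetry is analyzed by pairing each configuration with its
reflected, relabeled copy (x negated, mirror pairs swapped; on-axis points
keep their labels) and superimposing originals and copies jointly under the
chosen treatment. A covariance PCA of the superimposed coordinates then
splits into *symmetric* axes (original and copy score identically) and
*asymmetric* axes (scores sign-opposite). Classification uses the cosine
between original and copy score vectors with threshold ±0.99; values in
between can only arise from numerically tied eigenvalues and raise a
warning. Per object, the symmetric component is the mean of the aligned
original and its copy and the asymmetric component half their difference;
the two reconstruct the aligned original exactly.

**Total shape asymmetry** per object is, by default, the Euclidean norm of
the object's scores over all asymmetric axes; an alternative statistic (sum
of per-axis absolute scores) is available behind a flag and in the
diagnostics output. The verbal definition this statistic operationalizes is
ambiguous between the two; the Euclidean norm is the default because it
equals the asymmetric-component norm exactly when all asymmetric axes are
retained (asserted in tests), making the univariate and multivariate
analyses commensurable. Both statistics are invariant to the
original/reflected choice and zero for an exactly symmetric object.

## Allometry

Multivariate linear regression of all shape coordinates on centroid size
(raw size by default; log-size behind a flag — the regression this package
mirrors uses raw size). Reported: percentage of total shape variation
explained (100·SS_fit/SS_total), Wilks' λ computed on the scores of all PCs
with nonzero variance (Procrustes coordinates are rank-deficient, so the
determinant is otherwise undefined; with a single predictor
λ = 1 − h'T⁻¹h with T the diagonal total SSCP of the scores), and a
permutation p-value from shuffling size labels,
p = (#{λ_perm ≤ λ_obs} + 1)/(n_perm + 1). Size adjustment ("accounting for
allometry") replaces the data by mean shape + residuals of this regression.

## Nested ANOVA

Records enter the multivariate model four times per segment (2 sides × 2
replicates). Type I (sequential) sums of squares in the fixed order
[centroid size,] locality, plant(locality), segment(plant), side(plant),
segment×side(plant), measurement error. Because the design is balanced in
side and replicate, each categorical SS equals the hierarchical group-mean
decomposition, which is computed directly and asserted (to 1e-8) to add to
the total on every run; an independent design-matrix least-squares oracle
verifies the same numbers in the tests. Multivariate SS are summed
univariate SS across coordinates — identical to the squared tangent
Procrustes distance formulation.

F-ratios follow the nesting: locality/plant, plant/segment, segment/FA,
side/FA, FA/error. Degenerate F (zero denominator MS) is reported as absent
with a flag, never as infinity.

The size covariate, when included, is removed first by regression (the
residuals then enter the categorical decomposition) and consumes one degree
of freedom from the error row. Its F is taken over the pooled MS of all
non-error factor rows, i.e. (SS_total − SS_size − SS_error)/(df of those
rows). Because original and mirrored copies of a record share the same
centroid size exactly, the side and segment×side rows are invariant to size
adjustment by construction; this is asserted to 1e-8 relative.

### Restricted permutations

Each effect is tested by shuffling labels only at its own design level
(999 permutations default; p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1), so the
minimum attainable p at 999 permutations is 0.001):

* **locality** — whole plants are permuted across localities (locality +
  plant SS is invariant, so only the locality SS is recomputed);
* **plant** — whole segments are permuted across plants within locality;
* **side (DA)** — the original/reflected labels of each segment are flipped
  independently (equivalently, the sign of its asymmetric component);
* **segment** — within each plant, each side's cell means are shuffled
  independently across segments. This destroys true segment differences
  while preserving the plant, side, and error structure, so permuted
  segment variation arises from asymmetry alone — matching the
  segment-over-FA F-ratio. (A side-label flip, the scheme used for DA,
  leaves segment means untouched and would reduce the segment test to a
  copy of the side test.)
* **FA** — the four records of each segment are shuffled across its
  side × replicate cells, testing FA against digitization error. (Swapping
  replicate labels *within* a cell is a no-op with two replicates, so the
  exchange happens across the cells of one segment.)

Under a generator whose only source of variation is digitization noise, all
five p-values are uniform (Kolmogorov–Smirnov over 200 simulated datasets,
family-wise α = 0.01); this calibration is part of the test suite and the
acceptance script.

The univariate total-asymmetry model uses the same machinery without the
side factors: order [size,] locality, plant, segment, error; F-ratios
locality/plant, plant/segment, segment/error; segment p by shuffling records
across segments within plants.

### Per-plant decomposition and population comparison

Each plant with ≥ 3 segments is decomposed separately into segment
(symmetric variation), side (DA), segment×side (FA) and error; MS and R²
are reported without p-values (the per-plant tables are descriptive).
Localities are compared by bootstrapping the difference in medians of each
component (resampling plants with replacement within locality, 999
resamples): 95% percentile CI, two-sided p = 2·min(tail fractions) floored
at 1/n_boot; "significant" means 0 outside the CI. Pearson correlations
among the per-plant MS of the three components quantify whether plants
variable in one component are variable in the others.

## Synthetic data generator

The generator draws hierarchical populations matching the nested design.
Defaults emulate the study conditions: 2 localities × 48 plants, 982
segments with a median of 9.5 per plant, locality A median size 18% below
locality B, 90-point outlines, two digitization replicates.

* **Base outline**: a mirror-symmetric bean, r(φ) = r₀(1 + Σ aₘ cos mφ)
  with a₁ = −0.10, a₂ = 0.15, a₃ = 0.04, sampled arc-length equidistantly
  from the basal pole and re-symmetrized exactly under the scheme pairing.
* **Sizes** (dimensionless units, locality medians 0.82/1.0): lognormal
  plant effect (log-sd 0.15) times lognormal segment effect (log-sd 0.10).
* **Allometry**: a fixed symmetric radial field scaled by
  slope × (log size − mean log size), slope 0.35. This makes the locality
  size difference induce a purely allometric shape difference, which the
  size-adjusted ANOVA should (and does) remove.
* **Plant-level symmetric effect**: radial cosine fields, coefficient sd
  0.02; **segment-level symmetric noise**: same basis, sd 0.035.
* **DA**: one fixed antisymmetric field per plant (radial sine basis,
  unit-normalized coefficients) scaled by 0.005.
* **FA**: i.i.d. antisymmetric fields per segment, sd 0.015 in *absolute*
  coordinate units (i.e., divided by segment size before scaling);
  **digitization error**: i.i.d. Gaussian coordinate noise, sd 0.004
  absolute, per replicate.

The DA and FA magnitudes were set by moment-matching the variance structure
reported for the real system — a within-plant symmetric-to-FA mean-square
ratio near 5, a DA-over-FA F-ratio near 1.3, and FA an order of magnitude
above digitization error — so the preset exercises the analyses in the same
regime of subtle, statistically resolvable asymmetry.

Asymmetric perturbations use radial sine fields, which apply +δ to a left
point and the mirrored −δ to its pair, so injected DA/FA lie exactly in the
asymmetric subspace and variance bookkeeping is exact. FA and digitization
noise are absolute rather than proportional to size: after Procrustes
rescaling, smaller segments carry relatively more asymmetry, reproducing the
negative size–asymmetry correlation characteristic of real outline data
(the defaults give Pearson r ≈ −0.35 between centroid size and total
asymmetry). All randomness flows from one seed through per-level child
streams, so changing segment counts does not perturb plant-level draws;
identical seeds give bit-identical datasets.

The preset's per-plant segment counts are a fixed vector (48×9, 14×10,
32×12, 2×13; total 982, median 9.5) dealt alternately to the two
localities, so the nested model's degrees of freedom reproduce the study
design exactly: (1, 94, 886, 96, 886, 1964) multivariate and
(1, 94, 886, 982) univariate.

**What the generator does not emulate**: digitization direction errors
(replicates are generated in the convention order; the reversal correction
is exercised by dedicated tests instead), outline self-intersection,
within-plant positional gradients along the branch, non-Gaussian effect
distributions, and pixel quantization. Passing tests therefore demonstrate
the statistical machinery under the model's assumptions, not the biological
conclusions themselves.

## Numerical choices and degenerate inputs

* GPA tolerance 1e-7 on consensus displacement, max 100 iterations — far
  below the 3-decimal reporting precision of the downstream statistics.
* PCA/rank decisions use a relative singular-value threshold of 1e-9.
* Coincident outline points: resampling drops exact duplicates; a
  zero-length tangent (coincident sliding neighbors) is an error naming the
  landmark.
* Degenerate configurations (all points identical) and constant covariates
  raise immediately.
* Constant responses give all-zero SS and flagged (absent) F ratios.
* Bootstrap p-values are floored at 1/n_boot; permutation p-values cannot
  be zero by the +1/(n+1) convention.

## Problem sizes used in the shipped runs

The acceptance script runs the full study-sized design (982 segments, 3928
combined records of 90 points) for the superimposition, PCA, allometry and
nested-ANOVA stages with 999 permutations and 999 bootstrap resamples, and
desk-scale designs (≤ 500 segments, 16–24 points) for the oracle,
parameter-recovery, and 200-simulation calibration stages. The test suite
uses the same desk-scale designs throughout.

## Known limitations

* 2D outlines only; no 3D or surface semilandmarks, no missing landmarks.
* One fixed anchor landmark per outline (multiple anchors would change the
  sliding topology).
* Type I SS only; the within-plant design is balanced by construction, and
  unbalanced side/replicate structures are rejected rather than
  approximated.
* The minPD treatment is retained for diagnostics and comparison; its
  output is excluded from downstream symmetry/ANOVA stages by default
  because independent per-point sliding distorts variable outlines (points
  sliding past neighbors), and a flag is required to force inclusion.
* Wilks' λ uses the reduced-rank PC basis; with a single predictor the
  permutation test is equivalent to permuting against the multivariate R²,
  not an independent check of it.
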