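# Methods

This note documents the models, conventions, numerical choices and known
limitations of `gravqtl`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Response model and traits

A gravitropism time course (tip angle vs. minutes after a 90° rotation,
initial angle subtracted) is summarized by two three-parameter sigmoids in
the growth-curve parameterization where λ is the intercept of the
maximal-slope tangent with the time axis:

* logistic: `y(t) = A / (1 + exp(4µ(λ−t)/A + 2))` — maximum slope µ at
  `y = A/2`;
* Gompertz: `y(t) = A·exp(−exp(µe(λ−t)/A + 1))` — maximum slope µ at
  `y = A/e`.

Units: *A* deg, *µ* deg/min, *λ* min.  Both models are fit by nonlinear
least squares (`scipy.optimize.least_squares`, `ftol = xtol = 1e−12`, up to
5 log-normal-jittered restarts on failure) from the data-driven start
`A₀ = max y`, `µ₀ = max central-difference slope`,
`λ₀ = max(t_slope − y(t_slope)/µ₀, 0)`, with bounds `A, µ > 0`.  The model
with lower AIC is selected; with equal parameter counts this reduces to
lower RSS, and exact ties go to the logistic.  Whether the source analysis
fixed one model per dataset or chose per line is not documented anywhere we
could rely on; per-line AIC selection is this package's choice.

Three further traits come from the data, not the sigmoid: *P*, the maximum
of a cubic smoothing spline whose penalty is chosen by generalized
cross-validation (`scipy.interpolate.make_smoothing_spline`), evaluated on
a 0.1-min grid; the overshoot *P − A*, deliberately left unclipped so that
responses without an overshoot scatter around zero (a clip-at-zero option
is trivial for callers); and *I*, the composite-trapezoid integral of the
selected sigmoid on a 0.1-min grid over the observation window (0–180 min
for the maize-style grid, 0–480 min for the Arabidopsis-style grid).

## Genotype model and QTL machinery

Genotypes are two homozygous states (AA/BB), appropriate for an intermated
RIL panel whose map is already expansion-adjusted; the Haldane map function
`r(d) = (1 − e^(−2d/100))/2` is applied directly to map distances, with no
interference and no residual heterozygosity.

* **Genotype probabilities**: a hand-written 2-state forward–backward pass
  on a grid of markers plus pseudomarkers every `step_cM` (default 1 cM),
  vectorized over individuals.  Emissions are `1 − ε` / `ε` (default
  ε = 0.002); missing calls and pseudomarkers are uninformative.  A
  brute-force path-enumeration oracle checks it in the tests.  An optional
  forward-filter backward-sampling imputation (`sim_geno`, default 256
  draws) is provided; the scans below use expected dosages, which are
  deterministic and therefore preferred for reproducible analysis.
* **Scan**: Haley–Knott regression of the phenotype on the expected dosage
  `P(BB) − P(AA) ∈ [−1, 1]`, `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`.  The reported
  additive effect is the OLS coefficient on that dosage, i.e. half the
  AA↔BB difference.  RSS is floored at `RSS₀·1e−15` so numerically perfect
  fits cannot manufacture LOD for further terms.
* **Thresholds**: genome-wide maxima over `n_perm` phenotype permutations;
  the threshold is the type-7 (linear-interpolation) `1 − α` quantile,
  α = 0.05 per trait.  No correction is applied across the 60 time-point
  traits — each time point is mapped independently by design.
* **Stepwise selection**: forward addition of the position maximizing the
  joint additive-model LOD with coordinate-wise refinement of all selected
  positions after each addition (up to `max_qtl = 6`), then backward
  elimination; among all visited models the one maximizing
  `pLOD = LOD − k·penalty` wins, the empty model (pLOD = 0) included.  The
  penalty defaults to the trait's permutation threshold.  Ties in the
  forward argmax break to the lowest (chromosome, position).
* **Support intervals**: 1.5-LOD drop on the per-QTL profile scan (other
  model terms as covariates), expanded by one evaluated grid position on
  each side; flat profiles return the whole chromosome.
* **tQTL tracks**: per-time-point stepwise models; a track is a maximal run
  of consecutive time points with a significant QTL on the same chromosome
  whose peak moves ≤ 10 cM between frames; duration = run length × frame
  interval (3 min default).  A track matches a pQTL when they share a
  chromosome and come within 10 cM.  Both distances are configuration
  knobs because no published co-location rule exists to adopt; 10 cM is of
  the order of a support-interval half-width on these maps.
* The time grid is 61 points (0–180 min every 3 min); t = 0 is identically
  zero after initial-angle subtraction and is excluded, leaving 60 mapped
  time points.  The grid is fully configurable (e.g. 2-min × 8-h).

## Image phenotyping

The pipeline is classical and deterministic: Otsu threshold → largest
connected component (≥ `min_area_px`) → `skimage.morphology.skeletonize`.
The seed is assumed at the top of the frame (kernels suspended tip-down;
configurable by rotating input frames), so the tip is the skeleton endpoint
geodesically farthest from the topmost endpoint.

The angle rule is built for sub-pixel accuracy, because a line fit through
the last ~5 integer skeleton pixels quantizes to roughly ±8°: the local
tube half-width *w* is read from the distance transform just behind the
tip; the apex is the centroid of mask pixels within `w + 2` px of the tip
pixel; and the direction is the vector from the centroid of a 2-px-thick
cross-section band centered `tail_mm·px_per_mm + w` px behind the apex
(default tail 0.5 mm at 10 px/mm) to the apex.  Angles are signed, in
(−180°, 180°] with image *y* down, so straight-down growth reads +90° and a
horizontal root 0°; a fold-to-[0°, 90°] option is left to callers since the
measurement itself is signed.  Isolated single-frame measurement failures
are linearly interpolated; runs of ≥ 2 failed frames stay missing.

Group comparisons follow the mutant-assay conventions: per-time-point
one-way ANOVA with Tukey HSD pairwise decisions (`scipy.stats.tukey_hsd`)
compressed to compact letter displays by insert-and-absorb, at α = 0.1, or
an equal-variance two-sample *t* test for two groups.  Time points are
tested independently, with no correction across times.  All-zero
within-group variance is resolved exactly (p = 1 on tied means, else 0).

## Orthology

QTL intervals live in cM; annotations in bp.  Marker anchors (chrom, cM,
bp) bridge them by linear interpolation, clamping out-of-span endpoints to
the terminal anchors with a flag.  Genes overlap an interval if they share
≥ 1 bp, strand-agnostic.  One representative protein per gene is used — the
longest annotated isoform when isoforms are present.

Alignment is Smith–Waterman local alignment with affine gaps under
BLOSUM62, gap open 11 / extend 1 in the BLAST convention (a gap of length
L costs 11 + L), executed by `Bio.Align.PairwiseAligner`; the tests verify
it against a hand-written affine-gap dynamic program on short sequences.
Percent identity counts identities over all alignment columns including
gap columns.  A best hit needs a raw score ≥ 50 (configurable to 0); ties
break by higher percent identity, then lexicographic subject id.  No
E-value model is used.  A BBH pair requires each gene to be the other's
best hit against the *full* opposite proteome, with both genes inside
their species' intervals — candidate sets first, reciprocal search against
full proteomes second.  An adapter for external tabular (outfmt-6-style)
search results is provided for genome-scale runs.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study: a 10-chromosome
two-state RIL panel (Markov genotypes under Haldane recombination),
trajectories from the logistic/Gompertz family whose parameters carry
additive QTL effects (±½ genotype coding, so a planted "effect" is the
between-homozygote difference) plus between-line parameter noise and
independent Gaussian observation noise per time point (default 3° — a
plausible figure for automated tip tracking, chosen once; no published
noise model exists to copy), an optional overshoot injected as a Gaussian
bump centered at `λ + A/µ` with width `A/(2µ)` (a free modeling choice of
this generator), proteome pairs mutated from common ancestors with
paralog decoys and engineered reciprocity failures, and root image stacks
drawn as a thick tube growing 16 px per frame whose terminal tangent
equals the prescribed per-frame angle exactly.

It does *not* emulate: correlated (autoregressive) measurement error,
segregation distortion or residual heterozygosity, epistasis, root
morphology (branching, hair, kernel shape), image artifacts (condensation,
occlusion, uneven backlight), or realistic protein domain structure.
Passing tests therefore demonstrate correctness of the machinery under the
stated generative model, not robustness to every failure mode of real
assays.

## Default study conditions

| quantity | default | unit |
|---|---|---|
| RIL panel size | 250 | individuals |
| genome | 10 × 100 | cM |
| marker spacing | 5 | cM |
| time grid | 0–180 every 3 | min |
| baseline (A, µ, λ) | 60, 0.7, 20 | deg, deg/min, min |
| between-line SD (A, µ, λ, overshoot) | 4, 0.08, 3, 1.5 | param units |
| observation noise | 3 | deg |
| genoprob step / error | 1 / 0.002 | cM / – |
| permutations | 200 (tests: up to 1000) | – |
| genome-wide α | 0.05 | – |
| stepwise max QTL | 6 | – |
| link / match distance | 10 | cM |
| LOD drop | 1.5 | – |
| alignment | BLOSUM62, 11/1, min score 50 | – |

Simulation sizes in the test suite and acceptance script (e.g. 20
replicates for recovery rates, 1,000 permutations × 1,000 fresh nulls for
calibration, 200 genes per synthetic proteome) are the package's chosen
desk-scale study conditions; the published analyses this design mirrors
used larger runs (tens of thousands of permutations, full genomes), which
the same code accepts unchanged.

## Known limitations

* Stepwise search is additive-only; epistatic penalties and interaction
  scans are out of scope, as are covariates and multi-parent designs.
* Haley–Knott regression slightly misstates support in regions of high
  missingness compared with full-likelihood interval mapping; it is used
  for determinism and speed.
* The permutation threshold treats lines as exchangeable — family
  structure within the panel is not modeled.
* The in-package aligner is quadratic per pair; genome-scale reciprocal
  searches should use an external engine and the tabular-import adapter.
* The tip detector assumes one root per frame (the largest object); plates
  with touching seedlings need upstream cropping.
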