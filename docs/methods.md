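# Methods

`morphancestry` implements a dense quasi-landmark analysis of regional
facial ancestry: it aligns registered 3D facial landmark configurations,
removes covariate effects by partial least squares regression (PLSR),
quantifies how much facial variation genetic ancestry principal components
(PCs) explain, and contrasts that genetic description of ancestry with a
phenotypic one built from regional consensus faces. Because the cohorts
this design targets are consent-restricted, the package ships a synthetic
cohort generator with known ground truth; every claim the tests make is a
claim about recovery of that ground truth or about the algebra of the
operations themselves.

## Data model

An individual is a configuration of L corresponding surface quasi-landmarks
(x, y, z per landmark), as produced by non-rigid template registration.
Cohorts are `n x L x 3` arrays with aligned id lists across shapes,
covariates, genetic PC scores and admixture proportions. The template
carries the triangulation and a bilateral landmark pairing (an involution;
midline points are self-paired).

## Regional selection

Individuals are labelled by the argmax of their admixture row (ties break
to the lowest column index, for determinism). Each regional group is then
thresholded at the median of its members' maximum proportions — inclusive,
with the midpoint convention for even counts — and a fixed number per
region (default 186) is drawn uniformly without replacement from the
survivors, by seeded shuffle of the *sorted* ids so the draw is independent
of input row order. A region with at most the target count keeps everyone.
A median threshold can never discard more than half a group, which the
tests assert.

## Alignment

Faces are symmetrized by averaging each configuration with its relabelled
mirror image (X negated, landmarks re-indexed by the bilateral pairing).
The average is taken directly in the shared registration frame, with no
extra rigid alignment of the reflection: registered scans already share the
template frame, and direct averaging makes the output an exact fixed point
of the reflection operator.

Generalized Procrustes analysis (GPA) then removes translation, rotation
and scale: configurations are centred, scaled to unit centroid size, and
iteratively rotated onto the running mean using the SVD orthogonal
Procrustes solution with a determinant correction so reflections are never
introduced. Iteration stops when the RMS change of the mean drops below
1e-8 (default; `max_iter` 100). Centroid size is recorded *before* scaling
so it can serve as the size covariate while the analysis itself is in shape
space. The output frame is anchored to the initial orientation of the
configuration with the lexicographically smallest id: this keeps results
reproducible run-to-run *and* invariant to the order in which individuals
are supplied (a positional anchor would not be).

Degenerate (rank < 3) configurations are rejected by id. Planar inputs are
therefore out of scope; the synthetic template is a curved height field, so
this never binds in practice.

## Covariate and ancestry correction

Shapes (flattened to `n x 3L`) are regressed on sex, age, age², height,
weight, centroid size and camera system with PLS2. Predictors are
standardized (they mix years, cm, kg and ±1 codes); responses are centred
only (landmark coordinates share units). The number of components defaults
to the number of predictors, at which full-rank PLSR coincides with
multivariate ordinary least squares — the tests exploit this as an
independent oracle (normal equations). Corrected faces are the residuals
plus the mean shape, so the grand mean is preserved exactly and corrected
coordinates are exactly decorrelated from every predictor in-sample.

Ancestry correction repeats this with the first k = 4 genetic PCs on the
covariate-corrected shapes. The per-individual difference before minus
after is the *genetic facial ancestry effect*; regional means of it are the
regional effect faces. The effect of a single PC is the leave-one-out
contrast (correcting with all k versus all but that PC), signed so that the
per-individual effects of in-sample-orthogonal PCs sum to the total effect.
Note the cohort mean of a single-PC effect vanishes identically for centred
predictors; the informative summaries are regional means. Exaggeration
(4x regional, 8x single-PC) is applied only when exporting visualization
faces, never inside statistics.

## Permutation testing

Shape variation is reduced by PCA of the corrected coordinates, retaining
the smallest set of components reaching 96% cumulative variance; scores are
normalized to unit variance with the eigenvalues kept for back-weighting.
The statistic is the total R² of a full-component PLSR (= OLS) of retained
scores on the predictor set. Two weightings are exposed: eigenvalue
weighting (the headline "% of facial variation explained") and unit
weighting (components equal, matching the normalized scores). The null is
built by permuting the predictor-to-individual assignment B times (default
10,000) with the add-one p estimator, so p ≥ 1/(B+1). Exchangeability makes
row permutation equivalent to residual permutation for this global test; a
Freedman–Lane-style residual scheme is available behind `scheme="residual"`
and agrees in distribution. An exact-enumeration mode (n ≤ 8) backs the
calibration tests. Subgroup tables recompute the shape PCA *within* each
group (ALL, six pairwise, four single regions), and "PCs in combination"
use a joint fit, not a sum of marginals. Raw p-values are reported without
multiplicity correction, matching the protocol this implements.

## Consensus faces

Consensus faces are per-region arithmetic means of the covariate-corrected
cohort after a fresh GPA over the *full* cohort (not per region, and not a
separate alignment of the four means): subtraction of a consensus from an
individual requires a single shared frame. Consensus correction is
`face - consensus(region) + grand mean`; by construction it removes
between-region mean differences exactly, which the tests verify to
relative SS < 1e-12. The admixture-weighted variant subtracts the Q-weighted
mixture of consensus faces instead, is linear in Q, and reduces bitwise to
the plain correction for indicator rows. Stores serialize to JSON (one
consensus face per region plus a manifest); a consensus face describes no
individual and can be shared. Groups below 30 members trigger a robustness
warning.

## Effect maps

Vertex normals are area-weighted averages of incident triangle normals on
the base (pre-effect) face, with outward orientation fixed by the template
winding. Normal displacement is the signed dot product of the landmark
displacement with the unit normal (positive = outward); angle difference is
the angle in degrees between two displacement fields, defined as 0 where
either vector is shorter than eps (default 1e-9 length units, recorded in
output metadata). Maximum ancestry shift takes, per landmark, the largest
pre- vs post-correction distance over individuals. The method-comparison
maps express both the consensus face and the genetic-PC regional face
relative to the shared base face and report displacement and angle between
them.

## Synthetic cohort generator

The generator emulates the statistical structure of a four-region European
cohort:

* **Template** — an `nx x ny` grid (7160 landmarks by default, 40 x 179)
  carrying a smooth dome height field, bilaterally symmetric about x = 0,
  with consistent counter-clockwise winding (+z outward). The default
  extent is 100 template units, a face-sized box if read as millimetres.
* **Region effects** — one smooth random field per region (sums of six
  Gaussian bumps, width a quarter of the template extent), bilaterally
  symmetrized, projected onto the complement of the similarity group's
  tangent space (no net translation, rotation or scaling — regional effects
  are *shape* effects, otherwise GPA would absorb part of the ground truth
  and recovery would be ill-defined), normalized to RMS 2.0 units, and
  centred across regions so the grand mean is the template.
* **Covariate effects** — per-covariate smooth fields scaled to RMS 0.5
  (sex), 0.3 (camera) and 0.02 per unit (age, height, weight); covariate
  values are sex/camera ∈ {−1, 1}, age ~ U(18, 65), height ~ N(170, 10) cm,
  weight ~ N(75, 15) kg.
* **Individual variation** — 10 smooth modes of RMS 1.0 with standard
  normal scores (within-region variation ≈ 3.2 units RMS, comfortably
  above the between-region signal per coordinate, as in real faces), plus
  isotropic landmark noise of SD 0.5 applied *un*-symmetrized, which gives
  each face mild bilateral asymmetry.
* **Genetic PCs** — 20 scores per individual: a per-region mean plus unit
  Gaussian noise. Default loadings give PC1 = (−1.5, 3.0, 0.0, −1.5) over
  (North, South, East, West) — a South vs North/West axis; PC2 =
  (0, 0, 3.0, −3.0) — an East–West gradient; PC3 = (1.5, 0, 0, −1.5) — a
  weaker North–West contrast; PCs 4..20 carry no regional structure. The
  separation-to-noise ratio (~3 units between extreme regions vs unit
  within-region SD) mirrors the clearly separated regional clusters such
  cohorts show.
* **Admixture** — Dirichlet rows with concentration 10 on the true region
  and 1 elsewhere, so the argmax recovers the true region for ≥ 95% of
  individuals.

One `SeedSequence` drives a stream for the shared fields and one substream
per individual, so generation is bit-reproducible and subsetting a cohort
never reshuffles anyone else's noise. The within-region/between-region
variance ratio is deliberately a free parameter (`mode_sd`,
`region_effect_scale`) rather than a fixed constant.

What the generator does *not* emulate: real facial geometry or its spatial
covariance structure, genotypes (PC scores are drawn directly),
relatedness, non-linear covariate effects, and registration error beyond
isotropic noise. Passing tests therefore demonstrate that the pipeline's
algebra and inference are correct and that known effects of realistic
relative magnitude are recovered — not that any particular real-data result
would replicate.

## Problem sizes and numerical choices

The analysis scripts and the acceptance script run scaled-down study
conditions chosen as a single-CPU desk protocol: 500 landmarks instead of
7160, 1,000 permutations instead of 10,000 for the full tables (199–719 in
the replicated Monte-Carlo checks), and 50 individuals per region in the
replicate studies (186 in the single-run analysis scripts). Landmark count
enters the statistics only through the shape-PCA reduction, and permutation
resolution only through 1/(B+1), so these scalings change precision, not
structure.

Tolerances: GPA convergence 1e-8; symmetrization and consensus algebra are
exact to floating point (asserted at 1e-12); PLSR/OLS agreement at 1e-6;
angle maps treat sub-eps displacement vectors (1e-9) as direction-free.
Ties in the regional argmax break to the lowest column index; the
even-count median is the midpoint of the central pair.

## Known limitations

* PLSR component counts other than "number of predictors" are supported but
  unvalidated against an oracle; cross-validated selection is out of scope.
* Row permutation assumes exchangeability of individuals; family or batch
  structure would require restricted permutation schemes that are not
  implemented.
* The consensus route assumes every individual belongs to (or mixes over)
  the stored regions; no mechanism discovers new subpopulations.
* Surface registration, genotype PCA and admixture estimation are consumed,
  not performed; errors in those upstream steps propagate unexamined.
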