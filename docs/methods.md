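# Methods

`canalmorph` analyses the shape of the three semicircular canals (SCCs) of
the bony labyrinth — anterior (ASC), posterior (PSC) and horizontal (HSC) —
represented as 3D centerline curves, the form in which micro-CT
segmentations of the inner ear are usually reduced for comparative work.
The package covers the full chain from curves to statistics: landmarking,
Procrustes superimposition, ordination and classification, allometric
decomposition, and a landmark-free curve dissimilarity with a planar
embedding.  A synthetic cohort generator with a complete truth table makes
every stage testable without access to fossil material.

## Landmarking model

Each specimen enters as three labeled polylines plus digitised markers: the
ampulla centre of each canal and the bifurcation point of the common crus
(the limb shared by the ASC and PSC).  Five fixed landmarks anchor every
configuration:

* **Ld1, Ld2** — the crossings of the HSC centerline with the total-least-squares
  best-fit plane of the ASC, taken nearest (by arc length) to the lateral
  (ampullar) and medial ends of the HSC respectively.  Crossings are located
  by linear interpolation within the crossing segment.  When a noisy plane
  fit produces more than two crossings, the end-nearest ones are kept.
* **Ld3, Ld5** — the PSC and ASC ampulla centres (taken as supplied; they are
  digitised points, not re-estimated).
* **Ld4** — the common-crus bifurcation point.

A cochlear-apex marker (Ld6) can be stored but never enters SCC shape
configurations: the configuration sizes are 5 + 3k points for k
semilandmarks per canal, giving 8 / 26 / 59 / 149 points for the preset
densities k = 1 / 7 / 18 / 48.

Semilandmarks are placed at equal arc-length spacing L/(k+1) strictly
between the endpoints of each canal, ordered from the ampullar end.  They
are **not** slid to minimise bending energy; equal-arc placement is
deterministic, cheap, and sufficient for curves without sharp features.
Left-side specimens are reflected across x = 0 onto the right-side
convention before any statistics; mirroring is an exact involution and an
isometry, so no size or shape information is lost.

Orientation conventions are intrinsic, never frame-dependent: the HSC-plane
normal is oriented toward the common crus (which lies superior to the HSC),
which fixes "below/above" for the posterior-canal index PSCI1 = (PSC arc
length below the HSC plane) / (arc length above) regardless of how the
specimen sits in space.  PSCI1 is reported as below/above, with "below"
the side away from the crus.

### The 35-variable profile

`compute_profile` returns one area (the oval window area, OWA, measured
externally and passed through), six arc lengths, six linear distances, 12
dimensionless indices (including PSCI1) and 10 angles.  Only OWA and PSCI1
follow published definitions; the remaining variables are documented
stand-ins registered in `VARIABLE_REGISTRY` (category, units, definition,
provenance), chosen so that lengths scale linearly under similarity
transforms while indices and angles are similarity- and mirror-invariant.
The registry is versioned with the package so definitions can be audited or
swapped against an external variable list without touching calling code.
Missing canals produce an incomplete profile with the affected variables
named, not an exception.

## Procrustes machinery

Generalized Procrustes analysis centres each configuration, scales it to
unit centroid size (CS = root summed squared distances from the centroid)
and iteratively rotates all specimens to the running consensus using proper
rotations only (determinant +1); reflections are excluded because chirality
is handled explicitly by the mirroring step.  The consensus starts from the
first specimen and iterates to convergence (default tolerance 1e-10 on the
consensus change, max 1000 iterations), which makes results deterministic;
at convergence the alignment is independent of input order up to one global
rotation, so ordination scores are reproducible up to per-axis sign.

* **PCA** of the vectorised aligned coordinates, with a deterministic sign
  convention (largest-magnitude loading positive).
* **Between-group PCA**: PCA of the group mean shapes with all specimens
  projected.  With g groups only g−1 axes can carry variance; surplus axes
  are reported with exactly zero variance and their scores should be
  ignored (the null-space direction is arbitrary).
* **Permutation test**: the statistic is the between-group share of total
  inertia of the aligned shapes; the null permutes group labels over
  specimens; p = (1 + #{perm ≥ obs}) / (1 + n_perm).  999 permutations by
  default, 10 000 supported by configuration; all seeds are logged.
* **CVA** on retained principal components (default: the smallest set
  explaining ≥ 90% of variance, capped at n − g − 1 so the pooled
  within-group scatter stays invertible).  Canonical axes solve the
  generalised eigenproblem of between- versus pooled-within scatter and are
  scaled to unit within-group variance, so Euclidean distance in canonical
  space is Mahalanobis distance.  Classification assigns each specimen to
  the nearest group mean under leave-one-out refitting.  The chance-level
  assessment permutes labels and leaves each specimen out of its own
  (permuted) group mean; without that correction the self-contribution
  biases the chance rate above 100/g %.
* **Projection of indeterminate specimens** superimposes a held-out
  configuration onto the frozen consensus by ordinary Procrustes (no GPA
  re-run) and projects it onto the stored axes; nearest-group reports break
  ties toward the lexicographically smallest label.

## Allometric decomposition (CAC/RSC)

Shapes and log centroid sizes are centred by group means; the common
allometric component is the normalised pooled within-group regression of
shape on log CS, a = Xwᵀ sw / (swᵀ sw).  Scores (for both CAC and the
residual shape components) are computed from grand-mean-centred shapes, so
group structure remains visible in score plots while the axis itself is
estimated strictly within groups; adding a constant to all log sizes
changes nothing.  RSC axes are the principal components of the within-group
variation orthogonal to the CAC, which makes the pooled within-group
correlation of every RSC score vector with log CS zero by construction.
The decomposition is orthogonal and complete: ‖Xw‖² splits exactly into the
CAC component plus the residual.

One attenuation effect is worth knowing: if the allometric shape change
itself inflates centroid size (as a posterior-canal expansion does), then
regressing on sizes re-measured from the same configurations underestimates
the planted rate; parameter-recovery checks therefore regress on the
generator's true log sizes from the truth table.

Scalar size statistics: Wilcoxon rank-sum contrasts use exact enumeration
for min(n) ≤ 25 without ties, an exact/seeded permutation method with ties,
and the normal approximation with continuity correction otherwise; no
multiple-testing correction is applied and the output table says so.  The
standard-deviation separation statistic is (min(B) − mean(A)) / SD(A) with
the n−1 standard deviation.  The all-one-sex probability p_femaleⁿ is the
extreme binomial tail used in sex-ratio arguments for small samples
(0.5⁴ = 0.0625 for four specimens under a balanced ratio).

## Currents dissimilarity and non-metric MDS

As a landmark-free complement, curves are compared with the metric of
currents: each polyline becomes segment midpoints cᵢ and length-weighted
tangents τᵢ, and ⟨A,B⟩ = Σᵢⱼ exp(−‖cᵢ−cⱼ‖²/σ²) (τᵢ·τⱼ); the distance is
the norm of the difference, √(⟨A,A⟩+⟨B,B⟩−2⟨A,B⟩).  This compares
non-homologous curves without point correspondence.  Diffeomorphic
registration is deliberately out of scope: the module either computes the
currents distance directly, or imports externally computed per-pair control
point displacement fields and applies the average-L2-norm rule, so published
deformation-based matrices can be consumed without re-estimating them.

Before the currents computation every specimen is mirrored to the
right-side convention, moved to an intrinsic canonical pose (centroid at
the origin, superior HSC normal → +z, ASC-normal component → +y signed
toward the HSC ampulla) and scaled to unit centroid size; distances are
therefore invariant to position, orientation, chirality and size.  Curves
are oriented ampulla → common crus, fixing tangent signs.  The kernel width
σ defaults to 10% of the mean normalised canal arc length — wide enough for
refinement invariance of the discretisation, narrow enough to resolve
canal-scale differences — and is configurable and logged.

Non-metric MDS minimises stress by SMACOF with monotone regression, run
from a deterministic classical-scaling start plus n_init seeded random
starts (and any caller-supplied start); the reported figure of merit is
Kruskal stress-1 with ties handled by the primary approach.  The best
candidate over all starts (including the raw starts themselves) is kept and
centred.  Supplying the zero-padded lower-dimensional solution as a start
guarantees stress is non-increasing in embedding dimension.

## Synthetic cohorts

The generator composes, in order: a circular-arc template (radii ~2.8–3.2 mm
and spans 230–300°, the scale and geometry of a hominin labyrinth, with the
ASC and PSC sharing the common-crus point exactly); a per-group mean-shape
offset (random homotheties anchored at the common crus for ASC/PSC, plus a
shifted homothety for the HSC, scaled to a requested RMS displacement); an
allometric radial expansion of the PSC about the common crus, proportional
to the specimen's centred log size — so larger specimens carry a
proportionally more developed posterior canal; a global scaling to the
specimen's true centroid size; iid Gaussian digitisation noise per point;
and a uniform random rotation, a translation, and a reflection for
left-side specimens.  Group mean log sizes are offsets from the template's
log centroid size.  The crus marker of a noisy specimen is the midpoint of
the two noisy crus-end digitisations, as a human digitiser would place it.

OWA is drawn lognormally per group, independent of canal centroid size;
sex is balanced with no size effect by default (a `sex_size_effect` knob
exists, default 0).  Everything — offset fields, sizes, rotations, the
allometric field — is recorded in a JSON-serialisable truth table, and the
whole cohort is a pure function of the specification including its seed.

The default demonstration cohort has nine groups of four specimens with
group mean log sizes spanning ±0.15, shape offsets of 0.3 mm RMS,
allometric slope 0.5, noise 0.15 mm (~5% of a canal radius) and 30%
left-sided specimens.  Offset magnitudes have no published physical value;
these were fixed once for a regime where group structure is clear but not
trivial (between-group inertia near 50%, permutation p ≈ 0.001).

What the generator does **not** emulate: real canal cross-sections and
torsion (arcs are planar circles), digitisation error correlated along the
centerline, taphonomic damage, or missing canals.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery on
curves of realistic scale and structure — not that any particular fossil
signal exists.

## Numerical choices

* GPA: tol 1e-10 on consensus change, max 1000 iterations, warning on
  non-convergence with the final change reported.
* Plane fits reject collinear inputs at a relative singular-value threshold
  of 1e-12; crossing and side-splitting computations interpolate linearly
  within segments.
* bgPCA variances at or below 1e-24 of the leading one (relative) are
  snapped to exactly zero.
* CVA refuses a pooled within-scatter with condition number above 1e12 and
  asks for fewer retained PCs.
* Multiple plane–polyline crossings: the crossing nearest the designated
  end (by arc length) wins.
* Permutation p-values use the add-one rule exactly; permutation is over
  specimens.
* All randomness flows from configuration seeds (simulation, permutation,
  MDS starts, CVA label permutation each have their own).

## Problem sizes used in the bundled checks

Calibration checks run 200 null cohorts of five groups × 10 specimens at
k = 1 with 199 permutations; the spurious-separation guard runs 100
one-population cohorts of 40 specimens relabeled into five arbitrary
groups; allometric recovery uses 20 cohorts of 2 × 50 specimens at k = 7.
These sizes give stable Monte-Carlo estimates while keeping a full run in
the low tens of seconds.

## Known limitations

* The 30 stand-in profile variables are faithful in spirit (category,
  units, invariances) but are not reconciled against any external variable
  catalogue.
* The currents distance is a data-attachment metric, not a deformation
  distance; imported displacement fields exist precisely so externally
  computed deformation results can be embedded without re-estimation.
* Classification rates on small groups (n ≤ 4) are coarse-grained by
  construction; the leave-one-out scheme is honest but high-variance there.
* Semilandmark sliding, Procrustes ANOVA and phylogenetically corrected
  allometry are out of scope.
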