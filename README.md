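# canalmorph

Geometric morphometrics of semicircular-canal centerlines.

The bony labyrinth of the inner ear — and in particular the three
semicircular canals (anterior, posterior, horizontal: ASC, PSC, HSC) — is a
favourite structure for comparing fossil hominin populations, because it
preserves well and its shape carries both taxonomic and size-related
(allometric) signal.  Comparative studies reduce micro-CT segmentations to
canal centerline curves, digitise landmarks on them, and ask whether
a-priori groups of specimens (sites, stratigraphic units, species)
separate in shape space, how much of that separation is allometry, and how
robust it is to analytic choices such as semilandmark density.

`canalmorph` is a tested, reusable implementation of that analysis chain
for researchers in vertebrate palaeontology and evolutionary morphology:

* **geometry** — best-fit canal planes; the five fixed landmarks (two
  ASC-plane/HSC crossings, two ampullae, the common-crus bifurcation);
  equal-arc semilandmarks (5 + 3k points for k per canal: 8/26/59/149 for
  k = 1/7/18/48); mirroring of left sides; the posterior-canal index PSCI1;
  a 35-variable morphometric profile.
* **procrustes** — generalized Procrustes analysis with scaling (proper
  rotations only), PCA and between-group PCA, a permutation test on the
  between-group share of total shape inertia, CVA with Mahalanobis
  distances and leave-one-out classification, projection of indeterminate
  specimens into frozen ordination spaces.
* **allometry** — the common allometric component / residual shape
  component (CAC/RSC) decomposition: the CAC is the pooled within-group
  direction of shape–log-size covariation,
  `a = Xwᵀ sw / (swᵀ sw)` after group-mean centring, and the RSCs are the
  orthogonal within-group principal components; plus Wilcoxon size
  contrasts, SD-separation statistics and the all-one-sex binomial
  probability.
* **dissimilarity** — a currents-metric curve distance
  (`√(⟨A,A⟩+⟨B,B⟩−2⟨A,B⟩)` with a Gaussian kernel on oriented segments),
  imported displacement-field distances (average L2 norm), and non-metric
  MDS with Kruskal stress-1.
* **synthetic** — labyrinth cohorts with known group structure, a planted
  posterior-canal allometric trend, digitisation noise, random rigid
  motions and left/right sides, all recorded in a truth table.
* **pipeline / CLI** — a seeded, configuration-driven end-to-end run
  (`canalmorph all -c config.json`) writing provenance-stamped tables.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
import canalmorph as cm

# a nine-group synthetic cohort (4 specimens each, 30% left-sided)
spec = cm.default_nine_group_spec(seed=1, n_per_group=4)
records, truth = cm.simulate_cohort(spec)

# landmark (k = 7 semilandmarks per canal -> 26 points) and superimpose
configs = [cm.build_configuration(r.centerlines, k=7) for r in records]
sample = cm.ShapeSample.from_configurations(configs, [r.group for r in records])
res = cm.gpa(sample)

perm = cm.permutation_inertia_test(res, n_perm=999, seed=2)
print(f"between-group inertia: {100*perm.observed:.1f}% (p = {perm.p_value:.3f})")

dec = cm.cac_rsc_from_gpa(res)
print(f"CAC vs log centroid size: r^2 = {dec.r2:.3f} (p = {dec.p_value:.2g})")

D = cm.pairwise_matrix([r.centerlines for r in records])
emb = cm.nmds(D, dim=2, seed=3)
print(f"non-metric MDS stress-1: {emb.stress:.3f}")

prof = cm.compute_profile(records[0].centerlines, owa=records[0].owa_mm2)
print(f"PSCI1 of {records[0].specimen_id}: {prof.values['PSCI1']:.2f}")
print(f"all-female probability, n=4: {cm.sexratio_probability(4, 0.5)}")
```

prints

```
between-group inertia: 49.7% (p = 0.001)
CAC vs log centroid size: r^2 = 0.592 (p = 4.1e-08)
non-metric MDS stress-1: 0.074
PSCI1 of G1_000: 3.99
all-female probability, n=4: 0.0625
```

Reading the numbers: about half the total shape variation lies between the
nine groups, and no label permutation out of 999 reached the observed
separation (p = 0.001, the add-one minimum).  CAC scores correlate with log
centroid size (r² = 0.59) because the generator plants a posterior-canal
expansion in larger specimens — evolutionary allometry.  The stress of
0.074 says the planar MDS of the currents distances is a fair but not
perfect summary.  PSCI1 ≈ 4 means that specimen's posterior canal has about
four times as much arc below the horizontal-canal plane as above it, and
0.5⁴ = 0.0625 is the chance that four specimens are all female under a
balanced sex ratio.

The same run from the shell:

```sh
canalmorph all -o out_dir        # simulate -> landmark -> gpa -> ordinate
                                 # -> classify -> allometry -> mds -> report
cat out_dir/report.md
```

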