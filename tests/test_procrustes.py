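"""GPA, ordination, permutation tests, CVA and projections."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

import canalmorph as cm
from canalmorph.procrustes import ShapeStatsError, retain_pcs
from conftest import (
    cohort_sample,
    make_cohort_spec,
    random_configuration,
    random_rotation,
)


def oracle_opa_distance(a, b):
    """Independent ordinary-Procrustes distance via scipy's solver.

    Centres and unit-scales both configurations, finds the best orthogonal
    map with ``scipy.linalg.orthogonal_procrustes`` and, if it is a
    reflection, re-solves under the proper-rotation constraint by flipping
    the smallest singular direction.
    """
    ua = a - a.mean(axis=0)
    ua /= np.linalg.norm(ua)
    ub = b - b.mean(axis=0)
    ub /= np.linalg.norm(ub)
    R, _ = scipy.linalg.orthogonal_procrustes(ua, ub)
    if np.linalg.det(R) < 0:
        U, s, Vt = np.linalg.svd(ua.T @ ub)
        D = np.diag([1.0, 1.0, -1.0])
        R = (U @ D @ Vt)
    return float(np.linalg.norm(ua @ R - ub))


class TestCentroidSize:
    def test_unit_square_is_sqrt_two(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert cm.centroid_size(square) == pytest.approx(np.sqrt(2.0))

    def test_homogeneity_and_rotation_invariance(self):
        rng = np.random.default_rng(0)
        cfg = random_configuration(rng)
        cs = cm.centroid_size(cfg)
        assert cm.centroid_size(3.0 * cfg) == pytest.approx(3.0 * cs)
        assert cm.centroid_size(cfg @ random_rotation(rng).T) == pytest.approx(cs)

    def test_degenerate_rejected(self):
        with pytest.raises(ShapeStatsError):
            cm.centroid_size(np.ones((4, 3)))


class TestGPA:
    def test_same_shape_zero_distance(self):
        rng = np.random.default_rng(1)
        cfg = random_configuration(rng)
        moved = 2.5 * cfg @ random_rotation(rng).T + rng.normal(size=3)
        assert cm.procrustes_distance(cfg, moved) < 1e-9

    def test_copies_align_identically(self):
        rng = np.random.default_rng(2)
        base = random_configuration(rng)
        configs = [base @ random_rotation(rng).T * s + rng.normal(size=3)
                   for s in (1.0, 2.0, 0.5)]
        configs.append(random_configuration(rng))
        sample = cm.ShapeSample(coords=np.stack(configs),
                                ids=tuple("abcd"), groups=("g",) * 4)
        res = cm.gpa(sample)
        for i in (1, 2):
            assert np.abs(res.aligned[i] - res.aligned[0]).max() < 1e-8

    def test_aligned_invariants(self, two_group_gpa):
        res = two_group_gpa
        for cfg in res.aligned:
            assert np.linalg.norm(cfg.mean(axis=0)) < 1e-9
            assert abs(np.linalg.norm(cfg) - 1.0) < 1e-9
        assert res.converged

    def test_pairwise_distances_match_opa_oracle(self):
        rng = np.random.default_rng(3)
        configs = [random_configuration(rng, p=26) for _ in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                mine = cm.procrustes_distance(configs[i], configs[j])
                assert mine == pytest.approx(
                    oracle_opa_distance(configs[i], configs[j]), abs=1e-6)

    def test_reflection_not_allowed(self):
        rng = np.random.default_rng(4)
        cfg = random_configuration(rng)
        mirrored = cfg * np.array([-1.0, 1.0, 1.0])
        # a chiral configuration cannot be superimposed on its mirror image
        assert cm.procrustes_distance(cfg, mirrored) > 0.1


class TestPCA:
    def test_line_in_shape_space_gives_single_axis(self):
        rng = np.random.default_rng(5)
        base = random_configuration(rng)
        direction = rng.standard_normal(base.shape)
        direction -= direction.mean(axis=0)
        coords = np.stack([base + t * 1e-3 * direction
                           for t in np.linspace(-1, 1, 8)])
        sample = cm.ShapeSample(coords=coords, ids=tuple(f"s{i}" for i in range(8)),
                                groups=("g",) * 8)
        res = cm.pca(cm.gpa(sample))
        assert res.variance_explained[0] > 0.999

    def test_variance_fractions_sum_to_one(self, two_group_gpa):
        res = cm.pca(two_group_gpa)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.variance_explained) <= 1e-15)

    def test_full_rank_scores_preserve_distances(self, two_group_gpa):
        res = cm.pca(two_group_gpa)
        X = two_group_gpa.flattened()
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(res.scores), pdist(X), atol=1e-9)


class TestBgPCA:
    def test_two_groups_give_one_nonzero_axis(self, two_group_gpa):
        res = cm.bgpca(two_group_gpa)
        nonzero = res.variance_explained > 0
        assert nonzero.sum() == 1

    def test_axes_beyond_group_rank_have_exactly_zero_variance(self, two_group_gpa):
        res = cm.bgpca(two_group_gpa)
        g = len(set(two_group_gpa.sample.groups))
        assert np.all(res.variance_explained[g - 1:] == 0.0)

    def test_group_mean_projects_to_score_centroid(self, two_group_gpa):
        res = cm.bgpca(two_group_gpa)
        X = two_group_gpa.flattened()
        groups = np.asarray(two_group_gpa.sample.groups)
        for g in set(groups):
            mean_shape = X[groups == g].mean(axis=0)
            proj = (mean_shape - res.mean) @ res.axes.T
            np.testing.assert_allclose(proj, res.scores[groups == g].mean(axis=0),
                                       atol=1e-10)

    def test_single_group_rejected(self):
        spec = make_cohort_spec(n_groups=1, n=5, seed=1)
        _, sample = cohort_sample(spec, k=1)
        with pytest.raises(ShapeStatsError):
            cm.bgpca(cm.gpa(sample))


class TestPermutationTest:
    def test_addone_formula_and_seed_reproducibility(self, two_group_gpa):
        r1 = cm.permutation_inertia_test(two_group_gpa, n_perm=199, seed=7,
                                         keep_null=True)
        r2 = cm.permutation_inertia_test(two_group_gpa, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value
        expect = (1 + int((r1.permuted >= r1.observed).sum())) / 200
        assert r1.p_value == pytest.approx(expect)

    def test_separated_groups_reach_minimum_p(self):
        spec = make_cohort_spec(n_groups=2, n=10, offset=1.5, noise=0.01,
                                seed=13)
        _, sample = cohort_sample(spec, k=1)
        res = cm.permutation_inertia_test(cm.gpa(sample), n_perm=199, seed=3)
        assert res.p_value == pytest.approx(1 / 200)

    def test_zero_within_variance_gives_unit_inertia(self):
        # two point-clusters with no within-group scatter, synthetic coords
        a = np.zeros((4, 6, 3))
        b = np.ones((4, 6, 3)) * 0.1
        b[:, :, 1] = np.linspace(0, 1, 6)  # make shapes non-degenerate
        a[:, :, 1] = np.linspace(0, 1, 6)
        a[:, 0, 0] = 0.5
        b[:, 0, 0] = -0.5
        coords = np.concatenate([a, b])
        sample = cm.ShapeSample(coords=coords,
                                ids=tuple(f"s{i}" for i in range(8)),
                                groups=("a",) * 4 + ("b",) * 4)
        res = cm.permutation_inertia_test(cm.gpa(sample), n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0, abs=1e-12)

    def test_too_few_groups_rejected(self, two_group_gpa):
        with pytest.raises(ShapeStatsError):
            cm.permutation_inertia_test(two_group_gpa,
                                        groups=("x",) * two_group_gpa.sample.n)


class TestCVA:
    @staticmethod
    def _two_gaussians(rng, n=50, dim=5, sep=4.0):
        a = rng.standard_normal((n, dim))
        b = rng.standard_normal((n, dim))
        b[:, 0] += sep
        scores = np.concatenate([a, b])
        groups = ("a",) * n + ("b",) * n
        return scores, groups

    def test_cv1_recovers_separation_axis(self):
        scores, groups = self._two_gaussians(np.random.default_rng(17))
        ordination, _ = cm.cva(scores, groups)
        axis = ordination.axes[0] / np.linalg.norm(ordination.axes[0])
        assert abs(axis[0]) > 0.95

    def test_perfect_separation_classifies_100_percent(self):
        scores, groups = self._two_gaussians(np.random.default_rng(19), sep=30.0)
        _, cls = cm.cva(scores, groups)
        assert all(r == 100.0 for r in cls.rates.values())
        assert cls.confusion.sum() == len(groups)
        np.testing.assert_array_equal(cls.confusion.sum(axis=1), [50, 50])

    def test_permuted_labels_classify_at_chance(self):
        rng = np.random.default_rng(23)
        scores = rng.standard_normal((150, 3))
        groups = tuple(np.repeat(["a", "b", "c"], 50))
        _, cls = cm.cva(scores, groups, n_perm_rates=100, seed=5)
        assert cls.chance_rate == pytest.approx(100.0 / 3, abs=5.0)

    def test_singular_within_scatter_rejected(self):
        rng = np.random.default_rng(29)
        scores = rng.standard_normal((6, 10))  # p >> n
        with pytest.raises(ShapeStatsError):
            cm.cva(scores, ("a", "a", "a", "b", "b", "b"))

    def test_retain_pcs_rule(self):
        var = np.array([0.5, 0.3, 0.15, 0.05])
        assert retain_pcs(var, n=50, g=3, target=0.90) == 3
        assert retain_pcs(var, n=6, g=3, target=0.90) == 2  # capped at n-g-1


class TestProjection:
    def test_member_projects_to_its_own_scores(self, two_group_gpa):
        res = cm.pca(two_group_gpa)
        raw = two_group_gpa.sample.coords[4]
        out = cm.project_indeterminate(res, two_group_gpa, {"held": raw})
        np.testing.assert_allclose(out["held"]["scores"], res.scores[4],
                                   atol=1e-6)

    def test_nearest_group_recovery(self):
        # one cohort split in half: train a frozen bgPCA space, project the
        # held-out half and require >= 90% nearest-group recovery
        spec = make_cohort_spec(n_groups=2, n=24, offset=0.8, noise=0.05,
                                seed=31)
        records, all_sample = cohort_sample(spec, k=7)
        groups = np.asarray(all_sample.groups)
        train = np.zeros(len(records), dtype=bool)
        for g in set(groups):
            train[np.nonzero(groups == g)[0][:12]] = True
        sample = cm.ShapeSample(coords=all_sample.coords[train],
                                ids=tuple(np.asarray(all_sample.ids)[train]),
                                groups=tuple(groups[train]))
        res = cm.gpa(sample)
        bg = cm.bgpca(res)
        hits = n_held = 0
        for i in np.nonzero(~train)[0]:
            out = cm.project_indeterminate(
                bg, res, {all_sample.ids[i]: all_sample.coords[i]})
            hits += out[all_sample.ids[i]]["nearest_group"] == groups[i]
            n_held += 1
        assert hits / n_held >= 0.9

    def test_point_count_mismatch_rejected(self, two_group_gpa):
        res = cm.pca(two_group_gpa)
        with pytest.raises(ShapeStatsError):
            cm.project_indeterminate(res, two_group_gpa,
                                     {"bad": np.zeros((4, 3))})


class TestDisplacementField:
    def test_zero_and_constant_fields(self):
        a = np.random.default_rng(0).normal(size=(26, 3))
        out = cm.vector_displacement_field(a, a)
        assert out["max_norm"] == 0.0
        shifted = cm.vector_displacement_field(a, a + [0.25, 0, 0])
        np.testing.assert_allclose(shifted["vectors"],
                                   np.tile([0.25, 0, 0], (26, 1)))

    def test_psc_only_difference_concentrates_on_psc(self):
        spec0 = make_cohort_spec(n_groups=1, n=1, noise=0.0, sd_log_cs=0.0,
                                 seed=1)
        records, _ = cm.simulate_cohort(spec0)
        import dataclasses

        from canalmorph.synthetic import posterior_displacement_field

        template = cm.generate_canal_template()
        field = posterior_displacement_field(template)
        bumped = dataclasses.replace(
            template,
            canals={k: v + 0.1 * field[k] for k, v in template.canals.items()})
        a = cm.build_configuration(template, 7).points
        b = cm.build_configuration(bumped, 7).points
        out = cm.vector_displacement_field(a, b, k=7)
        per = out["per_canal_mean_norm"]
        assert per["PSC"] > 3 * per["ASC"]
        assert per["PSC"] > 3 * per["HSC"]


class TestPipelineInvariances:
    def test_rigid_motion_invariance_of_scores(self):
        spec = make_cohort_spec(n_groups=3, n=5, offset=0.4, noise=0.05,
                                seed=37)
        records, sample = cohort_sample(spec, k=7)
        res = cm.gpa(sample)
        scores = cm.pca(res).scores

        rng = np.random.default_rng(99)
        moved = []
        for rec in records:
            R = random_rotation(rng)
            t = rng.normal(size=3, scale=10)
            s = np.exp(rng.normal(scale=0.3))
            c = rec.centerlines.transformed(R * s, t)  # rotation+scale+shift
            moved.append(cm.build_configuration(c, 7))
        sample2 = cm.ShapeSample.from_configurations(
            moved, [r.group for r in records])
        scores2 = cm.pca(cm.gpa(sample2)).scores
        for j in range(scores.shape[1] - 1):  # last axis is numerically null
            diff = min(np.abs(scores2[:, j] - scores[:, j]).max(),
                       np.abs(scores2[:, j] + scores[:, j]).max())
            assert diff < 1e-6, j

    def test_density_rank_order_of_group_separations_stable(self):
        spec = make_cohort_spec(n_groups=4, n=6, offset=0.5, noise=0.05,
                                seed=41)
        records, _ = cm.simulate_cohort(spec)
        seps = {}
        for k in (1, 7, 18, 48):
            configs = [cm.build_configuration(r.centerlines, k)
                       for r in records]
            sample = cm.ShapeSample.from_configurations(
                configs, [r.group for r in records])
            res = cm.gpa(sample)
            X = res.flattened()
            groups = np.asarray(sample.groups)
            labels = sorted(set(groups))
            means = {g: X[groups == g].mean(axis=0) for g in labels}
            seps[k] = [np.linalg.norm(means[a] - means[b])
                       for i, a in enumerate(labels) for b in labels[i + 1:]]
        base = seps[1]
        for k in (7, 18, 48):
            rho = scipy.stats.spearmanr(base, seps[k]).statistic
            assert rho >= 0.8, k
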