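import numpy as np
import pytest

import canalmorph as cm
from canalmorph.synthetic import CanalTemplateParams, CohortSpec, GroupSpec

#: coarser template for tests that simulate many specimens
FAST_TEMPLATE = CanalTemplateParams(points_per_canal=40)


def make_cohort_spec(n_groups=2, n=10, offset=0.0, slope=0.0, noise=0.05,
                     size_spread=0.1, sd_log_cs=0.05, seed=0, side_fraction=0.0,
                     template=FAST_TEMPLATE):
    """Cohort spec helper: groups spaced in size and (optionally) shape."""
    sizes = (np.linspace(-size_spread, size_spread, n_groups)
             if n_groups > 1 else np.array([0.0]))
    groups = tuple(GroupSpec(label=f"g{i}", n=n, mean_log_cs=float(m),
                             shape_offset=offset)
                   for i, m in enumerate(sizes))
    return CohortSpec(groups=groups, allometric_slope=slope, noise_sd=noise,
                      sd_log_cs=sd_log_cs, side_fraction=side_fraction,
                      seed=seed, template=template)


def cohort_sample(spec, k=7):
    """Simulate a cohort and return (records, ShapeSample at density k)."""
    records, _ = cm.simulate_cohort(spec)
    configs = [cm.build_configuration(r.centerlines, k) for r in records]
    sample = cm.ShapeSample.from_configurations(
        configs, [r.group for r in records])
    return records, sample


def random_configuration(rng, p=26, scale=1.0):
    return scale * rng.standard_normal((p, 3))


def random_rotation(rng):
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=rng)


@pytest.fixture(scope="session")
def template():
    return cm.generate_canal_template()


@pytest.fixture(scope="session")
def two_group_gpa():
    """GPA of a cohort with two clearly offset groups (session-cached)."""
    spec = make_cohort_spec(n_groups=2, n=10, offset=0.6, noise=0.05, seed=11)
    _, sample = cohort_sample(spec, k=7)
    return cm.gpa(sample)
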