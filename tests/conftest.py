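import numpy as np
import pytest

from podoseg.synthetic import CohortSpec, SceneParams, simulate_cohort


def mini_scene_params(**overrides) -> SceneParams:
    """Desk-scale glomeruli sized for 128 px frames at 1 um/px."""
    defaults = dict(glom_radius_mean_um=45.0, glom_radius_sd_um=4.0,
                    podocyte_count_mean=55.0, podocyte_count_sd=10.0)
    defaults.update(overrides)
    return SceneParams(**defaults)


def mini_cohort_spec(**overrides) -> CohortSpec:
    defaults = dict(n_subjects_per_group=3, glomeruli_per_subject=(3, 3),
                    image_size=128, seed=7, scene=mini_scene_params())
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """18 rendered 128 px samples (3+3 subjects x 3 glomeruli)."""
    samples, truth = simulate_cohort(mini_cohort_spec())
    return samples, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
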