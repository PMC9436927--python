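import numpy as np
import pytest

from phenopet.petsim import PetSimConfig, build_atlas, uniform_baseline


@pytest.fixture(scope="session")
def atlas():
    return build_atlas()


@pytest.fixture(scope="session")
def cube_atlas():
    """Single-ROI cube 'brain' (16^3 in-mask voxels) for calibration runs."""
    return build_atlas(shape=(18, 18, 18),
                       roi_spec=[(1, "BR", "whole brain", (1, 1, 1),
                                  (16, 16, 16))])


@pytest.fixture
def null_pet_config(cube_atlas):
    """No group effects, no global-scale nuisance: pure Gaussian noise."""
    return PetSimConfig(baseline_uptake=uniform_baseline(cube_atlas),
                        group_multipliers={"A": {}, "B": {}},
                        noise_sd=5.0, global_scale_sd=0.0, seed=0)
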