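import numpy as np
import pytest

from ctvi_synth.image_io import ImageVolume
from ctvi_synth.phantom import PhantomSpec, generate_case
from ctvi_synth.pipeline import run_experiment

#: Tiny experiment config used by the pipeline smoke / determinism tests.
SMOKE_CONFIG = {
    "seed": 11,
    "n_cases": 4,
    "n_folds": 2,
    "phantom": {"grid_shape": [24, 32, 32], "spacing_mm": 8.0},
    "preprocess": {"target_spacing_mm": 8.0, "crop_shape": [24, 32, 32],
                   "closing_radius_vox": 1, "min_component_vox": 20},
    "train": {"epochs": 2, "max_translation_px": 2},
    "network": {"base_filters": 4, "depth": 2},
}

#: Small phantom grid used throughout unit tests (4 mm voxels).
TEST_SPEC = PhantomSpec(grid_shape=(40, 64, 64), spacing_mm=4.0, seed=123)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic small phantom case shared across tests."""
    return generate_case(TEST_SPEC, case_id="fixture_case")


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """A completed tiny end-to-end experiment (manifest + artifacts)."""
    out = tmp_path_factory.mktemp("smoke_run")
    manifest = run_experiment(SMOKE_CONFIG, out)
    return {"manifest": manifest, "out_dir": out}


def make_volume(data, spacing=(1.0, 1.0, 1.0), units="HU"):
    return ImageVolume(np.asarray(data), spacing=spacing, units=units)
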