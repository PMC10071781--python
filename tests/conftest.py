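"""Shared fixtures: template assets and small random-volume helpers."""

import numpy as np
import pytest

from petnorm import phantom as ph
from petnorm.quantification import build_phantom_atlas


@pytest.fixture(scope="session")
def template_assets():
    """Default 48³ template used across modules."""
    return ph.make_template((48, 48, 48), seed=0)


@pytest.fixture(scope="session")
def small_assets():
    """Smallest supported template grid, for cheap tests."""
    return ph.make_template((32, 32, 32), seed=0)


@pytest.fixture(scope="session")
def phantom_atlas(template_assets):
    return build_phantom_atlas(template_assets.tissue_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_study_config(out_dir, master_seed: int = 5):
    """Smallest meaningful end-to-end study (32³, 3+3 subjects, 2 epochs)."""
    from petnorm.network import CascadeConfig, TrainConfig
    from petnorm.pipeline import StudyConfig

    return StudyConfig(
        n_train=3, n_test=3,
        grid_shape=(32, 32, 32),
        deform_amplitude=1.5,
        ventricle_scale_range=(1.0, 1.3),
        noise_sd=0.02,
        cascade=CascadeConfig(base_channels=4, ncc_window=7),
        train=TrainConfig(epochs=2),
        registration_max_iter=200,
        out_dir=str(out_dir),
        master_seed=master_seed,
    )


@pytest.fixture(scope="session")
def tiny_study_twice(tmp_path_factory):
    """The same tiny study run twice with one master seed (shared across
    the smoke, determinism and reproducibility tests)."""
    from petnorm.pipeline import run_phantom_study

    base = tmp_path_factory.mktemp("tiny_study")
    rep_a = run_phantom_study(tiny_study_config(base / "a"))
    rep_b = run_phantom_study(tiny_study_config(base / "b"))
    return rep_a, rep_b
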