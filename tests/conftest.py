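import numpy as np
import pytest

import amycnn as a

TINY_GRID = (16, 16, 12)
SMALL_GRID = (32, 32, 16)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, jitter-free phantom spec on a small grid."""
    return a.PhantomSpec(grid_shape=SMALL_GRID, noise_cv=0.0,
                         between_subject_sd=0.0)


@pytest.fixture(scope="session")
def clean_neg_scan(clean_spec):
    return a.generate_phantom(clean_spec, label=0, rng_seed=11)


@pytest.fixture(scope="session")
def clean_pos_scan(clean_spec):
    return a.generate_phantom(clean_spec, label=1, rng_seed=12)


@pytest.fixture(scope="session")
def tiny_separable_dataset():
    """Small separable cohort decomposed sagittally, for training tests.

    6 negatives / 6 positives on a tiny grid with 5% voxel noise; the class
    contrast (cortical SUVR 1.0 vs 1.6) dominates the noise by far.
    """
    spec = a.PhantomSpec(grid_shape=TINY_GRID, noise_cv=0.05,
                         between_subject_sd=0.0)
    scans = a.generate_cohort(spec, 6, 6, seed=21)
    return a.scans_to_suvr_datasets(scans, ("sagittal",))["sagittal"]


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_separable_dataset):
    """A small CNN trained briefly on the tiny cohort (shared, read-only)."""
    cfg = a.CNNConfig(conv_filters=(4, 4, 8, 8), epochs=50, rng_seed=3)
    stack0 = tiny_separable_dataset.items[0][0]
    shape = (stack0.planes.shape[1], stack0.planes.shape[2], stack0.n_slices)
    model = a.build_model(shape, cfg, axis="sagittal")
    a.train(model, tiny_separable_dataset, None, cfg)
    return model


def make_stack(planes, axis="sagittal", scan_id="s", label=0):
    return a.SliceStack(planes=np.asarray(planes, dtype=float), axis=axis,
                        scan_id=scan_id, label=label)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
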