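import numpy as np
import pytest

from eblrm import (
    FeatureSpec,
    FittedLRM,
    MMISpace,
    load_reference_model,
    reference_surface_config,
    sample_roi,
    simulate_batch,
)


@pytest.fixture(scope="session")
def roi() -> MMISpace:
    return MMISpace.ectopic_beat_roi()


@pytest.fixture(scope="session")
def ref_model() -> FittedLRM:
    return load_reference_model()


@pytest.fixture(scope="session")
def toy_config():
    return reference_surface_config()


@pytest.fixture(scope="session")
def set1(roi):
    return roi.point(ca_i_ini=150, ca_sr_ini=500, g_k1_sf=0.338, k_ryr_sf=1)


def make_observations(config, points, n_realizations, seed):
    """Simulate one batch per point with per-batch child seeds."""
    seeds = np.random.SeedSequence(seed).spawn(len(points))
    return [
        simulate_batch(config, pt, n_realizations, ss)
        for pt, ss in zip(points, seeds)
    ]


@pytest.fixture(scope="session")
def roi_observations(roi, toy_config):
    """200 uniform ROI sets x 1000 realizations from the reference surface."""
    pts = sample_roi(roi, 200, np.random.default_rng(20240901))
    return make_observations(toy_config, pts, 1000, 20240902)
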