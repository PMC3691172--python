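"""Shared fixtures.

The ``study`` fixture runs the full synthetic study once per session
(two seeding conditions x four times x three replicates, with a threshold
sweep per image) and is shared by the detection-property, calibration and
acceptance tests; everything else uses small per-test fixtures.
"""

import numpy as np
import pytest

import edgesense as es
from edgesense.pipeline import calibrate_study, summarize_study


@pytest.fixture(scope="session")
def study():
    """Full synthetic study: 11-point threshold grid,
    11 mm field of view (0.01 mm/px)."""
    cfg = es.default_config(seed=7)
    cfg.S_grid = [0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50]
    profiles, images = es.generate_study(cfg)
    detections = es.detect_study(cfg, images)
    summary, sweeps, band = summarize_study(cfg, detections)
    maps = calibrate_study(sweeps, profiles, cfg.times_h)
    return {
        "config": cfg,
        "profiles": profiles,
        "images": images,
        "detections": detections,
        "summary": summary,
        "sweeps": sweeps,
        "band": band,
        "maps": maps,
    }


@pytest.fixture(scope="session")
def fixture_params():
    """Render parameters for a 7 mm field around a 3 mm test disk."""
    return es.RenderParams(image_size=700)


@pytest.fixture(scope="session")
def disk_image(fixture_params):
    return es.make_disk_fixture(3.0, fixture_params)


@pytest.fixture(scope="session")
def model_profile():
    """A solved 10,000-cell model at the study times (default numerics)."""
    K = es.carrying_capacity(25.0)
    C0 = es.initial_density(10000, 3.0, K)
    params = es.ModelParams(D=1000.0, C0=C0)
    return es.solve(params, [0.0, 24.0, 48.0, 72.0])


@pytest.fixture()
def uniform_disk_profile():
    """u = const inside r <= a, zero outside, on the default domain."""
    r = np.linspace(0.0, 7.8, 781)
    u = np.where(r <= 3.0, 0.5, 0.0)
    return es.DensityProfile(r=r, u=u[None, :], times=[0.0])
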