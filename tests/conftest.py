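import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hidspatial.synthgen import SimConfig, generate_roi_points, render_roi_image

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def half_size_config() -> SimConfig:
    """Half-scale ROI config (quarter area) for image-level unit tests."""
    return SimConfig(seed=11).scaled_to_shape((520, 696))


@pytest.fixture(scope="session")
def rendered_roi(half_size_config):
    """One clean rendered ROI with its planted cells (shared, read-only)."""
    rng = np.random.default_rng(11)
    cells, _ = generate_roi_points(half_size_config, "P000", "P000_R00", rng)
    image, truth = render_roi_image(cells, half_size_config, rng)
    return {"cells": cells, "image": image, "truth": truth, "config": half_size_config}
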