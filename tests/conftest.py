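import math

import numpy as np
import pandas as pd
import pytest

from scmorpho import phantom, pipeline


def brute_force_axes(mask: np.ndarray, lat: float, ax: float):
    """Independent moment-ellipse oracle: explicit double loop over pixels.

    Returns (major_um, minor_um) of the equal-second-moment ellipse, computed
    without any of the package's vectorized moment code.
    """
    pts = [(c * lat, r * ax) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    n = len(pts)
    xbar = sum(p[0] for p in pts) / n
    ybar = sum(p[1] for p in pts) / n
    sxx = syy = sxy = 0.0
    for x, y in pts:
        sxx += (x - xbar) ** 2
        syy += (y - ybar) ** 2
        sxy += (x - xbar) * (y - ybar)
    uxx = sxx / n + lat * lat / 12.0
    uyy = syy / n + ax * ax / 12.0
    uxy = sxy / n
    common = math.sqrt((uxx - uyy) ** 2 + 4 * uxy * uxy)
    major = 2 * math.sqrt(2) * math.sqrt(uxx + uyy + common)
    minor = 2 * math.sqrt(2) * math.sqrt(max(uxx + uyy - common, 0.0))
    return major, minor


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230706)


@pytest.fixture(scope="session")
def small_design():
    """Compact two-group clamped-IOP design used across statistical tests."""
    return phantom.default_study_design(eyes_per_group=2, n_bscans=12, eye_scale_sd=0.05)


@pytest.fixture(scope="session")
def small_measurements(small_design) -> pd.DataFrame:
    """Measured eye table from one compact in-memory phantom experiment."""
    return pipeline.measure_experiment_arrays(small_design, seed=11)
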