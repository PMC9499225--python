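import math

import numpy as np
import pytest

from ommatidics.model import EyeProfile


def circle_profile(
    R: float = 0.5,
    pitch: float = 0.02,
    span_deg: float = 100.0,
    center=(0.0, 0.0),
    phase: float = 0.0,
) -> EyeProfile:
    """Noiseless points at facet boundaries on a circular arc.

    Independent of the package's own generator: direct trigonometry, used
    as the geometric ground truth in estimator tests.
    """
    delta = pitch / R
    n = int(math.floor(math.radians(span_deg) / delta))
    angles = phase + (np.arange(n + 1) - n / 2.0) * delta
    pts = np.column_stack(
        [center[0] + R * np.cos(angles), center[1] + R * np.sin(angles)]
    )
    return EyeProfile(points=pts, apex_index=(n + 1) // 2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
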