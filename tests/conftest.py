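import numpy as np
import pytest

from arthroguide.datasets import shoulder_cadaver_study
from arthroguide.geometry import Point3


@pytest.fixture(scope="session")
def study():
    """The five-attempt cadaver shoulder-targeting dataset."""
    return shoulder_cadaver_study()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def trajectory():
    """A planned trajectory running mainly posterior, 40 mm deep."""
    entry = Point3(-75.0, -9.0, 35.0, frame="scanner", label="entry")
    target = Point3(-76.0, -48.0, 34.0, frame="scanner", label="target")
    return entry, target


def brute_force_best_line_residual(points: np.ndarray, step_deg: float = 2.0) -> float:
    """Independent oracle: minimum sum of squared perpendicular residuals
    over a dense grid of line directions through the centroid."""
    centred = points - points.mean(axis=0)
    best = np.inf
    total = float((centred**2).sum())
    for theta in np.arange(0.0, 180.0 + step_deg, step_deg):
        t = np.radians(theta)
        for phi in np.arange(0.0, 360.0, step_deg):
            p = np.radians(phi)
            d = np.array(
                [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
            )
            resid = total - float(((centred @ d) ** 2).sum())
            best = min(best, resid)
    return best
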