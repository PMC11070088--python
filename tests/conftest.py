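import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from assembloid_quant import BoundaryROI, SceneParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_star_polygon(
    rng: np.random.Generator,
    n_vertices: int = 12,
    radius: float = 30.0,
    center: tuple[float, float] = (40.0, 40.0),
    irregularity: float = 0.6,
) -> np.ndarray:
    """Random star-shaped (hence simple) polygon as (x, y) vertices."""
    ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    rad = radius * rng.uniform(1.0 - irregularity / 2, 1.0 + irregularity / 2,
                               n_vertices)
    return np.column_stack([center[0] + rad * np.cos(ang),
                            center[1] + rad * np.sin(ang)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240505)


@pytest.fixture
def square_roi():
    """Axis-aligned 10x10 square with corner at (5, 5)."""
    return BoundaryROI(np.array([[5, 5], [15, 5], [15, 15], [5, 15]], float))


def small_scene_params(seed: int, **overrides) -> SceneParams:
    """Compact assembloid scene for fast pipeline tests."""
    defaults = dict(
        image_shape=(1, 160, 160),
        organoid_polygon="ellipse(80, 80, 62, 62, 48, 0.03)",
        n_cells=120,
        decay_length_um=50.0,
        nuclear_density=0.008,
        seed=seed,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)
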