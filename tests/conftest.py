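import math

import numpy as np
import pytest

from onsight.phantom import PhantomSpec, generate_idealized_phantom


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def random_star_polygon(rng: np.random.Generator, n: int) -> np.ndarray:
    """Simple (star-shaped) polygon with random vertex radii."""
    # jittered equally spaced angles keep every angular gap below pi,
    # so each edge stays inside its wedge and the polygon is simple
    ang = 2 * np.pi * (np.arange(n) + rng.uniform(0.0, 0.8, n)) / n
    r = rng.uniform(0.5, 2.0, n)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def random_rigid_transform(rng: np.random.Generator):
    """Random proper rotation matrix and translation vector in 3D."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-50, 50, 3)
    return rot, trans


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Idealized tube phantom at printed dimensions, noise off."""
    return generate_idealized_phantom(PhantomSpec(snr=math.inf, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Idealized tube phantom with Rician noise at SNR 20."""
    return generate_idealized_phantom(PhantomSpec(snr=20.0, seed=42))
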