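import numpy as np
import pytest

import aptaprobe as ap


@pytest.fixture(scope="session")
def chain_config() -> ap.GeneratorConfig:
    return ap.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def chain(chain_config) -> ap.ParticleModel:
    return ap.generate_chain_model(chain_config)


@pytest.fixture(scope="session")
def sphere_cloud() -> ap.ParticleModel:
    """~4000 points uniform in a sphere of radius 5 nm (fixed seed)."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(-1.0, 1.0, size=(20000, 3))
    pts = pts[np.sum(pts * pts, axis=1) <= 1.0][:4000] * 5.0
    return ap.ParticleModel(pts)


@pytest.fixture(scope="session")
def dumbbell() -> ap.ParticleModel:
    return ap.ParticleModel([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def sphere_form_factor(s: np.ndarray, radius: float) -> np.ndarray:
    """Analytic normalized intensity of a uniform sphere."""
    x = s * radius
    f = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return f * f


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Analytic p(r) of a uniform sphere (unit area on the given grid)."""
    x = np.clip(r / (2.0 * radius), 0.0, 1.0)
    p = r * r * (1.0 - 1.5 * x + 0.5 * x**3)
    p[r > 2.0 * radius] = 0.0
    area = np.trapezoid(p, r)
    return p / area if area > 0 else p
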