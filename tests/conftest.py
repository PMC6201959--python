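import numpy as np
import pytest

from segmorph.io_formats import OutlineConfiguration, study_scheme
from segmorph.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def scheme90():
    return study_scheme(90)


@pytest.fixture(scope="session")
def scheme24():
    return study_scheme(24)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset: 2 localities x 4
    plants x 5 segments x 2 replicates, 24-point outlines."""
    spec = SyntheticSpec(
        plants_per_locality=4,
        segments_per_plant=5,
        n_points=24,
        seed=101,
    )
    configs, meta, truth = generate(spec)
    return spec, configs, meta, truth


def random_outline(rng: np.random.Generator, n_points: int = 24,
                   wobble: float = 0.1) -> np.ndarray:
    """A random smooth closed star-shaped curve (not necessarily symmetric)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = 1.0 + wobble * (np.cos(2 * phi) * rng.normal()
                        + np.sin(3 * phi) * rng.normal()
                        + np.cos(phi) * rng.normal())
    r = np.clip(r, 0.2, None)
    return np.column_stack([r * np.sin(phi), -r * np.cos(phi)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
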