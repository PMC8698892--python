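import numpy as np
import pytest

from mammoprep import PipelineConfig
from mammoprep.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def phantom_with_everything():
    """One phantom carrying every artefact kind, plus its truth masks."""
    spec = PhantomSpec(
        has_corner_label=True,
        has_border_line=True,
        has_attached_line=True,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def plain_phantom():
    """Artefact-free phantom (breast + lesion only)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_mask(rng: np.random.Generator, shape=(64, 64), p: float = 0.5) -> np.ndarray:
    return np.where(rng.random(shape) < p, np.uint8(255), np.uint8(0))
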