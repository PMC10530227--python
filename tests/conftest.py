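import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icehab import ClassParams, IceScapeConfig, PipelineConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_icescape_config() -> IceScapeConfig:
    """A fast icescape: 25 colonies on a 5,500 km coast, 4 annual cycles."""
    return IceScapeConfig(
        grid_shape=(12, 1100), years=4, seed=11, break_start_km=25.0, break_end_km=40.0
    )


@pytest.fixture(scope="session")
def small_pipeline_config(small_icescape_config) -> PipelineConfig:
    return PipelineConfig(
        icescape=small_icescape_config,
        k_min=2,
        k_max=3,
        n_starts=4,
        closeness_samples=20_000,
        seed=5,
    )


@pytest.fixture(scope="session")
def flat_classes() -> tuple[ClassParams, ...]:
    """Noise-free, cycle-free classes (degenerate series checks)."""
    return tuple(ClassParams(p, 0.0, 258.0, 0.0, 0.0) for p in (1.0, 1.0, 1.0))


def make_vei_data(
    rng: np.random.Generator,
    means: np.ndarray,
    volumes: np.ndarray,
    shape: np.ndarray,
    weights: np.ndarray,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n points from an exact VEI mixture; returns (X, component)."""
    comp = rng.choice(len(weights), size=n, p=weights)
    sd = np.sqrt(volumes[:, None] * shape[None, :])
    X = means[comp] + sd[comp] * rng.standard_normal((n, means.shape[1]))
    return X, comp
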