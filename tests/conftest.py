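import numpy as np
import pytest

from memconnect import RunConfig, SpotSimParams, generate_spot_image


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


def small_spot_params(completeness: float, seed: int = 7, **overrides) -> SpotSimParams:
    """Down-scaled spot parameters used throughout the image tests.

    A 400-µm spot with 80 cells keeps a full pipeline run to a couple of
    seconds while preserving the geometry (touching cells, detached
    islets, 0.25 µm/px).
    """
    kwargs = dict(
        n_cells=80,
        spot_diameter_um=400.0,
        membrane_completeness=completeness,
        seed=seed,
    )
    kwargs.update(overrides)
    return SpotSimParams(**kwargs)


@pytest.fixture(scope="session")
def complete_spot():
    """One fully membrane-stained synthetic spot plus its ground truth."""
    return generate_spot_image(small_spot_params(1.0))


def draw_ring(shape=(200, 200), center=(100, 100), radius=60.0, width_px=2.0):
    """Binary ring of given centre-line radius and thickness."""
    ring = np.zeros(shape, dtype=bool)
    theta = np.linspace(0.0, 2.0 * np.pi, 6000)
    for rad in np.arange(radius - width_px / 2, radius + width_px / 2 + 0.25, 0.5):
        rr = np.round(center[0] + rad * np.sin(theta)).astype(int)
        cc = np.round(center[1] + rad * np.cos(theta)).astype(int)
        ring[rr, cc] = True
    return ring
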