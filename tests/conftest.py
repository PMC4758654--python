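import numpy as np
import pytest

from angiofield import FieldState, Grid, ModelParameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture()
def small_grid() -> Grid:
    return Grid(nx=64, ny=48)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def smooth_random_field(grid: Grid, rng: np.random.Generator,
                        lo: float, hi: float, smoothing: int = 6) -> np.ndarray:
    """Random field smoothed by repeated local averaging, rescaled to [lo, hi]."""
    arr = rng.random(grid.shape)
    for _ in range(smoothing):
        padded = np.pad(arr, 1, mode="edge")
        arr = (padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2]
               + padded[1:-1, 2:] + arr) / 5.0
    arr = (arr - arr.min()) / (arr.max() - arr.min() + 1e-30)
    return lo + (hi - lo) * arr


@pytest.fixture()
def uniform_state(small_grid) -> FieldState:
    shape = small_grid.shape
    return FieldState(phi=np.zeros(shape), sigma=np.full(shape, 0.45),
                      c=np.full(shape, -1.0), f=np.zeros(shape))
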