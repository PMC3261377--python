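import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_series(rng):
    """A small random complex cine series (6 frames, 16x16)."""
    from cscine import CineSeries

    frames = rng.normal(size=(6, 16, 16)) + 1j * rng.normal(size=(6, 16, 16))
    return CineSeries(frames, pixel_size_mm=0.1, slice_thickness_mm=1.0)


def make_sparse_fixture(n=64, n_frames=20, amplitude=30.0):
    """Static bright block plus 5 time-varying pixels: exactly sparse diffs."""
    bg = np.zeros((n, n), complex)
    bg[20:44, 20:44] = 80.0
    truth = np.repeat(bg[None], n_frames, axis=0)
    pixels = [(30, 30), (25, 40), (40, 22), (33, 35), (28, 26)]
    for i, (y, x) in enumerate(pixels):
        truth[:, y, x] = truth[:, y, x] + amplitude * np.sin(
            2 * np.pi * np.arange(n_frames) / n_frames + i
        )
    return truth, pixels


@pytest.fixture
def tiny_phantom_spec():
    from cscine import PhantomSpec

    return PhantomSpec.scaled(matrix=64, n_frames=10, n_slices=2, seed=7)
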