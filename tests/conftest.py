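import numpy as np
import pytest

from colonytrack.mask_io import LabeledFrame, MaskMovie
from colonytrack.simulate import ColonyConfig, simulate


def square_frame(index: int, positions: list[tuple[int, int]],
                 size: int = 5, canvas: int = 64) -> LabeledFrame:
    """Frame with one `size` x `size` square per position (top-left corners),
    labeled 1..n in order."""
    img = np.zeros((canvas, canvas), dtype=np.int32)
    for i, (r, c) in enumerate(positions, start=1):
        img[r:r + size, c:c + size] = i
    return LabeledFrame(index=index, labels=img)


def disc_mask(radius: int, canvas: int = 64, label: int = 1) -> np.ndarray:
    img = np.zeros((canvas, canvas), dtype=np.int32)
    rr, cc = np.mgrid[:canvas, :canvas]
    ctr = canvas / 2 - 0.5
    img[(rr - ctr) ** 2 + (cc - ctr) ** 2 <= radius ** 2] = label
    return img


@pytest.fixture(scope="session")
def small_budding_colony():
    """A small but crowded budding colony with ground truth (session-scoped:
    several test modules reuse it)."""
    return simulate(ColonyConfig(mode="budding", n_frames=40,
                                 initial_cells=6, seed=42))


@pytest.fixture(scope="session")
def small_fission_colony():
    return simulate(ColonyConfig(mode="fission", n_frames=40,
                                 initial_cells=4, seed=43))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
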