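import numpy as np
import pytest

from mitodet.synthetic import TileGenParams, gen_he_tile


@pytest.fixture(scope="session")
def small_tile():
    """A 96-px easy-regime tile with 3 mitotic figures and ground truth."""
    return gen_he_tile(TileGenParams(side=96, n_nuclei=12, n_mitotic=3, seed=5))


@pytest.fixture(scope="session")
def blank_tile():
    """A near-white background-only tile (no tissue)."""
    from mitodet.tile import HistologyTile

    rng = np.random.default_rng(0)
    pixels = np.clip(
        250 + rng.normal(0, 1.5, size=(96, 96, 3)), 0, 255
    ).astype(np.uint8)
    return HistologyTile(pixels=pixels, id="blank")


class StubRng:
    """Deterministic stand-in for a Generator: replays queued values."""

    def __init__(self, uniforms=(), integers=()):
        self._u = list(uniforms)
        self._i = list(integers)

    def uniform(self, low=0.0, high=1.0, size=None):
        def nxt():
            v = self._u.pop(0) if self._u else 0.5
            return low + (high - low) * v
        if size is None:
            return nxt()
        n = int(np.prod(size))
        return np.array([nxt() for _ in range(n)]).reshape(size)

    def integers(self, low, high=None, size=None):
        def nxt():
            return self._i.pop(0) if self._i else low
        if size is None:
            return nxt()
        n = int(np.prod(size))
        return np.array([nxt() for _ in range(n)])


@pytest.fixture
def stub_rng():
    return StubRng
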