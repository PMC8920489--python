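import numpy as np
import pytest

import oisconn as oc


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def full_mask():
    """11x11 all-true mask (no edge-renormalization effects interior)."""
    return oc.BrainMask.from_image(np.ones((11, 11), dtype=bool))


def make_normalized(data: np.ndarray, fs: float = 1.0) -> oc.NormalizedSeries:
    """Wrap a raw panel as a NormalizedSeries on a 1-row-per-pixel mask."""
    n = data.shape[0]
    side = int(np.ceil(np.sqrt(n)))
    img = np.zeros((side, side), dtype=bool)
    img.flat[:n] = True
    mask = oc.BrainMask.from_image(img)
    data = (data - data.mean(axis=1, keepdims=True)) / data.std(
        axis=1, keepdims=True)
    return oc.NormalizedSeries(data=data, fs=fs, mask=mask,
                               provenance=("normalize",))


@pytest.fixture
def ar1_series():
    """Panel of 60 independent AR(1) pixels, phi=0.75, T=300, at 1 Hz."""
    panel = oc.generate_ar1_panel(60, 300, 0.75, seed=11)
    return make_normalized(panel)


@pytest.fixture
def planted_dataset():
    """Default two-network synthetic run (within 0.7, between -0.3)."""
    return oc.generate_dataset(oc.SyntheticConfig(seed=42))


@pytest.fixture
def planted_series(planted_dataset):
    return oc.normalize(oc.global_signal_regress(planted_dataset.raw))
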