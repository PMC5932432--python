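import numpy as np
import pytest

from mgmfseg.gmf import GMFParams
from mgmfseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chaudhuri_params():
    return GMFParams(sigma=2.0, L=9, T=13, kappa=12)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact mixed-width phantom used by several unit tests."""
    cfg = PhantomConfig(size=128, n_vessels=3, width_range=(1.5, 2.5), seed=42)
    image, mask, sigma_map = generate_phantom(cfg)
    return cfg, image, mask, sigma_map


def random_histograms(n, seed, min_occupied=2):
    """Random 256-bin histograms of assorted shapes for oracle-equivalence tests."""
    from mgmfseg.thresholding import Histogram

    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        kind = rng.integers(4)
        if kind == 0:
            counts = rng.integers(0, 200, size=256)
        elif kind == 1:  # bimodal gaussian mixture
            a = rng.normal(rng.uniform(40, 100), rng.uniform(5, 20), size=3000)
            b = rng.normal(rng.uniform(140, 220), rng.uniform(5, 20), size=3000)
            counts = np.bincount(np.clip(np.concatenate([a, b]).astype(int), 0, 255), minlength=256)
        elif kind == 2:  # sparse spikes
            counts = np.zeros(256, dtype=int)
            idx = rng.choice(256, size=rng.integers(2, 8), replace=False)
            counts[idx] = rng.integers(1, 500, size=len(idx))
        else:  # skewed
            counts = rng.geometric(rng.uniform(0.01, 0.2), size=256)
        if np.count_nonzero(counts) >= min_occupied:
            out.append(Histogram(counts=counts.astype(np.int64), vmin=0.0, vmax=1.0))
    return out
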