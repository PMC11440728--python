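import numpy as np
import pytest

from ioradiomics.image_core import ImageVolume, zscore_standardize
from ioradiomics.simulate import PhantomSpec, generate_phantom

SURV_DT = [("event", "?"), ("time", "<f8")]


def surv(events, times) -> np.ndarray:
    return np.array(list(zip(np.asarray(events, bool), np.asarray(times, float))),
                    dtype=SURV_DT)


@pytest.fixture(scope="session")
def phantom():
    """One mid-size phantom shared by extraction tests."""
    spec = PhantomSpec(grid_shape=(64, 64, 64), tumor_radius_mm=8.0,
                       tortuosity=0.2, seed=11)
    vol, tumor, lung, vessel, gt = generate_phantom(spec)
    return {"spec": spec, "volume": vol, "tumor": tumor, "lung": lung,
            "vessel": vessel, "truth": gt}


@pytest.fixture(scope="session")
def std_phantom(phantom):
    return zscore_standardize(phantom["volume"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def straight_tube(shape=(40, 40, 40), radius=3.0, axis=2) -> np.ndarray:
    """Binary straight tube along ``axis`` centred on a voxel line."""
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"))
    center = [n // 2 for n in shape]
    trans = [i for i in range(3) if i != axis]
    d2 = sum((coords[i] - center[i]) ** 2 for i in trans)
    return d2 <= radius**2
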