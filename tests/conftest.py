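import numpy as np
import pytest
from hypothesis import settings

from radstab.core import ImageVolume, RoiMask, ScanMeta

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """The reduced-extent 14-scan synthetic study (both virtual scanners,
    seven spacings), rendered once per session."""
    from radstab.phantom import make_dataset, small_spec

    return make_dataset(small_spec(), base_seed=1)


def _block_mask(shape=(20, 10, 4)) -> np.ndarray:
    """Ten rectangular ROIs tiling the x-y plane."""
    labels = np.zeros(shape, dtype=np.int16)
    lab = 1
    for ix in range(5):
        for iy in range(2):
            labels[ix * 4 : (ix + 1) * 4, iy * 5 : (iy + 1) * 5, :] = lab
            lab += 1
    return labels


@pytest.fixture()
def tiny_scan():
    """One small scan with 10 block ROIs of 80 voxels each."""
    rng = np.random.default_rng(11)
    vox = rng.normal(0, 120, (20, 10, 4))
    vol = ImageVolume(vox, (0.7, 0.7, 1.25))
    mask = RoiMask(_block_mask())
    meta = ScanMeta("tiny", "toy", 0.7, 1.25)
    return vol, mask, meta


@pytest.fixture()
def tiny_model_dataset():
    """Seven scans of one toy scanner at the protocol spacings, all with
    identical voxel data (only metadata differs)."""
    rng = np.random.default_rng(5)
    vox = rng.normal(0, 120, (20, 10, 4))
    mask = RoiMask(_block_mask())
    scans = []
    for k, sp in enumerate((0.39, 0.49, 0.59, 0.68, 0.78, 0.88, 0.98)):
        # identical grids too: only the recorded acquisition spacing varies
        vol = ImageVolume(vox.copy(), (0.7, 0.7, 1.25))
        scans.append((vol, mask, ScanMeta(f"scan{k+1}", "toy", sp, 1.25)))
    return scans
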