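import numpy as np
import pytest

from prostacad import CaseBundle, Mask3D, PhantomSpec, Volume3D, simulate_phantom


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> Volume3D:
    return Volume3D(np.asarray(data, dtype=float), spacing, origin)


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> Mask3D:
    return Mask3D(np.asarray(data, dtype=np.uint8), spacing, origin)


def make_bundle(shape=(8, 8, 4), spacing=(1.0, 1.0, 1.0), seed=0) -> CaseBundle:
    """A small geometry-consistent bundle with plausible channel ranges."""
    rng = np.random.default_rng(seed)
    return CaseBundle(
        t2w=make_volume(300 + 50 * rng.standard_normal(shape), spacing),
        adc=make_volume(1000 + 150 * rng.standard_normal(shape), spacing),
        uptake=make_volume(120 + 30 * rng.standard_normal(shape), spacing),
        prob=make_volume(rng.uniform(0, 1, shape), spacing),
    )


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom case, shared across tests."""
    return simulate_phantom(PhantomSpec(seed=42))


def random_discrete_roi(rng, max_side=6, max_levels=4):
    """Random small discretized ROI: levels in 0..max_levels (0 = outside)."""
    from prostacad.preprocess import DiscretizedROI

    shape = tuple(rng.integers(2, max_side + 1, size=3))
    nb = int(rng.integers(2, max_levels + 1))
    levels = rng.integers(0, nb + 1, size=shape)
    if not (levels > 0).any():
        levels.flat[0] = 1
    mask = Mask3D((levels > 0).astype(np.uint8), (1.0, 1.0, 1.0))
    return DiscretizedROI(levels=levels.astype(np.int32), n_bins=nb, mask=mask)
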