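import numpy as np
import pytest

from mwiseg import (PhantomSpec, RegionMask, contract_roi, generate_phantom)


@pytest.fixture(scope="session")
def default_truth():
    """Default clean phantom, fixed seed, shared across tests (read-only)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def default_roi(default_truth):
    return contract_roi(default_truth.domain_boundary_mask, 3.5)


@pytest.fixture
def disk_mask():
    """Digitized disk of radius 20 px on a 50x50 grid, spacing 1 mm."""
    yy, xx = np.mgrid[:50, :50]
    rr = np.hypot(xx - 24.5, yy - 24.5)
    return RegionMask((rr <= 20).astype(np.uint8), 1.0)


def tissue_dice(ref_seg, rec_seg, tissue, restrict=None):
    a = ref_seg.mask(tissue)
    if restrict is not None:
        a = a & restrict
    b = rec_seg.mask(tissue)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else float("nan")
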