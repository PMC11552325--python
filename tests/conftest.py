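import numpy as np
import pandas as pd
import pytest

from stroi.model import ScaleFactors, SpatialDataset
from stroi.synthetic import FixtureSpec, Region, make_fixture


@pytest.fixture(scope="session")
def two_region():
    """Standard planted two-region fixture (dataset + ground truth)."""
    return make_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def small_fixture():
    """Small, fast fixture for geometric and IO tests."""
    spec = FixtureSpec(
        image_shape=(96, 96),
        regions=[
            Region("rectangle", (8, 8, 40, 88), (200, 60, 60)),
            Region("disk", (70, 48, 18), (60, 80, 200)),
        ],
        spot_pitch=8,
        n_genes=60,
        markers_per_region=4,
        n_decoy_terms=3,
        decoy_term_size=4,
        seed=11,
    )
    return make_fixture(spec)


def tiny_dataset(counts, fullres_xy=None, in_tissue=None, image_hw=(20, 20),
                 scalef=1.0, diameter=4.0):
    """Hand-rolled minimal SpatialDataset for unit tests."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    if fullres_xy is None:
        fullres_xy = [(5.0 + i, 5.0 + i) for i in range(n)]
    if in_tissue is None:
        in_tissue = [True] * n
    table = pd.DataFrame(
        {
            "barcode": [f"BC{i}" for i in range(n)],
            "in_tissue": in_tissue,
            "fullres_x": [p[0] for p in fullres_xy],
            "fullres_y": [p[1] for p in fullres_xy],
        }
    )
    return SpatialDataset(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(g)],
        spot_table=table,
        scale=ScaleFactors(hires_scalef=scalef, spot_diameter_fullres=diameter),
        image=np.zeros((*image_hw, 3), dtype=np.uint8),
    )
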