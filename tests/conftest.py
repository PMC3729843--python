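import numpy as np
import pandas as pd
import pytest

from conntrace import (Cohort, Parcellation, SyntheticConfig, make_cohort,
                       make_parcellation, random_connected_edges)


@pytest.fixture(scope="session")
def small_parcellation():
    """8 connected regions in a 12^3 volume, 2 mm voxels."""
    return make_parcellation(8, (12, 12, 12), seed=1)


@pytest.fixture()
def slab_parcellation():
    """Two regions tiling a 4x4x1 slab with an identity-scale affine."""
    labels = np.ones((4, 4, 1), dtype=np.int32)
    labels[2:, :, :] = 2
    affine = np.eye(4)
    regions = pd.DataFrame({
        "label": [1, 2],
        "name": ["left", "right"],
        "cx": [0.5, 2.5], "cy": [1.5, 1.5], "cz": [0.0, 0.0],
    })
    return Parcellation(label_volume=labels, affine=affine, regions=regions)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SyntheticConfig(n_regions=20, n_subjects_a=10, n_subjects_b=10,
                          edge_density=0.5, seed=42)
    cohort, truth = make_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong planted effect: 10-edge connected component at ratio 8."""
    planted = random_connected_edges(10, 30, np.random.default_rng(7))
    cfg = SyntheticConfig(n_regions=30, n_subjects_a=12, n_subjects_b=12,
                          planted_edges=planted, effect_ratio=8.0,
                          novel_fraction=0.2, edge_density=0.4, seed=17)
    cohort, truth = make_cohort(cfg)
    return cohort, truth


def cohort_from_matrices(mats, groups):
    return Cohort(matrices=np.stack(mats), groups=np.asarray(groups))
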