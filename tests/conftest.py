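import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from rsfc import BrainMask, ImageGrid, SubjectZSet
import pandas as pd


@pytest.fixture
def grid8():
    return ImageGrid.standard((8, 8, 8), 3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_zset(
    grid,
    n_per_group,
    n_voxels=None,
    rng=None,
    effect=None,
    sites=3,
    groups=("A", "B"),
):
    """Synthetic SubjectZSet built directly from Gaussian z values.

    ``effect`` maps group label -> per-voxel mean added to the post session.
    """
    rng = rng or np.random.default_rng(0)
    mask = BrainMask(grid, np.ones(grid.dims, dtype=bool))
    v = mask.n_voxels if n_voxels is None else n_voxels
    if n_voxels is not None:
        inc = np.zeros(grid.dims, dtype=bool)
        inc.ravel()[:n_voxels] = True
        mask = BrainMask(grid, inc)
    rows, pre, post = [], [], []
    i = 0
    for g, n in zip(groups, n_per_group):
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"s{g}{k}",
                    "group": g,
                    "site": i % sites,
                    "medicated": bool(k % 2),
                }
            )
            base = rng.normal(0, 0.1, size=v)
            delta = rng.normal(0, 0.1, size=v)
            if effect and g in effect:
                delta = delta + effect[g]
            pre.append(base)
            post.append(base + delta)
            i += 1
    return SubjectZSet(
        grid=grid,
        mask=mask,
        subjects=pd.DataFrame(rows),
        pre=np.asarray(pre),
        post=np.asarray(post),
    )


@pytest.fixture
def zset_factory():
    return make_zset
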