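import numpy as np
import pandas as pd
import pytest

from snowscr.captures import DetectorArray
from snowscr.double_observer import GroupRecord
from snowscr.geomask import MaskGrid


def make_mask(n_cols, n_rows, spacing=1000.0, covariates=None, origin=(0.0, 0.0)):
    """A full rectangular mask of cell centres with optional covariates."""
    xs = origin[0] + (np.arange(n_cols) + 0.5) * spacing
    ys = origin[1] + (np.arange(n_rows) + 0.5) * spacing
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    cov = pd.DataFrame(covariates) if covariates is not None else None
    return MaskGrid(centers=centers, spacing=spacing, covariates=cov)


def make_detectors(xy, effort=80.0, n_cameras=None, topography=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return DetectorArray.from_arrays(
        ids=[f"T{i+1:02d}" for i in range(n)],
        x=xy[:, 0], y=xy[:, 1],
        effort_days=np.full(n, effort),
        n_cameras=n_cameras if n_cameras is not None else np.ones(n, dtype=int),
        topography=topography if topography is not None else ["cliff"] * n,
    )


def _records(c, s1, s2, sizes, species, blocks=("B",)):
    """Build group records with the given two-observer tallies and sizes."""
    flags = [(True, True)] * c + [(True, False)] * s1 + [(False, True)] * s2
    assert len(flags) == len(sizes)
    return [
        GroupRecord(species, blocks[i % len(blocks)], int(sz), a, b)
        for i, ((a, b), sz) in enumerate(zip(flags, sizes))
    ]


@pytest.fixture(scope="session")
def table1_records():
    """Synthetic group records whose tallies and pooled counts reproduce the
    published double-observer survey: blue sheep (C=75, S1=18, S2=6, naive
    N=1470 over 99 groups) and ibex (C=18, S1=5, S2=1, naive N=297 over 24
    groups)."""
    blue_sizes = [15] * 84 + [14] * 15          # sums to 1470 over 99 groups
    ibex_sizes = [13] * 9 + [12] * 15           # sums to 297 over 24 groups
    blue = _records(75, 18, 6, blue_sizes, "blue sheep")
    ibex = _records(18, 5, 1, ibex_sizes, "ibex")
    return {"blue sheep": blue, "ibex": ibex, "overall": blue + ibex}
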