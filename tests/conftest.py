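"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import settings

from lesionmap import LesionDataset, LesionMask, VoxelGrid, make_two_region_toy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p by exhaustive table enumeration.

    Enumerates every 2x2 table with the observed margins and sums, in exact
    rational arithmetic, the hypergeometric probabilities of all tables
    whose point probability does not exceed the observed one.
    """
    n, m, k = a + b + c + d, a + b, a + c
    lo, hi = max(0, m + k - n), min(m, k)
    denom = comb(n, k)
    pts = {x: Fraction(comb(m, x) * comb(n - m, k - x), denom) for x in range(lo, hi + 1)}
    obs = pts[a]
    return float(sum(p for p in pts.values() if p <= obs))


def masks_from_columns(columns: np.ndarray, grid: VoxelGrid | None = None) -> LesionDataset:
    """Build a dataset whose voxel (i,0,0) damage pattern is columns[:, i]."""
    columns = np.asarray(columns, dtype=np.uint8)
    n, v = columns.shape
    grid = grid or VoxelGrid(dims=(v, 1, 1))
    masks = [
        LesionMask(grid=grid, voxels=columns[i].reshape(grid.dims), subject_id=f"s{i}")
        for i in range(n)
    ]
    return LesionDataset(grid=grid, masks=masks)


@pytest.fixture(scope="session")
def toy():
    """The canonical two-region fixture: 40 affected-type, 40 unaffected."""
    return make_two_region_toy(40, 40, seed=1)


@pytest.fixture(scope="session")
def toy_dataset(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_parcellation(toy):
    return toy[1]
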