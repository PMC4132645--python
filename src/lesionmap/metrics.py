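"""Overlap metrics between voxel sets."""

from __future__ import annotations

import numpy as np

__all__ = ["dice_coefficient"]


def _as_set(voxels) -> set[tuple[int, int, int]]:
    arr = np.asarray(voxels, dtype=int).reshape(-1, 3)
    return set(map(tuple, arr))


def dice_coefficient(voxels_a, voxels_b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between two voxel index sets."""
    a, b = _as_set(voxels_a), _as_set(voxels_b)
    if not a and not b:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))
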