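"""Shared 3-D neighborhood machinery for the texture families."""

from __future__ import annotations

from itertools import product

import numpy as np

#: The 13 unique 3-D offsets at Chebyshev distance 1 (one per +/- pair),
#: ordered so the first non-zero component is positive.
UNIQUE_OFFSETS: list[tuple[int, int, int]] = [
    o
    for o in product((-1, 0, 1), repeat=3)
    if o != (0, 0, 0) and o > (0, 0, 0)
]

#: All 26 neighbors.
ALL_OFFSETS: list[tuple[int, int, int]] = [
    o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
]

assert len(UNIQUE_OFFSETS) == 13 and len(ALL_OFFSETS) == 26


def shifted_views(a: np.ndarray, offset: tuple[int, int, int]):
    """Index tuples (src, dst) so that a[src] aligns with a[dst] + offset.

    Returns slices selecting the overlap of the array with itself shifted
    by ``offset``; a[center] pairs with a[neighbor] where
    neighbor = center + offset.
    """
    center, neighbor = [], []
    for n, d in zip(a.shape, offset):
        if d == 0:
            center.append(slice(0, n))
            neighbor.append(slice(0, n))
        elif d > 0:
            center.append(slice(0, n - d))
            neighbor.append(slice(d, n))
        else:
            center.append(slice(-d, n))
            neighbor.append(slice(0, n + d))
    return tuple(center), tuple(neighbor)
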