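"""Splicing/decomposable (SD) coding: grid cells under the Chebyshev metric.

A point's SD code at scale ``s`` is the coordinate vector of the grid cell of
side ``delta^s = 1/sim_min^s`` that contains it.  Two points are *similar* at
that scale exactly when their cells are the same or Chebyshev-adjacent (every
coordinate differs by at most one) -- adjacency itself is the criterion; no
exact distance check follows it.  Grouping by cell key and enumerating each
occupied cell's ``3^d - 1`` neighbor keys makes linking linear in n for fixed d.

Cells are half-open, ``[k*delta, (k+1)*delta)``, anchored at the per-dimension
data minima.  Consequences used elsewhere:

* pairs closer than ``delta`` (Chebyshev) are always linked;
* linked pairs are always closer than ``2*delta``;
* duplicates share a cell at every scale.

For the canonical power-of-two schedule (``lambda_ = 1``) the cell side halves
at each scale, so a point's coarse cell coordinates are the bit-shifted prefix
of its fine ones; :func:`interleaved_bits` exports that decomposable bit code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Tuple

import numpy as np

from .data import Dataset

#: beyond this dimensionality 3^d neighbor enumeration is infeasible; use DM coding
MAX_SD_DIM = 12


def chebyshev(x, y) -> float:
    """L-infinity distance: the maximum per-dimension absolute difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.max(np.abs(x - y))) if x.size else 0.0


@dataclass(frozen=True)
class CellCode:
    """Grid-cell coordinates of every point at one scale."""

    cells: np.ndarray  # n x d integer matrix
    delta: float
    scale: int

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    @property
    def d(self) -> int:
        return self.cells.shape[1]


def sd_encode(X: Dataset, delta: float, scale: int = 1) -> CellCode:
    """Assign each point its half-open grid cell of side ``delta``.

    ``cells[i][j] = floor((values[i][j] - origin[j]) / delta)``; coordinates
    are non-negative because the grid is anchored at the data minima.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    rel = X.values - X.origin[None, :]
    cells = np.floor(rel / delta).astype(np.int64)
    np.clip(cells, 0, None, out=cells)  # guard against -0.0 / rounding at the anchor
    return CellCode(cells=cells, delta=float(delta), scale=int(scale))


def _neighbor_offsets(d: int) -> list:
    """Lexicographically-positive half of the 3^d - 1 Chebyshev neighbor offsets."""
    offsets = []
    for off in product((-1, 0, 1), repeat=d):
        if off > (0,) * d:  # canonical half: first nonzero coordinate positive
            offsets.append(off)
    return offsets


def sd_link(code: CellCode) -> Iterator[Tuple[int, int]]:
    """Yield merge operations linking points in the same or adjacent cells.

    For each occupied cell one representative point is chosen; all co-located
    points are linked to it, and representatives of Chebyshev-adjacent occupied
    cells are linked pairwise.  The union of these merges connects exactly the
    pairs satisfying the same-or-neighboring-cell predicate (transitively the
    connected components are identical, which is all the clustering consumes).
    """
    if code.d > MAX_SD_DIM:
        raise ValueError(
            f"d={code.d} exceeds the SD neighbor-enumeration cap ({MAX_SD_DIM}); "
            "use DM coding for high-dimensional data"
        )
    buckets: dict = {}
    for i, key in enumerate(map(tuple, code.cells.tolist())):
        if key in buckets:
            yield buckets[key], i  # co-located points union into the representative
        else:
            buckets[key] = i
    offsets = _neighbor_offsets(code.d)
    for key, rep in buckets.items():
        for off in offsets:
            nb = tuple(k + o for k, o in zip(key, off))
            other = buckets.get(nb)
            if other is not None:
                yield rep, other


def sd_pairs_bruteforce(code: CellCode) -> set:
    """All-pairs same-or-adjacent-cell predicate; O(n^2) oracle for testing."""
    cells = code.cells
    out = set()
    for i in range(code.n - 1):
        diff = np.abs(cells[i + 1 :] - cells[i]).max(axis=1)
        for j in np.nonzero(diff <= 1)[0]:
            out.add((i, i + 1 + int(j)))
    return out


def interleaved_bits(code: CellCode, bits_per_dim: int) -> list:
    """Morton-style bit-interleaved cell codes (one integer per point).

    With the power-of-two schedule the cell side halves per scale, so dropping
    the last ``d`` bits of a point's code yields its code one scale coarser --
    the decomposability property of SD codes.  Export-only; clustering uses the
    integer coordinate vectors directly.
    """
    out = []
    for row in code.cells.tolist():
        v = 0
        for b in range(bits_per_dim - 1, -1, -1):
            for c in row:
                v = (v << 1) | ((c >> b) & 1)
        out.append(v)
    return out
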