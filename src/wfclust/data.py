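"""In-memory container for the points to cluster."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Dataset:
    """An n x d real matrix of points, with its per-dimension minima.

    The minima serve as the anchor (origin) of the mesh grid used by SD
    coding, so every grid-cell coordinate is non-negative.
    """

    values: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-d matrix (rows = points)")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("need at least one point and one dimension")
        if not np.isfinite(v).all():
            raise ValueError("values contain NaN or infinity")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @classmethod
    def from_array(cls, values) -> "Dataset":
        v = np.asarray(values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        return cls(values=v, origin=v.min(axis=0))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]
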