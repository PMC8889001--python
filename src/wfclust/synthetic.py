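"""Synthetic datasets with planted multi-scale structure.

Two generators:

* :func:`make_mixture` -- 2-d point clouds mixing Gaussian blobs, noisy line
  segments, noisy quadratic arcs and uniform boxes.  The default spec plants
  3000 points in overlapping components (a uniform box containing an arc and a
  Gaussian; a line segment carrying a second Gaussian; a free-standing third
  Gaussian), with densities ordered gaussian > curve/line > uniform so that as
  the observation scale sharpens, the sparse components fragment first and the
  tight blobs last -- clusters emerge in stages rather than all at once.

* :func:`make_planted_binary` -- marker-set data with planted Jaccard
  structure: each cluster has a disjoint core marker set; points drop each
  core marker with a flip probability and gain background markers at a low
  rate, so within-cluster Jaccard exceeds between-cluster Jaccard by a margin
  computable in closed form.  This is a synthetic stand-in for DM-coded
  expression data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .data import Dataset
from .dm import BinaryCodes


@dataclass(frozen=True)
class Component:
    """One mixture component: a shape, a size and shape parameters."""

    shape: str  # gaussian | line | curve | uniform
    n: int
    label: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0


@dataclass(frozen=True)
class MixtureSpec:
    components: Tuple[Component, ...]
    seed: int = 0

    @property
    def total(self) -> int:
        return sum(c.n for c in self.components)


def default_mixture_spec(seed: int = 0) -> MixtureSpec:
    """The frozen 3000-point reference mixture (four shape families).

    Layout: a uniform box [0,4]^2 overlapping a quadratic arc and a tight
    Gaussian; a line from (5.5, 5) to (9.5, 8.5) overlapping a second
    Gaussian at its midpoint; a third, free-standing Gaussian.
    """
    return MixtureSpec(
        components=(
            Component("uniform", 1000, "uniform", {"box": (0.0, 4.0, 0.0, 4.0)}),
            Component(
                "curve",
                550,
                "curve",
                {"x_range": (0.5, 6.5), "x0": 3.5, "y0": 1.5, "a": 0.2},
                noise_sd=0.05,
            ),
            Component("line", 250, "line", {"start": (5.5, 5.0), "end": (9.5, 8.5)}, noise_sd=0.05),
            Component("gaussian", 400, "gaussian_a", {"center": (2.0, 3.0), "sd": 0.07}),
            Component("gaussian", 400, "gaussian_b", {"center": (7.5, 6.75), "sd": 0.07}),
            Component("gaussian", 400, "gaussian_c", {"center": (8.5, 1.5), "sd": 0.07}),
        ),
        seed=seed,
    )


def make_mixture(spec: MixtureSpec) -> Tuple[Dataset, List[str]]:
    """Draw the mixture; every point carries its component label."""
    rng = np.random.default_rng(spec.seed)
    chunks, labels = [], []
    for comp in spec.components:
        if comp.n <= 0:
            raise ValueError(f"component {comp.label!r} has non-positive count")
        if comp.shape == "gaussian":
            c = np.asarray(comp.params["center"], dtype=float)
            pts = rng.normal(loc=c, scale=comp.params["sd"], size=(comp.n, c.size))
        elif comp.shape == "line":
            a = np.asarray(comp.params["start"], dtype=float)
            b = np.asarray(comp.params["end"], dtype=float)
            t = rng.uniform(0, 1, size=comp.n)[:, None]
            pts = a[None, :] + t * (b - a)[None, :]
        elif comp.shape == "curve":
            lo, hi = comp.params["x_range"]
            x = rng.uniform(lo, hi, size=comp.n)
            y = comp.params["y0"] + comp.params["a"] * (x - comp.params["x0"]) ** 2
            pts = np.stack([x, y], axis=1)
        elif comp.shape == "uniform":
            xmin, xmax, ymin, ymax = comp.params["box"]
            pts = np.stack(
                [rng.uniform(xmin, xmax, comp.n), rng.uniform(ymin, ymax, comp.n)], axis=1
            )
        else:
            raise ValueError(f"unknown shape {comp.shape!r}")
        if comp.noise_sd > 0:
            pts = pts + rng.normal(0.0, comp.noise_sd, size=pts.shape)
        chunks.append(pts)
        labels.extend([comp.label] * comp.n)
    return Dataset.from_array(np.vstack(chunks)), labels


@dataclass(frozen=True)
class PlantedBinarySpec:
    """Planted Jaccard clusters over D binary markers."""

    n_clusters: int = 5
    points_per_cluster: int = 100
    D: int = 500
    core_size: int = 30
    flip_prob: float = 0.1
    background_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters * self.core_size > self.D:
            raise ValueError("disjoint core marker sets do not fit in D dimensions")
        if not (
            expected_within_jaccard(self) > expected_between_jaccard(self)
        ):
            raise ValueError("spec does not separate within- from between-cluster Jaccard")


def expected_within_jaccard(spec: PlantedBinarySpec) -> float:
    """Ratio-of-expectations Jaccard for two points of the same cluster.

    Each core marker is present in a point with probability p = 1 - flip_prob,
    each of the D - core_size other markers with the background rate g; all
    independently.  E[|intersection|] / E[|union|] approximates E[J] well for
    cores of a few dozen markers.
    """
    p = 1.0 - spec.flip_prob
    g = spec.background_rate
    m, rest = spec.core_size, spec.D - spec.core_size
    inter = m * p * p + rest * g * g
    union = m * (1 - spec.flip_prob**2) + rest * (1 - (1 - g) ** 2)
    return inter / union


def expected_between_jaccard(spec: PlantedBinarySpec) -> float:
    """Ratio-of-expectations Jaccard for two points of different clusters."""
    p = 1.0 - spec.flip_prob
    g = spec.background_rate
    m, rest = spec.core_size, spec.D - 2 * spec.core_size
    inter = 2 * m * p * g + rest * g * g
    union = 2 * m * (1 - (1 - p) * (1 - g)) + rest * (1 - (1 - g) ** 2)
    return inter / union


def make_planted_binary(spec: PlantedBinarySpec) -> Tuple[BinaryCodes, List[int]]:
    """Draw the planted marker sets; labels are cluster indices 0..n_clusters-1."""
    rng = np.random.default_rng(spec.seed)
    markers, labels = [], []
    for c in range(spec.n_clusters):
        core = np.arange(c * spec.core_size, (c + 1) * spec.core_size, dtype=np.int64)
        for _ in range(spec.points_per_cluster):
            keep = core[rng.uniform(size=spec.core_size) >= spec.flip_prob]
            mask = rng.uniform(size=spec.D) < spec.background_rate
            mask[core] = False
            bg = np.nonzero(mask)[0]
            mk = np.union1d(keep, bg)
            if mk.size == 0:  # vanishingly rare; keep the code well-formed
                mk = core[:1]
            markers.append(mk)
            labels.append(c)
    return BinaryCodes(markers, D=spec.D), labels
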