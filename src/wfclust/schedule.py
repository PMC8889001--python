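"""Weber-Fechner observation schedule.

The algorithm observes a dataset at a finite sequence of scales ``s = 1 .. s_end``.
At each scale, two points are linked when their similarity reaches a scale-wise
threshold ``sim_min^s``.  The threshold sequence is driven by the Weber-Fechner
law: the just-noticeable difference (JND) in a stimulus is a constant fraction
``lambda_`` of the background stimulus, so consecutive thresholds satisfy

    sim_min^{s+1} = (1 + lambda_) * sim_min^s

anchored at the global minimum pairwise similarity ``sim_min`` and ending once
the global maximum ``sim_max`` is passed:

    s_end = floor( log_{1+lambda_}( sim_max / sim_min ) )

(clamped to at least one scale).  Two alternative update policies are provided
for comparison studies: a hyper-exponential policy
``sim_min^s = (1+lambda_)^((s-1)^2) * sim_min`` that skips scales aggressively,
and a linear policy ``sim_min^s = sim_min * (1 + (s-1)*lambda_)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

Policy = Literal["weber_fechner", "hyper_exponential", "linear"]

_POLICIES = ("weber_fechner", "hyper_exponential", "linear")


@dataclass(frozen=True)
class ScaleSchedule:
    """Similarity thresholds for every observation scale.

    Attributes
    ----------
    lambda_ : float
        Weber fraction; the relative threshold increment between scales.
    sim_min, sim_max : float
        Global minimum / maximum pairwise similarity in the dataset
        (over distinct pairs; see :func:`estimate_similarity_bounds`).
    s_end : int
        Number of scales, ``floor(log_{1+lambda}(sim_max/sim_min))`` clamped
        to at least 1.
    policy : str
        Threshold update rule: ``weber_fechner`` (geometric), ``hyper_exponential``
        or ``linear``.
    thresholds : tuple of float
        ``sim_min^s`` for s = 1..s_end; strictly increasing.
    """

    lambda_: float
    sim_min: float
    sim_max: float
    s_end: int
    policy: Policy = "weber_fechner"
    thresholds: tuple = field(default_factory=tuple)

    @property
    def distance_thresholds(self) -> tuple:
        """Chebyshev cell sides ``delta^s = 1 / sim_min^s`` (SD mode); decreasing."""
        return tuple(1.0 / t for t in self.thresholds)

    def threshold_at(self, s: int) -> float:
        """Return ``sim_min^s`` for a 1-based scale index."""
        if not 1 <= s <= self.s_end:
            raise ValueError(f"scale s={s} out of range [1, {self.s_end}]")
        return self.thresholds[s - 1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambda": self.lambda_,
                "policy": self.policy,
                "sim_min": self.sim_min,
                "sim_max": self.sim_max,
                "s_end": self.s_end,
                "thresholds": list(self.thresholds),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaleSchedule":
        obj = json.loads(text)
        return cls(
            lambda_=obj["lambda"],
            sim_min=obj["sim_min"],
            sim_max=obj["sim_max"],
            s_end=obj["s_end"],
            policy=obj["policy"],
            thresholds=tuple(obj["thresholds"]),
        )


def _threshold(sim_min: float, lambda_: float, s: int, policy: Policy) -> float:
    # log-space evaluation: (1+lambda)^(s-1) overflows for large s_end otherwise
    if s == 1:
        return sim_min  # the anchor is exact, not exp(log(sim_min))
    if policy == "weber_fechner":
        return math.exp((s - 1) * math.log1p(lambda_) + math.log(sim_min))
    if policy == "hyper_exponential":
        return math.exp((s - 1) ** 2 * math.log1p(lambda_) + math.log(sim_min))
    if policy == "linear":
        return sim_min * (1.0 + (s - 1) * lambda_)
    raise ValueError(f"unknown policy {policy!r}")


def build_schedule(
    sim_min: float,
    sim_max: float,
    lambda_: float,
    policy: Policy = "weber_fechner",
) -> ScaleSchedule:
    """Build the scale schedule from similarity bounds and the Weber fraction.

    ``s_end = floor(log_{1+lambda}(sim_max/sim_min))``, clamped to a minimum of
    one scale; for the non-geometric policies s_end counts the thresholds the
    policy produces before exceeding ``sim_max * (1 + lambda_)`` (one-JND
    overshoot allowed, mirroring the floor), capped at the geometric s_end.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if sim_min <= 0:
        raise ValueError("sim_min must be positive")
    if sim_max < sim_min:
        raise ValueError("sim_max must be >= sim_min")
    log_ratio = math.log(sim_max) - math.log(sim_min)
    s_end = max(1, math.floor(log_ratio / math.log1p(lambda_) + 1e-12))
    if policy != "weber_fechner":
        # count thresholds not exceeding the one-JND overshoot bound
        bound = sim_max * (1.0 + lambda_)
        k = 1
        while k < s_end and _threshold(sim_min, lambda_, k + 1, policy) <= bound:
            k += 1
        s_end = k
    thresholds = tuple(_threshold(sim_min, lambda_, s, policy) for s in range(1, s_end + 1))
    return ScaleSchedule(
        lambda_=lambda_,
        sim_min=sim_min,
        sim_max=sim_max,
        s_end=s_end,
        policy=policy,
        thresholds=thresholds,
    )


def threshold_at(schedule: ScaleSchedule, s: int) -> float:
    """Module-level alias for :meth:`ScaleSchedule.threshold_at`."""
    return schedule.threshold_at(s)


def _chebyshev_nonzero_min(values: np.ndarray) -> float:
    d = pdist(values, metric="chebyshev")
    nz = d[d > 0]
    if nz.size == 0:
        raise ValueError("zero similarity range: all points identical")
    return float(nz.min())


def estimate_similarity_bounds(
    X,
    mode: str = "sd",
    codes=None,
    sample_size: int = 2000,
    seed: int = 0,
) -> tuple:
    """Estimate global (sim_min, sim_max) over point pairs.

    SD mode: similarity is 1/Chebyshev distance, so
    ``sim_min = 1 / chebyshev_diameter`` (diameter computed exactly from the
    per-dimension ranges in one pass) and ``sim_max = 1 / min nonzero pairwise
    Chebyshev distance`` -- exact via all pairs when n <= sample_size, else
    estimated from nearest-neighbor distances within a seeded random sample.

    DM mode: bounds are the max and min *nonzero* pairwise Jaccard similarity,
    exact for n <= sample_size, else over a seeded random pair sample; sim_min
    is clamped below by ``1/(2 D)`` so a single near-disjoint pair cannot
    inflate the scale count unboundedly.

    Parameters
    ----------
    X : Dataset or None
        Point matrix (SD mode).
    mode : {"sd", "dm"}
    codes : BinaryCodes, required in DM mode.
    """
    rng = np.random.default_rng(seed)
    if mode == "sd":
        values = np.asarray(X.values, dtype=float)
        n = values.shape[0]
        if n < 2:
            raise ValueError("need at least two points")
        ranges = values.max(axis=0) - values.min(axis=0)
        diameter = float(ranges.max())
        if diameter == 0.0:
            raise ValueError("zero similarity range: all points identical")
        if n <= sample_size:
            dmin = _chebyshev_nonzero_min(values)
        else:
            idx = rng.choice(n, size=sample_size, replace=False)
            dmin = _chebyshev_nonzero_min(values[idx])
        return 1.0 / diameter, 1.0 / dmin
    elif mode == "dm":
        if codes is None:
            raise ValueError("DM mode requires codes")
        from .dm import jaccard_sim  # local import to avoid cycle

        n = len(codes)
        if n < 2:
            raise ValueError("need at least two points")
        if n <= sample_size:
            pairs = ((i, j) for i in range(n) for j in range(i + 1, n))
        else:
            left = rng.integers(0, n, size=sample_size * 4)
            right = rng.integers(0, n, size=sample_size * 4)
            pairs = ((int(i), int(j)) for i, j in zip(left, right) if i != j)
        smax = 0.0
        smin = math.inf
        for i, j in pairs:
            s = jaccard_sim(codes[i], codes[j])
            if s > 0.0:
                smax = max(smax, s)
                if s < smin:
                    smin = s
        if smax == 0.0:
            raise ValueError("zero similarity range: no pair shares a marker")
        smin = max(smin, 1.0 / (2.0 * codes.D))
        smin = min(smin, smax)
        return smin, smax
    raise ValueError(f"unknown mode {mode!r}")
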