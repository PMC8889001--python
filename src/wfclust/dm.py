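"""Dimension-marker (DM) coding: binary codes, Jaccard similarity, MinHash + LSH.

For high-dimensional data each point is encoded as the *set of its informative
dimensions* -- a binary marker vector ``c(x)``.  The similarity of two points is
the Jaccard index of their marker sets,

    sim(x, y) = H(c(x) AND c(y)) / H(c(x) OR c(y))

with ``H`` the Hamming weight.  Retrieving all pairs above a threshold ``t``
without quadratic work uses MinHash signatures (k seeded universal hash
functions; the probability two signatures agree at one coordinate equals the
pair's Jaccard similarity) partitioned into ``b`` bands of ``r`` rows: pairs
colliding in at least one band are candidates, and by default each candidate is
verified exactly, so the output has no false positives and only the (rare)
banding false negatives.

Three marker rules are provided, since what counts as "informative" depends on
the data:

``nonzero``
    dimension j is marked iff ``x_j != 0`` -- natural for sparse expression
    counts, where expressed genes are the markers;
``top_m``
    the m largest-magnitude dimensions are marked -- for dense vectors with a
    few dominant coordinates;
``binned``
    each dimension is quantized into B equal-width bins over its observed
    range and the marker is ``j*B + bin(x_j)`` -- Jaccard then measures the
    fraction of dimensions falling in identical bins, suited to dense
    embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .data import Dataset

# Mersenne prime 2^31 - 1: products a*x with a, x < p fit in int64
_PRIME = 2_147_483_647

#: guaranteed worst-case collision probability for a pair exactly at the
#: retrieval threshold; bandings that cannot provide it are not used
RECALL_FLOOR = 0.99


class BinaryCodes:
    """A collection of marker sets, one per point, over D possible markers."""

    def __init__(self, markers: Sequence[np.ndarray], D: int):
        self.markers: List[np.ndarray] = [
            np.unique(np.asarray(m, dtype=np.int64)) for m in markers
        ]
        self.D = int(D)
        empty = [i for i, m in enumerate(self.markers) if m.size == 0]
        if empty:
            raise ValueError(f"points with no marked dimension: rows {empty[:20]}")
        for m in self.markers:
            if m[0] < 0 or m[-1] >= self.D:
                raise ValueError("marker index out of range")

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.markers[i]


def dm_encode(X: Dataset, mode: str = "nonzero", m: int = 0, B: int = 8) -> BinaryCodes:
    """Encode each point's informative dimensions as a marker set."""
    v = X.values
    n, d = v.shape
    if mode == "nonzero":
        markers = [np.nonzero(v[i])[0] for i in range(n)]
        zero_rows = [i for i, mk in enumerate(markers) if mk.size == 0]
        if zero_rows:
            raise ValueError(f"all-zero rows cannot be DM-encoded: rows {zero_rows[:20]}")
        return BinaryCodes(markers, D=d)
    if mode == "top_m":
        if not 1 <= m <= d:
            raise ValueError("top_m mode requires 1 <= m <= d")
        order = np.argsort(-np.abs(v), axis=1, kind="stable")[:, :m]
        return BinaryCodes([np.sort(order[i]) for i in range(n)], D=d)
    if mode == "binned":
        if B < 1:
            raise ValueError("binned mode requires B >= 1")
        lo = v.min(axis=0)
        rng = v.max(axis=0) - lo
        rng[rng == 0] = 1.0  # constant columns all land in bin 0
        bins = np.clip(np.floor((v - lo) / rng[None, :] * B).astype(np.int64), 0, B - 1)
        base = np.arange(d, dtype=np.int64) * B
        return BinaryCodes([base + bins[i] for i in range(n)], D=d * B)
    raise ValueError(f"unknown DM mode {mode!r}")


def _incidence(codes: BinaryCodes):
    """n x D sparse binary incidence matrix of the marker sets."""
    import scipy.sparse as sp

    indptr = np.zeros(len(codes) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([m.size for m in codes.markers])
    indices = np.concatenate(codes.markers) if len(codes) else np.empty(0, dtype=np.int64)
    data = np.ones(indices.size, dtype=np.int64)
    return sp.csr_matrix((data, indices, indptr), shape=(len(codes), codes.D))


def jaccard_for_pairs(codes: BinaryCodes, pairs) -> np.ndarray:
    """Vectorized Jaccard similarities for an iterable of (i, j) pairs."""
    pairs = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
    if pairs.shape[0] == 0:
        return np.empty(0)
    M = _incidence(codes)
    sizes = np.asarray([m.size for m in codes.markers], dtype=np.int64)
    A = M[pairs[:, 0]]
    B = M[pairs[:, 1]]
    inter = np.asarray(A.multiply(B).sum(axis=1)).ravel()
    union = sizes[pairs[:, 0]] + sizes[pairs[:, 1]] - inter
    return inter / union


def jaccard_sim(cx: np.ndarray, cy: np.ndarray) -> float:
    """Jaccard index of two marker sets: |intersection| / |union|."""
    if cx.size == 0 and cy.size == 0:
        raise ValueError("both codes empty")
    inter = np.intersect1d(cx, cy, assume_unique=True).size
    union = cx.size + cy.size - inter
    return inter / union


@dataclass(frozen=True)
class MinHashIndex:
    """MinHash signatures: n x k matrix of per-hash minima over marker indices."""

    signatures: np.ndarray
    k: int
    seed: int


def _mix64(z: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: high-quality 64-bit avalanche mixing."""
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def minhash_signatures(codes: BinaryCodes, k: int = 256, seed: int = 0) -> MinHashIndex:
    """Compute k-hash MinHash signatures for every code.

    Hash family: k seeded 64-bit mixing hashes ``h_i(x) = mix64(x XOR s_i)``
    (a splitmix64 finalizer, which avalanches every input bit; a plain linear
    congruential hash is *not* min-wise independent on structured marker
    sets).  Deterministic under (codes, k, seed); the per-coordinate collision
    probability of two signatures approximates the pair's Jaccard similarity.
    """
    if k < 16:
        raise ValueError("k must be at least 16")
    rng = np.random.default_rng(seed)
    salts = rng.integers(0, 2**63, size=k, dtype=np.int64).astype(np.uint64)
    n = len(codes)
    sig = np.empty((n, k), dtype=np.uint64)
    for i, mk in enumerate(codes.markers):
        h = _mix64(mk.astype(np.uint64)[None, :] ^ salts[:, None])
        sig[i] = h.min(axis=1)
    return MinHashIndex(signatures=sig, k=k, seed=seed)


def choose_bands(k: int, t: float) -> Tuple[int, int]:
    """Pick (bands b, rows r) with b*r = k and S-curve midpoint (1/b)^(1/r) <= t.

    Among admissible factorizations the midpoint closest to t is chosen;
    ties break toward larger r (fewer false positives).
    """
    if not 0 < t <= 1:
        raise ValueError("t must be in (0, 1]")
    best = None
    for b in range(1, k + 1):
        if k % b:
            continue
        r = k // b
        mid = (1.0 / b) ** (1.0 / r)
        if mid <= t and (best is None or (mid, r) > (best[0], best[2])):
            best = (mid, b, r)
    if best is None:
        raise ValueError(
            f"no (b, r) factorization of k={k} has S-curve midpoint <= t={t}; "
            "increase k"
        )
    return best[1], best[2]


def choose_bands_guaranteed(
    k: int, t: float, floor: float = RECALL_FLOOR
) -> Optional[Tuple[int, int]]:
    """Most precise (b, r) whose collision probability at similarity t is >= floor.

    Precision is ordered by the S-curve midpoint (1/b)^(1/r): a higher midpoint
    admits fewer false-positive candidates.  Returns None when no factorization
    of k can guarantee the floor -- the threshold is then too weak for MinHash
    retrieval at this sketch size.
    """
    best = None
    for b in range(1, k + 1):
        if k % b:
            continue
        r = k // b
        hit = 1.0 - (1.0 - t**r) ** b
        if hit < floor:
            continue
        mid = (1.0 / b) ** (1.0 / r)
        if best is None or (mid, r) > (best[0], best[2]):
            best = (mid, b, r)
    return None if best is None else (best[1], best[2])


def candidate_pairs(index: MinHashIndex, band_threshold: float) -> Set[Tuple[int, int]]:
    """Pairs colliding in at least one LSH band tuned for the given threshold."""
    b, r = choose_bands(index.k, band_threshold)
    return _band_collisions(index.signatures, b, r)


def _band_collisions(sig: np.ndarray, b: int, r: int) -> Set[Tuple[int, int]]:
    out: Set[Tuple[int, int]] = set()
    for band in range(b):
        block = sig[:, band * r : (band + 1) * r]
        buckets: dict = {}
        for i, row in enumerate(map(tuple, block.tolist())):
            buckets.setdefault(row, []).append(i)
        for members in buckets.values():
            if len(members) > 1:
                for ai in range(len(members)):
                    for aj in range(ai + 1, len(members)):
                        out.add((members[ai], members[aj]))
    return out


def marker_join_pairs(codes: BinaryCodes) -> Set[Tuple[int, int]]:
    """All pairs sharing at least one marker, via an inverted index.

    Any pair with nonzero Jaccard similarity shares a marker, so this is an
    exact candidate set for arbitrarily low thresholds, where MinHash banding
    cannot reach high recall.  Work is the sum of squared posting-list
    lengths -- output-sensitive rather than n^2 when markers are spread out.
    """
    import scipy.sparse as sp

    M = _incidence(codes)
    co = sp.triu(M @ M.T, k=1).tocoo()
    return set(zip(co.row.tolist(), co.col.tolist()))


def banding_recall_floor(k: int, t: float) -> float:
    """Worst-case collision probability for a pair exactly at threshold t."""
    b, r = choose_bands(k, max(t, 1.0 / k))
    return 1.0 - (1.0 - t**r) ** b


def retrieve_candidates(
    index: MinHashIndex, codes: BinaryCodes, t: float
) -> Set[Tuple[int, int]]:
    """Candidate pairs for threshold t with a guaranteed >= RECALL_FLOOR recall.

    Uses the most precise banding that still guarantees the floor for a pair
    exactly at t; when no banding of k hashes can (t very weak), every pair
    sharing at least one marker is enumerated exactly instead.
    """
    sel = choose_bands_guaranteed(index.k, min(max(t, 1e-12), 1.0))
    if sel is None:
        return marker_join_pairs(codes)
    return _band_collisions(index.signatures, *sel)


def lsh_pairs(
    index: MinHashIndex,
    codes: BinaryCodes,
    t: float,
    exact_verify: bool = True,
    band_threshold: Optional[float] = None,
    brute_force_cutoff: int = 0,
) -> List[Tuple[int, int]]:
    """All pairs with Jaccard similarity >= t, via LSH candidates.

    With ``exact_verify`` (default) every candidate is checked with
    :func:`jaccard_sim`, so the output contains no false positives; without it
    the raw band collisions are returned and may include pairs below t.

    ``band_threshold`` sets the banding independently of the verification
    threshold: generating candidates once at the grossest (smallest) scheduled
    threshold and re-verifying at each finer one makes the per-scale edge sets
    exactly nested, which is how the multi-scale driver uses this.  For
    n <= ``brute_force_cutoff`` an exact all-pairs scan replaces LSH.
    """
    n = len(codes)
    if n <= brute_force_cutoff:
        return sorted(
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if jaccard_sim(codes[i], codes[j]) >= t
        )
    bt = band_threshold if band_threshold is not None else t
    cands = retrieve_candidates(index, codes, bt)
    if not exact_verify:
        return sorted(cands)
    ordered = sorted(cands)
    sims = jaccard_for_pairs(codes, ordered)
    return [p for p, jv in zip(ordered, sims) if jv >= t]


def jaccard_pairs_bruteforce(codes: BinaryCodes, t: float) -> List[Tuple[int, int]]:
    """O(n^2) exact thresholded Jaccard retrieval; the oracle for LSH recall."""
    n = len(codes)
    M = _incidence(codes)
    inter = (M @ M.T).toarray()
    sizes = inter.diagonal()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    ii, jj = np.nonzero(np.triu(J >= t, k=1))
    return list(zip(ii.tolist(), jj.tolist()))
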