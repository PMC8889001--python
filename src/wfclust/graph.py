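"""The multi-scale clustering driver.

At every scale a graph is (implicitly) built whose edges are the point pairs
similar at that scale's threshold, and each connected component -- a maximal
connected subgraph -- is a cluster; points with no similar neighbor are
isolated singleton clusters.  Edges are consumed on the fly by a union-find
structure (path compression + union by size), so per-scale state is O(n).

Repeating from the grossest scale s = 1 to the finest s_end and tracking which
coarse cluster contains each finer cluster's members yields the cluster
hierarchy.  In DM mode edges at a finer scale are by construction a subset of
those at a coarser one (the threshold only rises on a fixed similarity), so
each partition exactly refines the previous one.  SD grid adjacency is not
strictly nested for lambda_ < 1 (a finer grid can link points whose coarse
cells are not adjacent); when a cluster's members span several coarse
clusters, the majority parent is assigned and the event counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import dm as _dm
from . import sd as _sd
from .config import RunConfig
from .data import Dataset
from .schedule import ScaleSchedule, build_schedule, estimate_similarity_bounds


class UnionFind:
    """Disjoint sets over [0, n) with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, i: int) -> int:
        root = i
        p = self.parent
        while p[root] != root:
            root = p[root]
        while p[i] != root:  # path compression
            p[i], i = root, p[i]
        return int(root)

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


@dataclass(frozen=True)
class ScaleClustering:
    """Cluster labels at one scale, canonicalized to smallest member index."""

    scale: int
    labels: np.ndarray
    sizes: Dict[int, int]
    isolated: Tuple[int, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]


def _snapshot(uf: UnionFind, n: int, scale: int) -> ScaleClustering:
    """Current union-find state as a canonical ScaleClustering."""
    roots = np.fromiter((uf.find(i) for i in range(n)), dtype=np.int64, count=n)
    # canonical label: smallest member index of each component
    canon: Dict[int, int] = {}
    for i in range(n):
        r = int(roots[i])
        if r not in canon:
            canon[r] = i  # first (= smallest) index seen for this root
    labels = np.fromiter((canon[int(r)] for r in roots), dtype=np.int64, count=n)
    ids, counts = np.unique(labels, return_counts=True)
    sizes = {int(c): int(k) for c, k in zip(ids, counts)}
    isolated = tuple(int(c) for c, k in zip(ids, counts) if k == 1)
    return ScaleClustering(scale=scale, labels=labels, sizes=sizes, isolated=isolated)


def connected_components(n: int, edges: Iterable[Tuple[int, int]], scale: int = 1) -> ScaleClustering:
    """Label connected components; singletons are reported as isolated."""
    uf = UnionFind(n)
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge endpoint out of range: ({i}, {j})")
        uf.union(i, j)
    return _snapshot(uf, n, scale)


def select_coding(n: int, d: int, override: Optional[str] = None) -> str:
    """Choose the coding: grids (sd) for low dimension, marker sets (dm) otherwise.

    The SD neighbor enumeration visits 3^d keys per cell, so it is capped at
    d <= 12; beyond that DM's MinHash retrieval keeps the run sub-quadratic.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    if override is not None and override != "auto":
        if override == "sd" and d > _sd.MAX_SD_DIM:
            raise ValueError(
                f"SD coding infeasible for d={d} (> {_sd.MAX_SD_DIM}): "
                "3^d neighbor enumeration; use dm"
            )
        if override not in ("sd", "dm"):
            raise ValueError(f"unknown coding {override!r}")
        return override
    return "sd" if d <= _sd.MAX_SD_DIM else "dm"


@dataclass(frozen=True)
class HierarchyNode:
    scale: int
    cluster_id: int
    size: int
    parent: Optional[int]  # cluster id at scale-1 coarser, None for scale 1


@dataclass(frozen=True)
class Hierarchy:
    """Tree of clusters across scales; children refine their parents."""

    nodes: Tuple[HierarchyNode, ...]
    repaired_parents: int  # members spanned >1 coarse cluster (SD only)

    @property
    def roots(self) -> List[HierarchyNode]:
        return [nd for nd in self.nodes if nd.scale == 1]

    def children(self, scale: int, cluster_id: int) -> List[HierarchyNode]:
        return [
            nd for nd in self.nodes if nd.scale == scale + 1 and nd.parent == cluster_id
        ]


def build_hierarchy(per_scale: Sequence[ScaleClustering], strict: bool = False) -> Hierarchy:
    """Link each scale-s cluster to the scale-(s-1) cluster holding its members.

    If the members span several coarser clusters (possible only with SD grids
    at lambda_ < 1) the majority one becomes the parent and the event is
    counted; with ``strict`` (DM mode) such an event raises instead.
    """
    if not per_scale:
        raise ValueError("per_scale must be nonempty")
    n = per_scale[0].labels.shape[0]
    nodes: List[HierarchyNode] = []
    repaired = 0
    for sc in per_scale:
        if sc.labels.shape[0] != n:
            raise ValueError("inconsistent point count across scales")
    for idx, sc in enumerate(per_scale):
        if idx == 0:
            for cid, size in sc.sizes.items():
                nodes.append(HierarchyNode(sc.scale, cid, size, None))
            continue
        coarse = per_scale[idx - 1].labels
        for cid, size in sc.sizes.items():
            parents = coarse[sc.labels == cid]
            uniq, counts = np.unique(parents, return_counts=True)
            if uniq.size > 1:
                if strict:
                    raise ValueError(
                        f"scale {sc.scale} cluster {cid} spans {uniq.size} coarse clusters"
                    )
                repaired += 1
            parent = int(uniq[np.argmax(counts)])
            nodes.append(HierarchyNode(sc.scale, cid, size, parent))
    return Hierarchy(nodes=tuple(nodes), repaired_parents=repaired)


@dataclass(frozen=True)
class WFCResult:
    """Everything a run produces: schedule, per-scale partitions, hierarchy, log."""

    schedule: ScaleSchedule
    per_scale: Tuple[ScaleClustering, ...]
    hierarchy: Hierarchy
    coding: str
    config: RunConfig
    log: Tuple[dict, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.per_scale[0].labels.shape[0]

    def labels_matrix(self) -> np.ndarray:
        """n x s_end matrix of per-scale cluster labels, original point order."""
        return np.stack([sc.labels for sc in self.per_scale], axis=1)


def _run_sd(X: Dataset, schedule: ScaleSchedule) -> Tuple[List[ScaleClustering], List[dict]]:
    per_scale, log = [], []
    for s in range(1, schedule.s_end + 1):
        delta = 1.0 / schedule.threshold_at(s)
        code = _sd.sd_encode(X, delta, scale=s)
        n_edges = 0

        def counted(gen):
            nonlocal n_edges
            for e in gen:
                n_edges += 1
                yield e

        sc = connected_components(X.n, counted(_sd.sd_link(code)), scale=s)
        per_scale.append(sc)
        log.append(
            {
                "scale": s,
                "threshold": schedule.threshold_at(s),
                "delta": delta,
                "edges": n_edges,
                "clusters": sc.n_clusters,
                "isolated": len(sc.isolated),
            }
        )
    return per_scale, log


def _run_dm(
    X: Optional[Dataset],
    codes: _dm.BinaryCodes,
    schedule: ScaleSchedule,
    cfg: RunConfig,
) -> Tuple[List[ScaleClustering], List[dict]]:
    n = len(codes)
    # banding cannot target below 1/k (the b=k, r=1 curve); clamp keeps the
    # most permissive factorization rather than failing the whole run
    t0 = min(max(schedule.thresholds[0], 1.0 / cfg.minhash_k), 1.0)
    if n <= cfg.brute_force_cutoff:
        cand = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif _dm.choose_bands_guaranteed(cfg.minhash_k, t0) is None:
        # grossest threshold too weak for reliable banding: join on shared markers
        cand = sorted(_dm.marker_join_pairs(codes))
    else:
        index = _dm.minhash_signatures(codes, k=cfg.minhash_k, seed=cfg.seed)
        cand = sorted(_dm.retrieve_candidates(index, codes, t0))
    # exact similarities computed once; per-scale edges are threshold filters
    # of this single list, so finer partitions exactly refine coarser ones
    sims = _dm.jaccard_for_pairs(codes, cand)
    cand = np.asarray(cand, dtype=np.int64).reshape(-1, 2)
    # finest scale first, adding edges as the threshold relaxes: each edge is
    # unioned exactly once, and the nesting of partitions is by construction
    order = np.argsort(-sims, kind="stable")
    uf = UnionFind(n)
    ptr = 0
    per_scale, log = [], []
    for s in range(schedule.s_end, 0, -1):
        t = schedule.threshold_at(s)
        while ptr < order.size and sims[order[ptr]] >= t:
            i, j = cand[order[ptr]]
            uf.union(int(i), int(j))
            ptr += 1
        sc = _snapshot(uf, n, scale=s)
        per_scale.append(sc)
        log.append(
            {
                "scale": s,
                "threshold": t,
                "edges": ptr,
                "clusters": sc.n_clusters,
                "isolated": len(sc.isolated),
            }
        )
    per_scale.reverse()
    log.reverse()
    return per_scale, log


def run_wfc(
    X: Dataset,
    lambda_: float = 1.0,
    coding: Optional[str] = None,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> WFCResult:
    """Cluster a dataset at every Weber-Fechner scale.

    Steps: encode points (SD re-encodes per scale at cell side delta^s; DM
    encodes once), estimate the global similarity bounds, build the threshold
    schedule, link similar pairs and take connected components at each scale,
    then assemble the cross-scale hierarchy.  Deterministic under
    (X, lambda_, config, seed).
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    cfg = replace(config) if config is not None else RunConfig()
    cfg.lambda_ = lambda_
    if seed is not None:
        cfg.seed = seed
    if coding is not None:
        cfg.coding = coding
    chosen = select_coding(X.n, X.d, override=cfg.coding)
    if chosen == "sd":
        sim_min, sim_max = estimate_similarity_bounds(
            X, mode="sd", sample_size=cfg.bounds_sample_size, seed=cfg.seed
        )
        schedule = build_schedule(sim_min, sim_max, cfg.lambda_)
        per_scale, log = _run_sd(X, schedule)
        hierarchy = build_hierarchy(per_scale, strict=False)
    else:
        if cfg.dm_mode == "top_m":
            codes = _dm.dm_encode(X, mode="top_m", m=cfg.dm_top_m)
        elif cfg.dm_mode == "binned":
            codes = _dm.dm_encode(X, mode="binned", B=cfg.dm_bins)
        else:
            codes = _dm.dm_encode(X, mode="nonzero")
        sim_min, sim_max = estimate_similarity_bounds(
            None, mode="dm", codes=codes, sample_size=cfg.bounds_sample_size, seed=cfg.seed
        )
        schedule = build_schedule(sim_min, sim_max, cfg.lambda_)
        per_scale, log = _run_dm(X, codes, schedule, cfg)
        hierarchy = build_hierarchy(per_scale, strict=cfg.exact_verify)
    return WFCResult(
        schedule=schedule,
        per_scale=tuple(per_scale),
        hierarchy=hierarchy,
        coding=chosen,
        config=cfg,
        log=tuple(log),
    )


def run_wfc_codes(
    codes: _dm.BinaryCodes,
    lambda_: float = 1.0,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> WFCResult:
    """DM-mode run directly on pre-built binary codes (e.g. planted sets)."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    cfg = replace(config) if config is not None else RunConfig()
    cfg.lambda_ = lambda_
    if seed is not None:
        cfg.seed = seed
    sim_min, sim_max = estimate_similarity_bounds(
        None, mode="dm", codes=codes, sample_size=cfg.bounds_sample_size, seed=cfg.seed
    )
    schedule = build_schedule(sim_min, sim_max, cfg.lambda_)
    per_scale, log = _run_dm(None, codes, schedule, cfg)
    hierarchy = build_hierarchy(per_scale, strict=cfg.exact_verify)
    return WFCResult(
        schedule=schedule,
        per_scale=tuple(per_scale),
        hierarchy=hierarchy,
        coding="dm",
        config=cfg,
        log=tuple(log),
    )
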