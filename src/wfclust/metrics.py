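"""Flat-clustering validation: purity and F1-measure against labeled classes.

Given clusters C and ground-truth classes L over n points, with co-occurrence
counts |c ∩ l|:

* global purity = (1/n) * sum_c max_l |c ∩ l| -- the fraction of points whose
  cluster's majority class matches their own;
* per-(c, l) recall R = |c ∩ l| / |l| and precision P = |c ∩ l| / |c|, with
  F1 = 2RP / (R + P); the global F1-measure is the mean over classes of each
  class's best F1 over clusters.

Isolated points are scored as singleton clusters by default: they are part of
the partition, and counting them penalizes over-fragmentation at fine scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ContingencyTable:
    """|C| x |L| co-occurrence counts between cluster and class assignments."""

    counts: np.ndarray
    cluster_ids: Tuple[int, ...]
    class_ids: Tuple

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def contingency(cluster_labels: Sequence, class_labels: Sequence) -> ContingencyTable:
    """Cross-tabulate cluster vs class assignments."""
    cl = pd.Series(list(cluster_labels))
    gt = pd.Series(list(class_labels))
    if len(cl) != len(gt):
        raise ValueError("cluster and class label vectors differ in length")
    if len(cl) == 0:
        raise ValueError("empty label vectors")
    tab = pd.crosstab(cl, gt)
    return ContingencyTable(
        counts=tab.to_numpy(dtype=np.int64),
        cluster_ids=tuple(tab.index),
        class_ids=tuple(tab.columns),
    )


def per_cluster_purity(table: ContingencyTable) -> np.ndarray:
    """max_l |c ∩ l| / |c| for each cluster, in table row order."""
    sizes = table.cluster_sizes
    if table.counts.size == 0 or table.n == 0:
        raise ValueError("empty contingency table")
    return table.counts.max(axis=1) / sizes


def purity(table: ContingencyTable) -> float:
    """Global purity: (1/n) * sum over clusters of the majority-class count."""
    if table.counts.size == 0 or table.n == 0:
        raise ValueError("empty contingency table")
    return float(table.counts.max(axis=1).sum() / table.n)


def f1_measure(table: ContingencyTable) -> float:
    """Mean over classes of the best per-cluster F1 (harmonic mean of R and P)."""
    counts = table.counts.astype(float)
    if counts.size == 0 or table.n == 0:
        raise ValueError("empty contingency table")
    class_sizes = table.class_sizes.astype(float)
    if (class_sizes == 0).any():
        raise ValueError("empty class in contingency table")
    cluster_sizes = table.cluster_sizes.astype(float)[:, None]
    R = counts / class_sizes[None, :]
    P = counts / cluster_sizes
    denom = R + P
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * R * P / denom, 0.0)
    return float(f1.max(axis=0).mean())


def high_quality_clusters(
    table: ContingencyTable, min_size: int = 100, min_purity: float = 0.9
) -> List:
    """Cluster ids passing both the size and per-cluster purity thresholds.

    The defaults (at least 100 members, purity at least 0.9) are the filter
    used when reporting high-quality cell clusters.
    """
    sizes = table.cluster_sizes
    pur = per_cluster_purity(table)
    return [
        cid
        for cid, sz, p in zip(table.cluster_ids, sizes, pur)
        if sz >= min_size and p >= min_purity
    ]


def best_match_per_class(table: ContingencyTable) -> Dict:
    """For each class: (best cluster id, recall, precision, F1); ties -> smaller index."""
    counts = table.counts.astype(float)
    out = {}
    for jl, lbl in enumerate(table.class_ids):
        col = counts[:, jl]
        with np.errstate(invalid="ignore", divide="ignore"):
            R = col / max(col.sum(), 1.0)
            P = col / table.cluster_sizes
            denom = R + P
            f1 = np.where(denom > 0, 2 * R * P / denom, 0.0)
        best = int(np.argmax(f1))  # argmax takes the smallest index on ties
        out[lbl] = (table.cluster_ids[best], float(R[best]), float(P[best]), float(f1[best]))
    return out


def scale_report(result, class_labels: Sequence) -> pd.DataFrame:
    """Per-scale metrics table: scale, n_clusters, n_isolated, purity, f1."""
    rows = []
    for sc in result.per_scale:
        tab = contingency(sc.labels, class_labels)
        rows.append(
            {
                "scale": sc.scale,
                "n_clusters": sc.n_clusters,
                "n_isolated": len(sc.isolated),
                "purity": purity(tab),
                "f1": f1_measure(tab),
            }
        )
    return pd.DataFrame(rows)
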