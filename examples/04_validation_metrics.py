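"""Purity and F1-measure on a hand-checkable contingency table.

Two clusters vs two classes with counts [[5, 1], [2, 4]] (n = 12):
purity = (5 + 4) / 12 = 0.75; class-wise best F1 values are 10/13 and 8/11,
so the global F1-measure is their mean.  The high-quality filter keeps only
clusters that are both large and pure.
"""

import numpy as np

from wfclust import f1_measure, high_quality_clusters, per_cluster_purity, purity
from wfclust.metrics import ContingencyTable

tab = ContingencyTable(counts=np.array([[5, 1], [2, 4]]),
                       cluster_ids=(0, 1), class_ids=("A", "B"))
print(f"purity     = {purity(tab):.4f}   (expected 0.75)")
print(f"F1-measure = {f1_measure(tab):.4f}   (expected (10/13 + 8/11)/2 = "
      f"{(10 / 13 + 8 / 11) / 2:.4f})")
print(f"per-cluster purity = {np.round(per_cluster_purity(tab), 3)}")

big = ContingencyTable(counts=np.array([[140, 10], [50, 0], [170, 30]]),
                       cluster_ids=(0, 1, 2), class_ids=("A", "B"))
kept = high_quality_clusters(big, min_size=100, min_purity=0.9)
print(f"high-quality clusters (>=100 members, purity >= 0.9): {kept}")
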