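"""DM coding on planted binary marker sets: Jaccard thresholds + MinHash/LSH.

Five clusters of 100 points each share disjoint 30-marker cores (10% of core
markers dropped per point, sparse background noise), so within-cluster Jaccard
(~0.7 expected) far exceeds between-cluster Jaccard (~0.005).  The multi-scale
run separates the clusters perfectly at intermediate thresholds, and because
the similarity graph only loses edges as the threshold rises, every finer
partition exactly refines the coarser one (zero repaired parent links).
"""

import numpy as np

from wfclust import PlantedBinarySpec, contingency, f1_measure, make_planted_binary, run_wfc_codes
from wfclust.synthetic import expected_between_jaccard, expected_within_jaccard

spec = PlantedBinarySpec(seed=0)
print(f"expected Jaccard: within {expected_within_jaccard(spec):.3f}, "
      f"between {expected_between_jaccard(spec):.3f}")

codes, labels = make_planted_binary(spec)
labels = np.array(labels)
res = run_wfc_codes(codes, lambda_=0.25, seed=0)
print(f"s_end = {res.schedule.s_end}, repaired parent links = "
      f"{res.hierarchy.repaired_parents}")

print("scale  threshold  clusters  F1")
for sc, rec in zip(res.per_scale, res.log):
    f1 = f1_measure(contingency(sc.labels, labels))
    print(f"{sc.scale:5d}  {rec['threshold']:9.4f}  {sc.n_clusters:8d}  {f1:.3f}")
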