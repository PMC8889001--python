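"""Run configuration: one scientific parameter, fixed defaults for the rest.

The method exposes a single tunable, the Weber fraction ``lambda_``; everything
else (coding choice, marker rule, sketch size, sampling) has a documented
default and is recorded alongside every result so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    lambda_: float = 1.0
    coding: str = "auto"          # auto | sd | dm
    dm_mode: str = "nonzero"      # nonzero | top_m | binned
    dm_top_m: int = 50
    dm_bins: int = 8
    minhash_k: int = 256
    seed: int = 0
    exact_verify: bool = True
    brute_force_cutoff: int = 600  # below this n, DM retrieval is exact all-pairs
    bounds_sample_size: int = 2000
    hvg: int = 2000
    min_cluster_size: int = 1      # presentation filter for reports only

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
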