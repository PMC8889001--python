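"""Build a Weber-Fechner observation schedule from similarity bounds.

The number of scales follows from the bounds and the Weber fraction alone:
s_end = floor(log_{1+lambda}(sim_max / sim_min)).  With a similarity ratio of
2^25 and lambda = 1 the ladder has exactly 25 scales, each threshold doubling
the previous one (equivalently, each Chebyshev cell side delta^s halving).
"""

from wfclust import build_schedule

sch = build_schedule(sim_min=1.0, sim_max=2**25, lambda_=1.0)
print(f"lambda = {sch.lambda_}, s_end = {sch.s_end}")
for s in (1, 2, 3, sch.s_end):
    print(f"  scale {s:2d}: sim_min^s = {sch.threshold_at(s):.6g}  "
          f"delta^s = {1 / sch.threshold_at(s):.6g}")

hyper = build_schedule(1.0, 2**25, 1.0, policy="hyper_exponential")
print(f"hyper-exponential policy reaches the same bounds in {hyper.s_end} scales")
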