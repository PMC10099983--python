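"""Attribute population growth variation to demographic pathways.

Runs the random-design transient LTRE on the generating rates of two
planted scenarios and shows that the analysis attributes the among-year
variance in growth to the pathway that actually carries it.
"""

from nestipm import ltre
from nestipm import simulate as sim

for scenario in ("immigration-driven", "reproduction-driven"):
    ds = sim.simulate_dataset(sim.planted_scenarios(scenario), seed=5)
    theta = ds.truth_theta_series()       # (T-1, 12) generating rates
    res = ltre.random_design(theta)
    grouped = res.grouped()
    print(f"scenario: {scenario}")
    print(f"  var(lambda_t) from decomposition : {res.total:.5f}")
    print(f"  sample var(lambda_t)             : {res.reference:.5f}")
    for group, value in sorted(grouped.items(), key=lambda kv: -abs(kv[1])):
        share = 100 * value / res.total if res.total else 0.0
        print(f"  {group:12s} {value:9.5f}  ({share:5.1f}% of total)")
    print()
# The dominant group matches the planted signal: the decomposition recovers
# which demographic pathway drives year-to-year population change.
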