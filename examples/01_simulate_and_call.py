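"""Simulate a two-condition splicing cohort and call dPSI.

Generates a synthetic genome with planted cryptic events (PSI 0 in
condition A, 0.5 in condition B), quantifies every local splicing
variation, and reports how many planted junctions reach the
high-confidence tier P(|dPSI| >= 0.2) >= 0.95.
"""

import numpy as np

import crypticsplice as cs

cfg = cs.SimulationConfig(seed=42, event_plan=cs.default_event_plan(5))
scenario = cs.simulate_scenario(cfg)
calls = cs.quantify_all(scenario.graph, scenario.table, seed=42)

confident = [c for c in calls if c.tier != "none"]
print(f"{len(calls)} junction calls across all LSVs; {len(confident)} at a tier")

hits, errors = 0, []
for truth in scenario.truth:
    lj = cs.SpliceJunction(truth.chrom, *truth.lsv_junction, truth.strand)
    best = max(
        (c for c in calls if c.junction == lj),
        key=lambda c: c.probs[0.2],
        default=None,
    )
    if best and best.probs[0.2] >= 0.95:
        hits += 1
    if best:
        errors.append(abs(abs(best.e_dpsi) - 0.5))

print(f"planted events recovered at tier V20: {hits}/{len(scenario.truth)}")
print(f"mean |E(dPSI) - 0.5| = {np.mean(errors):.3f}")
print("(the planted change is 0.5, so both numbers measure calling accuracy)")
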