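"""Classify confident splicing changes into the cryptic-event taxonomy.

Runs the noise-free default cohort end to end, prints the event-class
proportion table, and the fraction of cryptic internal exons whose
insertion would disrupt the protein reading frame.
"""

import crypticsplice as cs

cfg = cs.SimulationConfig(seed=7, noise_free=True)
scenario = cs.simulate_scenario(cfg)
calls = cs.quantify_all(scenario.graph, scenario.table, seed=7)
events = cs.classify_events(calls, scenario.graph, scenario.genome, scenario.table)

print(cs.summarize_event_types(events).to_string(index=False))

reports = cs.assess_events(events, scenario.graph, scenario.genome)
cryptic_ids = {e.event_id for e in events if e.event_class == "cryptic_internal_exon"}
frac = cs.disruptive_fraction([r for r in reports if r.event_id in cryptic_ids])
print(f"\ndisruptive fraction among cryptic internal exons: {frac:.2f}")
print("(the generator plants 84% of them frame-breaking, so ~0.84 is expected)")
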