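"""Splice-site strength percentiles: cryptic versus downstream exons.

Plants cryptic internal exons whose 3' splice sites carry two mismatches
from the acceptor consensus, scores every site with PWMs trained on the
annotated sites, and compares strength percentiles and ESE hexamer
densities between the cryptic exons and their downstream neighbours.
"""

import json

import crypticsplice as cs

cfg = cs.SimulationConfig(
    seed=3,
    event_plan=(cs.ClassPlan("cryptic_internal_exon", 10),),
    noise_free=True,
)
sc = cs.simulate_scenario(cfg)
calls = cs.quantify_all(sc.graph, sc.table, seed=3)
events = cs.classify_events(calls, sc.graph, sc.genome, sc.table)

donor_pwm, acceptor_pwm = cs.train_pwms_from_graph(sc.graph, sc.genome)
reference = {
    "donor": cs.reference_scores_from_graph(sc.graph, sc.genome, donor_pwm),
    "acceptor": cs.reference_scores_from_graph(sc.graph, sc.genome, acceptor_pwm),
}
ese = cs.EseModel(frozenset(["GAAGAA"]))
per_event, summary = cs.compare_cryptic_vs_downstream(
    events, sc.graph, sc.genome, donor_pwm, acceptor_pwm, ese, reference
)

print(json.dumps(summary, indent=1))
print("\nA low cryptic-acceptor mean percentile with p < 0.05 shows the planted")
print("weakness is detected; near-equal ESE densities show enhancer content is not")
print("what distinguishes the cryptic exons here.")
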