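import numpy as np
import pytest

import crypticsplice as cs


def tier_rank(tier: str) -> int:
    return 0 if tier == "none" else int(tier[1:])


def best_call_for(calls, junction):
    """Most confident call for a junction across its LSVs."""
    cands = [c for c in calls if c.junction == junction]
    return max(cands, key=lambda c: (tier_rank(c.tier), abs(c.e_dpsi)), default=None)


def recovered_class(truth, events):
    """Classes of events containing the planted primary junction."""
    pj = cs.SpliceJunction(truth.chrom, *truth.primary_junction, truth.strand)
    return [e.event_class for e in events if pj in e.junctions]


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Small noise-free scenario: 3 plants of each class, exact counts."""
    cfg = cs.SimulationConfig(
        seed=101,
        event_plan=cs.default_event_plan(3),
        n_background_genes=2,
        noise_free=True,
    )
    return cs.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def noise_free_events(noise_free_scenario):
    sc = noise_free_scenario
    calls = cs.quantify_all(sc.graph, sc.table, seed=7)
    events = cs.classify_events(calls, sc.graph, sc.genome, sc.table)
    return calls, events


@pytest.fixture(scope="session")
def cohort():
    """Strength/ESE comparison on 10 cryptic internal exons planted with
    two acceptor-consensus mismatches and equal ESE content."""
    cfg = cs.SimulationConfig(
        seed=31,
        event_plan=(cs.ClassPlan("cryptic_internal_exon", 10),),
        n_background_genes=1,
        noise_free=True,
        weak_mismatches=2,
    )
    sc = cs.simulate_scenario(cfg)
    calls = cs.quantify_all(sc.graph, sc.table, seed=3)
    events = cs.classify_events(calls, sc.graph, sc.genome, sc.table)
    donor_pwm, acceptor_pwm = cs.train_pwms_from_graph(sc.graph, sc.genome)
    ref = {
        "donor": cs.reference_scores_from_graph(sc.graph, sc.genome, donor_pwm),
        "acceptor": cs.reference_scores_from_graph(sc.graph, sc.genome, acceptor_pwm),
    }
    ese = cs.EseModel(frozenset(["GAAGAA"]))
    return cs.compare_cryptic_vs_downstream(
        events, sc.graph, sc.genome, donor_pwm, acceptor_pwm, ese, ref
    )


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    return cs.GenomeSequence({"c1": seq})
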