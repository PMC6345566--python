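import collections
import math

import pytest

import crypticsplice as cs
from crypticsplice import datasets as dsets
from conftest import recovered_class


@pytest.fixture(scope="module")
def graph():
    t = cs.TranscriptModel(
        "t1", "g1", "c1", "+",
        (
            cs.ExonInterval("c1", 0, 100, "+"),
            cs.ExonInterval("c1", 200, 300, "+"),
            cs.ExonInterval("c1", 400, 500, "+"),
        ),
    )
    return cs.SpliceGraph([t])


class TestFlagDeNovo:
    def test_annotated_junction(self, graph):
        f = cs.flag_de_novo(cs.SpliceJunction("c1", 100, 200, "+"), graph)
        assert (f.junction_annotated, f.donor_annotated, f.acceptor_annotated) == (
            True, True, True,
        )

    def test_novel_acceptor_annotated_donor(self, graph):
        f = cs.flag_de_novo(cs.SpliceJunction("c1", 100, 160, "+"), graph)
        assert (f.junction_annotated, f.donor_annotated, f.acceptor_annotated) == (
            False, True, False,
        )

    def test_fully_novel_junction(self, graph):
        f = cs.flag_de_novo(cs.SpliceJunction("c1", 120, 170, "+"), graph)
        assert (f.junction_annotated, f.donor_annotated, f.acceptor_annotated) == (
            False, False, False,
        )

    def test_strand_matters(self, graph):
        f = cs.flag_de_novo(cs.SpliceJunction("c1", 100, 200, "-"), graph)
        assert not f.junction_annotated and not f.donor_annotated


class TestAsymmetryRatio:
    def test_worked_example(self):
        assert cs.junction_asymmetry_ratio(140, 10) == 14.0

    def test_balanced(self):
        assert cs.junction_asymmetry_ratio(10, 10) == 1.0

    def test_zero_splice_out_is_infinite(self):
        assert math.isinf(cs.junction_asymmetry_ratio(100, 0))

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            cs.junction_asymmetry_ratio(0, 0)


class TestDetectTerminalExon:
    def test_asymmetric_with_signal(self):
        g, graph, table, exon = dsets.terminal_exon_fixture(140, 10, polya_offset=60)
        ev = cs.detect_terminal_exon(exon, table, g, min_ratio=5.0)
        assert ev is not None
        assert ev.asymmetry_ratio == 14.0
        assert ev.polya_signal == "AATAAA"
        assert ev.polya_position - exon.end == 60  # most proximal hit

    def test_balanced_counts_rejected(self):
        g, graph, table, exon = dsets.terminal_exon_fixture(10, 10)
        assert cs.detect_terminal_exon(exon, table, g, min_ratio=5.0) is None

    def test_signal_required(self):
        g, graph, table, exon = dsets.terminal_exon_fixture(
            100, 0, with_signal=False
        )
        assert cs.detect_terminal_exon(exon, table, g, min_ratio=5.0) is None

    def test_zero_splice_out_satisfies_ratio(self):
        g, graph, table, exon = dsets.terminal_exon_fixture(100, 0)
        ev = cs.detect_terminal_exon(exon, table, g, min_ratio=5.0)
        assert ev is not None and math.isinf(ev.asymmetry_ratio)


def _classify(fixture):
    g, graph, table = fixture
    calls = cs.quantify_all(graph, table, seed=1)
    return cs.classify_events(calls, graph, g, table)


class TestClassifyEvent:
    def test_internal_5ss_truncation_delta(self):
        """An exonic 5'ss 1407 nt upstream of the annotated donor removes
        1407 nt from the mature mRNA."""
        events = _classify(dsets.long_exon_internal_5ss_fixture(1407))
        assert [(e.event_class, e.delta_length) for e in events] == [
            ("alt5ss_truncation", -1407)
        ]
        ev = events[0]
        assert not ev.de_novo[ev.primary_junction].donor_annotated
        assert ev.de_novo[ev.primary_junction].acceptor_annotated

    def test_intronic_3ss_extension_delta(self):
        """An intronic 3'ss 1353 nt upstream of the annotated acceptor
        extends the exon by 1353 nt."""
        events = _classify(dsets.intron_3ss_extension_fixture(1353))
        assert [(e.event_class, e.delta_length) for e in events] == [
            ("alt3ss_extension", 1353)
        ]

    def test_exitron_classification(self):
        events = _classify(dsets.exitron_fixture(201))
        assert len(events) == 1
        ev = events[0]
        assert ev.event_class == "exitron"
        assert ev.delta_length == -201
        assert ev.dinucleotides[ev.primary_junction] == ("GT", "AG")
        assert not ev.non_canonical_donor

    def test_gc_donor_exitron_flagged(self):
        events = _classify(dsets.exitron_fixture(201, gc_donor=True))
        ev = events[0]
        assert ev.event_class == "exitron"
        assert ev.dinucleotides[ev.primary_junction] == ("GC", "AG")
        assert ev.non_canonical_donor

    def test_terminal_exon_event(self):
        g, graph, table, exon = dsets.terminal_exon_fixture(140, 10)
        calls = cs.quantify_all(graph, table, seed=1)
        events = cs.classify_events(calls, graph, g, table)
        assert [e.event_class for e in events] == ["cryptic_terminal_exon"]
        ev = events[0]
        assert ev.terminal_evidence.asymmetry_ratio == 14.0
        assert ev.exon == exon

    def test_mixed_strand_group_rejected(self, toy_genome):
        t = cs.TranscriptModel(
            "t1", "g1", "c1", "+",
            (cs.ExonInterval("c1", 0, 100, "+"),
             cs.ExonInterval("c1", 200, 300, "+")),
        )
        graph = cs.SpliceGraph([t])
        lsv = cs.LSVDefinition(
            "c1", 100, "+", "source",
            (cs.SpliceJunction("c1", 100, 200, "+"),
             cs.SpliceJunction("c1", 100, 250, "+")),
        )
        good = cs.DeltaPsiCall(lsv, lsv.junctions[0], 0.5, 0.5, 0.0,
                               {0.1: 0.0}, "none")
        bad = cs.DeltaPsiCall(lsv, cs.SpliceJunction("c1", 400, 500, "-"),
                              0.5, 0.5, 0.0, {0.1: 0.0}, "none")
        with pytest.raises(ValueError):
            cs.classify_event([good, bad], graph, toy_genome)


class TestRecoveryOnNoiseFreeData:
    def test_all_planted_classes_recovered(self, noise_free_scenario, noise_free_events):
        """Noise-free synthetic data: every planted event is recovered
        with its planted class."""
        _, events = noise_free_events
        for t in noise_free_scenario.truth:
            assert t.event_class in recovered_class(t, events), t

    def test_both_strands_represented_and_symmetric(
        self, noise_free_scenario, noise_free_events
    ):
        """The generator plants on both strands; class and |delta| recover
        identically regardless of strand."""
        _, events = noise_free_events
        strands = {t.strand for t in noise_free_scenario.truth}
        assert strands == {"+", "-"}
        for t in noise_free_scenario.truth:
            pj = cs.SpliceJunction(t.chrom, *t.primary_junction, t.strand)
            matches = [
                e for e in events
                if pj in e.junctions and e.event_class == t.event_class
            ]
            assert matches
            assert abs(matches[0].delta_length) == abs(t.delta_length)

    def test_cryptic_exon_boundaries_canonical(self, noise_free_events):
        """Cryptic internal exons planted with canonical sites report
        GT/GC-AG boundary dinucleotides."""
        _, events = noise_free_events
        checked = 0
        for ev in events:
            if ev.event_class != "cryptic_internal_exon":
                continue
            for j in ev.junctions:
                d, a = ev.dinucleotides[j]
                assert d in ("GT", "GC") and a == "AG"
            checked += 1
        assert checked >= 3


class TestSummarizeEventTypes:
    def _events(self, classes):
        out = []
        for i, cls in enumerate(classes):
            j = cs.SpliceJunction("c1", 100 + i * 10, 200 + i * 10, "+")
            out.append(
                cs.SpliceEvent(
                    event_id=f"E{i}", gene_id="g", chrom="c1", strand="+",
                    event_class=cls, junctions=(j,), primary_junction=j,
                    reference_junction=None, de_novo={}, dinucleotides={},
                    non_canonical_donor=False, delta_length=None,
                )
            )
        return out

    def test_two_classes_half_each(self):
        df = cs.summarize_event_types(
            self._events(["exitron", "exitron",
                          "alt5ss_truncation", "alt5ss_truncation"])
        )
        assert dict(zip(df.event_class, df.percent)) == {
            "exitron": 50.0, "alt5ss_truncation": 50.0,
        }

    def test_empty_list(self):
        assert len(cs.summarize_event_types([])) == 0

    def test_three_classes_sum_to_100(self):
        df = cs.summarize_event_types(
            self._events(["exitron", "annotated_cassette", "complex"])
        )
        assert abs(df.percent.sum() - 100.0) < 1e-9
        assert all(abs(p - 100 / 3) < 0.01 for p in df.percent)

    def test_stable_class_ordering(self):
        df = cs.summarize_event_types(
            self._events(["complex", "exitron", "annotated_cassette"])
        )
        order = [cs.EVENT_CLASSES.index(c) for c in df.event_class]
        assert order == sorted(order)
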