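from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crypticsplice as cs
from crypticsplice.clip import (
    CrosslinkSite,
    KmerConfig,
    annotate_region,
    control_windows,
    dinucleotide_shuffle,
    enrichment_vs_control,
    extract_windows,
    kmer_window_fractions,
    motif_position_map,
)

CFG = KmerConfig()


class TestExtractWindows:
    def test_window_geometry(self, toy_genome):
        w = extract_windows([CrosslinkSite("c1", 1000, "+")], toy_genome, CFG)
        assert len(w) == 1 and len(w[0]) == 101
        assert w[0] == toy_genome.fetch("c1", 950, 1051)

    def test_boundary_sites_dropped(self, toy_genome):
        w = extract_windows(
            [CrosslinkSite("c1", 10, "+"), CrosslinkSite("c1", 3995, "+")],
            toy_genome,
            CFG,
        )
        assert w == []

    def test_minus_strand_reverse_complement_oracle(self, toy_genome):
        plus, minus = (
            extract_windows([CrosslinkSite("c1", 1000, s)], toy_genome, CFG)[0]
            for s in "+-"
        )
        assert minus == cs.reverse_complement(plus)

    def test_n_windows_dropped(self):
        g = cs.GenomeSequence({"c": "A" * 200 + "N" + "A" * 200})
        assert extract_windows([CrosslinkSite("c", 200, "+")], g, CFG) == []


class TestKmerFractions:
    def test_once_per_window_rule(self):
        f = kmer_window_fractions(["A" * 101], CFG)
        assert f["AAAAA"] == 1.0  # counted once despite 97 occurrences

    def test_absent_kmer_zero(self):
        f = kmer_window_fractions(["A" * 101], CFG)
        assert f.get("CCCCC", 0.0) == 0.0

    def test_fraction_of_windows(self):
        wins = ["TGAAG" + "C" * 96, "C" * 101, "CC" + "TGAAG" + "C" * 94, "G" * 101]
        assert kmer_window_fractions(wins, CFG)["TGAAG"] == 0.5

    def test_matches_brute_force_presence_scan(self, toy_genome):
        rng = np.random.default_rng(8)
        sites = [CrosslinkSite("c1", int(p), "+")
                 for p in rng.integers(60, 3900, size=40)]
        wins = extract_windows(sites, toy_genome, CFG)
        fractions = kmer_window_fractions(wins, CFG)
        # oracle: exhaustive presence scan
        for kmer in list(fractions)[::17] + ["AAAAA", "ACGTA"]:
            present = sum(kmer in w for w in wins)
            assert fractions.get(kmer, 0.0) == present / len(wins)

    def test_empty_windows_error(self):
        with pytest.raises(ValueError):
            kmer_window_fractions([], CFG)


class TestEnrichment:
    def test_identity_gives_zero(self):
        f = {"AAAAA": 0.4, "CCCCC": 0.1}
        df = enrichment_vs_control(f, dict(f), pseudo=0.01)
        assert np.allclose(df.log2_enrichment, 0.0)

    def test_closed_form(self):
        df = enrichment_vs_control(
            {"TGAAG": 0.8}, {"TGAAG": 0.2}, pseudo=0.01, n_obs=100, n_ctrl=100
        )
        assert df.log2_enrichment[0] == pytest.approx(np.log2(0.81 / 0.21))
        assert df.log2_enrichment[0] == pytest.approx(1.9476, abs=1e-3)
        assert df.z[0] > 0

    def test_rank_ordering_and_aa_flag(self):
        df = enrichment_vs_control(
            {"TGAAG": 0.9, "CCCCC": 0.3, "GGGGG": 0.3},
            {"TGAAG": 0.1, "CCCCC": 0.3, "GGGGG": 0.3},
            pseudo=0.01,
        )
        assert list(df["rank"]) == [1, 2, 3]
        assert df.iloc[0]["kmer"] == "TGAAG"
        assert bool(df.iloc[0]["contains_AA"])
        # ties broken lexicographically
        assert list(df["kmer"][1:]) == ["CCCCC", "GGGGG"]

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            enrichment_vs_control({"AAAAA": 0.5}, {"AAAA": 0.5}, pseudo=0.01)


class TestDinucleotideShuffle:
    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=80), st.integers(0, 10**6))
    def test_preserves_dinucleotide_census(self, seq, seed):
        rng = np.random.default_rng(seed)
        out = dinucleotide_shuffle(seq, rng)
        assert len(out) == len(seq)
        assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_deterministic_given_seed(self):
        seq = "ACGTACGGTTACGATCGATCGGGTACAA"
        a = control_windows([seq], seed=3)
        b = control_windows([seq], seed=3)
        assert a == b

    def test_homopolymer_unchanged(self):
        rng = np.random.default_rng(0)
        assert dinucleotide_shuffle("AAAAAA", rng) == "AAAAAA"

    def test_actually_shuffles(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=101))
        outs = {dinucleotide_shuffle(seq, rng) for _ in range(5)}
        assert any(o != seq for o in outs)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            control_windows(["ACGT"], mode="markov")


@pytest.fixture(scope="module")
def graph():
    coding = cs.TranscriptModel(
        "t1", "g1", "c1", "+",
        (cs.ExonInterval("c1", 100, 300, "+"),
         cs.ExonInterval("c1", 500, 800, "+")),
        cds_start=200, cds_end=700,
    )
    nc = cs.TranscriptModel(
        "t2", "g2", "c1", "-",
        (cs.ExonInterval("c1", 2000, 2200, "-"),
         cs.ExonInterval("c1", 2400, 2600, "-")),
    )
    return cs.SpliceGraph([coding, nc])


class TestAnnotateRegion:
    @pytest.mark.parametrize(
        "pos, strand, region",
        [
            (250, "+", "CDS"),
            (150, "+", "5UTR"),  # exonic, upstream of the CDS start
            (750, "+", "3UTR"),
            (400, "+", "intron"),
            (50, "+", "intergenic"),
            (2100, "-", "ncRNA_exon"),
            (2300, "-", "intron"),
            (2100, "+", "intergenic"),  # strand-matched lookup
        ],
    )
    def test_regions(self, graph, pos, strand, region):
        assert annotate_region(CrosslinkSite("c1", pos, strand), graph) == region

    def test_cds_beats_intron_priority(self):
        a = cs.TranscriptModel(
            "a", "g", "c1", "+",
            (cs.ExonInterval("c1", 100, 400, "+"),),
            cds_start=150, cds_end=350,
        )
        b = cs.TranscriptModel(
            "b", "g", "c1", "+",
            (cs.ExonInterval("c1", 50, 80, "+"),
             cs.ExonInterval("c1", 500, 600, "+")),
        )
        graph = cs.SpliceGraph([a, b])
        assert annotate_region(CrosslinkSite("c1", 200, "+"), graph) == "CDS"

    def test_uniform_sites_match_span_geometry(self, noise_free_scenario):
        """Uniformly placed crosslink sites annotate as intronic at about
        the genes' intronic span fraction."""
        sc = noise_free_scenario
        sites = cs.simulate_crosslinks(
            sc, n_sites=800, planted=(), placement="uniform"
        )
        from crypticsplice.clip import region_distribution

        df = region_distribution(sites, sc.graph).set_index("region")
        intron_frac = df.loc["intron", "fraction"]
        spans = [sc.graph.gene_span(g) for g in sc.graph.genes]
        total = sum(hi - lo for _, lo, hi, _ in spans)
        exonic = sum(
            len(e)
            for t in sc.graph.transcripts.values()
            if t.transcript_id.endswith(".t1")
            for e in t.exons
        )
        expected = 1 - exonic / total
        assert abs(intron_frac - expected) < 0.05
        assert df.loc["intergenic", "count"] == 0


class TestMotifPositionMap:
    def test_planted_offset_peaks(self):
        g, jsets = cs.simulate_motif_map_fixture(seed=2, intron_offset=10)
        mm = motif_position_map(jsets, g, ["TGAAG"], side="acceptor",
                                exon_extent=30, intron_extent=60, smooth=3)
        reg, con = mm.tracks["regulated"], mm.tracks["control"]
        peak = mm.offsets[int(np.argmax(reg))]
        assert -10 <= peak <= -5  # k-mer spans offsets [-10, -6]
        assert reg.max() > 0.8
        assert con.max() < 0.1

    def test_identical_sets_ratio_one(self):
        g, jsets = cs.simulate_motif_map_fixture(seed=3)
        same = {"regulated": jsets["regulated"], "control": jsets["regulated"]}
        mm = motif_position_map(same, g, ["TGAAG"], exon_extent=20,
                                intron_extent=40)
        defined = ~np.isnan(mm.ratio)
        assert np.allclose(mm.ratio[defined], 1.0)

    def test_absent_kmer_zero_tracks(self, toy_genome):
        juncs = [cs.SpliceJunction("c1", 500, 700, "+")]
        mm = motif_position_map(
            {"regulated": juncs, "control": juncs},
            toy_genome,
            ["NNNNN"],
            exon_extent=10,
            intron_extent=10,
        )
        assert all(np.all(t == 0) for t in mm.tracks.values())

    def test_empty_set_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            motif_position_map({"regulated": []}, toy_genome, ["AAAAA"])
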