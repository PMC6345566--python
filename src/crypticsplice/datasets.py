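"""Small deterministic worked-example fixtures.

Each builder returns (genome, graph, table): a single synthetic gene with
canonical annotated splice sites, one planted splicing change, and a
two-condition junction-count table in which the change appears only in
condition B.  They mirror the hallmark cryptic-splicing geometries — an
exon-internal 5' splice site removing a long in-frame segment, a cryptic
3' splice site extending an exon from within the upstream intron, an
exitron, and a premature terminal exon whose inclusion junction carries
far more reads than its splice-out junction and is followed by an AATAAA
polyadenylation signal.
"""

from __future__ import annotations

import numpy as np

from .genome import ExonInterval, GenomeSequence, SpliceGraph, SpliceJunction, TranscriptModel
from .psi import JunctionCountTable, Sample
from .synthetic import ACCEPTOR_TAIL, DONOR_HEAD, EXON_HEAD, EXON_TAIL, POLYA_SIGNAL


def _background(rng, n):
    return list(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]))


def _stamp(seq, pos, s):
    seq[pos : pos + len(s)] = list(s)


def _three_exon_gene(rng, exon_lens, intron_lens, cds=(30, -30)):
    """Lay out a three-exon '+'-strand gene; returns (seq, exon bounds)."""
    bounds, pos = [], 0
    for i, le in enumerate(exon_lens):
        bounds.append((pos, pos + le))
        pos += le
        if i < len(intron_lens):
            pos += intron_lens[i]
    seq = _background(rng, pos)
    for i in range(len(intron_lens)):
        s, e = bounds[i][1], bounds[i + 1][0]
        _stamp(seq, bounds[i][1] - 3, EXON_TAIL)
        _stamp(seq, s, DONOR_HEAD)
        _stamp(seq, e - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL)
        _stamp(seq, e, EXON_HEAD)
    return seq, bounds


def _table(junction_counts: dict, n_rep: int = 1) -> JunctionCountTable:
    """counts: junction -> (count_A, count_B), replicated per condition."""
    samples = [Sample(f"A{i+1}", "A") for i in range(n_rep)] + [
        Sample(f"B{i+1}", "B") for i in range(n_rep)
    ]
    junctions = sorted(junction_counts)
    mat = np.array(
        [[junction_counts[j][0]] * n_rep + [junction_counts[j][1]] * n_rep
         for j in junctions],
        dtype=np.int64,
    )
    return JunctionCountTable(junctions, samples, mat)


def long_exon_internal_5ss_fixture(
    removed_nt: int = 1407, seed: int = 0, depth: int = 100
):
    """An unusually long CDS exon gains an internal (exonic) 5' splice
    site removed_nt upstream of its annotated donor; using it deletes
    removed_nt nucleotides from the mature mRNA (in frame when removed_nt
    is a multiple of three)."""
    rng = np.random.default_rng(seed)
    long_len = removed_nt + 139
    seq, bounds = _three_exon_gene(rng, [200, long_len, 200], [300, 300])
    chrom = "chrF"
    (e0, e1, e2) = bounds
    p = e1[1] - removed_nt  # the internal donor
    _stamp(seq, p - 3, EXON_TAIL)
    _stamp(seq, p, DONOR_HEAD)
    cds = (e0[0] + 30, e2[1] - 30)
    # keep the deletion's junction codon clean of stops
    u = (e0[1] - cds[0]) + (p - e1[0])
    r = u % 3
    if r and "".join(seq[p - r : p]) + "".join(seq[e2[0] : e2[0] + 3 - r]) in (
        "TAA", "TAG", "TGA",
    ):
        seq[p - r] = "C"
    genome = GenomeSequence({chrom: "".join(seq)})
    t = TranscriptModel(
        "F1.t1", "F1", chrom, "+",
        tuple(ExonInterval(chrom, s, e, "+") for s, e in bounds),
        cds_start=cds[0], cds_end=cds[1],
    )
    graph = SpliceGraph([t])
    ann1 = SpliceJunction(chrom, e0[1], e1[0], "+")
    ann2 = SpliceJunction(chrom, e1[1], e2[0], "+")
    alt = SpliceJunction(chrom, p, e2[0], "+")
    table = _table({
        ann1: (depth, depth),
        ann2: (depth, depth // 2),
        alt: (0, depth - depth // 2),
    })
    return genome, graph, table


def intron_3ss_extension_fixture(added_nt: int = 1353, seed: int = 0, depth: int = 100):
    """A cryptic 3' splice site inside the upstream intron extends an
    annotated exon by added_nt nucleotides."""
    rng = np.random.default_rng(seed)
    seq, bounds = _three_exon_gene(rng, [200, 180, 200], [added_nt + 200, 300])
    chrom = "chrF"
    (e0, e1, e2) = bounds
    q = e1[0] - added_nt  # the cryptic acceptor boundary
    _stamp(seq, q - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL)
    _stamp(seq, q, EXON_HEAD)
    genome = GenomeSequence({chrom: "".join(seq)})
    t = TranscriptModel(
        "F2.t1", "F2", chrom, "+",
        tuple(ExonInterval(chrom, s, e, "+") for s, e in bounds),
        cds_start=e0[0] + 30, cds_end=e2[1] - 30,
    )
    graph = SpliceGraph([t])
    ann1 = SpliceJunction(chrom, e0[1], e1[0], "+")
    ann2 = SpliceJunction(chrom, e1[1], e2[0], "+")
    alt = SpliceJunction(chrom, e0[1], q, "+")
    table = _table({
        ann1: (depth, depth // 2),
        ann2: (depth, depth),
        alt: (0, depth - depth // 2),
    })
    return genome, graph, table


def exitron_fixture(length: int = 201, gc_donor: bool = False, seed: int = 0,
                    depth: int = 100):
    """An exon-internal donor/acceptor pair whose use removes an interior
    exon segment (a multiple of three) as an intron."""
    if length % 3:
        raise ValueError("exitron length must be a multiple of three")
    rng = np.random.default_rng(seed)
    seq, bounds = _three_exon_gene(rng, [200, length + 160, 200], [300, 300])
    chrom = "chrF"
    (e0, e1, e2) = bounds
    d = e1[0] + 50
    a = d + length
    _stamp(seq, d - 3, EXON_TAIL)
    _stamp(seq, d, "GCAAGT" if gc_donor else DONOR_HEAD)
    _stamp(seq, a - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL)
    _stamp(seq, a, EXON_HEAD)
    genome = GenomeSequence({chrom: "".join(seq)})
    t = TranscriptModel(
        "F3.t1", "F3", chrom, "+",
        tuple(ExonInterval(chrom, s, e, "+") for s, e in bounds),
        cds_start=e0[0] + 30, cds_end=e2[1] - 30,
    )
    graph = SpliceGraph([t])
    ann1 = SpliceJunction(chrom, e0[1], e1[0], "+")
    ann2 = SpliceJunction(chrom, e1[1], e2[0], "+")
    cryptic_a = SpliceJunction(chrom, e0[1], a, "+")  # prev donor -> internal 3'ss
    interior = SpliceJunction(chrom, d, a, "+")  # the exitron intron
    table = _table({
        ann1: (depth, depth // 2),
        ann2: (depth, depth),
        cryptic_a: (0, 30),
        interior: (0, 22),
    })
    return genome, graph, table


def terminal_exon_fixture(
    inclusion: int = 140,
    splice_out: int = 10,
    polya_offset: int = 60,
    exon_len: int = 120,
    seed: int = 0,
    with_signal: bool = True,
):
    """A cryptic exon in the 5'UTR intron whose inclusion junction carries
    inclusion reads against splice_out reads leaving it, with an AATAAA
    signal polya_offset nt downstream of its 3' end."""
    rng = np.random.default_rng(seed)
    seq, bounds = _three_exon_gene(rng, [200, 300, 200], [1000, 300])
    chrom = "chrF"
    (e0, e1, e2) = bounds
    ce_start = e0[1] + 400
    ce_end = ce_start + exon_len
    _stamp(seq, ce_start - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL)
    _stamp(seq, ce_start, EXON_HEAD)
    _stamp(seq, ce_end - 3, EXON_TAIL)
    _stamp(seq, ce_end, DONOR_HEAD)
    # scrub chance polyadenylation signals from the host intron, then plant
    s, e = e0[1], e1[0]
    intron = "".join(seq[s:e])
    hit = intron.find(POLYA_SIGNAL)
    while hit != -1:
        seq[s + hit + 2] = "C"
        intron = "".join(seq[s:e])
        hit = intron.find(POLYA_SIGNAL)
    if with_signal:
        _stamp(seq, ce_end + polya_offset, POLYA_SIGNAL)
    genome = GenomeSequence({chrom: "".join(seq)})
    # the CDS sits in the second exon, so the cryptic exon is 5'UTR
    t = TranscriptModel(
        "F4.t1", "F4", chrom, "+",
        tuple(ExonInterval(chrom, s_, e_, "+") for s_, e_ in bounds),
        cds_start=e1[0] + 30, cds_end=e2[1] - 30,
    )
    graph = SpliceGraph([t])
    skip = SpliceJunction(chrom, e0[1], e1[0], "+")
    j_up = SpliceJunction(chrom, e0[1], ce_start, "+")
    j_down = SpliceJunction(chrom, ce_end, e1[0], "+")
    ann2 = SpliceJunction(chrom, e1[1], e2[0], "+")
    table = _table({
        skip: (150, 10),
        j_up: (0, inclusion),
        j_down: (0, splice_out),
        ann2: (150, 150),
    })
    exon = ExonInterval(chrom, ce_start, ce_end, "+")
    return genome, graph, table, exon
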