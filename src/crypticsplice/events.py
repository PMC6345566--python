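"""Classification of confident splicing changes into the cryptic-event taxonomy.

Event classes: annotated cassette exon, cryptic (de-novo) internal exon,
alternative 5'/3' splice-site extension or truncation, exitron (an exon with
internal splice sites), cryptic terminal exon (coupled to a downstream
polyadenylation signal), or complex.

An *event group* is the connected component of dPSI calls linked by shared
junctions.  Within a group the classifier distinguishes

* changing junctions — calls at a confidence tier,
* the reference junction — the annotated member with the highest pooled
  count (ties to the leftmost coordinate), and
* companion junctions — de-novo junctions with reads that never reach a
  tier on their own.  A terminal exon's splice-out junction and an
  exitron's interior junction are typical companions: the first is
  depleted by premature polyadenylation, the second sits in an LSV with no
  reads at all in the control condition, where the posterior stays at its
  prior and dPSI cannot be confident.

Rules are applied in a fixed order so classification is deterministic:
exitron, then cassette-type geometry (tested for terminal-exon evidence
before being labelled), then alternative splice sites, else complex.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome import (
    ExonInterval,
    GenomeSequence,
    SpliceGraph,
    SpliceJunction,
    acceptor_position,
    donor_position,
    junction_boundary_dinucleotides,
    reverse_complement,
)
from .psi import DeltaPsiCall, JunctionCountTable

log = logging.getLogger(__name__)

EVENT_CLASSES = (
    "annotated_cassette",
    "cryptic_internal_exon",
    "alt5ss_extension",
    "alt5ss_truncation",
    "alt3ss_extension",
    "alt3ss_truncation",
    "exitron",
    "cryptic_terminal_exon",
    "complex",
)

DEFAULT_POLYA_SIGNALS = ("AATAAA",)
DEFAULT_POLYA_WINDOW = 500
DEFAULT_MIN_RATIO = 5.0


@dataclass(frozen=True)
class TerminalExonConfig:
    window_nt: int = DEFAULT_POLYA_WINDOW
    signal_set: tuple[str, ...] = DEFAULT_POLYA_SIGNALS
    min_ratio: float = DEFAULT_MIN_RATIO


@dataclass(frozen=True)
class DeNovoFlags:
    junction_annotated: bool
    donor_annotated: bool
    acceptor_annotated: bool

    @property
    def any_de_novo(self) -> bool:
        return not (self.donor_annotated and self.acceptor_annotated)


@dataclass
class TerminalExonEvidence:
    exon: ExonInterval
    inclusion_count: int
    splice_out_count: int
    asymmetry_ratio: float
    polya_signal: Optional[str]
    polya_position: Optional[int]  # genomic start of the most proximal hit


@dataclass
class SpliceEvent:
    event_id: str
    gene_id: Optional[str]
    chrom: str
    strand: str
    event_class: str
    junctions: tuple[SpliceJunction, ...]
    primary_junction: SpliceJunction
    reference_junction: Optional[SpliceJunction]
    de_novo: Mapping[SpliceJunction, DeNovoFlags]
    dinucleotides: Mapping[SpliceJunction, tuple[str, str]]
    non_canonical_donor: bool
    delta_length: Optional[int]
    exon: Optional[ExonInterval] = None
    terminal_evidence: Optional[TerminalExonEvidence] = None
    calls: tuple[DeltaPsiCall, ...] = ()

    @property
    def tier(self) -> str:
        tiers = [c.tier for c in self.calls if c.tier != "none"]
        return max(tiers, default="none")

    @property
    def e_dpsi(self) -> float:
        changing = [c for c in self.calls if c.junction == self.primary_junction]
        return changing[0].e_dpsi if changing else float("nan")


def flag_de_novo(j: SpliceJunction, graph: SpliceGraph) -> DeNovoFlags:
    """Annotation status of the junction and of its two splice sites."""
    return DeNovoFlags(
        junction_annotated=graph.junction_annotated(j),
        donor_annotated=graph.donor_annotated(j.chrom, donor_position(j), j.strand),
        acceptor_annotated=graph.acceptor_annotated(
            j.chrom, acceptor_position(j), j.strand
        ),
    )


def junction_asymmetry_ratio(inclusion_count: int, splice_out_count: int) -> float:
    """Inclusion/splice-out read ratio; +inf when nothing splices out."""
    if inclusion_count < 0 or splice_out_count < 0:
        raise ValueError("counts must be >= 0")
    if inclusion_count == 0 and splice_out_count == 0:
        raise ValueError("asymmetry undefined when both counts are zero")
    if splice_out_count == 0:
        return math.inf
    return inclusion_count / splice_out_count


def _scan_signal(seq: str, signal_set: Sequence[str]) -> tuple[Optional[str], int]:
    """Most proximal signal hit in a 5'->3' sequence; (-1 if absent)."""
    best = (None, -1)
    for sig in signal_set:
        pos = seq.find(sig)
        if pos != -1 and (best[1] == -1 or pos < best[1]):
            best = (sig, pos)
    return best


def detect_terminal_exon(
    exon: ExonInterval,
    table: JunctionCountTable,
    genome: GenomeSequence,
    window_nt: int = DEFAULT_POLYA_WINDOW,
    signal_set: Sequence[str] = DEFAULT_POLYA_SIGNALS,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> Optional[TerminalExonEvidence]:
    """Terminal-exon evidence: read asymmetry plus a downstream polyA signal.

    Inclusion reads are junctions spliced *into* the exon's 5' end,
    splice-out reads junctions spliced *out of* its 3' end.  Evidence is
    returned only when the asymmetry ratio reaches min_ratio (zero
    splice-out counts satisfy it) AND a signal hexamer occurs on the
    transcribed strand within window_nt downstream of the exon's 3' end.
    """
    if window_nt <= 0:
        raise ValueError("window_nt must be > 0")
    if not signal_set:
        raise ValueError("signal_set must be non-empty")
    if exon.strand == "+":
        start5, end3 = exon.start, exon.end
    else:
        start5, end3 = exon.end, exon.start
    inclusion = splice_out = 0
    for j in table.junctions:
        if j.chrom != exon.chrom or j.strand != exon.strand:
            continue
        if acceptor_position(j) == start5:
            inclusion += table.pooled_count(j)
        if donor_position(j) == end3:
            splice_out += table.pooled_count(j)
    if inclusion == 0 and splice_out == 0:
        return None
    ratio = junction_asymmetry_ratio(inclusion, splice_out)
    if ratio < min_ratio:
        return None
    if exon.strand == "+":
        lo = exon.end
        hi = min(genome.chrom_length(exon.chrom), exon.end + window_nt)
        if lo >= hi:
            return None
        seq = genome.fetch(exon.chrom, lo, hi)
        sig, off = _scan_signal(seq, signal_set)
        pos = lo + off if sig else None
    else:
        lo = max(0, exon.start - window_nt)
        hi = exon.start
        if lo >= hi:
            return None
        seq = reverse_complement(genome.fetch(exon.chrom, lo, hi))
        sig, off = _scan_signal(seq, signal_set)
        pos = hi - off - len(sig) if sig else None
    if sig is None:
        return None
    return TerminalExonEvidence(
        exon=exon,
        inclusion_count=inclusion,
        splice_out_count=splice_out,
        asymmetry_ratio=ratio,
        polya_signal=sig,
        polya_position=pos,
    )


def group_lsv_calls(calls: Iterable[DeltaPsiCall]) -> list[list[DeltaPsiCall]]:
    """Connected components of calls linked by shared junctions or LSVs."""
    calls = list(calls)
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_junction: dict[SpliceJunction, int] = {}
    by_lsv: dict[str, int] = {}
    for i, c in enumerate(calls):
        if c.junction in by_junction:
            union(by_junction[c.junction], i)
        else:
            by_junction[c.junction] = i
        if c.lsv_id in by_lsv:
            union(by_lsv[c.lsv_id], i)
        else:
            by_lsv[c.lsv_id] = i
    groups: dict[int, list[DeltaPsiCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(find(i), []).append(c)
    return sorted(
        groups.values(),
        key=lambda g: (g[0].junction.chrom, min(c.junction.start for c in g)),
    )


def _tier_rank(t: str) -> int:
    if t == "none":
        return 0
    return int(t[1:])


def classify_event(
    lsv_calls: Sequence[DeltaPsiCall],
    graph: SpliceGraph,
    genome: GenomeSequence,
    table: Optional[JunctionCountTable] = None,
    terminal_cfg: Optional[TerminalExonConfig] = None,
    event_id: str = "E1",
    min_companion_count: int = 1,
) -> Optional[SpliceEvent]:
    """Classify one event group; None when nothing in the group changes."""
    terminal_cfg = terminal_cfg or TerminalExonConfig()
    strands = {c.junction.strand for c in lsv_calls}
    chroms = {c.junction.chrom for c in lsv_calls}
    if len(strands) > 1 or len(chroms) > 1:
        raise ValueError("event group mixes strands or chromosomes")
    strand, chrom = strands.pop(), chroms.pop()

    # one call per junction, keeping the most confident
    best: dict[SpliceJunction, DeltaPsiCall] = {}
    for c in lsv_calls:
        prev = best.get(c.junction)
        if prev is None or _tier_rank(c.tier) > _tier_rank(prev.tier):
            best[c.junction] = c
    junctions = sorted(best)
    flags = {j: flag_de_novo(j, graph) for j in junctions}
    dinucs = {j: junction_boundary_dinucleotides(j, genome) for j in junctions}

    changing = [j for j in junctions if best[j].tier != "none"]
    if not changing:
        return None
    annotated = [j for j in junctions if flags[j].junction_annotated]
    ref = None
    if annotated:
        pooled = (lambda j: table.pooled_count(j)) if table else (lambda j: 0)
        ref = max(annotated, key=lambda j: (pooled(j), -j.start))
    # the reference junction changes complementarily to the alternative
    # junction(s); geometry rules act on the non-reference changers
    changing = [j for j in changing if j != ref]
    if not changing:
        # only the reference moved: no interpretable alternative geometry
        j0 = ref
        return SpliceEvent(
            event_id=event_id,
            gene_id=graph.gene_at(chrom, j0.start, strand),
            chrom=chrom,
            strand=strand,
            event_class="complex",
            junctions=(j0,),
            primary_junction=j0,
            reference_junction=ref,
            de_novo={j0: flags[j0]},
            dinucleotides={j0: dinucs[j0]},
            non_canonical_donor=False,
            delta_length=None,
            calls=(best[j0],),
        )
    companions = [
        j
        for j in junctions
        if j not in changing
        and not flags[j].junction_annotated
        and (table is None or table.pooled_count(j) >= min_companion_count)
    ]

    def finish(cls, primary, delta, exon=None, evidence=None):
        involved = tuple(sorted(set(changing + companions + ([ref] if ref else []))))
        non_canon = any(
            dinucs[j][0] != "GT" for j in involved if not flags[j].junction_annotated
        )
        gene = graph.gene_at(chrom, primary.start, strand) or (
            graph.gene_at(chrom, ref.start, strand) if ref else None
        )
        return SpliceEvent(
            event_id=event_id,
            gene_id=gene,
            chrom=chrom,
            strand=strand,
            event_class=cls,
            junctions=involved,
            primary_junction=primary,
            reference_junction=ref,
            de_novo={j: flags[j] for j in involved},
            dinucleotides={j: dinucs[j] for j in involved},
            non_canonical_donor=non_canon,
            delta_length=delta,
            exon=exon,
            terminal_evidence=evidence,
            calls=tuple(best[j] for j in involved if j in best),
        )

    # (1) exitron: a de-novo junction with both splice sites strictly inside
    # one annotated exon.
    for j in changing + companions:
        if flags[j].junction_annotated:
            continue
        host = graph.exon_strictly_containing(j)
        if host is not None:
            return finish("exitron", j, -(j.end - j.start), exon=host)

    # (2) cassette-type geometry: two junctions delimiting an exon-sized
    # interval, outer splice sites annotated.  Tested for terminal-exon
    # evidence before being labelled cassette / cryptic internal exon.
    candidates = sorted(set(changing + companions))
    for ja, jb in itertools.combinations(candidates, 2):
        if ja.start > jb.start:
            ja, jb = jb, ja
        if ja.end >= jb.start:
            continue
        if ja not in changing and jb not in changing:
            continue
        # outer boundaries: site at ja.start and at jb.end
        if strand == "+":
            outer_ok = flags[ja].donor_annotated and flags[jb].acceptor_annotated
            inner_de_novo = (
                not flags[ja].acceptor_annotated or not flags[jb].donor_annotated
            )
            j_in = ja
        else:
            outer_ok = flags[ja].acceptor_annotated and flags[jb].donor_annotated
            inner_de_novo = (
                not flags[ja].donor_annotated or not flags[jb].acceptor_annotated
            )
            j_in = jb
        if not outer_ok:
            continue
        exon = ExonInterval(chrom, ja.end, jb.start, strand)
        evidence = None
        if table is not None:
            evidence = detect_terminal_exon(
                exon,
                table,
                genome,
                window_nt=terminal_cfg.window_nt,
                signal_set=terminal_cfg.signal_set,
                min_ratio=terminal_cfg.min_ratio,
            )
        if evidence is not None:
            return finish(
                "cryptic_terminal_exon", j_in, len(exon), exon=exon, evidence=evidence
            )
        cls = "cryptic_internal_exon" if inner_de_novo else "annotated_cassette"
        return finish(cls, j_in, len(exon), exon=exon)

    # (3)/(4) alternative splice sites: one changing junction sharing an
    # anchor with the reference junction.
    if ref is not None and len(changing) == 1 and changing[0] != ref:
        j = changing[0]
        delta = ref.intron_length - j.intron_length
        shares_acceptor = acceptor_position(j) == acceptor_position(ref)
        shares_donor = donor_position(j) == donor_position(ref)
        if shares_acceptor and not shares_donor:
            cls = "alt5ss_extension" if delta > 0 else "alt5ss_truncation"
            return finish(cls, j, delta)
        if shares_donor and not shares_acceptor:
            cls = "alt3ss_extension" if delta > 0 else "alt3ss_truncation"
            return finish(cls, j, delta)

    # (6) complex
    return finish("complex", changing[0], None)


def classify_events(
    calls: Iterable[DeltaPsiCall],
    graph: SpliceGraph,
    genome: GenomeSequence,
    table: Optional[JunctionCountTable] = None,
    terminal_cfg: Optional[TerminalExonConfig] = None,
) -> list[SpliceEvent]:
    """Group confident calls into events and classify each group."""
    events = []
    for i, group in enumerate(group_lsv_calls(calls), 1):
        ev = classify_event(
            group,
            graph,
            genome,
            table=table,
            terminal_cfg=terminal_cfg,
            event_id=f"E{i:04d}",
        )
        if ev is not None:
            events.append(ev)
    return events


def summarize_event_types(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    """Per-class counts and percentages (summing to 100) in stable order."""
    counts = {cls: 0 for cls in EVENT_CLASSES}
    for ev in events:
        counts[ev.event_class] += 1
    rows = [
        {"event_class": cls, "count": n, "percent": 100.0 * n / len(events)}
        for cls, n in counts.items()
        if n > 0
    ]
    return pd.DataFrame(rows, columns=["event_class", "count", "percent"])
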