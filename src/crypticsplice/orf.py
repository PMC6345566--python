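"""Reading-frame consequences of splicing events on an annotated CDS.

An event is *disruptive* when the length change it makes to the mature
mRNA is not a multiple of three, or when the inserted (or newly joined)
sequence places a stop codon in frame; events outside the CDS are
*noncoding*; everything else is *tolerated*.  The phase at the event
position is recomputed by walking the spliced transcript from the
annotated CDS start — GTF frame attributes are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .events import SpliceEvent
from .genome import GenomeSequence, SpliceGraph, TranscriptModel, reverse_complement

STOP_CODONS = ("TAA", "TAG", "TGA")

INSERTION_CLASSES = (
    "annotated_cassette",
    "cryptic_internal_exon",
    "cryptic_terminal_exon",
)


@dataclass
class OrfImpactReport:
    event_id: str
    transcript_id: Optional[str]
    delta_length: int
    frame_preserving: bool
    introduces_stop: bool
    codons_affected: Optional[int]
    disruption: str  # disruptive | tolerated | noncoding


def is_frame_preserving(delta_length: int) -> bool:
    """True when the mRNA length change is a multiple of three."""
    return delta_length % 3 == 0


def codons_affected(delta_length: int) -> int:
    """Codons inserted or removed by a frame-preserving change."""
    if delta_length % 3 != 0:
        raise ValueError(f"{delta_length} nt is not frame-preserving")
    return abs(delta_length) // 3


def inserted_sequence_has_stop(seq: str, phase: int) -> bool:
    """True iff any complete in-frame triplet of seq is a stop codon.

    phase is the offset of the first complete codon within seq (0..2);
    trailing incomplete triplets are ignored.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    for i in range(phase, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True
    return False


def _cds_split(
    transcript: TranscriptModel, genome: GenomeSequence, genomic_breakpoint: int
) -> tuple[str, str]:
    """CDS sequence (5'->3') split at a genomic breakpoint between exons.

    Returns (upstream, downstream) coding sequence around the breakpoint;
    exonic CDS bases genomically before the breakpoint on '+' (after it on
    '-') count as upstream.
    """
    up_parts, down_parts = [], []
    for e in transcript.exons:
        s = max(e.start, transcript.cds_start)
        en = min(e.end, transcript.cds_end)
        if s >= en:
            continue
        seq = genome.fetch(transcript.chrom, s, en)
        if transcript.strand == "+":
            if en <= genomic_breakpoint:
                up_parts.append(seq)
            elif s >= genomic_breakpoint:
                down_parts.append(seq)
            else:
                cut = genomic_breakpoint - s
                up_parts.append(seq[:cut])
                down_parts.append(seq[cut:])
        else:
            if s >= genomic_breakpoint:
                up_parts.append(seq)
            elif en <= genomic_breakpoint:
                down_parts.append(seq)
            else:
                cut = genomic_breakpoint - s
                down_parts.append(seq[:cut])
                up_parts.append(seq[cut:])
    if transcript.strand == "+":
        return "".join(up_parts), "".join(down_parts)
    # reverse-complementing the ascending-genomic concatenation yields
    # transcript (5'->3') order directly
    return (
        reverse_complement("".join(up_parts)),
        reverse_complement("".join(down_parts)),
    )


def _event_interval(event: SpliceEvent) -> tuple[int, int]:
    """Genomic interval of the sequence the event inserts or removes."""
    if event.event_class in INSERTION_CLASSES and event.exon is not None:
        return event.exon.start, event.exon.end
    if event.event_class == "exitron":
        j = event.primary_junction
        return j.start, j.end
    ref, alt = event.reference_junction, event.primary_junction
    if ref is None:
        j = event.primary_junction
        return j.start, j.end
    # alt-5'/3' events: the segment between the two competing sites
    if alt.start == ref.start:
        lo, hi = sorted((alt.end, ref.end))
    else:
        lo, hi = sorted((alt.start, ref.start))
    return lo, hi


def _stop_in_junction_codon(up: str, down: str) -> bool:
    """Stop formed by the hybrid codon at a new splice junction."""
    r = len(up) % 3
    if r == 0:
        return False
    codon = up[-r:] + down[: 3 - r]
    return len(codon) == 3 and codon in STOP_CODONS


def assess_event(
    event: SpliceEvent,
    transcript: TranscriptModel,
    genome: GenomeSequence,
) -> OrfImpactReport:
    """Score one event against one transcript's CDS."""
    delta = event.delta_length if event.delta_length is not None else 0
    lo, hi = _event_interval(event)
    if (
        not transcript.has_cds
        or hi <= transcript.cds_start
        or lo >= transcript.cds_end
    ):
        return OrfImpactReport(
            event_id=event.event_id,
            transcript_id=transcript.transcript_id,
            delta_length=delta,
            frame_preserving=is_frame_preserving(delta),
            introduces_stop=False,
            codons_affected=None,
            disruption="noncoding",
        )

    frame_ok = is_frame_preserving(delta)
    introduces_stop = False
    if delta > 0 and event.event_class in INSERTION_CLASSES and event.exon is not None:
        # insertion: scan the inserted exon plus the codons it straddles
        anchor = event.exon.start if event.strand == "+" else event.exon.end
        up, down = _cds_split(transcript, genome, anchor)
        ins = genome.fetch(event.chrom, event.exon.start, event.exon.end)
        if event.strand == "-":
            ins = reverse_complement(ins)
        r = len(up) % 3
        head = up[-r:] if r else ""
        need = (3 - (len(head) + len(ins)) % 3) % 3
        chunk = head + ins + down[:need]
        introduces_stop = inserted_sequence_has_stop(chunk, 0)
    elif delta < 0:
        # deletion: only the hybrid codon at the new junction can gain a stop
        if event.strand == "+":
            up, _ = _cds_split(transcript, genome, lo)
            _, down = _cds_split(transcript, genome, hi)
        else:
            up, _ = _cds_split(transcript, genome, hi)
            _, down = _cds_split(transcript, genome, lo)
        introduces_stop = _stop_in_junction_codon(up, down)

    disruptive = (not frame_ok) or introduces_stop
    return OrfImpactReport(
        event_id=event.event_id,
        transcript_id=transcript.transcript_id,
        delta_length=delta,
        frame_preserving=frame_ok,
        introduces_stop=introduces_stop,
        codons_affected=codons_affected(delta) if frame_ok else None,
        disruption="disruptive" if disruptive else "tolerated",
    )


def choose_transcript(
    event: SpliceEvent, graph: SpliceGraph
) -> Optional[TranscriptModel]:
    """Longest-CDS transcript of the event's gene (ties by id)."""
    if event.gene_id is None or event.gene_id not in graph.genes:
        return None
    ts = [graph.transcripts[tid] for tid in graph.genes[event.gene_id]]
    return max(ts, key=lambda t: (t.cds_length, t.transcript_id))


def assess_events(
    events, graph: SpliceGraph, genome: GenomeSequence
) -> list[OrfImpactReport]:
    reports = []
    for ev in events:
        t = choose_transcript(ev, graph)
        if t is None:
            continue
        reports.append(assess_event(ev, t, genome))
    return reports


def disruptive_fraction(reports) -> Optional[float]:
    """Fraction of CDS-overlapping reports classed disruptive."""
    coding = [r for r in reports if r.disruption != "noncoding"]
    if not coding:
        return None
    return sum(r.disruption == "disruptive" for r in coding) / len(coding)
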