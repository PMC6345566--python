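"""Genome sequences, transcript models and strand-aware splice graphs.

All internal coordinates are 0-based half-open.  GTF (1-based inclusive) is
converted at the file boundary; BED passes through unchanged.  A splice
junction is keyed by its intron interval plus strand, so multiple transcripts
sharing an intron map onto one junction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase ACGTN string."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq for name, seq in chroms.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> str:
        return self._chroms[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); out-of-range access is an error."""
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._chroms[chrom]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"window [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def write_slice(self, chrom: str, start: int, replacement: str) -> None:
        """Overwrite genome bases in place (used by the simulator)."""
        seq = self._chroms[chrom]
        end = start + len(replacement)
        if not (0 <= start < end <= len(seq)):
            raise IndexError(f"write [{start}, {end}) outside {chrom}")
        self._chroms[chrom] = seq[:start] + replacement + seq[end:]


def read_fasta(path) -> GenomeSequence:
    """Read a multi-record FASTA; sequences are uppercased and any base
    outside ACGTN is masked to N."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = _NON_ACGTN.sub("N", str(rec.seq).upper())
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True, order=True)
class ExonInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad exon interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: start = first intronic base (0-based), end exclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end - self.start < 4:
            raise ValueError(
                f"intron [{self.start}, {self.end}) too short for donor+acceptor"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def intron_length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


def donor_position(j: SpliceJunction) -> int:
    """Genomic coordinate anchoring the 5' splice site of the intron."""
    return j.start if j.strand == "+" else j.end


def acceptor_position(j: SpliceJunction) -> int:
    """Genomic coordinate anchoring the 3' splice site of the intron."""
    return j.end if j.strand == "+" else j.start


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    cds_start: Optional[int] = None  # genomic bounds, 0-based half-open
    cds_end: Optional[int] = None

    def __post_init__(self):
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon on {e.chrom}:{e.strand}, "
                    f"transcript on {self.chrom}:{self.strand}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if not any(e.contains(self.cds_start) for e in exons):
                raise ValueError(f"{self.transcript_id}: cds_start not exonic")
            if not any(e.contains(self.cds_end - 1) for e in exons):
                raise ValueError(f"{self.transcript_id}: cds_end not exonic")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_length(self) -> int:
        if not self.has_cds:
            return 0
        return sum(
            max(0, min(e.end, self.cds_end) - max(e.start, self.cds_start))
            for e in self.exons
        )

    def junctions(self) -> list[SpliceJunction]:
        return [
            SpliceJunction(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def exons_5to3(self) -> list[ExonInterval]:
        """Exons in transcript (5'->3') orientation."""
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]

    def mature_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.fetch(self.chrom, e.start, e.end) for e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


class SpliceGraph:
    """Transcripts plus the exact set of annotated introns and splice sites."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {
            t.transcript_id: t for t in transcripts
        }
        self.genes: dict[str, list[str]] = {}
        juncs: set[SpliceJunction] = set()
        donors: set[tuple[str, int, str]] = set()
        acceptors: set[tuple[str, int, str]] = set()
        self.exon_index: dict[str, IntervalTree] = {}
        self._gene_index: dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
            for j in t.junctions():
                juncs.add(j)
                donors.add((j.chrom, donor_position(j), j.strand))
                acceptors.add((j.chrom, acceptor_position(j), j.strand))
            tree = self.exon_index.setdefault(t.chrom, IntervalTree())
            for i, e in enumerate(t.exons):
                tree.addi(e.start, e.end, (t.transcript_id, i))
        for gene_id, tids in self.genes.items():
            ts = [self.transcripts[tid] for tid in tids]
            chrom, strand = ts[0].chrom, ts[0].strand
            lo = min(t.span[0] for t in ts)
            hi = max(t.span[1] for t in ts)
            self._gene_index.setdefault(chrom, IntervalTree()).addi(
                lo, hi, (gene_id, strand)
            )
        self.annotated_junctions: frozenset[SpliceJunction] = frozenset(juncs)
        self.donor_sites = frozenset(donors)
        self.acceptor_sites = frozenset(acceptors)

    def junction_annotated(self, j: SpliceJunction) -> bool:
        return j in self.annotated_junctions

    def donor_annotated(self, chrom: str, pos: int, strand: str) -> bool:
        return (chrom, pos, strand) in self.donor_sites

    def acceptor_annotated(self, chrom: str, pos: int, strand: str) -> bool:
        return (chrom, pos, strand) in self.acceptor_sites

    def exons_at(self, chrom: str, pos: int, strand: Optional[str] = None):
        """(transcript, exon) pairs whose exon covers pos."""
        tree = self.exon_index.get(chrom)
        if tree is None:
            return []
        out = []
        for iv in tree[pos]:
            tid, idx = iv.data
            t = self.transcripts[tid]
            if strand is None or t.strand == strand:
                out.append((t, t.exons[idx]))
        return out

    def exon_strictly_containing(
        self, j: SpliceJunction
    ) -> Optional[ExonInterval]:
        """An annotated exon with both junction ends strictly inside it."""
        tree = self.exon_index.get(j.chrom)
        if tree is None:
            return None
        for iv in tree[j.start]:
            tid, idx = iv.data
            t = self.transcripts[tid]
            e = t.exons[idx]
            if t.strand == j.strand and e.start < j.start and j.end < e.end:
                return e
        return None

    def gene_at(self, chrom: str, pos: int, strand: Optional[str] = None):
        tree = self._gene_index.get(chrom)
        if tree is None:
            return None
        for iv in tree[pos]:
            gene_id, g_strand = iv.data
            if strand is None or g_strand == strand:
                return gene_id
        return None

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        ts = [self.transcripts[tid] for tid in self.genes[gene_id]]
        lo = min(t.span[0] for t in ts)
        hi = max(t.span[1] for t in ts)
        return ts[0].chrom, lo, hi, ts[0].strand


def read_gtf(path) -> SpliceGraph:
    """Build a splice graph from GTF exon (and optional CDS) features."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS"):
            continue
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        if f.end < f.start:
            raise ValueError(f"feature with end < start in transcript {tid}")
        if tid in meta and meta[tid] != (gid, f.seqid, f.strand):
            raise ValueError(f"transcript {tid} spans two chroms/strands")
        meta[tid] = (gid, f.seqid, f.strand)
        # GTF 1-based inclusive -> 0-based half-open
        iv = (f.start - 1, f.end)
        (exons if f.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    transcripts = []
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(
                    ExonInterval(chrom, s, e, strand) for s, e in sorted(ivs)
                ),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return SpliceGraph(transcripts)


def write_gtf(graph: SpliceGraph, path, source: str = "crypticsplice") -> None:
    """Write exon/CDS features; re-reading reproduces the same graph."""
    with open(path, "w") as fh:
        for t in sorted(graph.transcripts.values(), key=lambda t: (t.chrom, t.span)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                if t.has_cds:
                    s = max(e.start, t.cds_start)
                    en = min(e.end, t.cds_end)
                    if s < en:
                        fh.write(
                            f"{t.chrom}\t{source}\tCDS\t{s + 1}\t{en}\t.\t"
                            f"{t.strand}\t.\t{attrs}\n"
                        )


def junction_boundary_dinucleotides(
    j: SpliceJunction, genome: GenomeSequence
) -> tuple[str, str]:
    """(donor, acceptor) dinucleotides in transcript orientation.

    Canonical introns read GT..AG; a GC donor is the recognised minor class.
    """
    if j.chrom not in genome:
        raise KeyError(f"chromosome {j.chrom!r} absent from genome")
    first = genome.fetch(j.chrom, j.start, j.start + 2)
    last = genome.fetch(j.chrom, j.end - 2, j.end)
    if j.strand == "+":
        return first, last
    return reverse_complement(last), reverse_complement(first)


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED6 intervals; BED3 strand defaults to '+'."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) not in (3, 6):
                raise ValueError(f"{path}:{ln}: expected 3 or 6 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            strand = cols[5] if len(cols) == 6 and cols[5] in ("+", "-") else "+"
            out.append((chrom, start, end, strand))
    return out
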