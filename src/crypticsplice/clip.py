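"""Crosslink-site pentamer enrichment, region annotation and motif maps.

Windows of +/-flank nt (default 50, i.e. 101 nt) are taken around each
crosslink site, strand-aware.  Each k-mer is counted at most once per
window; the per-k-mer statistic is the fraction of windows containing it,
corrected against the same fraction in control windows (by default
dinucleotide-preserving shuffles of the observed windows, Altschul-
Erickson style, which keep every window's exact dinucleotide census).
Enrichment = log2((f_obs + p) / (f_ctrl + p)), ranked descending with
lexicographic tie-breaks; a two-proportion z-score is reported alongside.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GenomeSequence,
    SpliceGraph,
    SpliceJunction,
    reverse_complement,
)

log = logging.getLogger(__name__)

REGION_PRIORITY = ("CDS", "5UTR", "3UTR", "ncRNA_exon", "intron", "intergenic")


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    position: int  # 0-based single base
    strand: str


@dataclass(frozen=True)
class KmerConfig:
    k: int = 5
    flank: int = 50
    count_once_per_window: bool = True

    def __post_init__(self):
        if self.k < 1 or self.flank <= 0:
            raise ValueError("k must be >= 1 and flank > 0")

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1


def sites_from_bed(intervals: Iterable[tuple[str, int, int, str]]) -> list[CrosslinkSite]:
    """BED intervals -> single-base crosslink sites (interval start)."""
    return [CrosslinkSite(c, s, strand) for c, s, _e, strand in intervals]


def extract_windows(
    sites: Iterable[CrosslinkSite],
    genome: GenomeSequence,
    cfg: KmerConfig = KmerConfig(),
) -> list[str]:
    """Strand-aware window sequences around each site.

    Windows truncated at chromosome ends, or containing N, are dropped
    (a count is logged).
    """
    windows = []
    n_truncated = n_masked = 0
    for s in sites:
        lo, hi = s.position - cfg.flank, s.position + cfg.flank + 1
        if s.chrom not in genome or lo < 0 or hi > genome.chrom_length(s.chrom):
            n_truncated += 1
            continue
        seq = genome.fetch(s.chrom, lo, hi)
        if "N" in seq:
            n_masked += 1
            continue
        windows.append(seq if s.strand == "+" else reverse_complement(seq))
    if n_truncated or n_masked:
        log.info(
            "extract_windows: dropped %d truncated and %d N-containing window(s)",
            n_truncated,
            n_masked,
        )
    return windows


def kmer_window_fractions(
    windows: Sequence[str], cfg: KmerConfig = KmerConfig()
) -> dict[str, float]:
    """Per k-mer, the fraction of windows containing it at least once."""
    if not windows:
        raise ValueError("empty window list")
    counts: dict[str, int] = defaultdict(int)
    for w in windows:
        seen = {w[i : i + cfg.k] for i in range(len(w) - cfg.k + 1)}
        for kmer in seen:
            if "N" not in kmer:
                counts[kmer] += 1
    n = len(windows)
    return {kmer: c / n for kmer, c in counts.items()}


def enrichment_vs_control(
    obs_fractions: Mapping[str, float],
    ctrl_fractions: Mapping[str, float],
    pseudo: Optional[float] = None,
    n_obs: int = 0,
    n_ctrl: int = 0,
) -> pd.DataFrame:
    """Log2 window-fraction enrichment table, ranked descending.

    pseudo defaults to 1/n_obs (scale-aware smoothing).  The z column is a
    two-proportion normal approximation; ranking is by enrichment with
    lexicographic tie-breaking.
    """
    ks = {len(k) for k in obs_fractions} | {len(k) for k in ctrl_fractions}
    if len(ks) > 1:
        raise ValueError("mismatched k-mer lengths between tables")
    if pseudo is None:
        if n_obs <= 0:
            raise ValueError("give pseudo explicitly or n_obs > 0")
        pseudo = 1.0 / n_obs
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    kmers = sorted(set(obs_fractions) | set(ctrl_fractions))
    rows = []
    for kmer in kmers:
        f_obs = obs_fractions.get(kmer, 0.0)
        f_ctrl = ctrl_fractions.get(kmer, 0.0)
        enr = float(np.log2((f_obs + pseudo) / (f_ctrl + pseudo)))
        z = np.nan
        if n_obs > 0 and n_ctrl > 0:
            pooled = (f_obs * n_obs + f_ctrl * n_ctrl) / (n_obs + n_ctrl)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n_obs + 1 / n_ctrl))
            z = float((f_obs - f_ctrl) / se) if se > 0 else 0.0
        rows.append(
            {
                "kmer": kmer,
                "f_obs": f_obs,
                "f_ctrl": f_ctrl,
                "log2_enrichment": enr,
                "z": z,
                "contains_AA": "AA" in kmer,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["log2_enrichment", "kmer"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide multiset (Altschul-Erickson).

    Keeps first and last characters fixed; a homopolymer (or any sequence
    with a single arrangement) is returned unchanged.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    start, end = seq[0], seq[-1]
    vertices = list(edges)

    def reaches_end(last: dict) -> bool:
        for v in last:
            seen = set()
            u = v
            while u != end:
                if u in seen or u not in last:
                    return False
                seen.add(u)
                u = last[u]
        return True

    for _ in range(1000):
        last = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != end
        }
        if reaches_end(last):
            break
    else:  # pragma: no cover - tiny alphabet, arborescence found quickly
        return seq
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != end:
            rest.remove(last[v])
        rng.shuffle(rest)
        if v != end:
            rest.append(last[v])
        ordered[v] = rest
    out = [start]
    ptr = defaultdict(int)
    u = start
    for _ in range(len(seq) - 1):
        nxt = ordered[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def control_windows(
    windows: Sequence[str],
    mode: str = "dinucleotide_shuffle",
    seed: int = 0,
    genome: Optional[GenomeSequence] = None,
    regions: Optional[Sequence[tuple[str, int, int, str]]] = None,
    cfg: KmerConfig = KmerConfig(),
) -> list[str]:
    """Composition-matched control window set.

    dinucleotide_shuffle (default): per-window dinucleotide-preserving
    shuffles, deterministic given the seed.  supplied_bed: windows around
    user-supplied region starts.
    """
    if mode == "dinucleotide_shuffle":
        rng = np.random.default_rng(seed)
        return [dinucleotide_shuffle(w, rng) for w in windows]
    if mode == "supplied_bed":
        if genome is None or regions is None:
            raise ValueError("supplied_bed mode needs genome and regions")
        return extract_windows(sites_from_bed(regions), genome, cfg)
    raise ValueError(f"unknown control mode {mode!r}")


def annotate_region(site: CrosslinkSite, graph: SpliceGraph) -> str:
    """Genomic region of a crosslink site, strand-matched, with priority
    CDS > 5UTR > 3UTR > ncRNA_exon > intron > intergenic."""
    found = set()
    for t, _exon in graph.exons_at(site.chrom, site.position, site.strand):
        if not t.has_cds:
            found.add("ncRNA_exon")
        elif t.cds_start <= site.position < t.cds_end:
            found.add("CDS")
        else:
            before_cds = (
                site.position < t.cds_start
                if t.strand == "+"
                else site.position >= t.cds_end
            )
            found.add("5UTR" if before_cds else "3UTR")
    if not found:
        gene = graph.gene_at(site.chrom, site.position, site.strand)
        if gene is not None:
            lo, hi = graph.gene_span(gene)[1:3]
            if lo <= site.position < hi:
                found.add("intron")
    if not found:
        return "intergenic"
    for region in REGION_PRIORITY:
        if region in found:
            return region
    return "intergenic"


def region_distribution(
    sites: Iterable[CrosslinkSite], graph: SpliceGraph
) -> pd.DataFrame:
    """Counts and fractions of crosslink sites per genomic region."""
    counts = {r: 0 for r in REGION_PRIORITY}
    n = 0
    for s in sites:
        counts[annotate_region(s, graph)] += 1
        n += 1
    rows = [
        {"region": r, "count": c, "fraction": (c / n if n else 0.0)}
        for r, c in counts.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class MotifPositionMap:
    side: str  # donor | acceptor
    offsets: np.ndarray  # transcript-orientation offsets; 0 = first nt past
    # the splice boundary (intron side for donor, exon side for acceptor)
    tracks: dict[str, np.ndarray]  # set name -> per-position fraction
    ratio: Optional[np.ndarray] = None  # regulated / control, where defined


def _junction_window(
    genome: GenomeSequence,
    j: SpliceJunction,
    side: str,
    upstream: int,
    downstream: int,
) -> Optional[str]:
    """Transcript-orientation sequence around one splice boundary."""
    if side == "donor":
        pos = j.start if j.strand == "+" else j.end
    else:
        pos = j.end if j.strand == "+" else j.start
    if j.strand == "+":
        lo, hi = pos - upstream, pos + downstream
    else:
        lo, hi = pos - downstream, pos + upstream
    if lo < 0 or hi > genome.chrom_length(j.chrom):
        return None
    seq = genome.fetch(j.chrom, lo, hi)
    return seq if j.strand == "+" else reverse_complement(seq)


def motif_position_map(
    junction_sets: Mapping[str, Sequence[SpliceJunction]],
    genome: GenomeSequence,
    query_kmers: Sequence[str],
    side: str = "acceptor",
    exon_extent: int = 50,
    intron_extent: int = 100,
    smooth: int = 5,
) -> MotifPositionMap:
    """Per-position fraction of junction windows where any query k-mer
    overlaps, in transcript orientation, one track per junction set.

    For the donor side the window is exon_extent exonic then intron_extent
    intronic nt; for the acceptor side intron_extent intronic then
    exon_extent exonic nt.  Offset 0 is the first nt past the boundary.
    """
    if exon_extent <= 0 or intron_extent <= 0:
        raise ValueError("extents must be > 0")
    if side == "donor":
        upstream, downstream = exon_extent, intron_extent
    elif side == "acceptor":
        upstream, downstream = intron_extent, exon_extent
    else:
        raise ValueError(f"side must be donor or acceptor, got {side!r}")
    length = upstream + downstream
    kmers = [k.upper() for k in query_kmers]
    tracks: dict[str, np.ndarray] = {}
    for name, juncs in junction_sets.items():
        juncs = list(juncs)
        if not juncs:
            raise ValueError(f"junction set {name!r} is empty")
        cover = np.zeros(length)
        used = 0
        for j in juncs:
            seq = _junction_window(genome, j, side, upstream, downstream)
            if seq is None:
                continue
            hit = np.zeros(length, dtype=bool)
            for kmer in kmers:
                start = seq.find(kmer)
                while start != -1:
                    hit[start : start + len(kmer)] = True
                    start = seq.find(kmer, start + 1)
            cover += hit
            used += 1
        track = cover / used if used else cover
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            track = np.convolve(track, kernel, mode="same")
        tracks[name] = track
    ratio = None
    if "regulated" in tracks and "control" in tracks:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                tracks["control"] > 0, tracks["regulated"] / tracks["control"], np.nan
            )
    return MotifPositionMap(
        side=side,
        offsets=np.arange(-upstream, downstream),
        tracks=tracks,
        ratio=ratio,
    )
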