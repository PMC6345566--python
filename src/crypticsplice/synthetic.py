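"""Synthetic two-condition splicing data with planted ground truth.

The generator emulates the study design the analysis assumes: two
genotypes with three biological replicates each, junction-spanning read
counts per local splicing variation, and crosslink sites enriched for
AA-containing pentamers.  Each gene carries at most one planted event:

* cryptic internal exons (weak 3' splice sites, planted ESE hexamers, a
  configurable fraction frame-disrupting),
* annotated cassette exons (a second transcript annotates the exon),
* exitrons — exon-internal donor/acceptor pairs, length a multiple of
  three, optionally with the minor GC donor,
* alternative 5'/3' splice sites extending or truncating annotated exons
  by a planted offset,
* cryptic terminal exons in the 5'UTR intron, with an AATAAA
  polyadenylation signal planted downstream and depleted splice-out reads.

Counts: per event and replicate the total is negative-binomial
(gamma-Poisson) around the configured depth and is allocated to member
junctions by the condition's PSI; a noise-free mode uses exact rounded
allocations.  All randomness flows from the config seed; outputs are
byte-identical on rerun.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import (
    ExonInterval,
    GenomeSequence,
    SpliceGraph,
    SpliceJunction,
    TranscriptModel,
    write_fasta,
    write_gtf,
)
from .psi import JunctionCountTable, Sample, write_sj_table

DONOR_HEAD = "GTAAGT"
GC_DONOR_HEAD = "GCAAGT"
EXON_TAIL = "CAG"  # last 3 exonic nt before a donor
EXON_HEAD = "G"  # first exonic nt after an acceptor
ACCEPTOR_TAIL = "TTTCTTTTCCTTCAG"  # polypyrimidine tract + AG, 15 nt
POLYA_SIGNAL = "AATAAA"

PLANTABLE_CLASSES = (
    "cryptic_internal_exon",
    "annotated_cassette",
    "exitron",
    "alt5ss_extension",
    "alt5ss_truncation",
    "alt3ss_extension",
    "alt3ss_truncation",
    "cryptic_terminal_exon",
)

# All planted pentamers carry AA internally (within positions 1-3), so
# the +/-1-shifted "shadow" pentamers created at write boundaries contain
# AA as well; mixed composition keeps dinucleotide-shuffle reform rates
# moderate so the planted arrangement stays enriched over its own
# composition-matched control.
DEFAULT_CROSSLINK_PLANTS = (
    ("TGAAG", 0.90),
    ("CAAGT", 0.50),
    ("GCAAG", 0.48),
    ("CTAAC", 0.46),
    ("GAAGC", 0.44),
    ("TTAAG", 0.42),
    ("GAACT", 0.40),
    ("CAACG", 0.38),
    ("TAAGC", 0.36),
    ("TAACG", 0.34),
)


@dataclass(frozen=True)
class ClassPlan:
    event_class: str
    count: int
    psi_a: float = 0.0
    psi_b: float = 0.5

    def __post_init__(self):
        if self.event_class not in PLANTABLE_CLASSES:
            raise ValueError(f"cannot plant class {self.event_class!r}")
        if not (0 <= self.psi_a <= 1 and 0 <= self.psi_b <= 1):
            raise ValueError("PSI values must be in [0, 1]")


def default_event_plan(count: int = 20) -> tuple[ClassPlan, ...]:
    return tuple(ClassPlan(cls, count) for cls in PLANTABLE_CLASSES)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    event_plan: tuple[ClassPlan, ...] = field(default_factory=default_event_plan)
    n_background_genes: int = 5
    n_exons: int = 6
    exon_len: tuple[int, int] = (120, 240)
    intron_len: tuple[int, int] = (400, 900)
    depth_mean: float = 100.0
    depth_dispersion: float = 0.1
    replicates: tuple[int, int] = (3, 3)
    noise_free: bool = False
    background_gc: float = 0.4
    weak_mismatches: int = 2  # acceptor-tract mismatches at cryptic sites
    disrupt_fraction: float = 0.84  # frame-disrupting cryptic internal exons
    gc_donor_every: int = 5  # every k-th exitron gets a GC donor
    exitron_secondary: float = 0.8  # interior-junction share of cryptic reads
    polya_offset: int = 60  # AATAAA distance past the terminal exon 3' end
    polya_window: int = 500
    terminal_asymmetry: float = 14.0
    ese_hexamers: tuple[str, ...] = ("GAAGAA",)
    ese_copies: int = 3
    chrom_name: str = "chr1"
    gene_gap: int = 500

    def __post_init__(self):
        if self.depth_dispersion < 0 or self.depth_mean <= 0:
            raise ValueError("bad depth parameters")
        if not (0 <= self.disrupt_fraction <= 1):
            raise ValueError("disrupt_fraction must be in [0, 1]")


@dataclass
class PlantTruth:
    gene_id: str
    event_class: str
    chrom: str
    strand: str
    psi_a: float
    psi_b: float
    delta_length: int
    primary_junction: tuple[int, int]  # the cryptic junction to recover
    lsv_junction: tuple[int, int]  # junction carrying the planted dPSI
    reference_junction: tuple[int, int]
    all_junctions: tuple[tuple[int, int], ...]
    exon: Optional[tuple[int, int]] = None
    frame_disrupting: Optional[bool] = None
    gc_donor: bool = False
    polya_position: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Scenario:
    config: SimulationConfig
    genome: GenomeSequence
    graph: SpliceGraph
    truth: list[PlantTruth]
    protected: dict[str, IntervalTree]
    table: Optional[JunctionCountTable] = None
    crosslink_sites: Optional[list] = None
    crosslink_plants: Optional[tuple] = None


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


class _GeneBuilder:
    """One gene in transcript-local (5'->3') coordinates."""

    def __init__(self, rng, cfg: SimulationConfig):
        self.rng = rng
        self.cfg = cfg
        self.seq: list[str] = []
        self.protected: list[tuple[int, int]] = []

    def stamp(self, pos: int, s: str, protect: bool = True):
        self.seq[pos : pos + len(s)] = list(s)
        if protect:
            self.protected.append((pos, pos + len(s)))

    def weak_acceptor_tail(self) -> str:
        tail = list(ACCEPTOR_TAIL)
        for i in (2, 5, 8)[: self.cfg.weak_mismatches]:
            tail[i] = "A"
        return "".join(tail)


def _draw_lengths(rng, cfg, n, bounds):
    lo, hi = bounds
    return [int(rng.integers(lo, hi + 1)) for _ in range(n)]


def _cds_nt_before(exon_bounds, cds, pos):
    """CDS nucleotides (transcript order) strictly before local pos."""
    cs, ce = cds
    total = 0
    for s, e in exon_bounds:
        lo, hi = max(s, cs), min(e, ce)
        if lo < hi:
            total += max(0, min(hi, pos) - lo)
    return total


def _build_gene(
    gene_idx: int,
    plan: Optional[ClassPlan],
    disrupting: Optional[bool],
    gc_donor: bool,
    rng: np.random.Generator,
    cfg: SimulationConfig,
):
    """Returns a dict describing the gene in local coordinates."""
    b = _GeneBuilder(rng, cfg)
    n = cfg.n_exons
    le = _draw_lengths(rng, cfg, n, cfg.exon_len)
    li = _draw_lengths(rng, cfg, n - 1, cfg.intron_len)
    cls = plan.event_class if plan else None

    # plant-driven geometry adjustments (drawn before layout)
    off = exitron_len = cryptic_len = None
    if cls in ("alt5ss_truncation", "alt3ss_truncation"):
        off = int(rng.integers(90, 241))
        host_exon = 2 if cls == "alt5ss_truncation" else 3
        le[host_exon] = max(le[host_exon], off + 70)
    elif cls in ("alt5ss_extension", "alt3ss_extension"):
        off = int(rng.integers(90, 241))
        li[2] = max(li[2], off + 170)
    elif cls == "exitron":
        exitron_len = 3 * int(rng.integers(50, 101))
        le[3] = max(le[3], exitron_len + 160)
    elif cls in ("cryptic_internal_exon", "annotated_cassette", "cryptic_terminal_exon"):
        host = 0 if cls == "cryptic_terminal_exon" else 2
        down_len = le[host + 1]
        cryptic_len = down_len + ((-down_len) % 3)
        if disrupting:
            cryptic_len += int(rng.integers(1, 3))
        li[host] = max(li[host], cryptic_len + 260)

    # layout
    exon_bounds, pos = [], 0
    for i in range(n):
        exon_bounds.append((pos, pos + le[i]))
        pos += le[i]
        if i < n - 1:
            pos += li[i]
    length = pos
    introns = [(exon_bounds[i][1], exon_bounds[i + 1][0]) for i in range(n - 1)]
    b.seq = _rand_seq(rng, length, cfg.background_gc)

    # annotated splice elements
    for i, (s, e) in enumerate(introns):
        b.stamp(exon_bounds[i][1] - 3, EXON_TAIL)
        b.stamp(s, DONOR_HEAD)
        b.stamp(e - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL)
        b.stamp(e, EXON_HEAD)
    cds = (exon_bounds[1][0] + 30, exon_bounds[n - 2][1] - 10)

    gene_id = f"G{gene_idx:04d}"
    out = {
        "gene_id": gene_id,
        "exon_bounds": exon_bounds,
        "cds": cds,
        "cassette_exon": None,
        "plant": None,
    }

    if cls is None:
        out["builder"] = b
        out["length"] = length
        return out

    weak_tail = b.weak_acceptor_tail()
    plant: dict = {"event_class": cls, "gc_donor": gc_donor}

    if cls in ("cryptic_internal_exon", "annotated_cassette", "cryptic_terminal_exon"):
        host = 0 if cls == "cryptic_terminal_exon" else 2
        s, e = introns[host]
        ce_start = s + (e - s - cryptic_len) // 2
        ce_end = ce_start + cryptic_len
        tail = ACCEPTOR_TAIL if cls == "annotated_cassette" else weak_tail
        b.stamp(ce_start - len(tail), tail)
        b.stamp(ce_start, EXON_HEAD)
        b.stamp(ce_end - 3, EXON_TAIL)
        b.stamp(ce_end, DONOR_HEAD)
        # equal ESE content in the planted exon and its downstream exon
        ds, de = exon_bounds[host + 1]
        slot = 0
        for hexamer in cfg.ese_hexamers:
            for _ in range(cfg.ese_copies):
                b.stamp(ce_start + 15 + slot * 9, hexamer)
                b.stamp(ds + 10 + slot * 9, hexamer)
                slot += 1
        if cls == "cryptic_terminal_exon":
            polya = ce_end + cfg.polya_offset
            # the signal must be unique within the host intron
            intron_seq = "".join(b.seq[s:e])
            start = intron_seq.find(POLYA_SIGNAL)
            while start != -1:
                b.seq[s + start + 2] = "C"
                intron_seq = "".join(b.seq[s:e])
                start = intron_seq.find(POLYA_SIGNAL)
            b.stamp(polya, POLYA_SIGNAL)
            b.protected.append((ce_end, min(length, ce_end + cfg.polya_window)))
            plant["polya_local"] = polya
        elif cls == "cryptic_internal_exon" and not disrupting:
            # scrub in-frame stop codons from the insertion chunk
            u = _cds_nt_before(exon_bounds, cds, exon_bounds[host][1])
            r = u % 3
            stamped = {
                i for lo, hi in b.protected for i in range(lo, hi)
            }
            chunk_pos = (
                list(range(exon_bounds[host][1] - r, exon_bounds[host][1]))
                + list(range(ce_start, ce_end))
                + list(range(ds, ds + 3))
            )
            i = 0
            while i + 3 <= len(chunk_pos):
                tri = [chunk_pos[i], chunk_pos[i + 1], chunk_pos[i + 2]]
                codon = "".join(b.seq[p] for p in tri)
                if codon in ("TAA", "TAG", "TGA"):
                    target = next((p for p in tri if p not in stamped), tri[0])
                    b.seq[target] = "C"
                i += 3
        if disrupting is not None:
            plant["frame_disrupting"] = bool(disrupting)
        if cls == "annotated_cassette":
            out["cassette_exon"] = (ce_start, ce_end)
        host_end = exon_bounds[host][1]
        next_start = exon_bounds[host + 1][0]
        plant.update(
            exon=(ce_start, ce_end),
            j_up=(host_end, ce_start),
            j_down=(ce_end, next_start),
            ref=(host_end, next_start),
            delta=cryptic_len,
        )
    elif cls == "exitron":
        es, ee = exon_bounds[3]
        d = es + 50
        a = d + exitron_len
        b.stamp(d - 3, EXON_TAIL)
        b.stamp(d, GC_DONOR_HEAD if gc_donor else DONOR_HEAD)
        b.stamp(a - len(weak_tail), weak_tail)
        b.stamp(a, EXON_HEAD)
        # keep the in-frame removal free of a junction-codon stop
        u = _cds_nt_before(exon_bounds, cds, d)
        r = u % 3
        if r:
            codon = "".join(b.seq[d - r : d]) + "".join(b.seq[a : a + 3 - r])
            if codon in ("TAA", "TAG", "TGA"):
                b.seq[d - r] = "C"
        plant.update(
            exon=(es, ee),
            exitron=(d, a),
            companion=(exon_bounds[2][1], a),
            ref=(exon_bounds[2][1], es),
            delta=-exitron_len,
            frame_disrupting=False,
        )
    elif cls in ("alt5ss_truncation", "alt5ss_extension"):
        host_end = exon_bounds[2][1]
        p = host_end - off if cls == "alt5ss_truncation" else host_end + off
        b.stamp(p - 3, EXON_TAIL)
        b.stamp(p, DONOR_HEAD)
        plant.update(
            alt=(p, exon_bounds[3][0]),
            ref=(host_end, exon_bounds[3][0]),
            delta=off if cls == "alt5ss_extension" else -off,
        )
    elif cls in ("alt3ss_truncation", "alt3ss_extension"):
        next_start = exon_bounds[3][0]
        q = next_start + off if cls == "alt3ss_truncation" else next_start - off
        b.stamp(q - len(weak_tail), weak_tail)
        b.stamp(q, EXON_HEAD)
        plant.update(
            alt=(exon_bounds[2][1], q),
            ref=(exon_bounds[2][1], next_start),
            delta=-off if cls == "alt3ss_truncation" else off,
        )

    plant["psi_a"] = plan.psi_a
    plant["psi_b"] = plan.psi_b
    out["plant"] = plant
    out["builder"] = b
    out["length"] = length
    return out


def _flip(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return length - iv[1], length - iv[0]


def generate_reference(config: SimulationConfig) -> Scenario:
    """Generate (genome, annotation, truth) with every planted event
    resolvable against the emitted splice graph."""
    rng = np.random.default_rng([config.seed, 0])
    plans: list[Optional[ClassPlan]] = []
    for plan in config.event_plan:
        plans.extend([plan] * plan.count)
    plans.extend([None] * config.n_background_genes)

    # frame plan for cryptic internal exons: an exact disrupt_fraction
    n_cryptic = sum(1 for p in plans if p and p.event_class == "cryptic_internal_exon")
    n_disrupt = int(round(config.disrupt_fraction * n_cryptic))
    disrupt_flags = [i < n_disrupt for i in range(n_cryptic)]
    rng.shuffle(disrupt_flags)

    pieces: list[str] = []
    transcripts: list[TranscriptModel] = []
    truth: list[PlantTruth] = []
    protected = IntervalTree()
    chrom = config.chrom_name
    offset = 0
    cryptic_i = exitron_i = 0
    for gi, plan in enumerate(plans):
        disrupting = None
        gc_donor = False
        if plan and plan.event_class == "cryptic_internal_exon":
            disrupting = disrupt_flags[cryptic_i]
            cryptic_i += 1
        if plan and plan.event_class == "exitron":
            gc_donor = exitron_i % config.gc_donor_every == 0
            exitron_i += 1
        g = _build_gene(gi, plan, disrupting, gc_donor, rng, config)
        strand = "+" if rng.random() < 0.5 else "-"
        length = g["length"]
        local_seq = "".join(g["builder"].seq)
        if strand == "-":
            from .genome import reverse_complement

            pieces.append(reverse_complement(local_seq))
        else:
            pieces.append(local_seq)
        g0 = offset

        def to_abs(iv):
            s, e = iv if strand == "+" else _flip(iv, length)
            return g0 + s, g0 + e

        exons = tuple(
            ExonInterval(chrom, *to_abs(iv), strand) for iv in g["exon_bounds"]
        )
        cds_abs = to_abs(g["cds"])
        gene_id = g["gene_id"]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_abs[0],
                cds_end=cds_abs[1],
            )
        )
        if g["cassette_exon"] is not None:
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t2",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons
                    + (ExonInterval(chrom, *to_abs(g["cassette_exon"]), strand),),
                    cds_start=cds_abs[0],
                    cds_end=cds_abs[1],
                )
            )
        for lo, hi in g["builder"].protected:
            a, bnd = to_abs((lo, hi))
            protected.addi(max(0, a - 3), bnd + 3)
        for s, e in g["exon_bounds"]:
            a, bnd = to_abs((s, e))
            protected.addi(max(0, a - 30), bnd + 30)

        p = g["plant"]
        if p is not None:
            cls = p["event_class"]
            if cls == "exitron":
                primary = to_abs(p["exitron"])
                lsv_j = to_abs(p["companion"])
                all_j = (primary, lsv_j, to_abs(p["ref"]))
                exon_abs = to_abs(p["exon"])
            elif "exon" in p:
                primary = to_abs(p["j_up"]) if strand == "+" else to_abs(p["j_up"])
                lsv_j = primary
                all_j = (to_abs(p["j_up"]), to_abs(p["j_down"]), to_abs(p["ref"]))
                exon_abs = to_abs(p["exon"])
            else:
                primary = to_abs(p["alt"])
                lsv_j = primary
                all_j = (primary, to_abs(p["ref"]))
                exon_abs = None
            polya_abs = None
            if "polya_local" in p:
                polya_abs = to_abs((p["polya_local"], p["polya_local"] + 6))[0]
            truth.append(
                PlantTruth(
                    gene_id=gene_id,
                    event_class=cls,
                    chrom=chrom,
                    strand=strand,
                    psi_a=p["psi_a"],
                    psi_b=p["psi_b"],
                    delta_length=p["delta"],
                    primary_junction=primary,
                    lsv_junction=lsv_j,
                    reference_junction=to_abs(p["ref"]),
                    all_junctions=all_j,
                    exon=exon_abs,
                    frame_disrupting=p.get("frame_disrupting"),
                    gc_donor=p["gc_donor"],
                    polya_position=polya_abs,
                )
            )
        offset += length
        pieces.append("".join(_rand_seq(rng, config.gene_gap, config.background_gc)))
        offset += config.gene_gap

    genome = GenomeSequence({chrom: "".join(pieces)})
    graph = SpliceGraph(transcripts)
    return Scenario(
        config=config,
        genome=genome,
        graph=graph,
        truth=truth,
        protected={chrom: protected},
    )


def _draw_total(rng, cfg: SimulationConfig) -> int:
    if cfg.noise_free:
        return int(round(cfg.depth_mean))
    if cfg.depth_dispersion == 0:
        return int(rng.poisson(cfg.depth_mean))
    lam = rng.gamma(1.0 / cfg.depth_dispersion, cfg.depth_mean * cfg.depth_dispersion)
    return int(rng.poisson(lam))


def _binom(rng, n, p, noise_free):
    if noise_free:
        return int(round(n * p))
    return int(rng.binomial(n, p))


def simulate_junction_counts(
    scenario: Scenario, config: Optional[SimulationConfig] = None
) -> JunctionCountTable:
    """Per-sample junction counts for the scenario's planted truth."""
    cfg = config or scenario.config
    rng = np.random.default_rng([cfg.seed, 1])
    n_a, n_b = cfg.replicates
    samples = [Sample(f"A{i + 1}", "A") for i in range(n_a)] + [
        Sample(f"B{i + 1}", "B") for i in range(n_b)
    ]
    n_s = len(samples)
    counts: dict[SpliceJunction, np.ndarray] = {}

    def add(junction: SpliceJunction, col: int, c: int):
        if junction not in counts:
            counts[junction] = np.zeros(n_s, dtype=np.int64)
        counts[junction][col] += c

    truth_by_gene = {t.gene_id: t for t in scenario.truth}
    for gene_id in sorted(scenario.graph.genes):
        t1 = scenario.graph.transcripts[f"{gene_id}.t1"]
        truth = truth_by_gene.get(gene_id)
        unit: dict[str, SpliceJunction] = {}
        if truth is not None:
            strand = truth.strand

            def j(iv):
                return SpliceJunction(truth.chrom, iv[0], iv[1], strand)

            cls = truth.event_class
            if cls == "exitron":
                unit = {
                    "ref": j(truth.reference_junction),
                    "cryptic": j(truth.lsv_junction),
                    "interior": j(truth.primary_junction),
                }
            elif truth.exon is not None:
                up, down, ref = truth.all_junctions
                unit = {"ref": j(ref), "up": j(up), "down": j(down)}
            else:
                unit = {"ref": j(truth.reference_junction), "alt": j(truth.primary_junction)}
        unit_juncs = set(unit.values())
        for col, sample in enumerate(samples):
            psi = None
            if truth is not None:
                psi = truth.psi_a if sample.condition == "A" else truth.psi_b
            for jn in t1.junctions():
                if jn in unit_juncs:
                    continue
                add(jn, col, _draw_total(rng, cfg))
            if truth is None:
                continue
            n = _draw_total(rng, cfg)
            cls = truth.event_class
            if cls == "exitron":
                cryptic = _binom(rng, n, psi, cfg.noise_free)
                add(unit["ref"], col, n - cryptic)
                add(unit["cryptic"], col, cryptic)
                add(unit["interior"], col, _binom(rng, cryptic, cfg.exitron_secondary, cfg.noise_free))
            elif truth.exon is not None:
                incl = _binom(rng, n, psi, cfg.noise_free)
                add(unit["ref"], col, n - incl)
                add(unit["up"], col, incl)
                if cls == "cryptic_terminal_exon":
                    add(
                        unit["down"],
                        col,
                        _binom(rng, incl, 1.0 / cfg.terminal_asymmetry, cfg.noise_free),
                    )
                else:
                    add(unit["down"], col, incl)
            else:
                alt = _binom(rng, n, psi, cfg.noise_free)
                add(unit["ref"], col, n - alt)
                add(unit["alt"], col, alt)
    junctions = sorted(counts)
    mat = np.stack([counts[jn] for jn in junctions]) if junctions else np.zeros((0, n_s), int)
    return JunctionCountTable(junctions, samples, mat)


def simulate_scenario(config: SimulationConfig) -> Scenario:
    scenario = generate_reference(config)
    scenario.table = simulate_junction_counts(scenario)
    return scenario


def simulate_crosslinks(
    scenario: Scenario,
    n_sites: int = 1500,
    planted: Sequence[tuple[str, float]] = DEFAULT_CROSSLINK_PLANTS,
    flank: int = 50,
    seed_stream: int = 2,
    placement: str = "clear",
):
    """Place crosslink sites in gene bodies and write planted pentamers
    into a configured fraction of their windows (genome is modified in
    place; writes overlapping protected splice elements are skipped).

    placement "clear" (default) rejection-samples positions whose whole
    window avoids splice-site elements, so window content is background
    plus plants only; "uniform" samples anywhere in the gene span (used
    for genomic-region distribution analyses).
    """
    from .clip import CrosslinkSite
    from .genome import reverse_complement

    if placement not in ("clear", "uniform"):
        raise ValueError(f"unknown placement {placement!r}")
    cfg = scenario.config
    rng = np.random.default_rng([cfg.seed, seed_stream])
    genes = sorted(scenario.graph.genes)
    chrom_len = scenario.genome.chrom_length(cfg.chrom_name)
    prot = scenario.protected[cfg.chrom_name]
    sites = []
    for _ in range(n_sites):
        gene = genes[int(rng.integers(len(genes)))]
        chrom, lo, hi, strand = scenario.graph.gene_span(gene)
        pos = int(rng.integers(lo + flank + 6, hi - flank - 6))
        if placement == "clear":
            for _attempt in range(200):
                if not prot.overlap(pos - flank - 1, pos + flank + 2):
                    break
                pos = int(rng.integers(lo + flank + 6, hi - flank - 6))
        sites.append(CrosslinkSite(chrom, pos, strand))
        used: list[tuple[int, int]] = []
        for pent, frac in planted:
            if rng.random() >= frac:
                continue
            for _attempt in range(12):
                o = int(rng.integers(-(flank - 6), flank - 6 - len(pent)))
                start = pos + o
                end = start + len(pent)
                if start < 0 or end > chrom_len:
                    continue
                if prot.overlap(start - 1, end + 1):
                    continue
                # 5-nt guard between writes: junction k-mers spanning two
                # plants would otherwise arise systematically
                if any(s < end + 5 and start - 5 < e for s, e in used):
                    continue
                written = pent if strand == "+" else reverse_complement(pent)
                scenario.genome.write_slice(chrom, start, written)
                used.append((start, end))
                break
    scenario.crosslink_sites = sites
    scenario.crosslink_plants = tuple(planted)
    return sites


def simulate_motif_map_fixture(
    seed: int = 0,
    n_regulated: int = 40,
    n_control: int = 40,
    kmer: str = "TGAAG",
    intron_offset: int = 10,
    intron_len: int = 300,
    gc: float = 0.4,
):
    """A minimal fixture for positional motif maps: acceptor-side windows
    with the query k-mer planted at a fixed intronic offset in every
    regulated junction, absent by construction near control junctions."""
    rng = np.random.default_rng(seed)
    block = 2 * intron_len + 200
    total = (n_regulated + n_control) * block
    seq = _rand_seq(rng, total, gc)
    regulated, control = [], []
    for i in range(n_regulated + n_control):
        base = i * block
        s = base + 100
        e = s + intron_len
        jn = SpliceJunction("chrM", s, e, "+")
        # remove chance occurrences near the acceptor
        window = "".join(seq[e - 120 : e + 60])
        start = window.find(kmer)
        while start != -1:
            seq[e - 120 + start + 2] = "C"
            window = "".join(seq[e - 120 : e + 60])
            start = window.find(kmer)
        if i < n_regulated:
            pos = e - intron_offset  # k-mer starts at track offset -intron_offset
            seq[pos : pos + len(kmer)] = list(kmer)
            regulated.append(jn)
        else:
            control.append(jn)
    genome = GenomeSequence({"chrM": "".join(seq)})
    return genome, {"regulated": regulated, "control": control}


def random_coding_transcript(
    rng: np.random.Generator,
    n_exons: int = 4,
    exon_len: tuple[int, int] = (90, 200),
    intron_len: tuple[int, int] = (100, 300),
    chrom: str = "chrT",
    strand: str = "+",
):
    """A single stop-free-CDS transcript on its own chromosome — used as a
    clean substrate for reading-frame oracles."""
    le = [int(rng.integers(*exon_len)) for _ in range(n_exons)]
    li = [int(rng.integers(*intron_len)) for _ in range(n_exons - 1)]
    bounds, pos = [], 0
    for i in range(n_exons):
        bounds.append((pos, pos + le[i]))
        pos += le[i]
        if i < n_exons - 1:
            pos += li[i]
    seq = _rand_seq(rng, pos, 0.45)
    cds = (bounds[0][0] + 12, bounds[-1][1] - 12)
    # scrub in-frame stops across the spliced CDS
    cds_positions = [
        p for s, e in bounds for p in range(max(s, cds[0]), min(e, cds[1]))
    ]
    for i in range(0, len(cds_positions) - 2, 3):
        tri = cds_positions[i : i + 3]
        if "".join(seq[p] for p in tri) in ("TAA", "TAG", "TGA"):
            seq[tri[1]] = "C"
    length = pos
    if strand == "-":
        from .genome import reverse_complement

        seq_str = reverse_complement("".join(seq))
        bounds = [_flip(b, length) for b in bounds][::-1]
        cds = _flip(cds, length)
    else:
        seq_str = "".join(seq)
    genome = GenomeSequence({chrom: seq_str})
    t = TranscriptModel(
        transcript_id="T1",
        gene_id="GT1",
        chrom=chrom,
        strand=strand,
        exons=tuple(ExonInterval(chrom, s, e, strand) for s, e in bounds),
        cds_start=cds[0],
        cds_end=cds[1],
    )
    return genome, t


def write_truth(truth: Sequence[PlantTruth], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in truth], fh, indent=1)


def write_scenario(scenario: Scenario, outdir) -> dict:
    """Emit genome.fa, annotation.gtf, sj/<sample>.tab, sample_sheet.tsv,
    truth.json and (when simulated) crosslinks.bed; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "truth": outdir / "truth.json",
        "sample_sheet": outdir / "sample_sheet.tsv",
    }
    write_fasta(scenario.genome, paths["genome"])
    write_gtf(scenario.graph, paths["gtf"])
    write_truth(scenario.truth, paths["truth"])
    sj_dir = outdir / "sj"
    sj_dir.mkdir(exist_ok=True)
    if scenario.table is None:
        raise ValueError("scenario has no junction counts; run simulate_scenario")
    with open(paths["sample_sheet"], "w") as fh:
        for s in scenario.table.samples:
            sj_path = sj_dir / f"{s.sample_id}.tab"
            write_sj_table(scenario.table, s.sample_id, sj_path, scenario.graph)
            fh.write(f"{s.sample_id}\t{sj_path}\t{s.condition}\n")
    if scenario.crosslink_sites:
        bed = outdir / "crosslinks.bed"
        with open(bed, "w") as fh:
            for s in scenario.crosslink_sites:
                fh.write(
                    f"{s.chrom}\t{s.position}\t{s.position + 1}\t.\t0\t{s.strand}\n"
                )
        paths["crosslinks"] = bed
    return paths
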