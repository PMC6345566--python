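"""End-to-end orchestration: quantify -> classify -> impact -> strength ->
clip (optional) -> report, with TSV/JSON artifacts and a run manifest.

Every output TSV starts with a provenance comment line (tool version,
seed, config digest); reruns on unchanged inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .clip import (
    KmerConfig,
    control_windows,
    enrichment_vs_control,
    extract_windows,
    kmer_window_fractions,
    motif_position_map,
    region_distribution,
    sites_from_bed,
)
from .events import (
    SpliceEvent,
    TerminalExonConfig,
    classify_events,
    summarize_event_types,
)
from .genome import (
    GenomeSequence,
    SpliceGraph,
    SpliceJunction,
    read_bed,
    read_fasta,
    read_gtf,
)
from .orf import assess_events, disruptive_fraction
from .psi import (
    DeltaPsiCall,
    JunctionCountTable,
    LSVDefinition,
    quantify_all,
    read_sample_sheet,
    read_sj_table,
)
from .strength import (
    compare_cryptic_vs_downstream,
    read_ese_list,
    reference_scores_from_graph,
    train_pwms_from_graph,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str
    gtf: str
    sample_sheet: str
    out_dir: str
    crosslinks: Optional[str] = None
    ese_list: Optional[str] = None
    # quantification
    alpha: float = 1.0
    n_draws: int = 10_000
    v_set: tuple[float, ...] = (0.1, 0.2)
    threshold: float = 0.95
    min_total: int = 10
    seed: int = 0
    # classification
    polya_window: int = 500
    polya_signals: tuple[str, ...] = ("AATAAA",)
    min_ratio: float = 5.0
    # clip
    clip_flank: int = 50
    clip_k: int = 5
    top_k: int = 10

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        for key in ("v_set", "polya_signals"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        # analysis parameters only: the output directory does not change
        # what is computed
        data = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    calls: list[DeltaPsiCall]
    events: list[SpliceEvent]
    impacts: list
    strength_summary: dict
    clip_table: Optional[pd.DataFrame]
    summary: dict
    artifacts: dict[str, Path]


def _provenance(cfg: RunConfig) -> str:
    return (
        f"# crypticsplice v{__version__} seed={cfg.seed} config={cfg.digest()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def calls_to_frame(calls: Sequence[DeltaPsiCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "lsv_id": c.lsv_id,
            "chrom": c.junction.chrom,
            "intron_start": c.junction.start,
            "intron_end": c.junction.end,
            "strand": c.junction.strand,
            "e_psi_a": c.e_psi_a,
            "e_psi_b": c.e_psi_b,
            "e_dpsi": c.e_dpsi,
            "tier": c.tier,
        }
        for v, p in c.probs.items():
            row[f"p_{v:g}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def calls_from_frame(df: pd.DataFrame) -> list[DeltaPsiCall]:
    """Rebuild calls (and their LSV groupings) from a calls table."""
    by_lsv: dict[str, list] = {}
    for _, r in df.iterrows():
        by_lsv.setdefault(r["lsv_id"], []).append(r)
    calls = []
    for lsv_id, rows in by_lsv.items():
        junctions = [
            SpliceJunction(r["chrom"], int(r["intron_start"]), int(r["intron_end"]), r["strand"])
            for r in rows
        ]
        lsv = LSVDefinition.parse_id(lsv_id, junctions)
        for r, j in zip(rows, junctions):
            probs = {
                float(col[2:]): float(r[col])
                for col in df.columns
                if col.startswith("p_")
            }
            calls.append(
                DeltaPsiCall(
                    lsv=lsv,
                    junction=j,
                    e_psi_a=float(r["e_psi_a"]),
                    e_psi_b=float(r["e_psi_b"]),
                    e_dpsi=float(r["e_dpsi"]),
                    probs=probs,
                    tier=str(r["tier"]),
                )
            )
    return calls


def events_to_frame(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        flags = ev.de_novo[ev.primary_junction]
        d, a = ev.dinucleotides[ev.primary_junction]
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "event_class": ev.event_class,
                "junctions": ";".join(
                    f"{j.start}-{j.end}" for j in ev.junctions
                ),
                "primary_junction": f"{ev.primary_junction.start}-{ev.primary_junction.end}",
                "reference_junction": (
                    f"{ev.reference_junction.start}-{ev.reference_junction.end}"
                    if ev.reference_junction
                    else ""
                ),
                "junction_de_novo": not flags.junction_annotated,
                "donor_de_novo": not flags.donor_annotated,
                "acceptor_de_novo": not flags.acceptor_annotated,
                "donor_dinucleotide": d,
                "acceptor_dinucleotide": a,
                "non_canonical_donor": ev.non_canonical_donor,
                "delta_length": ev.delta_length,
                "exon_start": ev.exon.start if ev.exon else "",
                "exon_end": ev.exon.end if ev.exon else "",
                "tier": ev.tier,
                "e_dpsi": ev.e_dpsi,
                "asymmetry_ratio": (
                    ev.terminal_evidence.asymmetry_ratio
                    if ev.terminal_evidence
                    else ""
                ),
                "polya_position": (
                    ev.terminal_evidence.polya_position
                    if ev.terminal_evidence
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def load_inputs(cfg: RunConfig):
    genome = read_fasta(cfg.genome)
    graph = read_gtf(cfg.gtf)
    singles = []
    from .psi import Sample

    for sample_id, path, condition in read_sample_sheet(cfg.sample_sheet):
        t = read_sj_table(path, sample_id, condition, graph)
        singles.append((Sample(sample_id, condition), t))
    table = JunctionCountTable.from_samples(singles)
    return genome, graph, table


def run_pipeline(cfg: RunConfig) -> RunResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log.info("loading inputs")
    genome, graph, table = load_inputs(cfg)

    log.info("quantifying PSI/dPSI")
    calls = quantify_all(
        graph,
        table,
        min_total=cfg.min_total,
        v_set=cfg.v_set,
        n_draws=cfg.n_draws,
        seed=cfg.seed,
        alpha=cfg.alpha,
        threshold=cfg.threshold,
    )
    n_conf = sum(1 for c in calls if c.tier != "none")
    log.info("%d LSV junction calls, %d at a confidence tier", len(calls), n_conf)
    calls_df = calls_to_frame(calls)
    artifacts["psi_calls"] = out / "psi_calls.tsv"
    _write_tsv(calls_df, artifacts["psi_calls"], cfg)

    log.info("classifying events")
    terminal_cfg = TerminalExonConfig(
        window_nt=cfg.polya_window,
        signal_set=tuple(cfg.polya_signals),
        min_ratio=cfg.min_ratio,
    )
    events = classify_events(calls, graph, genome, table, terminal_cfg)
    log.info("%d events classified", len(events))
    artifacts["events"] = out / "events.tsv"
    _write_tsv(events_to_frame(events), artifacts["events"], cfg)
    proportions = summarize_event_types(events)
    artifacts["event_proportions"] = out / "event_proportions.tsv"
    _write_tsv(proportions, artifacts["event_proportions"], cfg)

    log.info("assessing reading-frame impact")
    impacts = assess_events(events, graph, genome)
    impact_df = pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "transcript_id": r.transcript_id,
                "delta_length": r.delta_length,
                "frame_preserving": r.frame_preserving,
                "introduces_stop": r.introduces_stop,
                "codons_affected": r.codons_affected,
                "disruption": r.disruption,
            }
            for r in impacts
        ]
    )
    artifacts["impact"] = out / "impact.tsv"
    _write_tsv(impact_df, artifacts["impact"], cfg)

    log.info("scoring splice-site strength")
    donor_pwm, acceptor_pwm = train_pwms_from_graph(graph, genome)
    reference = {
        "donor": reference_scores_from_graph(graph, genome, donor_pwm),
        "acceptor": reference_scores_from_graph(graph, genome, acceptor_pwm),
    }
    ese = read_ese_list(cfg.ese_list) if cfg.ese_list else None
    strength_df, strength_summary = compare_cryptic_vs_downstream(
        events, graph, genome, donor_pwm, acceptor_pwm, ese, reference
    )
    artifacts["strength"] = out / "strength.tsv"
    _write_tsv(strength_df, artifacts["strength"], cfg)

    clip_table = None
    if cfg.crosslinks:
        log.info("pentamer enrichment around crosslink sites")
        kcfg = KmerConfig(k=cfg.clip_k, flank=cfg.clip_flank)
        sites = sites_from_bed(read_bed(cfg.crosslinks))
        windows = extract_windows(sites, genome, kcfg)
        ctrl = control_windows(windows, seed=cfg.seed, cfg=kcfg)
        clip_table = enrichment_vs_control(
            kmer_window_fractions(windows, kcfg),
            kmer_window_fractions(ctrl, kcfg),
            n_obs=len(windows),
            n_ctrl=len(ctrl),
        )
        artifacts["clip_enrichment"] = out / "clip_enrichment.tsv"
        _write_tsv(clip_table, artifacts["clip_enrichment"], cfg)
        regions_df = region_distribution(sites, graph)
        artifacts["clip_regions"] = out / "clip_regions.tsv"
        _write_tsv(regions_df, artifacts["clip_regions"], cfg)
        regulated = sorted(
            {c.junction for c in calls if c.tier != "none"}
        )
        control_juncs = sorted(
            j
            for j in graph.annotated_junctions
            if j not in set(regulated)
        )[: max(10, len(regulated))]
        if regulated and control_juncs:
            top = list(clip_table.head(3)["kmer"])
            mmap = motif_position_map(
                {"regulated": regulated, "control": control_juncs},
                genome,
                top,
            )
            mm_df = pd.DataFrame(
                {
                    "offset": mmap.offsets,
                    **{name: tr for name, tr in mmap.tracks.items()},
                    "ratio": mmap.ratio,
                }
            )
            artifacts["motif_map"] = out / "motif_map.tsv"
            _write_tsv(mm_df, artifacts["motif_map"], cfg)

    summary = report(cfg, events, impacts, strength_summary, clip_table)
    artifacts["summary"] = out / "summary.json"
    with open(artifacts["summary"], "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return RunResult(
        calls=calls,
        events=events,
        impacts=impacts,
        strength_summary=strength_summary,
        clip_table=clip_table,
        summary=summary,
        artifacts=artifacts,
    )


def report(
    cfg: RunConfig,
    events: Sequence[SpliceEvent],
    impacts,
    strength_summary: dict,
    clip_table: Optional[pd.DataFrame],
) -> dict:
    """Summary document: event-class proportions, the disruptive fraction
    among cryptic internal exons, strength comparison, top pentamers."""
    proportions = summarize_event_types(events)
    cryptic_ids = {
        ev.event_id for ev in events if ev.event_class == "cryptic_internal_exon"
    }
    cryptic_reports = [r for r in impacts if r.event_id in cryptic_ids]
    frac = disruptive_fraction(cryptic_reports)
    summary = {
        "n_events": len(events),
        "event_class_percentages": {
            r["event_class"]: r["percent"] for _, r in proportions.iterrows()
        },
        "cryptic_internal_exon_disruptive_fraction": frac,
        "strength_comparison": strength_summary,
    }
    if clip_table is not None:
        top = clip_table.head(cfg.top_k)
        summary["top_pentamers"] = [
            {
                "kmer": r["kmer"],
                "log2_enrichment": float(r["log2_enrichment"]),
                "contains_AA": bool(r["contains_AA"]),
            }
            for _, r in top.iterrows()
        ]
    else:
        summary["top_pentamers"] = None  # clip input absent, not empty
    return summary
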