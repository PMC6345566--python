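"""Splice-site strength scoring and exonic splicing enhancer (ESE) content.

Site strength is a position weight matrix (PWM) log2-odds score over a
fixed window — donor: 3 exonic + 6 intronic nt; acceptor: 20 intronic
(covering the polypyrimidine tract) + 3 exonic nt — reported as a midrank
percentile against a reference score set, by default the annotated sites
of the supplied annotation.  Percentiles are comparable across sites; the
raw log-odds scale is not meaningful on its own.

ESE content is the density of overlapping hexamer hits per 100 nt of exon
sequence.  The hexamer catalogue is user-supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    ExonInterval,
    GenomeSequence,
    SpliceGraph,
    SpliceJunction,
    TranscriptModel,
    reverse_complement,
)

log = logging.getLogger(__name__)

DONOR_EXONIC, DONOR_INTRONIC = 3, 6  # window -3..+6 around the 5'ss
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # window -20..+3 around the 3'ss
WINDOW_LENGTH = {"donor": DONOR_EXONIC + DONOR_INTRONIC,
                 "acceptor": ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PwmModel:
    site_kind: str  # donor | acceptor
    log_odds: np.ndarray  # (window length, 4), log2 odds vs background
    pseudocount: float
    background: np.ndarray

    def score(self, window: str) -> Optional[float]:
        """Sum of per-position log-odds; None if the window contains N."""
        if len(window) != self.log_odds.shape[0]:
            raise ValueError(
                f"{self.site_kind} window must be {self.log_odds.shape[0]} nt"
            )
        total = 0.0
        for i, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return None
            total += self.log_odds[i, idx]
        return total

    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[i] for i in self.log_odds.argmax(axis=1))


def train_pwm(
    sites: Sequence[str],
    site_kind: str,
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
) -> PwmModel:
    """Train a log2-odds PWM from aligned windows of the kind's fixed length."""
    if site_kind not in WINDOW_LENGTH:
        raise ValueError(f"site_kind must be donor or acceptor, got {site_kind!r}")
    if not sites:
        raise ValueError("need at least one training window")
    length = WINDOW_LENGTH[site_kind]
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = np.zeros((length, 4))
    for w in sites:
        if len(w) != length:
            raise ValueError(f"window {w!r} is not {length} nt")
        for i, base in enumerate(w):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                raise ValueError(f"window {w!r} contains a non-ACGT base")
            counts[i, idx] += 1
    freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return PwmModel(
        site_kind=site_kind,
        log_odds=np.log2(freqs / bg),
        pseudocount=pseudocount,
        background=bg,
    )


def donor_window(genome: GenomeSequence, junction: SpliceJunction) -> str:
    """3 exonic + 6 intronic nt around the 5' splice site, 5'->3'."""
    if junction.strand == "+":
        return genome.fetch(
            junction.chrom, junction.start - DONOR_EXONIC, junction.start + DONOR_INTRONIC
        )
    return reverse_complement(
        genome.fetch(
            junction.chrom, junction.end - DONOR_INTRONIC, junction.end + DONOR_EXONIC
        )
    )


def acceptor_window(genome: GenomeSequence, junction: SpliceJunction) -> str:
    """20 intronic + 3 exonic nt around the 3' splice site, 5'->3'."""
    if junction.strand == "+":
        return genome.fetch(
            junction.chrom,
            junction.end - ACCEPTOR_INTRONIC,
            junction.end + ACCEPTOR_EXONIC,
        )
    return reverse_complement(
        genome.fetch(
            junction.chrom,
            junction.start - ACCEPTOR_EXONIC,
            junction.start + ACCEPTOR_INTRONIC,
        )
    )


def score_site(
    pwm: PwmModel,
    genome: GenomeSequence,
    junction: SpliceJunction,
    side: Optional[str] = None,
) -> Optional[float]:
    """Score the fixed window around one side of a junction.

    Returns None (excluded from percentiles) when the window contains N.
    """
    side = side or pwm.site_kind
    if side != pwm.site_kind:
        raise ValueError(f"PWM is for {pwm.site_kind}, asked to score {side}")
    window = donor_window(genome, junction) if side == "donor" else acceptor_window(
        genome, junction
    )
    return pwm.score(window)


def percentile_rank(score: float, reference_scores: Sequence[float]) -> float:
    """Midrank percentile of score against a reference distribution:
    100 * (#strictly-less + 0.5 * #equal) / n."""
    ref = [s for s in reference_scores if s is not None]
    if not ref:
        raise ValueError("reference score set is empty")
    less = sum(1 for s in ref if s < score)
    equal = sum(1 for s in ref if s == score)
    return 100.0 * (less + 0.5 * equal) / len(ref)


@dataclass(frozen=True)
class EseModel:
    hexamers: frozenset[str]

    def __post_init__(self):
        for h in self.hexamers:
            if len(h) != 6 or any(b not in _BASE_INDEX for b in h):
                raise ValueError(f"bad ESE hexamer {h!r}")


def read_ese_list(path) -> EseModel:
    """One uppercase hexamer per line; blank and '#' lines ignored."""
    hexamers = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if line and not line.startswith("#"):
                hexamers.add(line)
    return EseModel(frozenset(hexamers))


def ese_density(exon_seq: str, ese_model: EseModel) -> float:
    """Overlapping hexamer hits per 100 nt of exon sequence."""
    if len(exon_seq) < 6:
        raise ValueError("exon sequence shorter than one hexamer")
    hits = sum(
        1
        for i in range(len(exon_seq) - 5)
        if exon_seq[i : i + 6] in ese_model.hexamers
    )
    return 100.0 * hits / (len(exon_seq) - 5)


def train_pwms_from_graph(
    graph: SpliceGraph, genome: GenomeSequence, pseudocount: float = 0.5
) -> tuple[PwmModel, PwmModel]:
    """Donor and acceptor PWMs trained on all annotated junctions."""
    donors, acceptors = [], []
    for j in sorted(graph.annotated_junctions):
        d, a = donor_window(genome, j), acceptor_window(genome, j)
        if "N" not in d:
            donors.append(d)
        if "N" not in a:
            acceptors.append(a)
    return (
        train_pwm(donors, "donor", pseudocount),
        train_pwm(acceptors, "acceptor", pseudocount),
    )


def reference_scores_from_graph(
    graph: SpliceGraph, genome: GenomeSequence, pwm: PwmModel
) -> list[float]:
    """Scores of every annotated site of the PWM's kind (N windows skipped)."""
    scores = []
    for j in sorted(graph.annotated_junctions):
        s = score_site(pwm, genome, j)
        if s is not None:
            scores.append(s)
    return scores


def _exon_sequence(exon: ExonInterval, genome: GenomeSequence) -> str:
    seq = genome.fetch(exon.chrom, exon.start, exon.end)
    return seq if exon.strand == "+" else reverse_complement(seq)


def _downstream_exon(
    event, graph: SpliceGraph
) -> Optional[tuple[TranscriptModel, int]]:
    """The annotated exon immediately downstream (3') of the event exon."""
    if event.gene_id is None or event.exon is None:
        return None
    for tid in graph.genes.get(event.gene_id, []):
        t = graph.transcripts[tid]
        if event.strand == "+":
            for i, e in enumerate(t.exons):
                if e.start >= event.exon.end:
                    return t, i
        else:
            for i in range(len(t.exons) - 1, -1, -1):
                if t.exons[i].end <= event.exon.start:
                    return t, i
    return None


def _exon_site_junctions(t: TranscriptModel, idx: int):
    """(acceptor junction, donor junction) flanking exon idx, or None."""
    juncs = t.junctions()
    if t.strand == "+":
        acc = juncs[idx - 1] if idx > 0 else None
        don = juncs[idx] if idx < len(juncs) else None
    else:
        acc = juncs[idx] if idx < len(juncs) else None
        don = juncs[idx - 1] if idx > 0 else None
    return acc, don


def compare_cryptic_vs_downstream(
    events,
    graph: SpliceGraph,
    genome: GenomeSequence,
    donor_pwm: PwmModel,
    acceptor_pwm: PwmModel,
    ese_model: Optional[EseModel],
    reference_scores: dict[str, Sequence[float]],
) -> tuple[pd.DataFrame, dict]:
    """Per cryptic internal exon: donor/acceptor strength percentiles and
    ESE density versus its immediately downstream annotated exon, with
    paired t-tests over the cohort."""
    rows = []
    for ev in events:
        if ev.event_class not in ("cryptic_internal_exon", "annotated_cassette"):
            continue
        ds = _downstream_exon(ev, graph)
        if ds is None:
            log.warning("%s: no downstream exon found, skipped", ev.event_id)
            continue
        t, idx = ds
        down_exon = t.exons[idx]
        # cryptic exon's flanking junctions: inclusion (acceptor side) and
        # splice-out (donor side), picked by geometry
        if ev.strand == "+":
            acc_j = next((j for j in ev.junctions if j.end == ev.exon.start), None)
            don_j = next((j for j in ev.junctions if j.start == ev.exon.end), None)
        else:
            acc_j = next((j for j in ev.junctions if j.start == ev.exon.end), None)
            don_j = next((j for j in ev.junctions if j.end == ev.exon.start), None)
        down_acc, down_don = _exon_site_junctions(t, idx)
        row = {"event_id": ev.event_id, "gene_id": ev.gene_id}
        for label, jn, pwm in (
            ("cryptic_acceptor", acc_j, acceptor_pwm),
            ("cryptic_donor", don_j, donor_pwm),
            ("downstream_acceptor", down_acc, acceptor_pwm),
            ("downstream_donor", down_don, donor_pwm),
        ):
            pct = None
            if jn is not None:
                s = score_site(pwm, genome, jn)
                if s is not None:
                    pct = percentile_rank(s, reference_scores[pwm.site_kind])
            row[f"{label}_percentile"] = pct
        if ese_model is not None:
            row["cryptic_ese_density"] = ese_density(
                _exon_sequence(ev.exon, genome), ese_model
            )
            row["downstream_ese_density"] = ese_density(
                _exon_sequence(down_exon, genome), ese_model
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    summary: dict = {"n": len(df)}
    if len(df) >= 2:
        for name, a_col, b_col in (
            ("acceptor_percentile", "cryptic_acceptor_percentile",
             "downstream_acceptor_percentile"),
            ("ese_density", "cryptic_ese_density", "downstream_ese_density"),
        ):
            if a_col not in df or b_col not in df:
                continue
            paired = df[[a_col, b_col]].dropna()
            if len(paired) < 2:
                continue
            t_stat, p = stats.ttest_rel(paired[a_col], paired[b_col])
            summary[name] = {
                "cryptic_mean": float(paired[a_col].mean()),
                "downstream_mean": float(paired[b_col].mean()),
                "t": float(t_stat),
                "p": float(p),
                "n": int(len(paired)),
            }
    return df, summary
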