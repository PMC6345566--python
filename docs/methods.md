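# Methods

## Quantification model

Junction-spanning read counts are modelled per local splicing variation
(LSV): the junctions sharing one donor (source LSV) or one acceptor
(target LSV), with at least two members and at least 10 summed reads
(`min_total`, configurable). Per replicate the member counts get a
Dirichlet posterior with a flat prior α = 1 (configurable); E(PSI) is the
posterior mean averaged over replicates, so with a single replicate it
reduces to the closed form (c + α)/(Σc + Jα), which the tests assert to
1e−9.

ΔPSI is estimated by Monte Carlo (default 10,000 draws): each draw picks
one replicate uniformly per condition, samples its Dirichlet, and takes
the difference of the two PSI coordinates. Replicates enter as an
equal-weight mixture rather than pooled counts so that between-replicate
variability widens the posterior. A junction is called at tier V when
P(|ΔPSI| ≥ V) ≥ 0.95; the default V set is {0.1, 0.2} ("V10"/"V20").
This is deliberately a simple, fully testable posterior model: it keeps
the calling contract (a posterior tail probability against a minimum
effect size) without any read-stack bootstrapping, GC correction, or
empirically fitted priors. Calls are deterministic given the seed;
the pipeline derives one child seed per LSV from the master seed so a
single LSV can be re-quantified in isolation and reproduce the
pipeline's numbers.

## Event classification

Confident calls are grouped into connected components linked by shared
junctions or LSVs. Within a group:

* the **reference junction** is the annotated member with the highest
  pooled count (ties broken toward the leftmost coordinate);
* **changing junctions** are members at a tier, excluding the reference —
  the reference always changes complementarily to its alternatives, and
  treating it as "changing" would misread every binary switch as
  complex;
* **companion junctions** are de-novo members with reads that never
  reach a tier on their own. Two geometries need them. A premature
  terminal exon's splice-out junction is depleted by design (that is
  what the asymmetry measures), so it cannot reach a tier. An exitron's
  interior junction sits in an LSV with no reads at all in the control
  condition, where the Dirichlet posterior stays at its prior and ΔPSI
  cannot become confident no matter how clear the event is.

Rules apply in a fixed order, so classification is deterministic:

1. **exitron** — any de-novo group junction lying strictly inside one
   annotated exon;
2. **cassette-type geometry** — a junction pair delimiting an interval
   whose outer splice sites are annotated. The putative exon is first
   tested for terminal-exon evidence (below); otherwise it is a
   `cryptic_internal_exon` when either inner splice site is de-novo,
   else `annotated_cassette`;
3. **alternative 5′/3′ splice sites** — a single changing junction
   sharing its acceptor (alt 5′) or donor (alt 3′) with the reference.
   The signed mRNA length change is the reference intron length minus
   the alternative intron length, which makes extension (+) versus
   truncation (−) strand-independent;
4. otherwise **complex**.

Terminal-exon evidence requires both the junction-read asymmetry
(inclusion/splice-out ≥ `min_ratio`, default 5 — conservatively below
the worked 14-fold case; zero splice-out counts satisfy it) and a polyA
signal on the transcribed strand within `window_nt` (default 500) nt
downstream of the exon's 3′ end. The signal set defaults to {AATAAA}
exactly; variants such as ATTAAA can be added by configuration. The
most proximal hit is reported.

Boundary dinucleotides are recorded for every junction; a de-novo
junction whose donor is not GT sets the `non_canonical_donor` flag (GC
donors — the recognised minor class — are therefore flagged, never
silently accepted).

## ORF impact

The reading-frame rule: an event is disruptive iff its mRNA length
change is not a multiple of three or it introduces an in-frame stop;
events not overlapping the CDS (genomic bounds) are noncoding; the rest
are tolerated. Phase is recomputed by walking the spliced transcript
from the annotated CDS start; GTF frame attributes are ignored. For
insertions the scan covers the inserted sequence *plus* the codons
straddling both splice boundaries, so stops formed by hybrid codons are
caught; for deletions only the new junction codon can gain a stop.
Multi-transcript genes are summarised on the longest-CDS transcript
(per-transcript reports remain available). The disruptive fraction is
counted per event. Equivalence with a brute-force
splice-translate-compare oracle is asserted on 1,000 random events.
NMD prediction (the 50-nt rule) is intentionally out of scope: the rule
scored here is frame/stop disruption, not decay.

## Splice-site strength and ESE content

One explicit PWM log₂-odds model per site kind — donor window −3..+6
(3 exonic + 6 intronic nt), acceptor window −20..+3 (covering the
polypyrimidine tract) — trained with pseudocount 0.5 against a uniform
background, scored strand-aware, with N-containing windows excluded.
Scores are reported as midrank percentiles against a reference score
set, by default all annotated sites of the supplied annotation. No
numeric equality with any published multi-algorithm scorer is claimed;
percentile *direction* (cryptic below downstream-annotated) is the
tested property. ESE content is overlapping hexamer hits per 100 nt;
the hexamer catalogue is user-supplied (the tests use a small synthetic
set).

## Crosslink pentamer enrichment

Windows are ±50 nt around each single-base crosslink site (101 nt),
strand-aware; truncated or N-containing windows are dropped with a
logged count. Each pentamer is counted at most once per window, and the
statistic per pentamer is the fraction of windows containing it.
Controls default to per-window dinucleotide-preserving shuffles
(Altschul–Erickson walk; exact census preservation is property-tested),
with user-supplied control regions as an alternative. Enrichment is
log₂((f_obs + p)/(f_ctrl + p)) with pseudocount p = 1/n_windows,
ranked descending with lexicographic tie-breaks; a two-proportion
z-score is reported alongside but does not drive ranking.

A consequence of composition-matched controls worth knowing: the control
fraction of a planted pentamer grows roughly with its observed fraction
(shuffles can reform it from its own dinucleotides), so log-ratios
compress at high planted fractions and the rank-1 pentamer among several
planted motifs is the one whose exact arrangement is least reformable,
not necessarily the most frequently planted. With a single planted
pentamer, rank 1 is a stable, tested property.

Motif maps anchor windows at the donor or acceptor boundary in
transcript orientation, mark every position a query pentamer overlaps,
average across junctions per set, smooth with a running mean, and report
the regulated/control ratio track.

## Synthetic data generator

The generator emulates the assumed study design: two conditions × three
replicates, ~100 junction-spanning reads per LSV. Defaults: planted
PSI 0.0 (condition A) → 0.5 (condition B); negative-binomial
(gamma-Poisson) depth with dispersion 0.1 — the simplest overdispersed
model for between-replicate variability — with multinomial allocation to
member junctions; 20 planted events per class; a `noise_free` mode uses
exact rounded allocations for recovery tests. Genes are built in
transcript-local coordinates with canonical elements (donor
CAG|GTAAGT, acceptor polypyrimidine tract + CAG|G) and flipped onto the
minus strand for about half the genes, so strand handling is exercised
everywhere.

Per class: cryptic internal exons sit mid-intron with weak acceptors
(2 mismatches in the pyrimidine tract by default — what the strength
comparison detects), planted ESE hexamers mirrored into the downstream
exon at equal copy number and near-equal length so densities match, and
an exact 84% of them frame-disrupting (length not a multiple of three;
in-frame plants are scrubbed of chunk stops). Exitron lengths are
multiples of three with a clean junction codon, every fifth exitron gets
a GC donor. Terminal exons sit in the 5′UTR intron with AATAAA planted
60 nt downstream (the host intron is scrubbed of chance signals first)
and splice-out reads at 1/14 of inclusion. Alt-site offsets are drawn
from 90–240 nt. The truth manifest records planted junctions, PSI
values, length changes and frame status, and always resolves against the
emitted GTF.

Crosslink simulation places sites in gene bodies — by default at
positions whose windows are clear of splice-site elements, so window
content is background plus plants (a `uniform` placement exists for
region-distribution analyses) — and writes pentamers into the genome at
guarded, non-overlapping offsets, skipping a protected interval set that
covers all splice elements and polyA signals. The default plant set is
ten AA-containing pentamers with AA away from the edges, so the shifted
pentamers that write boundaries create also contain AA.

What the generator does **not** emulate: read-level errors and mapping
bias, overlapping genes and alternative promoters, realistic splice-site
sequence diversity (annotated sites are near-identical, which makes the
PWM reference distribution much tighter than for real annotation), and
correlated crosslink/splicing placement. Passing tests therefore show
the statistics and classifiers behave as specified under their own
model assumptions, not that real-data performance matches.

## Problem sizes and numerical choices

The shipped tests run the default cohort (160 planted events), a
1,000-event ORF oracle sweep, 1,500 crosslink sites, and n = 10 strength
cohorts; the full suite completes in well under a minute. Ties are
broken deterministically everywhere (leftmost coordinate, lexicographic
k-mer order); all randomness flows from explicit seeds and simulation
outputs are byte-identical on rerun. Degenerate inputs fail loudly:
zero/zero asymmetry, empty reference score sets, empty window lists and
mixed-strand event groups raise errors rather than returning defaults.

## Known limitations

Intron retention is not quantified (junction counts cannot see it);
full novel-transcript assembly is out of scope; no multiple-testing
correction is applied across LSVs (calling is posterior-probability
based); the exitron rule accepts any de-novo junction wholly inside an
annotated exon, so an exitron co-occurring with an independent alt-site
change in the same group is reported once as an exitron plus separate
alt-site events from the other LSVs of the group.
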