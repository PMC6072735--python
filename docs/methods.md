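# Methods

## Scope and data model

The pipeline operates on transcript *structures*: ordered, non-overlapping
exon chains on a stranded chromosome.  Internally all coordinates are
0-based half-open; GFF3/GTF I/O converts to and from the 1-based inclusive
convention, and 5′/3′ exon ends are resolved in transcript orientation
(5′ = genomic start on the + strand, genomic end on the − strand).  Exon
chains are stored in genomic order; consecutive exons must be separated by
at least one base, so the exons and introns of a transcript tile its span
exactly.  Observed transcripts carry an integer read-support count
(`coverage`), a sampling site (KIL/GDA) and a salinity treatment
(CTRL/LS/RS); their gene assignment is taken from the GTF `gene_id`
attribute — read mapping and transcript assembly are upstream of this
package.

## Event detection

Detection compares one observed chain against one annotated isoform:

1. **Pairing.**  Each observed exon is paired with the reference exon of
   maximal base overlap (ties to the smaller reference start).  The pairing
   is injective on reference exons: a reference exon claimed twice goes to
   the larger overlap, ties to the upstream observed exon.  Zero-overlap
   exons stay unmatched.
2. **IR.**  An observed exon whose span contains an entire reference intron
   and overlaps both flanking reference exons yields one intron-retention
   event per retained intron; the defining interval is the intron.  Exons
   consumed by IR are excluded from boundary comparison, so a fused exon is
   not additionally scored AA/AD/AP.
3. **ES.**  A reference exon lying inside the observed span with zero
   overlap to every observed exon is an exon-skipping event; the defining
   interval is the skipped exon.  Reference exons outside the observed span
   are treated as truncation, not skipping.
4. **Boundary events.**  For every remaining matched pair the two genomic
   boundaries are compared, except the outer boundary of a chain-terminal
   exon in either chain (alternative TSS/polyadenylation is not splicing).
   One differing 5′ end is AD, one differing 3′ end is AA, both differing
   is AP, under the default `paper` end convention; `conventional` swaps
   the AD and AA labels.  The defining interval is the observed exon.

An observed exon absent from the reference (an exon gained relative to the
annotation) maps onto none of the five classes and is deliberately not
scored; the taxonomy describes losses and boundary changes relative to the
reference.

**Reference isoform choice.**  The annotated isoform minimizing the event
count explains the observation; ties break by fewer ES events, then the
lexicographically smaller transcript id.  By default only genes with ≥ 2
annotated isoforms are considered (`restrict_to_annotated_AS`), matching a
design that trusts the annotation's own AS flags; the switch can be
disabled for exploratory runs.

**Conservation.**  An event is conserved iff some *other* annotated isoform
of the gene exhibits an event with the same type and exactly equal defining
coordinates relative to the matched reference isoform.  Note an important
interaction with parsimonious reference choice: an observed chain that
simply replays an annotated isoform's processing *is* that isoform (zero
events), and any extra copy of such an event is absorbed by matching the
isoform that carries it.  The only configuration in which a conserved call
can surface is one where the inverse of the annotated difference is not
expressible in the event taxonomy — in practice, genes whose second isoform
retains an intron: trimming the fused exon back to one flank is a boundary
event relative to the second isoform that the first isoform reproduces
coordinate-for-coordinate.  The generator plants conserved truth through
exactly this construction, and the detector recovers it; conservation rates
from real cohorts should be read with the same caveat.

**Filtering and accounting.**  Transcripts with coverage < 2 are excluded
before detection (single-read support).  Identical events supported by
several group records of the same variant count once per variant; across
variants they stay distinct.  Every callset partitions into conserved +
novel events, and a variant is novel if any of its events is novel.

## Synthetic cohorts

The generator emulates the study conditions the package models: 300 genes
(exon counts 6–10, exon lengths 60–200 bases, introns 80–400), 60% of genes
carrying a second annotated isoform differing by exactly one uniformly
typed event; 600 observed variants on annotated-AS genes; event types drawn
from a mix dominated by ES (ES 0.518, AA 0.20, AD 0.13, AP 0.083,
IR 0.069); 1–3 events requested per variant at pairwise-distant loci (an
exon-index distance ≥ 2 from each other and from the second isoform's
locus, so planted events never interact — when a donor runs out of eligible
loci, fewer events are planted and the truth table reflects what was
actually planted); 5% unmodified transcripts; 11% conserved variants via
the intron-retention construction above; Poisson(30) coverage with 10%
coverage-1 decoys; equiprobable sites; and a treatment Venn structure with
proportions 462/16/15/11/3/1/1 over the seven regions (the sharing pattern
of the 509-variant cohort the study design comes from).  Boundary shifts
are uniform on [1, min(10, slack)] bases and never touch terminal exon
outer boundaries.  All randomness flows from one integer seed; identical
seeds give byte-identical GFF3/GTF/JSON outputs.

What the generator does **not** emulate: read-level noise (assembly or
mapping artifacts), exons gained relative to the annotation, overlapping
genes, coverage–event correlations, or any salinity effect size on event
rates (group sharing is a free parameter).  Passing recovery tests
therefore demonstrate the correctness of the structural comparison, not
robustness to noisy assemblies.

## Summaries

Events-per-variant bins are [1, 9], [10, 19], [20, ∞); percentages are
half-away-from-zero at two decimals (this convention reproduces the
printed 72.50/20.63/6.88 split of 369/105/35 over 509).  Group summary SD
is the sample (n−1) standard deviation (reproducing 1,825 / 689 / 0.351
for the printed per-group reads/genes/megabases).  Venn partitions are
exact: a variant observed in exactly {LS, RS} counts in that region only,
and region counts always sum to the number of labeled variants.  Species
sharing uppercases and trims symbols, counts focal genes present in any
catalog and in ≥ 2 catalogs, and reports the latter as a percentage of the
former.  Novelty per variant is the OR over its events.

## Enrichment

`hypergeom_upper_tail` uses the survival function of
`scipy.stats.hypergeom`; it matches exhaustive-enumeration rationals to
well below 1e-10 for all populations ≤ 12 and is monotone in the overlap.
BH q-values come from the standard step-up construction
(`statsmodels.stats.multitest`), satisfying q ≥ p and monotonicity along
the sorted p order.  The tested family is the set of terms passing the
minimum-overlap filter (filter-then-adjust); the choice is recorded in the
output metadata because adjusted values are only comparable within a
declared family.  Term membership is intersected with the background
before sizing.  Null calibration uses population sizes
(N, K, n) = (5000, 1000, 500), where the discrete p-value distribution is
close enough to uniform that the empirical type-I rate at α = 0.05 sits
within a 4σ binomial band of α over 1,000 simulations; with much smaller
terms the test is visibly conservative (discreteness), which is a property
of the hypergeometric test, not an implementation artifact.

## Numerical and design choices

- Rounding is half-away-from-zero everywhere a percentage is printed;
  known report-internal inconsistencies (a printed 2.94 where the printed
  inputs give 2.95, a 95.67 where they give 95.68) are not chased — the
  rule is canonical and the discrepant values are excluded from checks.
- The AD/AA naming follows the source study's stated rule (same 3′ end,
  different 5′ end → AD), which inverts the donor/acceptor convention used
  by most splicing tools; `end_convention: conventional` swaps the labels.
- Strand symmetry: relabelling the strand of all intervals swaps AD and AA
  and fixes ES/IR/AP; mirroring coordinates *and* flipping strand is an
  exact symmetry of transcript orientation and preserves every call.
- Degenerate inputs: empty callsets are an error for type frequencies,
  an empty label set is an error in Venn partitioning, single-value groups
  are an error for SD, and a coverage attribute is never defaulted.
- Problem sizes used by the test and acceptance runs (300 genes, 600
  variants, 1,000 null simulations, enumeration up to 5-exon chains with
  shifts ≤ 3) keep every stage in seconds while exercising all code paths.

## Known limitations

- Exon gains relative to the reference are invisible to the taxonomy (see
  above); so are combined IR-plus-boundary changes on the same fused exon,
  which are reported as IR only.
- Conservation is only observable in the intron-retention configuration
  under parsimonious reference selection; cohorts whose annotated isoform
  differences are all ES or boundary events will show zero conserved calls
  by construction.
- Reference isoform choice by parsimony is a modelling decision; the
  matched isoform is reported per variant so alternative policies can be
  audited.
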