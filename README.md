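# codsplice

Detection, typing and downstream analysis of alternative-splicing (AS)
variants from observed transcript structures, built around the kind of
cohort study that compares gill transcriptomes of Baltic cod held at
control, lowered and raised salinity across two sampling sites.  The
package is purely structural: it starts from exon chains (a reference
annotation in GFF3 and observed transcripts in GTF) and never touches
reads or sequence.

## What it computes

Given an observed transcript *O* and an annotated isoform *R* of the same
gene, every structural difference is typed as one of five events:

| type | definition |
|------|------------|
| ES   | a reference exon inside the observed span with zero overlap to every observed exon (exon skipping) |
| IR   | an observed exon that contains a whole reference intron and overlaps both flanking exons (intron retention) |
| AD   | a matched internal exon with the same 3′ end but a different 5′ end (alternative donor; `end_convention: conventional` swaps the AD/AA labels) |
| AA   | the mirror case — same 5′ end, different 3′ end |
| AP   | both ends of a matched internal exon differ (alternative position) |

Typing precedence is IR > ES > boundary events, outer boundaries of
chain-terminal exons are never compared (alternative transcription start or
polyadenylation is not splicing), and observed transcripts supported by a
single read are excluded.  The reference isoform for each observation is
chosen by parsimony (fewest events, then fewest ES, then smallest
transcript id).  An event is **conserved** when another annotated isoform
of the gene exhibits the same event — same type, identical coordinates —
relative to the matched reference; otherwise it is a novel arrangement.

On top of the calls the package reproduces the usual cohort-report
surfaces: events-per-variant bins, event-type frequencies, novel/conserved
splits, exact Venn partitions of variants across treatment groups or sites,
cross-species sharing of AS gene symbols, and mean ± SD group summaries.
Term over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for an overlap of k query genes with a K-member term in an
N-gene background, with Benjamini–Hochberg q-values (default filters:
minimum overlap 4, p < 0.01, q < 0.05 flagged).

A synthetic-data module generates the whole study shape — multi-isoform
gene models, cohorts with planted events of all five types, coverage-1
decoys, six site × treatment groups with configurable sharing, and GMT term
sets with one planted enriched term — with full ground truth, so every
stage is testable end to end.

## Worked example

```
python analysis/01_simulate.py --seed 1   # reference + cohort + truth + terms
python analysis/02_detect.py              # event calls + recovery vs truth
python analysis/03_summarize.py           # bins, types, Venn, sharing
python analysis/04_enrich.py              # term over-representation
```

The detection step prints, for the default seed-1 cohort:

```
1745 observed records, 175 excluded at coverage < 2, 511 AS variants with
710 events (60 conserved / 650 novel)
events by type: {'ES': 346, 'AA': 174, 'IR': 49, 'AD': 92, 'AP': 49}
recovery vs truth (coverage >= 2): precision 1.0000, recall 1.0000,
conservation-flag agreement 1.0000
```

i.e. every planted event is recovered with its exact type and coordinates,
nothing is called on unmodified or coverage-filtered transcripts, and the
conserved/novel flag matches the generator truth.  The enrichment step then
reports the planted term as the only significant one:

```
 * TERM0000 planted enriched term: k=17/K=19, p=0.00126, q=0.0314
```

The same stages are available as a configured pipeline
(`codsplice run --config pipeline.yaml`) with subcommands `simulate`,
`detect` and `enrich` for individual steps; see `codsplice --help`.

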