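#!/usr/bin/env python
"""Summarize the detected AS callset the way a cohort report would.

Writes the events-per-variant bin table, event-type frequencies, the
treatment-group Venn partition and a synthetic cross-species sharing table
under results/, and prints each surface.  The species catalogs used here
are synthetic: deterministic samples of the cohort's own AS gene symbols
standing in for real per-species AS gene lists.
"""

import argparse
from pathlib import Path

import numpy as np

from codsplice import detect_all, species_sharing, novelty_summary, bin_events_per_variant, type_frequencies
from codsplice import io as cio
from codsplice.summarize import variant_treatments, venn_partition


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = cio.read_gff3(args.sim / "reference.gff3")
    observed = cio.read_observed_gtf(args.sim / "observed.gtf")
    callset = detect_all(observed, annotation)

    rows, summary = bin_events_per_variant(callset)
    with open(args.out / "table2_bins.tsv", "w") as fh:
        fh.write("bin\tn_variants\tn_events\tpct_variants\n")
        for r in [*rows, summary]:
            fh.write(f"{r.bin_label}\t{r.n_variants}\t{r.n_events}\t{r.pct_variants:.2f}\n")
    print("events-per-variant bins:")
    for r in rows:
        print(f"  {r.bin_label:>6}: {r.n_variants:4d} variants, {r.n_events:4d} events, {r.pct_variants:6.2f}%")

    n_novel, n_conserved, pct_novel = novelty_summary(callset)
    print(f"novelty: {n_novel} novel / {n_conserved} conserved variants ({pct_novel}% novel)")

    freqs = type_frequencies(callset)
    with open(args.out / "event_type_freq.tsv", "w") as fh:
        fh.write("event_type\tcount\tpct\n")
        for t, (c, p) in freqs.items():
            fh.write(f"{t}\t{c}\t{p:.1f}\n")
    print("event types:", {t: f"{c} ({p}%)" for t, (c, p) in freqs.items()})

    groups = {v: t for v, t in variant_treatments(observed).items() if v in callset.variants}
    parts = venn_partition(groups, total=len(callset.variants))
    with open(args.out / "venn_groups.tsv", "w") as fh:
        fh.write("region\tcount\tpct_of_total\n")
        for p in parts:
            fh.write(f"{'+'.join(sorted(p.region))}\t{p.count}\t{p.pct_of_total:.2f}\n")
    print("treatment-group Venn partition:")
    for p in parts:
        print(f"  {'+'.join(sorted(p.region)):>12}: {p.count:4d} ({p.pct_of_total:.2f}%)")

    # synthetic per-species AS catalogs sampled from the cohort's AS genes
    rng = np.random.default_rng([args.seed, 4])
    focal = {annotation[e.gene_id].symbol for e in callset.events}
    pool = sorted(focal)
    catalogs = {
        sp: set(rng.choice(pool, size=max(2, int(f * len(pool))), replace=False).tolist())
        for sp, f in [("fugu", 0.35), ("medaka", 0.09), ("stickleback", 0.12), ("zebrafish", 0.08)]
    }
    per, n_any, n_two, pct_two = species_sharing(focal, catalogs)
    with open(args.out / "species_sharing.tsv", "w") as fh:
        fh.write("species\tshared\n")
        for sp in sorted(per):
            fh.write(f"{sp}\t{per[sp]}\n")
        fh.write(f"any\t{n_any}\ntwo_or_more\t{n_two}\npct_two_or_more\t{pct_two:.2f}\n")
    print(
        f"species sharing (synthetic catalogs): {n_any} shared with any, "
        f"{n_two} with two or more ({pct_two:.2f}%)"
    )


if __name__ == "__main__":
    main()
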