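"""Configured pipeline: simulate -> detect -> summarize -> enrich.

A single YAML config drives the run; all outputs are plain TSV/JSON under
one output directory and a manifest records the per-stage counts (input
transcripts, coverage-excluded, skipped non-AS-annotated, AS variants,
events, conserved/novel split) so a run leaves an audit trail mirroring the
tallies a cohort report would print.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .detect import ASCallSet, detect_all
from .enrich import run_enrichment
from .models import GenomeAnnotation, ObservedTranscript
from .simulate import SimulationConfig, generate_cohort, generate_reference, generate_term_sets, write_truth
from .summarize import (
    bin_events_per_variant,
    novelty_summary,
    species_sharing,
    type_frequencies,
    variant_treatments,
    venn_partition,
)

log = logging.getLogger("codsplice")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    annotation: str | None = None
    observed: str | None = None
    gmt: str | None = None
    background: str | None = None
    species_catalogs: dict[str, str] = field(default_factory=dict)
    min_coverage: int = 2
    restrict_to_annotated_AS: bool = True
    end_convention: str = "paper"
    min_overlap: int = 4
    p_cutoff: float = 0.01
    q_report: float = 0.05
    seed: int | None = None  # simulation mode
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        if self.end_convention not in ("paper", "conventional"):
            raise ConfigError(f"unknown end_convention {self.end_convention!r}")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        for name in ("p_cutoff", "q_report"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        simulating = self.seed is not None
        if not simulating:
            if self.annotation is None or self.observed is None:
                raise ConfigError("need annotation and observed paths (or a seed to simulate)")
            for label in ("annotation", "observed", "gmt", "background"):
                p = getattr(self, label)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{label} path does not exist: {p}")
            for sp, p in self.species_catalogs.items():
                if not Path(p).exists():
                    raise ConfigError(f"species catalog for {sp} does not exist: {p}")
        if self.gmt is not None and self.background is None and not simulating:
            raise ConfigError("enrichment needs a background list alongside the GMT")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, applying defaults and rejecting unknown
    keys (typos must fail loudly, before any compute)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {', '.join(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError(f"{path}: out_dir is required")
    try:
        config = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    config.validate()
    return config


def _write_events_tsv(callset: ASCallSet, path: Path) -> None:
    lines = ["variant_id\tgene_id\tevent_type\tchrom\tstart\tend\tstrand\treference_isoform_id\tconserved"]
    for e in sorted(callset.events, key=lambda e: (e.variant_id, e.defining_intervals[0].start)):
        iv = e.defining_intervals[0]
        lines.append(
            f"{e.variant_id}\t{e.gene_id}\t{e.event_type}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
            f"{iv.strand}\t{e.reference_isoform_id}\t{int(bool(e.conserved))}"
        )
    path.write_text("\n".join(lines) + "\n")


def _summarize_stage(callset: ASCallSet, observed, out: Path) -> dict:
    rows, summary = bin_events_per_variant(callset)
    with open(out / "table2_bins.tsv", "w") as fh:
        fh.write("bin\tn_variants\tn_events\tpct_variants\n")
        for r in [*rows, summary]:
            fh.write(f"{r.bin_label}\t{r.n_variants}\t{r.n_events}\t{r.pct_variants:.2f}\n")

    n_novel, n_conserved, pct_novel = novelty_summary(callset)
    freqs = type_frequencies(callset) if callset.events else {}
    with open(out / "event_type_freq.tsv", "w") as fh:
        fh.write("event_type\tcount\tpct\n")
        for t, (c, p) in freqs.items():
            fh.write(f"{t}\t{c}\t{p:.1f}\n")

    as_variants = callset.variants
    groups = {v: t for v, t in variant_treatments(observed).items() if v in as_variants}
    partitions = venn_partition(groups, total=len(as_variants)) if groups else []
    with open(out / "venn_groups.tsv", "w") as fh:
        fh.write("region\tcount\tpct_of_total\tmembers\n")
        for p in partitions:
            fh.write(
                f"{'+'.join(sorted(p.region))}\t{p.count}\t{p.pct_of_total:.2f}\t"
                f"{','.join(sorted(p.member_variant_ids))}\n"
            )
    return {
        "as_variants": len(as_variants),
        "events": len(callset.events),
        "conserved_events": callset.n_conserved,
        "novel_events": callset.n_novel,
        "novel_variants": n_novel,
        "conserved_variants": n_conserved,
        "pct_novel_variants": pct_novel,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    if config.seed is not None:
        log.info("simulating cohort (seed=%d)", config.seed)
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        annotation = generate_reference(sim)
        observed, truth = generate_cohort(annotation, sim)
        cio.write_gff3(annotation, out / "reference.gff3")
        cio.write_observed_gtf(observed, out / "observed.gtf")
        write_truth(truth, out / "truth.jsonl")
        manifest["stages"]["simulate"] = {
            "genes": len(annotation),
            "observed_records": len(observed),
            "planted_events": len(truth),
        }
    else:
        annotation = cio.read_gff3(config.annotation)
        observed = cio.read_observed_gtf(config.observed)

    log.info("detecting events over %d observed records", len(observed))
    callset = detect_all(
        observed,
        annotation,
        min_coverage=config.min_coverage,
        restrict_to_annotated_AS=config.restrict_to_annotated_AS,
        end_convention=config.end_convention,
    )
    _write_events_tsv(callset, out / "events.tsv")
    manifest["stages"]["detect"] = {
        "input_records": callset.n_input,
        "coverage_excluded": callset.filtered_out,
        "skipped_not_annotated_AS": callset.skipped_not_annotated_AS,
    }

    manifest["stages"]["summarize"] = _summarize_stage(callset, observed, out)
    log.info(
        "summary: %d AS variants, %d events (%d conserved / %d novel)",
        manifest["stages"]["summarize"]["as_variants"],
        len(callset.events),
        callset.n_conserved,
        callset.n_novel,
    )

    if config.species_catalogs:
        catalogs = {sp: cio.read_symbol_list(p) for sp, p in config.species_catalogs.items()}
        focal = {annotation[e.gene_id].symbol for e in callset.events}
        per_species, n_any, n_two, pct_two = species_sharing(focal, catalogs)
        with open(out / "species_sharing.tsv", "w") as fh:
            fh.write("species\tshared\n")
            for sp in sorted(per_species):
                fh.write(f"{sp}\t{per_species[sp]}\n")
            fh.write(f"any\t{n_any}\ntwo_or_more\t{n_two}\npct_two_or_more\t{pct_two:.2f}\n")
        manifest["stages"]["species_sharing"] = {
            "shared_any": n_any,
            "shared_two_or_more": n_two,
            "pct_two_or_more": pct_two,
        }

    if config.gmt is not None or config.seed is not None:
        if config.gmt is not None:
            terms = cio.read_gmt(config.gmt)
            background = (
                cio.read_symbol_list(config.background)
                if config.background
                else {g.symbol for g in annotation}
            )
        else:
            import numpy as np

            as_genes = sorted({annotation[e.gene_id].symbol for e in callset.events})
            terms = generate_term_sets(
                annotation,
                25,
                ("planted enriched term", set(as_genes[: min(15, len(as_genes))]), 0.8),
                np.random.default_rng([config.seed, 2]),
            )
            cio.write_gmt(terms, out / "terms.gmt")
            background = {g.symbol for g in annotation}
        query = {annotation[e.gene_id].symbol for e in callset.events}
        results = run_enrichment(
            query,
            background,
            terms,
            min_overlap=config.min_overlap,
            p_cutoff=config.p_cutoff,
            q_report=config.q_report,
        )
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("# family: terms passing min_overlap filter (filter-then-adjust BH)\n")
            fh.write("term_id\tname\tk\tK\tn\tN\tp\tq\tsignificant\n")
            for r in results:
                fh.write(
                    f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\n"
                )
        manifest["stages"]["enrich"] = {
            "reported": len(results),
            "significant": sum(r.significant for r in results),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
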