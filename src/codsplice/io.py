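"""Readers and writers for the formats the pipeline touches.

GFF3 carries the reference annotation (gene -> mRNA -> exon with ID/Parent),
GTF carries observed transcript structures (transcript/exon features with
``coverage``, ``site`` and ``treatment`` attributes), GMT carries term sets,
and plain one-symbol-per-line files carry gene catalogs.  Individual lines
are parsed with :func:`gffutils.feature.feature_from_line`; the hierarchy
assembly and validation on top of it report 1-based line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from gffutils.feature import feature_from_line

from .models import (
    BIOTYPES,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ModelError,
    ObservedTranscript,
    TranscriptModel,
)


class ParseError(ValueError):
    """A structured parse failure naming the file and 1-based line number."""

    def __init__(self, path: str | Path, lineno: int | None, message: str) -> None:
        loc = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _feature_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted exceptions
                raise ParseError(path, lineno, f"unparseable feature line ({exc})") from exc
            yield lineno, feat


def _single(attrs, key, path, lineno, required=True):
    vals = attrs.get(key, [])
    if not vals:
        if required:
            raise ParseError(path, lineno, f"missing attribute {key!r}")
        return None
    return vals[0]


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read a reference annotation from GFF3.

    Expects gene / mRNA (or transcript) / exon features linked by ID/Parent.
    GFF3 1-based inclusive coordinates become 0-based half-open internally.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    order: list[str] = []

    for lineno, feat in _feature_lines(path):
        ftype = feat.featuretype
        if ftype == "gene":
            gid = _single(feat.attributes, "ID", path, lineno)
            biotype = _single(feat.attributes, "biotype", path, lineno, required=False)
            symbol = _single(feat.attributes, "Name", path, lineno, required=False)
            if biotype is not None and biotype not in BIOTYPES:
                raise ParseError(path, lineno, f"unknown biotype {biotype!r}")
            genes[gid] = {
                "symbol": symbol or gid,
                "biotype": biotype or "protein_coding",
                "transcripts": [],
            }
            order.append(gid)
        elif ftype in ("mRNA", "transcript"):
            tid = _single(feat.attributes, "ID", path, lineno)
            parent = _single(feat.attributes, "Parent", path, lineno)
            if parent not in genes:
                raise ParseError(path, lineno, f"transcript {tid} has unknown Parent {parent!r}")
            if feat.strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {feat.strand!r}")
            transcripts[tid] = {"gene": parent, "strand": feat.strand, "exons": []}
            genes[parent]["transcripts"].append(tid)
        elif ftype == "exon":
            parent = _single(feat.attributes, "Parent", path, lineno)
            if parent not in transcripts:
                raise ParseError(path, lineno, f"exon has unknown Parent {parent!r}")
            if feat.strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {feat.strand!r}")
            try:
                iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            except ModelError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            transcripts[parent]["exons"].append((lineno, iv))
        # other feature types are ignored

    annotation = GenomeAnnotation()
    for gid in order:
        info = genes[gid]
        isoforms = []
        for tid in info["transcripts"]:
            t = transcripts[tid]
            exon_lines = [ln for ln, _ in t["exons"]]
            try:
                isoforms.append(
                    TranscriptModel(
                        transcript_id=tid,
                        gene_id=gid,
                        exons=[iv for _, iv in t["exons"]],
                        strand=t["strand"],
                    )
                )
            except ModelError as exc:
                lineno = exon_lines[0] if exon_lines else None
                raise ParseError(path, lineno, str(exc)) from exc
        annotation.add(GeneModel(gene_id=gid, symbol=info["symbol"], biotype=info["biotype"], isoforms=isoforms))
    return annotation


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gene in annotation:
        span_start = min(iso.exons[0].start for iso in gene.isoforms)
        span_end = max(iso.exons[-1].end for iso in gene.isoforms)
        chrom = gene.isoforms[0].chrom
        attrs = f"ID={gene.gene_id};Name={gene.symbol};biotype={gene.biotype}"
        lines.append(
            f"{chrom}\tcodsplice\tgene\t{span_start + 1}\t{span_end}\t.\t{gene.strand}\t.\t{attrs}"
        )
        for iso in gene.isoforms:
            lines.append(
                f"{chrom}\tcodsplice\tmRNA\t{iso.exons[0].start + 1}\t{iso.exons[-1].end}\t.\t"
                f"{iso.strand}\t.\tID={iso.transcript_id};Parent={gene.gene_id}"
            )
            for e in iso.exons:
                lines.append(
                    f"{chrom}\tcodsplice\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                    f"Parent={iso.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_observed_gtf(path: str | Path) -> list[ObservedTranscript]:
    """Read observed transcript structures from GTF.

    Every transcript must carry ``transcript_id``, ``gene_id``, ``coverage``,
    ``site`` and ``treatment`` attributes; coverage is never defaulted.  A
    variant observed in several treatment groups appears as one record per
    group: records carry unique transcript_ids and an optional shared
    ``variant_id`` attribute naming the variant (default: the
    transcript_id).
    """
    records: dict[str, dict] = {}
    order: list[str] = []
    for lineno, feat in _feature_lines(path):
        attrs = feat.attributes
        tid = _single(attrs, "transcript_id", path, lineno)
        if feat.featuretype == "transcript":
            gid = _single(attrs, "gene_id", path, lineno)
            cov = _single(attrs, "coverage", path, lineno)
            site = _single(attrs, "site", path, lineno)
            treatment = _single(attrs, "treatment", path, lineno)
            try:
                coverage = int(cov)
                if coverage < 0:
                    raise ValueError
            except ValueError:
                raise ParseError(path, lineno, f"coverage must be a non-negative integer, got {cov!r}")
            if feat.strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {feat.strand!r}")
            if tid in records:
                raise ParseError(path, lineno, f"duplicate transcript_id {tid!r}")
            records[tid] = {
                "variant_id": _single(attrs, "variant_id", path, lineno, required=False) or tid,
                "gene_id": gid,
                "coverage": coverage,
                "site": site,
                "treatment": treatment,
                "strand": feat.strand,
                "exons": [],
                "lineno": lineno,
            }
            order.append(tid)
        elif feat.featuretype == "exon":
            if tid not in records:
                raise ParseError(path, lineno, f"exon precedes transcript record for {tid!r}")
            try:
                records[tid]["exons"].append(
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                )
            except ModelError as exc:
                raise ParseError(path, lineno, str(exc)) from exc

    out = []
    for tid in order:
        r = records[tid]
        try:
            out.append(
                ObservedTranscript(
                    variant_id=r["variant_id"],
                    gene_id=r["gene_id"],
                    exons=r["exons"],
                    strand=r["strand"],
                    coverage=r["coverage"],
                    site=r["site"],
                    treatment=r["treatment"],
                )
            )
        except ModelError as exc:
            raise ParseError(path, r["lineno"], str(exc)) from exc
    return out


def write_observed_gtf(observed: Iterable[ObservedTranscript], path: str | Path) -> None:
    lines = []
    for obs in observed:
        attrs = (
            f'gene_id "{obs.gene_id}"; transcript_id "{obs.variant_id}.{obs.treatment}"; '
            f'variant_id "{obs.variant_id}"; coverage "{obs.coverage}"; '
            f'site "{obs.site}"; treatment "{obs.treatment}";'
        )
        lines.append(
            f"{obs.chrom}\tcodsplice\ttranscript\t{obs.exons[0].start + 1}\t{obs.exons[-1].end}\t.\t"
            f"{obs.strand}\t.\t{attrs}"
        )
        for e in obs.exons:
            lines.append(
                f"{obs.chrom}\tcodsplice\texon\t{e.start + 1}\t{e.end}\t.\t{obs.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read gene sets from GMT: term_id <tab> description <tab> members..."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "GMT line needs id, description and >=1 member")
            terms[parts[0]] = (parts[1], {p for p in parts[2:] if p})
    return terms


def write_gmt(terms: dict[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    lines = []
    for term_id, (desc, members) in terms.items():
        lines.append("\t".join([term_id, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_symbol_list(path: str | Path) -> set[str]:
    """One gene symbol per line; compared case-insensitively downstream."""
    out = set()
    with open(path) as fh:
        for raw in fh:
            sym = raw.strip()
            if sym:
                out.add(sym)
    return out


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(symbols)) + "\n")
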