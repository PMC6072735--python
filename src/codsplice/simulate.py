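"""Synthetic reference annotations and observed-transcript cohorts with
planted, ground-truthed alternative-splicing events.

The generator emulates the structure of the gill-transcriptome study the
package models: multi-isoform gene models; observed transcripts derived from
one annotated isoform by planting 0..k events of the five types (ES, IR, AA,
AD, AP); per-transcript integer coverage including coverage-1 decoys that
the detector must exclude; and six experimental groups (two sampling sites
x three salinity treatments) with a configurable Venn sharing structure.

Planted events target pairwise-distant loci (exon-index distance >= 2 from
one another and from the locus distinguishing the gene's second annotated
isoform), so each event is independently recoverable and chains always keep
the exon-chain invariants.

Conserved truth is planted through genes whose second annotated isoform
retains an internal intron: the observed chain is that merged exon trimmed
back to the longer flanking exon.  Relative to the (parsimony-selected)
second isoform this is a single boundary event whose coordinates the first
isoform reproduces exactly — the one configuration in which the
identical-coordinates conservation rule can fire at all when references are
chosen parsimoniously, since any event copied verbatim from an annotated
isoform is otherwise absorbed by matching that isoform.  Event labels in the
truth table follow the default donor/acceptor end convention.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .models import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ObservedTranscript,
    TranscriptModel,
)

EVENT_TYPES = ("ES", "IR", "AA", "AD", "AP")

# Venn regions over treatments, written as '+'-joined sorted labels.  The
# default proportions mirror the sharing structure reported for the cod
# cohort (462/16/15/11/3/1/1 over 509 AS variants).
DEFAULT_GROUP_SHARING = {
    "CTRL+LS+RS": 462 / 509,
    "LS+RS": 16 / 509,
    "CTRL+RS": 15 / 509,
    "CTRL+LS": 11 / 509,
    "LS": 3 / 509,
    "RS": 1 / 509,
    "CTRL": 1 / 509,
}

# Event-type mix: ES dominates (as reported), IR is rare.
DEFAULT_EVENT_MIX = {"ES": 0.518, "AA": 0.20, "AD": 0.13, "AP": 0.083, "IR": 0.069}

_BIOTYPE_PROBS = {"protein_coding": 0.9759, "pseudogene": 0.0177, "non_coding": 0.0064}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale: 300 genes and 600 observed variants give a
    cohort comfortably above 500 AS variants after decoy filtering while
    keeping every downstream stage sub-second.
    """

    seed: int
    n_genes: int = 300
    n_variants: int = 600
    exons_per_gene: tuple[int, int] = (6, 10)
    fraction_multi_isoform: float = 0.6
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    events_per_variant: tuple[int, int] = (1, 3)
    fraction_unmodified: float = 0.05
    fraction_conserved: float = 0.11
    coverage_model: tuple = ("poisson", 30.0)
    fraction_coverage_one_decoys: float = 0.10
    group_sharing: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_SHARING))
    site_probability: float = 0.5  # probability of KIL (else GDA)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_variants < 0:
            raise SimulationError("n_genes must be >= 1 and n_variants >= 0")
        lo, hi = self.exons_per_gene
        if lo < 3:
            raise SimulationError(
                "exons_per_gene minimum must be >= 3 (ES/IR planting needs internal exons)"
            )
        if hi < lo:
            raise SimulationError("exons_per_gene range is inverted")
        if not 0 <= self.fraction_multi_isoform <= 1:
            raise SimulationError("fraction_multi_isoform must be in [0, 1]")
        if not self.event_mix or all(w <= 0 for w in self.event_mix.values()):
            raise SimulationError("event_mix needs at least one positive weight")
        for etype, w in self.event_mix.items():
            if etype not in EVENT_TYPES or w < 0:
                raise SimulationError(f"bad event_mix entry {etype!r}: {w}")
        if abs(sum(self.group_sharing.values()) - 1.0) > 1e-9:
            raise SimulationError("group_sharing proportions must sum to 1")
        for region in self.group_sharing:
            labels = set(region.split("+"))
            if not labels or not labels <= {"CTRL", "LS", "RS"}:
                raise SimulationError(f"bad group_sharing region {region!r}")
        kind = self.coverage_model[0]
        if kind not in ("poisson", "negative_binomial"):
            raise SimulationError(f"unknown coverage model {kind!r}")
        for frac in (
            self.fraction_unmodified,
            self.fraction_conserved,
            self.fraction_coverage_one_decoys,
        ):
            if not 0 <= frac <= 1:
                raise SimulationError("fractions must lie in [0, 1]")


@dataclass
class TruthRecord:
    """One planted event: the simulator's ground truth for recovery tests."""

    variant_id: str
    event_type: str
    defining_intervals: list[GenomicInterval]
    donor_isoform_id: str
    planted_as_conserved: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant_id": self.variant_id,
                "event_type": self.event_type,
                "defining_intervals": [
                    [iv.chrom, iv.start, iv.end, iv.strand] for iv in self.defining_intervals
                ],
                "donor_isoform_id": self.donor_isoform_id,
                "planted_as_conserved": self.planted_as_conserved,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "TruthRecord":
        d = json.loads(line)
        return cls(
            variant_id=d["variant_id"],
            event_type=d["event_type"],
            defining_intervals=[GenomicInterval(*iv) for iv in d["defining_intervals"]],
            donor_isoform_id=d["donor_isoform_id"],
            planted_as_conserved=d["planted_as_conserved"],
        )


def write_truth(records: Iterable[TruthRecord], path: str | Path) -> None:
    Path(path).write_text("\n".join(r.to_json() for r in records) + "\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    return [
        TruthRecord.from_json(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


# ---------------------------------------------------------------------------
# reference generation

_EXON_LEN = (60, 200)
_INTRON_LEN = (80, 400)
_GENE_GAP = 1000
_GENES_PER_CHROM = 25


def _random_chain(rng, chrom, offset, n_exons, strand) -> list[GenomicInterval]:
    exons = []
    pos = offset
    for i in range(n_exons):
        length = int(rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(_INTRON_LEN[0], _INTRON_LEN[1] + 1))
    return exons


def _shift_boundary(rng, lo_bound: int, start: int, end: int, hi_bound: int, which: str) -> tuple[int, int]:
    """Shift one genomic boundary of [start, end) by 1..10 bases, keeping the
    exon >= 2 bases long and >= 1 base away from its neighbours."""
    if which == "start":
        extend = start - lo_bound - 1
        shrink = end - start - 2
    else:
        extend = hi_bound - end - 1
        shrink = end - start - 2
    directions = []
    if extend >= 1:
        directions.append(("extend", extend))
    if shrink >= 1:
        directions.append(("shrink", shrink))
    if not directions:
        raise SimulationError("no slack to shift exon boundary")
    direction, slack = directions[int(rng.integers(len(directions)))]
    delta = int(rng.integers(1, min(10, slack) + 1))
    if which == "start":
        start = start - delta if direction == "extend" else start + delta
    else:
        end = end + delta if direction == "extend" else end - delta
    return start, end


def _plant_on_chain(
    exons: list[GenomicInterval],
    event_type: str,
    rng,
    used: set[int],
    *,
    ir_internal_only: bool = False,
) -> tuple[list[GenomicInterval], GenomicInterval, set[int]] | None:
    """Plant one event on a chain, avoiding exon indices within distance 1 of
    ``used``.  Returns (new chain, defining interval, core indices) or None
    when no eligible locus remains."""
    n = len(exons)
    strand = exons[0].strand
    chrom = exons[0].chrom

    def free(core: Sequence[int]) -> bool:
        return all(abs(c - u) >= 2 for c in core for u in used)

    if event_type == "ES":
        candidates = [i for i in range(1, n - 1) if free([i])]
        if not candidates:
            return None
        i = candidates[int(rng.integers(len(candidates)))]
        new = exons[:i] + exons[i + 1 :]
        return new, exons[i], {i}

    if event_type == "IR":
        lo, hi = (1, n - 3) if ir_internal_only else (0, n - 2)
        candidates = [j for j in range(lo, hi + 1) if free([j, j + 1])]
        if not candidates:
            return None
        j = candidates[int(rng.integers(len(candidates)))]
        a, b = exons[j], exons[j + 1]
        intron = GenomicInterval(chrom, a.end, b.start, strand)
        merged = GenomicInterval(chrom, a.start, b.end, strand)
        new = exons[:j] + [merged] + exons[j + 2 :]
        return new, intron, {j, j + 1}

    # boundary events target an internal exon
    candidates = [i for i in range(1, n - 1) if free([i])]
    if not candidates:
        return None
    i = candidates[int(rng.integers(len(candidates)))]
    e = exons[i]
    start, end = e.start, e.end
    lo_bound, hi_bound = exons[i - 1].end, exons[i + 1].start
    five_is_start = strand == "+"
    # default ("paper") convention: AD = 5' end shifted, AA = 3' end shifted
    if event_type in ("AD", "AP"):
        which = "start" if five_is_start else "end"
        start, end = _shift_boundary(rng, lo_bound, start, end, hi_bound, which)
    if event_type in ("AA", "AP"):
        which = "end" if five_is_start else "start"
        start, end = _shift_boundary(rng, lo_bound, start, end, hi_bound, which)
    modified = GenomicInterval(chrom, start, end, strand)
    new = exons[:i] + [modified] + exons[i + 1 :]
    return new, modified, {i}


def plant_event(
    donor: TranscriptModel, event_type: str, rng, variant_id: str = ""
) -> tuple[list[GenomicInterval], TruthRecord]:
    """Derive an observed exon chain from ``donor`` by planting one event.

    ES removes an internal exon, IR merges two consecutive exons across their
    intron, AD shifts only the 5' boundary of an internal exon, AA only the
    3' boundary, AP both.  The truth record carries the defining interval:
    the removed exon, the retained intron, or the modified exon.
    """
    if event_type not in EVENT_TYPES:
        raise SimulationError(f"unknown event type {event_type!r}")
    if len(donor.exons) < 3:
        raise SimulationError(f"donor {donor.transcript_id} too short for {event_type}")
    planted = _plant_on_chain(list(donor.exons), event_type, rng, used=set())
    if planted is None:
        raise SimulationError(f"no eligible locus on donor {donor.transcript_id}")
    chain, interval, _ = planted
    return chain, TruthRecord(
        variant_id=variant_id,
        event_type=event_type,
        defining_intervals=[interval],
        donor_isoform_id=donor.transcript_id,
    )


def generate_reference(config: SimulationConfig) -> GenomeAnnotation:
    """Generate a reference annotation: ``n_genes`` single-isoform genes, a
    fraction of which carry a second annotated isoform differing by exactly
    one randomly typed event (the annotated-AS genes)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n_multi = math.ceil(config.fraction_multi_isoform * config.n_genes)
    multi_ids = set(rng.choice(config.n_genes, size=n_multi, replace=False).tolist())
    biotypes = list(_BIOTYPE_PROBS)
    bt_probs = np.array(list(_BIOTYPE_PROBS.values()))
    bt_probs = bt_probs / bt_probs.sum()

    annotation = GenomeAnnotation()
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        offset = (i % _GENES_PER_CHROM) * (_GENE_GAP + 4000) + _GENE_GAP
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[int(rng.choice(len(biotypes), p=bt_probs))]
        iso1 = TranscriptModel(f"{gid}.t1", gid, _random_chain(rng, chrom, offset, n_exons, strand), strand)
        isoforms = [iso1]
        if i in multi_ids:
            etype = EVENT_TYPES[int(rng.integers(len(EVENT_TYPES)))]
            planted = _plant_on_chain(
                list(iso1.exons), etype, rng, used=set(), ir_internal_only=True
            )
            chain, _, _ = planted
            isoforms.append(TranscriptModel(f"{gid}.t2", gid, chain, strand))
        annotation.add(GeneModel(gene_id=gid, symbol=f"GENE{i:04d}", biotype=biotype, isoforms=isoforms))
    return annotation


# ---------------------------------------------------------------------------
# cohort generation

def _second_isoform_diff(iso1: TranscriptModel, iso2: TranscriptModel):
    """Describe how iso2 differs from iso1 by direct chain comparison:
    returns (kind, iso1 exon core indices), kind in {ES, IR, boundary}."""
    c1, c2 = iso1.chain(), iso2.chain()
    if len(c2) == len(c1) - 1:
        set2 = set(c2)
        missing = [i for i, c in enumerate(c1) if c not in set2]
        if len(missing) == 1:  # skipped exon
            return "ES", {missing[0]}
        # merged pair: find a with (start_a, end_{a+1}) present in c2
        for a in range(len(c1) - 1):
            if (c1[a][0], c1[a + 1][1]) in set2:
                return "IR", {a, a + 1}
        raise SimulationError(f"cannot reconcile isoforms of {iso1.gene_id}")
    if len(c2) == len(c1):
        diff = [i for i in range(len(c1)) if c1[i] != c2[i]]
        if len(diff) == 1:
            return "boundary", {diff[0]}
    raise SimulationError(f"cannot reconcile isoforms of {iso1.gene_id}")


def _conserved_chain(gene: GeneModel) -> tuple[list[GenomicInterval], TruthRecord] | None:
    """Build a conserved observed chain for a gene whose second isoform
    retains an internal intron: trim the merged exon back to the longer
    flanking exon.  Returns None when the gene is not eligible."""
    if not gene.annotated_AS:
        return None
    iso1, iso2 = gene.isoforms[0], gene.isoforms[1]
    try:
        kind, core = _second_isoform_diff(iso1, iso2)
    except SimulationError:
        return None
    if kind != "IR":
        return None
    a = min(core)
    n = len(iso1.exons)
    if not (1 <= a and a + 1 <= n - 2):
        return None  # both flanking exons must be internal
    A, B = iso1.exons[a], iso1.exons[a + 1]
    keep = A if len(A) >= len(B) else B
    drop_idx = a + 1 if keep is A else a
    chain = [e for i, e in enumerate(iso1.exons) if i != drop_idx]
    # relative to iso2 the trim is a one-ended boundary change of the merged
    # exon; label it with the default donor/acceptor end convention
    end_changed = keep is A  # genomic end differs; else genomic start differs
    five_prime_changed = end_changed == (gene.strand == "-")
    etype = "AD" if five_prime_changed else "AA"
    truth = TruthRecord(
        variant_id="",
        event_type=etype,
        defining_intervals=[keep],
        donor_isoform_id=iso2.transcript_id,
        planted_as_conserved=True,
    )
    return chain, truth


def _plant_many(
    exons: list[GenomicInterval],
    n_events: int,
    mix_types: list[str],
    mix_probs,
    rng,
    used: set[int],
) -> tuple[list[GenomicInterval], list[tuple[str, GenomicInterval]]]:
    """Plant up to ``n_events`` events at pairwise-distant loci of one donor
    chain.  All loci are chosen in the original chain's index space and the
    transformed chain is assembled in a single pass, so events never
    interact.  Returns (new chain, [(event_type, defining interval)])."""
    n = len(exons)
    used = set(used)

    def free(core) -> bool:
        return all(abs(c - u) >= 2 for c in core for u in used)

    removed: set[int] = set()
    merged_at: dict[int, GenomicInterval] = {}
    replaced: dict[int, GenomicInterval] = {}
    planted: list[tuple[str, GenomicInterval]] = []
    attempts = 0
    while len(planted) < n_events and attempts < 20 * max(n_events, 1):
        attempts += 1
        etype = mix_types[int(rng.choice(len(mix_types), p=mix_probs))]
        if etype == "ES":
            candidates = [i for i in range(1, n - 1) if free([i])]
            if not candidates:
                continue
            i = candidates[int(rng.integers(len(candidates)))]
            removed.add(i)
            used.add(i)
            planted.append((etype, exons[i]))
        elif etype == "IR":
            candidates = [j for j in range(n - 1) if free([j, j + 1])]
            if not candidates:
                continue
            j = candidates[int(rng.integers(len(candidates)))]
            a, b = exons[j], exons[j + 1]
            merged_at[j] = GenomicInterval(a.chrom, a.start, b.end, a.strand)
            used |= {j, j + 1}
            planted.append((etype, GenomicInterval(a.chrom, a.end, b.start, a.strand)))
        else:
            candidates = [i for i in range(1, n - 1) if free([i])]
            if not candidates:
                continue
            i = candidates[int(rng.integers(len(candidates)))]
            e = exons[i]
            start, end = e.start, e.end
            lo_bound, hi_bound = exons[i - 1].end, exons[i + 1].start
            five_is_start = e.strand == "+"
            if etype in ("AD", "AP"):
                which = "start" if five_is_start else "end"
                start, end = _shift_boundary(rng, lo_bound, start, end, hi_bound, which)
            if etype in ("AA", "AP"):
                which = "end" if five_is_start else "start"
                start, end = _shift_boundary(rng, lo_bound, start, end, hi_bound, which)
            replaced[i] = GenomicInterval(e.chrom, start, end, e.strand)
            used.add(i)
            planted.append((etype, replaced[i]))

    chain: list[GenomicInterval] = []
    i = 0
    while i < n:
        if i in removed:
            i += 1
        elif i in merged_at:
            chain.append(merged_at[i])
            i += 2
        elif i in replaced:
            chain.append(replaced[i])
            i += 1
        else:
            chain.append(exons[i])
            i += 1
    return chain, planted


def _draw_coverage(rng, model) -> int:
    kind = model[0]
    if kind == "poisson":
        return int(rng.poisson(model[1]))
    mean, dispersion = model[1], model[2]
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def generate_cohort(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[list[ObservedTranscript], list[TruthRecord]]:
    """Generate the observed cohort over a reference annotation.

    Every variant sits on an annotated-AS (multi-isoform) gene, carries a
    sampling site, a coverage draw (decoys forced to 1) and a treatment-set
    sampled from ``group_sharing``; it is emitted once per treatment in its
    region, so a variant shared by all three groups contributes three GTF
    records with the same structure and variant_id.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    multi = [g for g in annotation if g.annotated_AS]
    if config.n_variants and not multi:
        raise SimulationError("no annotated-AS genes available to host variants")
    eligible_conserved = [g for g in multi if _conserved_chain(g) is not None]

    n = config.n_variants
    n_conserved = int(round(config.fraction_conserved * n))
    n_unmod = int(round(config.fraction_unmodified * n))
    if n_conserved and not eligible_conserved:
        raise SimulationError(
            "fraction_conserved > 0 but no gene with an internal intron-retention "
            "second isoform is available"
        )
    roles = ["conserved"] * n_conserved + ["unmodified"] * n_unmod
    roles += ["novel"] * (n - len(roles))
    rng.shuffle(roles)

    n_decoys = int(round(config.fraction_coverage_one_decoys * n))
    decoy_ids = set(rng.choice(n, size=n_decoys, replace=False).tolist()) if n_decoys else set()

    regions = list(config.group_sharing)
    region_probs = np.array([config.group_sharing[r] for r in regions])
    region_probs = region_probs / region_probs.sum()

    mix_types = [t for t in EVENT_TYPES if config.event_mix.get(t, 0) > 0]
    mix_probs = np.array([config.event_mix[t] for t in mix_types])
    mix_probs = mix_probs / mix_probs.sum()

    observed: list[ObservedTranscript] = []
    truth: list[TruthRecord] = []
    for v in range(n):
        vid = f"V{v:05d}"
        role = roles[v]
        records: list[TruthRecord] = []
        if role == "conserved":
            gene = eligible_conserved[int(rng.integers(len(eligible_conserved)))]
            chain, rec = _conserved_chain(gene)
            rec = dataclasses.replace(rec, variant_id=vid)
            records = [rec]
        else:
            gene = multi[int(rng.integers(len(multi)))]
            iso1 = gene.isoforms[0]
            chain = list(iso1.exons)
            if role == "novel":
                _, used = _second_isoform_diff(iso1, gene.isoforms[1])
                k = int(rng.integers(config.events_per_variant[0], config.events_per_variant[1] + 1))
                chain, planted_types = _plant_many(
                    list(iso1.exons), k, mix_types, mix_probs, rng, set(used)
                )
                records = [
                    TruthRecord(
                        variant_id=vid,
                        event_type=etype,
                        defining_intervals=[interval],
                        donor_isoform_id=iso1.transcript_id,
                    )
                    for etype, interval in planted_types
                ]
        coverage = 1 if v in decoy_ids else max(2, _draw_coverage(rng, config.coverage_model))
        site = "KIL" if rng.random() < config.site_probability else "GDA"
        region = regions[int(rng.choice(len(regions), p=region_probs))]
        for treatment in sorted(region.split("+")):
            observed.append(
                ObservedTranscript(
                    variant_id=vid,
                    gene_id=gene.gene_id,
                    exons=list(chain),
                    strand=gene.strand,
                    coverage=coverage,
                    site=site,
                    treatment=treatment,
                )
            )
        truth.extend(records)
    return observed, truth


def generate_term_sets(
    annotation: GenomeAnnotation,
    n_terms: int,
    enriched_term_spec: tuple[str, set[str], float],
    rng,
    *,
    size_range: tuple[int, int] = (10, 40),
) -> dict[str, tuple[str, set[str]]]:
    """Generate a GMT-shaped term collection with one planted enriched term.

    ``enriched_term_spec`` is (term name, target gene symbols, strength);
    strength in (0, 1] is the fraction of the enriched term made up of the
    target set, the remainder being background-sampled padding.  The other
    ``n_terms - 1`` terms sample genes uniformly.
    """
    if n_terms < 1:
        raise SimulationError("n_terms must be >= 1")
    name, target, strength = enriched_term_spec
    symbols = sorted(g.symbol for g in annotation)
    universe = set(symbols)
    if not set(target) <= universe:
        raise SimulationError("enriched-term target genes must be annotated genes")
    if not 0 < strength <= 1:
        raise SimulationError("enrichment strength must be in (0, 1]")

    terms: dict[str, tuple[str, set[str]]] = {}
    term_size = max(1, math.ceil(len(target) / strength))
    padding = term_size - len(target)
    pool = sorted(universe - set(target))
    members = set(target)
    if padding:
        members |= set(rng.choice(pool, size=min(padding, len(pool)), replace=False).tolist())
    terms["TERM0000"] = (name, members)
    for t in range(1, n_terms):
        size = int(rng.integers(size_range[0], min(size_range[1], len(symbols)) + 1))
        members = set(rng.choice(symbols, size=size, replace=False).tolist())
        terms[f"TERM{t:04d}"] = (f"random term {t}", members)
    return terms
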