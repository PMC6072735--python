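"""Alternative-splicing event detection from exon-chain comparison.

An observed transcript is compared against one annotated isoform of its gene
and every structural difference is typed as one of five event classes:

* ES  (exon skipping)      — a reference exon absent from the observed chain,
* IR  (intron retention)   — a reference intron fused into an observed exon,
* AD / AA (alternative donor / acceptor site) — one internal exon boundary
  shifted; under the default ``paper`` end convention an exon with the same
  3' end but a different 5' end is AD, the mirror case AA (the
  ``conventional`` setting swaps the two labels),
* AP  (alternative position) — both boundaries of a matched exon shifted.

Typing precedence is IR > ES > boundary events, so an exon fused by intron
retention is not additionally scored for boundary shifts.  Outer boundaries
of chain-terminal exons are never compared: alternative transcription start
or polyadenylation is not splicing.

An event is *conserved* when another annotated isoform of the gene exhibits
the same event (same type, identical defining coordinates) relative to the
matched reference isoform; otherwise it is novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .models import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ObservedTranscript,
    TranscriptModel,
    introns_of,
)

EVENT_TYPES = ("ES", "IR", "AA", "AD", "AP")
END_CONVENTIONS = ("paper", "conventional")


class DetectionError(ValueError):
    pass


@dataclass
class ASEvent:
    """One typed splicing difference between an observed chain and its
    matched reference isoform."""

    event_type: str
    gene_id: str
    variant_id: str
    reference_isoform_id: str
    defining_intervals: list[GenomicInterval]
    conserved: bool | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise DetectionError(f"unknown event type {self.event_type!r}")
        if not self.defining_intervals:
            raise DetectionError("event needs at least one defining interval")

    @property
    def identity_key(self) -> tuple:
        coords = tuple(sorted(iv.coords() for iv in self.defining_intervals))
        return (self.gene_id, self.event_type, coords)


@dataclass
class ASCallSet:
    """All events called over a cohort, with per-variant bookkeeping."""

    events: list[ASEvent] = field(default_factory=list)
    filtered_out: int = 0
    skipped_not_annotated_AS: int = 0
    n_input: int = 0
    reference_of: dict[str, str] = field(default_factory=dict)

    @property
    def variants(self) -> set[str]:
        return {e.variant_id for e in self.events}

    @property
    def events_per_variant(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.events:
            counts[e.variant_id] = counts.get(e.variant_id, 0) + 1
        return counts

    @property
    def n_conserved(self) -> int:
        return sum(1 for e in self.events if e.conserved)

    @property
    def n_novel(self) -> int:
        return sum(1 for e in self.events if not e.conserved)


def filter_by_coverage(
    observed: Sequence[ObservedTranscript], min_coverage: int = 2
) -> tuple[list[ObservedTranscript], int]:
    """Drop observed transcripts supported by fewer than ``min_coverage``
    reads (default 2: single-read alignments are excluded)."""
    retained = [o for o in observed if o.coverage >= min_coverage]
    return retained, len(observed) - len(retained)


def pair_exons(
    observed_exons: Sequence[GenomicInterval],
    reference_exons: Sequence[GenomicInterval],
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match observed exons to reference exons by maximal base overlap.

    Each observed exon is paired with the reference exon it overlaps most
    (ties to the reference exon with smaller genomic start).  The pairing is
    injective on reference exons: a reference exon claimed by two observed
    exons goes to the larger overlap, ties to the upstream observed exon.
    Returns (pairs, unmatched_reference_indices, unmatched_observed_indices).
    """
    if observed_exons and reference_exons:
        if observed_exons[0].chrom != reference_exons[0].chrom:
            raise DetectionError("chromosome mismatch between observed and reference")
        if observed_exons[0].strand != reference_exons[0].strand:
            raise DetectionError("strand mismatch between observed and reference")

    # best reference exon per observed exon
    claims: dict[int, list[tuple[int, int]]] = {}  # ref idx -> [(overlap, obs idx)]
    best_ref: dict[int, int] = {}
    for oi, oe in enumerate(observed_exons):
        best = None  # (overlap, ref start, ref idx)
        for ri, re in enumerate(reference_exons):
            ov = oe.overlap(re)
            if ov <= 0:
                continue
            cand = (-ov, re.start, ri)
            if best is None or cand < best:
                best = cand
        if best is not None:
            ri = best[2]
            best_ref[oi] = ri
            claims.setdefault(ri, []).append((-best[0], oi))

    pairs = []
    for ri, claimants in claims.items():
        # larger overlap wins; tie -> upstream (smaller index) observed exon
        winner = sorted(claimants, key=lambda c: (-c[0], c[1]))[0][1]
        pairs.append((winner, ri))
    pairs.sort()
    matched_obs = {oi for oi, _ in pairs}
    matched_ref = {ri for _, ri in pairs}
    unmatched_ref = [ri for ri in range(len(reference_exons)) if ri not in matched_ref]
    unmatched_obs = [oi for oi in range(len(observed_exons)) if oi not in matched_obs]
    return pairs, unmatched_ref, unmatched_obs


def _boundary_event_type(start_differs: bool, end_differs: bool, strand: str, end_convention: str) -> str | None:
    if not (start_differs or end_differs):
        return None
    if start_differs and end_differs:
        return "AP"
    # exactly one genomic boundary differs; translate to 5'/3'
    five_prime_differs = start_differs if strand == "+" else end_differs
    if end_convention == "paper":
        # same 3' end, different 5' end -> AD; same 5', different 3' -> AA
        return "AD" if five_prime_differs else "AA"
    return "AA" if five_prime_differs else "AD"


def classify_against_isoform(
    observed_exons: Sequence[GenomicInterval],
    reference: TranscriptModel,
    *,
    gene_id: str = "",
    variant_id: str = "",
    end_convention: str = "paper",
) -> list[ASEvent]:
    """Type every splicing difference between an observed exon chain and one
    reference isoform.  Returns an empty list for identical chains."""
    if end_convention not in END_CONVENTIONS:
        raise DetectionError(f"unknown end convention {end_convention!r}")
    observed_exons = sorted(observed_exons, key=lambda e: e.start)
    ref_exons = reference.exons
    strand = reference.strand
    gene_id = gene_id or reference.gene_id
    events: list[ASEvent] = []

    pairs, unmatched_ref, _ = pair_exons(observed_exons, ref_exons)

    def make(event_type: str, interval: GenomicInterval) -> ASEvent:
        return ASEvent(
            event_type=event_type,
            gene_id=gene_id,
            variant_id=variant_id,
            reference_isoform_id=reference.transcript_id,
            defining_intervals=[interval],
        )

    # (1) intron retention: an observed exon spans an entire reference intron
    # and overlaps both flanking reference exons
    ref_introns = introns_of(reference)
    consumed_obs: set[int] = set()
    for oi, oe in enumerate(observed_exons):
        for ii, intron in enumerate(ref_introns):
            if oe.contains(intron) and oe.overlap(ref_exons[ii]) > 0 and oe.overlap(ref_exons[ii + 1]) > 0:
                events.append(make("IR", intron))
                consumed_obs.add(oi)

    # (2) exon skipping: a reference exon strictly inside the observed span
    # with zero overlap to every observed exon
    if observed_exons:
        ospan_start = observed_exons[0].start
        ospan_end = observed_exons[-1].end
        for ri in unmatched_ref:
            re = ref_exons[ri]
            if ospan_start <= re.start and re.end <= ospan_end and all(
                oe.overlap(re) == 0 for oe in observed_exons
            ):
                events.append(make("ES", re))

    # (3) boundary comparison on matched pairs not consumed by IR, ignoring
    # the outer boundary of chain-terminal exons in either chain
    for oi, ri in pairs:
        if oi in consumed_obs:
            continue
        oe, re = observed_exons[oi], ref_exons[ri]
        start_comparable = oi != 0 and ri != 0
        end_comparable = oi != len(observed_exons) - 1 and ri != len(ref_exons) - 1
        start_differs = start_comparable and oe.start != re.start
        end_differs = end_comparable and oe.end != re.end
        etype = _boundary_event_type(start_differs, end_differs, strand, end_convention)
        if etype is not None:
            events.append(make(etype, oe))

    events.sort(key=lambda e: (e.defining_intervals[0].start, e.event_type))
    return events


def choose_reference_isoform(
    observed: ObservedTranscript,
    gene: GeneModel,
    *,
    end_convention: str = "paper",
) -> tuple[TranscriptModel, list[ASEvent]]:
    """Pick the annotated isoform explaining the observation most
    parsimoniously: fewest events, then fewest ES events, then the
    lexicographically smallest transcript_id."""
    if not gene.isoforms:
        raise DetectionError(f"gene {gene.gene_id} has no isoforms")
    best = None
    for iso in sorted(gene.isoforms, key=lambda t: t.transcript_id):
        evs = classify_against_isoform(
            observed.exons,
            iso,
            gene_id=gene.gene_id,
            variant_id=observed.variant_id,
            end_convention=end_convention,
        )
        n_es = sum(1 for e in evs if e.event_type == "ES")
        key = (len(evs), n_es, iso.transcript_id)
        if best is None or key < best[0]:
            best = (key, iso, evs)
    return best[1], best[2]


def call_conservation(
    event: ASEvent,
    gene: GeneModel,
    *,
    end_convention: str = "paper",
) -> bool:
    """An event is conserved when some *other* annotated isoform of the gene
    exhibits the same event — same type, identical defining-interval
    coordinates — relative to the matched reference isoform."""
    reference = next(
        (iso for iso in gene.isoforms if iso.transcript_id == event.reference_isoform_id),
        None,
    )
    if reference is None:
        raise DetectionError(
            f"reference isoform {event.reference_isoform_id} not found in gene {gene.gene_id}"
        )
    key = event.identity_key
    for iso in gene.isoforms:
        if iso.transcript_id == reference.transcript_id:
            continue
        for annot_event in classify_against_isoform(
            iso.exons, reference, gene_id=gene.gene_id, end_convention=end_convention
        ):
            if annot_event.identity_key == key:
                return True
    return False


def detect_all(
    observed: Sequence[ObservedTranscript],
    annotation: GenomeAnnotation,
    *,
    min_coverage: int = 2,
    restrict_to_annotated_AS: bool = True,
    end_convention: str = "paper",
) -> ASCallSet:
    """Run the full detection pipeline over a cohort.

    Coverage filter -> per-transcript reference-isoform choice ->
    classification -> conservation call, with events deduplicated per variant
    by their identity key (the same variant seen in several treatment groups
    contributes each event once).
    """
    unknown = sorted({o.variant_id for o in observed if o.gene_id not in annotation})
    if unknown:
        raise DetectionError(f"unknown gene_id for variants: {', '.join(unknown)}")

    callset = ASCallSet(n_input=len(observed))
    retained, callset.filtered_out = filter_by_coverage(observed, min_coverage)

    seen: dict[str, set[tuple]] = {}
    skipped_variants: set[str] = set()
    for obs in retained:
        gene = annotation[obs.gene_id]
        if restrict_to_annotated_AS and not gene.annotated_AS:
            skipped_variants.add(obs.variant_id)
            continue
        reference, events = choose_reference_isoform(obs, gene, end_convention=end_convention)
        callset.reference_of[obs.variant_id] = reference.transcript_id
        for event in events:
            key = event.identity_key
            if key in seen.setdefault(obs.variant_id, set()):
                continue
            seen[obs.variant_id].add(key)
            event.conserved = call_conservation(event, gene, end_convention=end_convention)
            callset.events.append(event)
    callset.skipped_not_annotated_AS = len(skipped_variants)
    return callset


def reconstruct_chain(
    reference: TranscriptModel, events: Sequence[ASEvent]
) -> list[GenomicInterval]:
    """Apply a variant's events to its matched reference isoform, giving back
    the observed exon chain (round-trip check for detection output)."""
    exons = list(reference.exons)
    # removals/merges first so boundary replacements see stable indices
    for event in sorted(events, key=lambda e: ("ES", "IR").index(e.event_type) if e.event_type in ("ES", "IR") else 2):
        iv = event.defining_intervals[0]
        if event.event_type == "ES":
            exons = [e for e in exons if e.coords() != iv.coords()]
        elif event.event_type == "IR":
            merged = []
            i = 0
            while i < len(exons):
                e = exons[i]
                if i + 1 < len(exons) and e.end == iv.start and exons[i + 1].start == iv.end:
                    merged.append(GenomicInterval(e.chrom, e.start, exons[i + 1].end, e.strand))
                    i += 2
                else:
                    merged.append(e)
                    i += 1
            exons = merged
        else:  # AA / AD / AP: the defining interval is the observed exon
            replaced = False
            out = []
            for e in exons:
                if not replaced and e.overlap(iv) > 0:
                    out.append(iv)
                    replaced = True
                else:
                    out.append(e)
            exons = out
    return sorted(exons, key=lambda e: e.start)
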