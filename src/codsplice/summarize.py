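"""Descriptive summaries of an AS callset: events-per-variant bins, event
type frequencies, novelty split, experimental-group Venn partitions,
cross-species sharing and per-group summary statistics.

Percentages are rounded half-away-from-zero at the stated number of
decimals; standard deviations are sample (n-1) standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detect import EVENT_TYPES, ASCallSet

BIN_EDGES = ((1, 9), (10, 19), (20, None))
BIN_LABELS = ("1-9", "10-19", ">=20")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of the summary tables),
    unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, decimals: int = 2) -> float:
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class BinRow:
    bin_label: str
    n_variants: int
    n_events: int
    pct_variants: float


def bin_events_per_variant(callset: ASCallSet) -> tuple[list[BinRow], BinRow]:
    """Bucket AS variants by their event count into 1-9 / 10-19 / >=20 and
    return the rows plus a summary row over all variants with >= 1 event."""
    counts = callset.events_per_variant
    total_variants = len(counts)
    rows = []
    for label, (lo, hi) in zip(BIN_LABELS, BIN_EDGES):
        members = {v: c for v, c in counts.items() if c >= lo and (hi is None or c <= hi)}
        rows.append(
            BinRow(
                bin_label=label,
                n_variants=len(members),
                n_events=sum(members.values()),
                pct_variants=pct(len(members), total_variants) if total_variants else 0.0,
            )
        )
    summary = BinRow("Summary", total_variants, sum(counts.values()), 100.0 if total_variants else 0.0)
    return rows, summary


def novelty_summary(callset: ASCallSet) -> tuple[int, int, int]:
    """(n_novel, n_conserved, pct_novel) over AS variants.

    A variant is conserved only when every one of its events is conserved;
    any novel event makes the whole variant a novel arrangement.
    """
    by_variant: dict[str, bool] = {}
    for e in callset.events:
        by_variant[e.variant_id] = by_variant.get(e.variant_id, True) and bool(e.conserved)
    n_conserved = sum(1 for all_cons in by_variant.values() if all_cons)
    n_novel = len(by_variant) - n_conserved
    pct_novel = int(round_half_up(100.0 * n_novel / len(by_variant), 0)) if by_variant else 0
    return n_novel, n_conserved, pct_novel


def type_frequencies(callset: ASCallSet) -> dict[str, tuple[int, float]]:
    """Event counts and percentage of all events per type, 1 decimal."""
    if not callset.events:
        raise ValueError("cannot compute type frequencies of an empty callset")
    counts = {t: 0 for t in EVENT_TYPES}
    for e in callset.events:
        counts[e.event_type] += 1
    total = len(callset.events)
    return {t: (c, pct(c, total, 1)) for t, c in counts.items()}


@dataclass
class VennPartition:
    region: frozenset[str]
    member_variant_ids: set[str]
    count: int
    pct_of_total: float


def venn_partition(
    variant_groups: Mapping[str, set[str]], total: int
) -> list[VennPartition]:
    """Exact set partition of variants by the full label set they carry: a
    variant seen in exactly {LS, RS} counts in that region only, never in
    the LS-only or RS-only regions.  Percentages are of ``total``."""
    regions: dict[frozenset[str], set[str]] = {}
    for vid, labels in variant_groups.items():
        if not labels:
            raise ValueError(f"variant {vid} has an empty label set")
        regions.setdefault(frozenset(labels), set()).add(vid)
    out = [
        VennPartition(
            region=region,
            member_variant_ids=members,
            count=len(members),
            pct_of_total=pct(len(members), total) if total else 0.0,
        )
        for region, members in regions.items()
    ]
    out.sort(key=lambda p: (-p.count, sorted(p.region)))
    return out


def species_sharing(
    focal_genes: set[str], catalogs: Mapping[str, set[str]]
) -> tuple[dict[str, int], int, int, float]:
    """Share of the focal AS gene set with per-species AS catalogs.

    Symbols are compared case-insensitively after trimming.  Returns
    (per-species shared counts, n shared with any species, n shared with two
    or more species, the latter as a percentage of the former).
    """
    if not focal_genes:
        raise ValueError("focal gene set is empty")
    focal = {g.strip().upper() for g in focal_genes}
    norm_catalogs = {sp: {g.strip().upper() for g in cat} for sp, cat in catalogs.items()}
    per_species = {sp: len(focal & cat) for sp, cat in norm_catalogs.items()}
    union = set().union(*norm_catalogs.values()) if norm_catalogs else set()
    shared_any = focal & union
    n_two_plus = sum(
        1 for g in focal if sum(g in cat for cat in norm_catalogs.values()) >= 2
    )
    if shared_any:
        pct_two_plus = pct(n_two_plus, len(shared_any))
    else:
        warnings.warn("no focal gene shared with any species catalog; reporting 0%")
        pct_two_plus = 0.0
    return per_species, len(shared_any), n_two_plus, pct_two_plus


@dataclass
class GroupStats:
    values: list[float]
    mean: float
    sd: float


def group_summary_stats(values: Sequence[float]) -> GroupStats:
    """Mean and sample (n-1 denominator) standard deviation of per-group
    tallies, as printed in cohort summary tables."""
    if len(values) < 2:
        raise ValueError("need at least two values for a summary with SD")
    arr = np.asarray(values, dtype=float)
    return GroupStats(values=list(map(float, values)), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def annotation_rate(n_annotated: int, n_correct: int, total: int) -> tuple[float, float]:
    """Percent of AS variants with any annotation and with a correct one,
    both over the total number of AS variants, 2 decimals."""
    if not 0 <= n_correct <= n_annotated <= total:
        raise ValueError("need 0 <= n_correct <= n_annotated <= total")
    return pct(n_annotated, total), pct(n_correct, total)


def variant_treatments(observed) -> dict[str, set[str]]:
    """Collect the treatment-label set per variant_id from observed records
    (input shape for venn_partition)."""
    out: dict[str, set[str]] = {}
    for obs in observed:
        out.setdefault(obs.variant_id, set()).add(obs.treatment)
    return out


def variant_sites(observed) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for obs in observed:
        out.setdefault(obs.variant_id, set()).add(obs.site)
    return out
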