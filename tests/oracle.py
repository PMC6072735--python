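"""Independent brute-force event classifier used as a test oracle.

Written directly from the interval-relation definitions of the five event
types, separately from the package implementation: every reference intron is
checked for retention, every reference exon for skipping, and exon pairing
plus boundary comparison are re-derived from the stated rules.  Events are
returned as (type, (start, end)) tuples so tests compare pure values.
"""

from __future__ import annotations


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def brute_force_classify(
    observed: list[tuple[int, int]],
    reference: list[tuple[int, int]],
    strand: str,
    end_convention: str = "paper",
) -> set[tuple[str, tuple[int, int]]]:
    observed = sorted(observed)
    reference = sorted(reference)
    events: set[tuple[str, tuple[int, int]]] = set()

    introns = [(reference[i][1], reference[i + 1][0]) for i in range(len(reference) - 1)]

    # intron retention: an observed exon covers a whole reference intron and
    # touches both flanking reference exons
    retained_obs = set()
    for oi, o in enumerate(observed):
        for ii, intr in enumerate(introns):
            if o[0] <= intr[0] and intr[1] <= o[1]:
                if _overlap(o, reference[ii]) > 0 and _overlap(o, reference[ii + 1]) > 0:
                    events.add(("IR", intr))
                    retained_obs.add(oi)

    # exon skipping: a reference exon inside the observed span that no
    # observed exon touches
    span = (observed[0][0], observed[-1][1])
    for r in reference:
        if span[0] <= r[0] and r[1] <= span[1] and all(_overlap(o, r) == 0 for o in observed):
            events.add(("ES", r))

    # pairing: per observed exon the reference exon of maximal overlap (tie:
    # smaller reference start); injective on reference (larger overlap wins,
    # tie: upstream observed exon)
    choice = {}
    for oi, o in enumerate(observed):
        overlaps = [(_overlap(o, r), -ri) for ri, r in enumerate(reference)]
        best = max(overlaps)
        if best[0] > 0:
            choice[oi] = (-best[1], best[0])  # (ref idx, overlap)
    winners: dict[int, tuple[int, int]] = {}
    for oi, (ri, ov) in choice.items():
        if ri not in winners or (ov, -oi) > (winners[ri][1], -winners[ri][0]):
            winners[ri] = (oi, ov)

    for ri, (oi, _) in winners.items():
        if oi in retained_obs:
            continue
        o, r = observed[oi], reference[ri]
        start_comparable = oi != 0 and ri != 0
        end_comparable = oi != len(observed) - 1 and ri != len(reference) - 1
        d_start = start_comparable and o[0] != r[0]
        d_end = end_comparable and o[1] != r[1]
        if d_start and d_end:
            events.add(("AP", o))
        elif d_start or d_end:
            d5 = d_start if strand == "+" else d_end
            if end_convention == "paper":
                events.add(("AD" if d5 else "AA", o))
            else:
                events.add(("AA" if d5 else "AD", o))
    return events
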