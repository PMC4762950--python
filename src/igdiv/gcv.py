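"""Gene-conversion (GCV) classification of mutation calls.

In chicken IgL diversification, a cluster of changes is counted as a gene
conversion only if the mutated stretch exactly matches at least one pseudo-V
donor. This module finds maximal donor-identical tracts over a mutated
sequence, groups donor-explained substitutions into gene-conversion events
(>= 2 donor markers required by default), labels lone donor-explained
substitutions ambiguous (a point mutation and a one-marker conversion are
indistinguishable), and passes everything else through as point mutations or
indels. Events are classified per sequence, then clonally corrected per
subclone like point mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .calling import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    CloneCallSet,
    RawCall,
)
from .synth import DonorSet, ReferenceLocus

__all__ = [
    "MutationEvent",
    "SpectrumSummary",
    "DonorTract",
    "find_donor_tracts",
    "classify_sequence",
    "classify_events",
    "summarize_spectrum",
    "CATEGORIES",
]

POINT = "point_mutation"
GCV = "gene_conversion"
AMBIGUOUS = "ambiguous"
CATEGORIES = (POINT, GCV, AMBIGUOUS, INSERTION, DELETION)

DEFAULT_TRACT_SUPPORT = 2  # donor-explained substitutions required for GCV


@dataclass(frozen=True)
class DonorTract:
    """A maximal reference interval where a mutated sequence is base-identical
    to one donor and contains >= 1 donor-vs-locus difference (so the tract is
    observable). ``markers`` are those difference positions."""

    donor_index: int
    donor_id: str
    start: int
    end: int
    markers: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MutationEvent:
    """One counted diversification event (after clonal correction)."""

    subclone: str
    category: str
    start: int
    end: int  # half-open; start+1 for point events
    members: tuple[tuple[int, str, str], ...]  # (position, ref, alt) per member call
    donor_ids: tuple[str, ...] = ()
    support: int = 0
    multiplicity: int = 1
    seq_ids: tuple[str, ...] = ()


@dataclass
class SpectrumSummary:
    """Event-spectrum counts suitable for pie-chart rendering."""

    counts: dict[str, int]
    proportions: dict[str, Fraction]
    donor_usage: dict[str, int]
    tract_lengths: list[int]
    total: int


def apply_substitutions(locus: ReferenceLocus, calls: list[RawCall]) -> str:
    """Reference-frame mutated sequence: locus with substitution calls applied."""
    seq = list(locus.sequence)
    for c in calls:
        if c.kind == SUBSTITUTION:
            seq[c.position] = c.alt
    return "".join(seq)


def find_donor_tracts(
    mutated_sequence: str, locus: ReferenceLocus, donors: DonorSet
) -> list[DonorTract]:
    """All maximal donor-identical tracts containing a donor marker.

    Requires positionally homologous donors so 'exactly matched' is a per-base
    comparison on the shared coordinate frame.
    """
    if len(donors) == 0:
        raise ValueError("donor set is empty")
    if not donors.alignment_mode:
        raise ValueError("donors must be positionally homologous (alignment_mode)")
    ref = locus.sequence
    n = len(ref)
    if len(mutated_sequence) != n:
        raise ValueError("mutated sequence must be in the reference frame")
    tracts: list[DonorTract] = []
    for di, (name, dseq) in enumerate(donors.donors):
        if len(dseq) != n:
            raise ValueError(f"donor {name} length differs from locus")
        i = 0
        while i < n:
            if mutated_sequence[i] != dseq[i]:
                i += 1
                continue
            j = i
            while j < n and mutated_sequence[j] == dseq[j]:
                j += 1
            markers = tuple(p for p in range(i, j) if dseq[p] != ref[p])
            if markers:
                tracts.append(DonorTract(di, name, i, j, markers))
            i = j
    return tracts


def _split_by_kind(calls: list[RawCall]):
    subs = sorted((c for c in calls if c.kind == SUBSTITUTION), key=lambda c: c.position)
    indels = [c for c in calls if c.kind != SUBSTITUTION]
    return subs, indels


def classify_sequence(
    calls: list[RawCall],
    locus: ReferenceLocus,
    donors: DonorSet,
    tract_support: int = DEFAULT_TRACT_SUPPORT,
) -> list[MutationEvent]:
    """Partition one sequence's calls into events.

    Greedy assignment over maximal donor tracts: repeatedly take the tract
    explaining the most still-unassigned substitutions (ties: shorter
    reference interval, then lowest donor index), as long as it explains
    >= ``tract_support`` of them. Each remaining substitution becomes one
    ambiguous event if some donor carries its alt allele at that position,
    else a point mutation. Indels pass through. Every call lands in exactly
    one event.
    """
    subs, indels = _split_by_kind(calls)
    subclone = calls[0].subclone if calls else ""
    seq_id = calls[0].seq_id if calls else ""
    by_pos = {c.position: c for c in subs}
    events: list[MutationEvent] = []

    if subs:
        mutseq = apply_substitutions(locus, subs)
        tracts = find_donor_tracts(mutseq, locus, donors)
        remaining = set(by_pos)
        while True:
            best = None
            best_key = None
            for t in tracts:
                live = tuple(p for p in t.markers if p in remaining)
                if len(live) < tract_support:
                    continue
                key = (-len(live), t.length, t.donor_index)
                if best_key is None or key < best_key:
                    best, best_key, best_live = t, key, live
            if best is None:
                break
            # retain every donor whose tract explains the same live marker set
            co_donors = tuple(dict.fromkeys(
                t.donor_id for t in tracts
                if tuple(p for p in t.markers if p in remaining) == best_live
            ))
            events.append(MutationEvent(
                subclone=subclone, category=GCV, start=best.start, end=best.end,
                members=tuple((p, by_pos[p].ref, by_pos[p].alt) for p in best_live),
                donor_ids=co_donors, support=len(best_live), seq_ids=(seq_id,),
            ))
            remaining -= set(best_live)
        for p in sorted(remaining):
            c = by_pos[p]
            explaining = tuple(
                name for name, dseq in donors.donors
                if dseq[p] == c.alt and dseq[p] != locus.sequence[p]
            )
            cat = AMBIGUOUS if explaining else POINT
            events.append(MutationEvent(
                subclone=subclone, category=cat, start=p, end=p + 1,
                members=((p, c.ref, c.alt),), donor_ids=explaining,
                support=1 if explaining else 0, seq_ids=(seq_id,),
            ))
    for c in indels:
        events.append(MutationEvent(
            subclone=subclone, category=c.kind, start=c.position,
            end=c.position + (len(c.ref) if c.kind == DELETION else 0),
            members=((c.position, c.ref, c.alt),), seq_ids=(seq_id,),
        ))
    events.sort(key=lambda e: (e.start, e.category))
    return events


def _event_key(e: MutationEvent) -> tuple:
    return (e.subclone, e.category, e.start, e.end, e.members, e.donor_ids)


def classify_events(
    callset: CloneCallSet,
    donors: DonorSet,
    tract_support: int = DEFAULT_TRACT_SUPPORT,
) -> list[MutationEvent]:
    """Classify every sequence, then clonally correct events per subclone.

    An event duplicated across clonally related sequences (identical category,
    interval, member calls, and donors within one subclone) is counted once,
    mirroring the point-mutation clonal-correction rule.
    """
    per_seq: dict[str, list[RawCall]] = {}
    for c in callset.raw_calls:
        per_seq.setdefault(c.seq_id, []).append(c)
    merged: dict[tuple, MutationEvent] = {}
    order: list[tuple] = []
    for seq_id in per_seq:
        for e in classify_sequence(per_seq[seq_id], callset.locus, donors, tract_support):
            key = _event_key(e)
            if key in merged:
                prev = merged[key]
                merged[key] = MutationEvent(
                    subclone=prev.subclone, category=prev.category,
                    start=prev.start, end=prev.end, members=prev.members,
                    donor_ids=prev.donor_ids, support=prev.support,
                    multiplicity=prev.multiplicity + 1,
                    seq_ids=prev.seq_ids + e.seq_ids,
                )
            else:
                merged[key] = e
                order.append(key)
    return [merged[k] for k in order]


def summarize_spectrum(events: list[MutationEvent]) -> SpectrumSummary:
    """Exact counts and proportions per category, donor usage, tract lengths.

    Donor-usage ties (co-optimal donors on one event) are all credited;
    proportions are exact rationals of the total and empty-undefined.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    donor_usage: dict[str, int] = {}
    tract_lengths: list[int] = []
    for e in events:
        counts[e.category] += 1
        if e.category == GCV:
            tract_lengths.append(e.end - e.start)
            for d in e.donor_ids:
                donor_usage[d] = donor_usage.get(d, 0) + 1
    total = sum(counts.values())
    proportions = (
        {cat: Fraction(n, total) for cat, n in counts.items() if n > 0} if total else {}
    )
    return SpectrumSummary(
        counts=counts, proportions=proportions, donor_usage=donor_usage,
        tract_lengths=sorted(tract_lengths), total=total,
    )
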