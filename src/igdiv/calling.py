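"""Mutation-event calling with clonal correction.

Clone amplicons are aligned to the reference locus, per-sequence differences
are called, and calls shared by multiple sequences of one subclone at an
identical position are collapsed to a single counted mutation (clonal
correction: such sequences descend from a common ancestor, so the mutation
arose once). Event frequency is the number of counted events divided by the
total base pairs sequenced, duplicates included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .alignment import PairwiseAlignment, align_to_reference
from .synth import CloneRecord, ReferenceLocus

__all__ = [
    "RawCall",
    "CollapsedCall",
    "EventTally",
    "call_raw",
    "clonal_collapse",
    "event_frequency",
    "call_clone_set",
    "CloneCallSet",
]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

MIN_IDENTITY = 0.90  # sequences below this identity to the locus are excluded


@dataclass(frozen=True)
class RawCall:
    """One per-sequence difference against the reference.

    ``position`` is a 0-based reference coordinate. For substitutions and
    deletions ``ref`` is the reference allele at that position; insertions
    carry the inserted string in ``alt`` and sit after ``position - 1``
    (i.e. before reference base ``position``).
    """

    seq_id: str
    subclone: str
    position: int
    kind: str
    ref: str
    alt: str


@dataclass(frozen=True)
class CollapsedCall:
    """A clonally corrected call: one counted mutation with its multiplicity."""

    subclone: str
    position: int
    kind: str
    ref: str
    alt: str
    multiplicity: int
    seq_ids: tuple[str, ...]


@dataclass
class EventTally:
    """Counted events and sequencing depth for one subclone."""

    subclone: str
    events: list = field(default_factory=list)
    bp_sequenced: int = 0

    @property
    def n_events(self) -> int:
        return len(self.events)


def call_raw(alignment: PairwiseAlignment, seq_id: str = "", subclone: str = "") -> list[RawCall]:
    """Substitution and indel calls from a global alignment.

    One substitution per mismatch column; each maximal gap run is a single
    insertion or deletion. Terminal gap runs are trimmed: a read that does not
    reach the locus boundary is incomplete coverage, not a deletion, and
    overhanging read bases are not locus events.
    """
    ref, qry = alignment.aligned_ref, alignment.aligned_query
    n = len(ref)
    # interior span: first/last column where both strings have a base
    first = next((i for i in range(n) if ref[i] != "-" and qry[i] != "-"), n)
    last = next((i for i in range(n - 1, -1, -1) if ref[i] != "-" and qry[i] != "-"), -1)
    calls: list[RawCall] = []
    pos = sum(1 for i in range(first) if ref[i] != "-")  # ref coordinate at `first`
    i = first
    while i <= last:
        if ref[i] != "-" and qry[i] != "-":
            if ref[i] != qry[i]:
                calls.append(RawCall(seq_id, subclone, pos, SUBSTITUTION, ref[i], qry[i]))
            pos += 1
            i += 1
        elif qry[i] == "-":  # gap in query: deletion of reference bases
            j = i
            while j <= last and qry[j] == "-":
                j += 1
            deleted = ref[i:j].replace("-", "")
            calls.append(RawCall(seq_id, subclone, pos, DELETION, deleted, ""))
            pos += len(deleted)
            i = j
        else:  # gap in reference: insertion before reference base `pos`
            j = i
            while j <= last and ref[j] == "-":
                j += 1
            inserted = qry[i:j].replace("-", "")
            calls.append(RawCall(seq_id, subclone, pos, INSERTION, "", inserted))
            i = j
    return calls


def aligned_reference_bp(alignment: PairwiseAlignment) -> int:
    """Reference positions covered by aligned (non-gap) read bases."""
    return sum(
        1 for r, q in zip(alignment.aligned_ref, alignment.aligned_query)
        if r != "-" and q != "-"
    )


def clonal_collapse(calls: list[RawCall]) -> list[CollapsedCall]:
    """Clonal correction: merge identical calls within a subclone.

    Substitutions with identical (position, alt) in one subclone are counted
    once, recording multiplicity. Identical indels at identical positions are
    collapsed by the same rule (their kind keeps them distinct in the report).
    Collapsing never crosses subclones. Idempotent by construction.
    """
    groups: dict[tuple, list[RawCall]] = {}
    order: list[tuple] = []
    for c in calls:
        key = (c.subclone, c.position, c.kind, c.ref, c.alt)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(c)
    out = []
    for key in order:
        members = groups[key]
        sub, pos, kind, ref, alt = key
        out.append(CollapsedCall(
            subclone=sub, position=pos, kind=kind, ref=ref, alt=alt,
            multiplicity=len(members),
            seq_ids=tuple(dict.fromkeys(c.seq_id for c in members)),
        ))
    return out


def event_frequency(n_events: int, bp_sequenced: int) -> tuple[Fraction, float]:
    """Events per base pair sequenced, exact and on the per-10^4-bp scale."""
    if bp_sequenced <= 0:
        raise ValueError("bp_sequenced must be > 0")
    freq = Fraction(n_events, bp_sequenced)
    return freq, float(freq) * 1e4


@dataclass
class CloneCallSet:
    """Alignment products for a clone set: per-sequence calls and depth."""

    locus: ReferenceLocus
    raw_calls: list[RawCall]
    collapsed: list[CollapsedCall]
    bp_by_subclone: dict[str, int]
    alignments: dict[str, PairwiseAlignment]
    excluded: list[str]

    @property
    def total_bp(self) -> int:
        return sum(self.bp_by_subclone.values())


def call_clone_set(
    records: list[CloneRecord],
    locus: ReferenceLocus,
    min_identity: float = MIN_IDENTITY,
    **scoring,
) -> CloneCallSet:
    """Align every clone sequence to the locus and produce corrected calls.

    Sequences below ``min_identity`` to the locus are excluded (off-target
    amplicons) and listed. ``bp_sequenced`` per subclone counts aligned
    reference bases over all retained sequences, clonal duplicates included.
    """
    raw: list[RawCall] = []
    bp: dict[str, int] = {}
    alns: dict[str, PairwiseAlignment] = {}
    excluded: list[str] = []
    for rec in records:
        aln = align_to_reference(rec.sequence, locus.sequence, **scoring)
        if aln.identity() < min_identity:
            excluded.append(rec.seq_id)
            continue
        alns[rec.seq_id] = aln
        raw.extend(call_raw(aln, seq_id=rec.seq_id, subclone=rec.subclone))
        bp[rec.subclone] = bp.get(rec.subclone, 0) + aligned_reference_bp(aln)
    return CloneCallSet(
        locus=locus, raw_calls=raw, collapsed=clonal_collapse(raw),
        bp_by_subclone=bp, alignments=alns, excluded=excluded,
    )
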