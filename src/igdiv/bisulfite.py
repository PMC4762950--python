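"""Single-stranded-DNA patch detection in bisulfite-treated amplicons.

Bisulfite converts cytosines on exposed single-stranded DNA to uracil, read
out after PCR as C->T transitions on the top strand and G->A transitions on
the bottom strand (reported in top-strand coordinates). A single-stranded
patch is a run of >= 2 successive converted positions — successive meaning
consecutive in the ordered list of reference C (or G) positions, with no
intervening unconverted candidate. Patch boundaries are the first unmodified
C/G flanking the run on each side; runs abutting a read end get a sentinel
boundary (None) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import align_to_reference
from .synth import ReferenceLocus

__all__ = [
    "ConversionProfile",
    "BisulfitePatch",
    "profile_conversions",
    "call_patches",
    "patch_frequency",
    "infer_strand",
    "PATCH_MINIMUM",
]

PATCH_MINIMUM = 2
STRAND_RATIO = 3.0  # C->T vs G->A majority required to auto-call a strand


@dataclass(frozen=True)
class ConversionProfile:
    """Converted/unconverted status of every candidate position on one read."""

    read_id: str
    strand: str  # "top" (C positions) or "bottom" (G positions)
    positions: tuple[int, ...]  # reference coordinates, strictly increasing
    converted: tuple[bool, ...]
    non_bisulfite_mismatches: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.converted):
            raise ValueError("positions and converted flags must align")
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class BisulfitePatch:
    """A strand-specific ssDNA patch: its converted run and flank boundaries."""

    read_id: str
    strand: str
    first: int  # reference coordinate of first converted position in the run
    last: int
    run_length: int  # number of converted C/G in the run
    boundary5: int | None  # nearest unmodified C/G 5' of the run; None = read start
    boundary3: int | None


def infer_strand(read: str, locus: ReferenceLocus) -> str:
    """Call top/bottom strand from the transition spectrum.

    Top-strand bisulfite products show C->T transitions, bottom-strand
    products G->A. Requires a >= 3:1 majority; anything else is rejected.
    """
    aln = align_to_reference(read, locus.sequence)
    ct = ga = 0
    for r, q in zip(aln.aligned_ref, aln.aligned_query):
        if r == "C" and q == "T":
            ct += 1
        elif r == "G" and q == "A":
            ga += 1
    if ct >= STRAND_RATIO * max(ga, 1) and ct > 0:
        return "top"
    if ga >= STRAND_RATIO * max(ct, 1) and ga > 0:
        return "bottom"
    if ct == ga == 0:
        return "top"  # fully unconverted read: strand is arbitrary
    raise ValueError(f"cannot infer strand: {ct} C->T vs {ga} G->A transitions")


def profile_conversions(
    read: str,
    locus: ReferenceLocus,
    strand: str | None = None,
    min_identity: float = 0.80,
    read_id: str = "",
) -> ConversionProfile:
    """Classify every reference C (top) or G (bottom) as converted or not.

    The read is globally aligned to the locus; the identity threshold is
    checked after masking bisulfite transitions (a fully converted read is
    still on-target). Mismatches that are not bisulfite transitions (e.g.
    C->A) are excluded from the profile and reported separately.
    """
    if strand is None:
        strand = infer_strand(read, locus)
    if strand not in ("top", "bottom"):
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")
    aln = align_to_reference(read, locus.sequence)
    base, converted_to = ("C", "T") if strand == "top" else ("G", "A")
    matches = bis = ref_len = 0
    pos = 0
    positions: list[int] = []
    flags: list[bool] = []
    odd: list[int] = []
    for r, q in zip(aln.aligned_ref, aln.aligned_query):
        if r != "-":
            ref_len += 1
            if r == q:
                matches += 1
            elif r == base and q == converted_to:
                bis += 1
            if r == base and q != "-":
                if q == r:
                    positions.append(pos)
                    flags.append(False)
                elif q == converted_to:
                    positions.append(pos)
                    flags.append(True)
                else:
                    odd.append(pos)
            pos += 1
    if ref_len == 0 or (matches + bis) / ref_len < min_identity:
        raise ValueError(
            f"read identity {(matches + bis) / max(ref_len, 1):.2f} below {min_identity} after masking transitions"
        )
    return ConversionProfile(
        read_id=read_id, strand=strand,
        positions=tuple(positions), converted=tuple(flags),
        non_bisulfite_mismatches=tuple(odd),
    )


def call_patches(profile: ConversionProfile, patch_minimum: int = PATCH_MINIMUM) -> list[BisulfitePatch]:
    """Maximal runs of successive conversions with length >= the patch minimum.

    Runs of length 1 are never patches. Boundaries are the flanking
    unconverted candidate positions, or None sentinels at read ends.
    """
    pos, conv = profile.positions, profile.converted
    n = len(pos)
    patches: list[BisulfitePatch] = []
    i = 0
    while i < n:
        if not conv[i]:
            i += 1
            continue
        j = i
        while j < n and conv[j]:
            j += 1
        if j - i >= patch_minimum:
            patches.append(BisulfitePatch(
                read_id=profile.read_id, strand=profile.strand,
                first=pos[i], last=pos[j - 1], run_length=j - i,
                boundary5=pos[i - 1] if i > 0 else None,
                boundary3=pos[j] if j < n else None,
            ))
        i = j
    return patches


def patch_frequency(n_patches: int, bp_sequenced: int) -> float:
    """Percent single-stranded patches: 100 x patches / bp sequenced."""
    if bp_sequenced <= 0:
        raise ValueError("bp_sequenced must be > 0")
    return 100.0 * n_patches / bp_sequenced
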