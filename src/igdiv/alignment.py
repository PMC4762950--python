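"""Global pairwise alignment of clone amplicons to the reference locus.

Wraps an affine-gap global aligner and post-normalizes indels so that every
gap run sits at its leftmost score-equivalent placement. Left-shifting makes
indel coordinates reproducible across co-optimal alignments, which matters
because clonal collapse keys on exact positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

__all__ = ["PairwiseAlignment", "AlignmentError", "align_to_reference", "DEFAULT_SCORING"]

# Conservative scoring for low-divergence Sanger amplicons.
DEFAULT_SCORING = {"match": 1.0, "mismatch": -2.0, "gap_open": -5.0, "gap_extend": -1.0}

_AMBIGUITY = set("ACGTN")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings."""

    aligned_ref: str
    aligned_query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned strings must have equal length")

    def identity(self) -> float:
        """Matching columns / reference length (gap columns count against)."""
        matches = sum(a == b for a, b in zip(self.aligned_ref, self.aligned_query))
        ref_len = sum(c != "-" for c in self.aligned_ref)
        return matches / ref_len if ref_len else 0.0


def _validate(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = [i for i, c in enumerate(seq) if c not in _AMBIGUITY]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        raise AlignmentError(f"{label} has non-ACGTN characters at positions {shown}")
    return seq


def _left_shift_gaps(ref: list[str], qry: list[str]) -> None:
    """Shift every gap run left while the literal alignment stays valid.

    A gap run can move one column left when the non-gap base immediately left
    of the run equals the base the run would uncover on its right; the swap
    changes neither sequence content nor (with uniform per-base scores) the
    alignment score. Classic indel left-normalization.
    """
    for gapped, other in ((ref, qry), (qry, ref)):
        n = len(gapped)
        i = 0
        while i < n:
            if gapped[i] != "-":
                i += 1
                continue
            e = i
            while e < n and gapped[e] == "-":
                e += 1
            scan_from = e
            s = i
            while s > 0:
                x = gapped[s - 1]
                if x == "-" or other[s - 1] == "-":
                    break
                if s >= 2 and gapped[s - 2] == "-":
                    break  # merging runs would change the gap-open count
                if (x == other[e - 1]) != (x == other[s - 1]):
                    break  # shift would change the column score
                gapped[e - 1] = x
                gapped[s - 1] = "-"
                s -= 1
                e -= 1
            i = scan_from


def align_to_reference(
    sequence: str,
    locus_sequence: str,
    match: float = DEFAULT_SCORING["match"],
    mismatch: float = DEFAULT_SCORING["mismatch"],
    gap_open: float = DEFAULT_SCORING["gap_open"],
    gap_extend: float = DEFAULT_SCORING["gap_extend"],
) -> PairwiseAlignment:
    """Optimal global alignment of a clone sequence to the reference.

    Among co-optimal alignments, gaps are left-shifted for deterministic
    indel coordinates.
    """
    if not sequence:
        raise AlignmentError("empty sequence")
    sequence = _validate(sequence, "sequence")
    locus_sequence = _validate(locus_sequence, "locus")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(locus_sequence, sequence)[0]
    ref, qry = list(str(aln[0])), list(str(aln[1]))
    _left_shift_gaps(ref, qry)
    return PairwiseAlignment(aligned_ref="".join(ref), aligned_query="".join(qry), score=float(aln.score))
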