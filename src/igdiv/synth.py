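"""Synthetic data generation with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
planted-truth ledger: Sanger-style amplicon sequences of a V-like target
region carrying point mutations and donor-templated gene-conversion (GCV)
tracts with clonal lineage duplication; bisulfite-converted strands with
planted single-stranded-DNA patches; ChIP-style coverage tracks with
separately controlled promoter-proximal and gene-body signal densities; and
GFP-loss subclone fractions under a per-generation inactivation model.

All generators are deterministic for a fixed seed and record everything they
plant, so downstream callers can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chip import CoverageTrack, GeneModel

BASES = "ACGT"

__all__ = [
    "ReferenceLocus",
    "DonorSet",
    "PlantedEvent",
    "PlantedTruth",
    "CloneRecord",
    "BisulfiteRead",
    "PlantedPatch",
    "make_locus",
    "make_donor_set",
    "simulate_clone_set",
    "simulate_bisulfite_reads",
    "simulate_coverage",
    "simulate_gfp_loss",
]


@dataclass(frozen=True)
class ReferenceLocus:
    """A rearranged V-like target sequence (or GFP cassette stand-in)."""

    name: str
    sequence: str
    origin: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 50:
            raise ValueError(f"locus must be >= 50 bp, got {len(self.sequence)}")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"locus alphabet restricted to ACGT; found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DonorSet:
    """Pseudo-V donor repertoire used for GCV attribution.

    When ``alignment_mode`` is true the donors are positionally homologous to
    the locus (same length, no indel divergence), which makes exact tract
    matching well defined.
    """

    donors: tuple[tuple[str, str], ...]
    alignment_mode: bool = True

    def __post_init__(self) -> None:
        if len(self.donors) < 1:
            raise ValueError("donor set requires at least one donor")
        for name, seq in self.donors:
            bad = set(seq) - set(BASES)
            if bad:
                raise ValueError(f"donor {name}: alphabet restricted to ACGT")

    def __len__(self) -> int:
        return len(self.donors)

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.donors]

    def names(self) -> list[str]:
        return [name for name, _ in self.donors]


@dataclass(frozen=True)
class PlantedEvent:
    """One planted diversification event in the truth ledger.

    ``kind`` is one of point / gcv_tract / insertion / deletion. Tract
    coordinates are 0-based half-open; ``positions`` lists the donor-marker
    positions a GCV tract actually changed (or the single point position).
    """

    kind: str
    seq_id: str
    subclone: str
    start: int
    end: int
    positions: tuple[int, ...] = ()
    donor_id: str | None = None
    alt: str | None = None


@dataclass
class PlantedTruth:
    """Ledger of everything the clone simulator planted."""

    events: list[PlantedEvent] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)  # seq_id -> clonal group

    def events_for(self, seq_id: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.seq_id == seq_id]


@dataclass(frozen=True)
class CloneRecord:
    seq_id: str
    subclone: str
    group: str
    sequence: str


@dataclass(frozen=True)
class BisulfiteRead:
    seq_id: str
    strand: str  # "top" or "bottom"; bottom reads are reported in top-strand frame
    sequence: str


@dataclass(frozen=True)
class PlantedPatch:
    read_id: str
    strand: str
    positions: tuple[int, ...]  # converted C (top) / G (bottom) reference positions
    boundary5: int | None  # nearest unmodified C/G 5' of the run, None at read start
    boundary3: int | None


def make_locus(length: int, gc_fraction: float, seed: int, name: str = "locus") -> ReferenceLocus:
    """Random target locus with the requested GC content."""
    if length < 50:
        raise ValueError(f"length must be >= 50, got {length}")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    is_gc = rng.random(length) < gc_fraction
    halves = rng.random(length) < 0.5
    seq = np.where(is_gc, np.where(halves, "G", "C"), np.where(halves, "A", "T"))
    return ReferenceLocus(name=name, sequence="".join(seq))


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(len(choices))]


def make_donor_set(
    locus: ReferenceLocus,
    n_donors: int,
    divergence: float,
    seed: int,
) -> DonorSet:
    """Pseudo-V donors as point-diverged, positionally homologous locus copies.

    Each donor carries independent substitutions at per-base rate
    ``divergence`` and is guaranteed to differ from the locus at >= 1 site
    (resampled otherwise) so that every donor is observable as a GCV template.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if not 0.0 < divergence <= 0.5:
        raise ValueError("divergence must be in (0, 0.5]; 0 would make GCV undetectable")
    rng = np.random.default_rng(seed)
    ref = list(locus.sequence)
    donors = []
    for i in range(n_donors):
        while True:
            mask = rng.random(len(ref)) < divergence
            if mask.any():
                break
        seq = ref.copy()
        for pos in np.flatnonzero(mask):
            seq[pos] = _substitute(ref[pos], rng)
        donors.append((f"pseudoV{i + 1:02d}", "".join(seq)))
    return DonorSet(donors=tuple(donors), alignment_mode=True)


def _plant_gcv(
    seq: list[str],
    ref: str,
    donors: DonorSet,
    tract_length: tuple[int, int],
    rng: np.random.Generator,
    occupied: set[int],
    min_markers: int = 2,
    max_tries: int = 200,
) -> tuple[int, int, str, tuple[int, ...]]:
    """Copy a donor segment carrying donor-locus markers onto ``seq``.

    Resamples donor/position until the tract window contains at least
    ``min_markers`` visible differences and avoids previously planted tracts;
    an invisible tract is never emitted. The default of 2 markers makes every
    planted tract observable *as a conversion* — a 1-marker tract is
    inherently indistinguishable from a point mutation that happens to match
    a donor.
    """
    lo, hi = tract_length
    names = donors.names()
    dseqs = donors.sequences()
    for _ in range(max_tries):
        di = int(rng.integers(len(dseqs)))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(ref) - length + 1))
        if any(p in occupied for p in range(start, start + length)):
            continue
        window = slice(start, start + length)
        markers = tuple(
            p for p in range(start, start + length) if dseqs[di][p] != ref[p]
        )
        if len(markers) < min_markers:
            continue
        seq[window] = list(dseqs[di][window])
        return start, start + length, names[di], markers
    raise RuntimeError("could not place a visible GCV tract; donors too similar to locus")


def simulate_clone_set(
    locus: ReferenceLocus,
    donors: DonorSet,
    n_subclones: int,
    seqs_per_subclone: int,
    point_rate: float,
    gcv_rate: float,
    tract_length: tuple[int, int],
    clonal_dup_prob: float,
    seed: int,
    min_tract_markers: int = 2,
) -> tuple[list[CloneRecord], PlantedTruth]:
    """Simulate the sequencing experiment: amplicons per subclone with planted
    point mutations, GCV tracts, and exact clonal duplicates.

    Point mutations are substitutions to a uniformly chosen different base and
    are kept off planted tracts so that every planted event stays individually
    re-derivable from (locus, sequence). With probability ``clonal_dup_prob`` a
    sequence is an exact copy of an earlier sequence in the same subclone and
    shares its clonal-group label.
    """
    if point_rate < 0 or gcv_rate < 0:
        raise ValueError("rates must be >= 0")
    if not 0.0 <= clonal_dup_prob <= 1.0:
        raise ValueError("clonal_dup_prob must be in [0, 1]")
    if gcv_rate > 0 and tract_length[1] > len(locus):
        raise ValueError("tract max exceeds locus length")
    rng = np.random.default_rng(seed)
    ref = locus.sequence
    records: list[CloneRecord] = []
    truth = PlantedTruth()
    for s in range(n_subclones):
        sub = f"sc{s + 1:02d}"
        lineage: list[tuple[str, str, list[PlantedEvent]]] = []  # (seq, group, events)
        for j in range(seqs_per_subclone):
            seq_id = f"{sub}_seq{j + 1:03d}"
            if lineage and rng.random() < clonal_dup_prob:
                src = lineage[int(rng.integers(len(lineage)))]
                seq_str, group, src_events = src
                events = [
                    PlantedEvent(
                        kind=e.kind, seq_id=seq_id, subclone=sub, start=e.start,
                        end=e.end, positions=e.positions, donor_id=e.donor_id, alt=e.alt,
                    )
                    for e in src_events
                ]
            else:
                seq = list(ref)
                events = []
                group = f"{sub}.g{len({g for _, g, _ in lineage}) + 1}"
                n_gcv = rng.poisson(gcv_rate)
                occupied: set[int] = set()
                for _ in range(n_gcv):
                    start, end, donor_id, markers = _plant_gcv(
                        seq, ref, donors, tract_length, rng, occupied, min_tract_markers)
                    occupied.update(range(start, end))
                    events.append(PlantedEvent(
                        kind="gcv_tract", seq_id=seq_id, subclone=sub,
                        start=start, end=end, positions=markers, donor_id=donor_id,
                    ))
                n_point = rng.poisson(point_rate * len(ref))
                free = [p for p in range(len(ref)) if p not in occupied]
                n_point = min(n_point, len(free))
                for pos in rng.choice(len(free), size=n_point, replace=False):
                    p = free[int(pos)]
                    alt = _substitute(ref[p], rng)
                    seq[p] = alt
                    events.append(PlantedEvent(
                        kind="point", seq_id=seq_id, subclone=sub,
                        start=p, end=p + 1, positions=(p,), alt=alt,
                    ))
                seq_str = "".join(seq)
            lineage.append((seq_str, group, events))
            records.append(CloneRecord(seq_id=seq_id, subclone=sub, group=group, sequence=seq_str))
            truth.groups[seq_id] = group
            truth.events.extend(events)
    return records, truth


def simulate_bisulfite_reads(
    locus: ReferenceLocus,
    n_reads: int,
    strand_mix: float,
    patch_rate: float,
    patch_c_run: tuple[int, int],
    background_conversion: float,
    seed: int,
) -> tuple[list[BisulfiteRead], list[PlantedPatch]]:
    """Bisulfite-converted strands with planted single-stranded-DNA patches.

    Top-strand reads convert C->T over a run of >= 2 consecutive C positions
    inside each planted patch; bottom-strand reads convert G->A, reported in
    top-strand coordinates. Background conversion is applied independently per
    C (or G) outside patches. Planted patches are separated by at least one
    unconverted candidate position so they never merge.
    """
    if not 0.0 <= background_conversion < 1.0:
        raise ValueError("background_conversion must be in [0, 1)")
    if patch_c_run[0] < 2:
        raise ValueError("patch minimum is 2 successive conversions")
    if not 0.0 <= strand_mix <= 1.0:
        raise ValueError("strand_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = locus.sequence
    cand = {
        "top": [i for i, b in enumerate(ref) if b == "C"],
        "bottom": [i for i, b in enumerate(ref) if b == "G"],
    }
    reads: list[BisulfiteRead] = []
    patches: list[PlantedPatch] = []
    for r in range(n_reads):
        strand = "top" if rng.random() < strand_mix else "bottom"
        positions = cand[strand]
        n_cand = len(positions)
        n_patches = rng.poisson(patch_rate)
        if n_patches > 0 and n_cand < patch_c_run[0]:
            raise ValueError(f"locus has <{patch_c_run[0]} {'C' if strand == 'top' else 'G'} positions; cannot plant patch")
        converted_idx: set[int] = set()  # indices into the candidate-position list
        blocked: set[int] = set()
        read_id = f"bs{r + 1:03d}"
        for _ in range(n_patches):
            run = int(rng.integers(patch_c_run[0], patch_c_run[1] + 1))
            run = min(run, n_cand)
            starts = [
                i for i in range(n_cand - run + 1)
                # keep one unconverted candidate flanking each planted run
                if all(k not in blocked for k in range(i - 1, i + run + 1))
            ]
            if not starts:
                break
            i0 = starts[int(rng.integers(len(starts)))]
            idx = list(range(i0, i0 + run))
            converted_idx.update(idx)
            blocked.update(range(i0 - 1, i0 + run + 1))
            patches.append(PlantedPatch(
                read_id=read_id,
                strand=strand,
                positions=tuple(positions[i] for i in idx),
                boundary5=positions[i0 - 1] if i0 > 0 else None,
                boundary3=positions[i0 + run] if i0 + run < n_cand else None,
            ))
        if background_conversion > 0:
            for i in range(n_cand):
                if i not in blocked and rng.random() < background_conversion:
                    converted_idx.add(i)
        seq = list(ref)
        to = "T" if strand == "top" else "A"
        for i in converted_idx:
            seq[positions[i]] = to
        reads.append(BisulfiteRead(seq_id=read_id, strand=strand, sequence="".join(seq)))
    return reads, patches


def simulate_coverage(
    model: GeneModel,
    proximal_density: float,
    body_density: float,
    noise_cv: float,
    flank_density: float,
    seed: int,
    flank_bp: int = 500,
    total_mapped_reads: float = 1e6,
) -> CoverageTrack:
    """ChIP-style coverage with separately controlled promoter-proximal and
    gene-body densities (RPM/kb) plus flanking background.

    The proximal region is TSS +/- 100 bp and the body runs from +101 to the
    gene end, mirroring how a GFP-cassette elongation index is defined.
    Per-base signal is the region density with multiplicative gamma noise of
    coefficient of variation ``noise_cv`` (mean 1), so planted densities are
    recoverable by direct averaging.
    """
    for name, d in (("proximal", proximal_density), ("body", body_density), ("flank", flank_density)):
        if d < 0:
            raise ValueError(f"{name} density must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = min(model.tss, model.tts), max(model.tss, model.tts)
    start = lo - flank_bp
    end = hi + flank_bp
    n = end - start
    signal = np.full(n, flank_density / 1000.0)

    prox = model.offset_interval(-100, 100)
    body = model.offset_interval(101, model.length)
    for (a, b), dens in ((prox, proximal_density), (body, body_density)):
        signal[a - start : b - start] = dens / 1000.0
    if noise_cv > 0:
        shape = 1.0 / noise_cv**2
        signal = signal * rng.gamma(shape, 1.0 / shape, size=n)
    return CoverageTrack(
        contig=model.contig, start=start, signal=signal,
        total_mapped_reads=total_mapped_reads,
    )


def simulate_gfp_loss(
    n_subclones: int,
    per_generation_loss: float,
    generations: int,
    cells_sampled: int,
    seed: int,
    jackpot: bool = False,
) -> list[float]:
    """GFP-loss fluctuation assay: per-subclone GFP-negative percentages.

    Default model: independent per-generation inactivation, so the expected
    negative fraction after g generations is 1 - (1 - loss)^g, observed as a
    binomial sample of ``cells_sampled`` cells. With ``jackpot=True`` each
    subclone is instead grown as a branching process from a single cell
    (Luria-Delbruck-style variance inflation from early loss events).
    """
    if not 0.0 <= per_generation_loss <= 1.0:
        raise ValueError("per_generation_loss must be in [0, 1]")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[float] = []
    for _ in range(n_subclones):
        if jackpot:
            pos, neg = 1, 0
            for _ in range(generations):
                new_neg = rng.binomial(2 * pos, per_generation_loss) if pos > 0 else 0
                pos, neg = 2 * pos - new_neg, 2 * neg + new_neg
            frac = neg / (pos + neg)
        else:
            frac = 1.0 - (1.0 - per_generation_loss) ** generations
        k = rng.binomial(cells_sampled, frac)
        out.append(100.0 * k / cells_sampled)
    return out
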