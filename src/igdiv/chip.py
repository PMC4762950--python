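"""ChIP-seq elongation-index and metagene computations.

Operates on RPM-normalized per-base coverage tracks and strand-aware gene
models. The elongation index is the signal density (RPM per kb) in the gene
body divided by the density in the promoter-proximal window — the inverse in
spirit of a pausing index: a paused factor gives a small index, a factor that
travels with elongating Pol II gives an index near 1.

Conventions: all coordinates are 0-based half-open internally. For a minus-
strand gene the TSS has the larger genomic coordinate and "downstream"
decreases; window offsets are always expressed in transcription direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoverageTrack",
    "GeneModel",
    "ElongationIndex",
    "MetageneProfile",
    "rpm_normalize",
    "windowed_scores",
    "region_density",
    "elongation_index",
    "gfp_elongation_index",
    "metagene_bins",
    "gene_elongation_indexes",
    "select_top_overlap",
    "percentile_rank",
    "metagene_profile",
]

# GFP-cassette windows: promoter-proximal = TSS +/- 100 bp, body = +101 .. end.
GFP_PROXIMAL = (-100, 100)
GFP_BODY_START = 101
# refSeq-gene windows: proximal = -100 .. +300 from the TSS, body = +300 .. TTS.
GENE_PROXIMAL = (-100, 300)
GENE_BODY_START = 300


@dataclass
class CoverageTrack:
    """Per-base signal (reads-per-million scale) over [start, start+len)."""

    contig: str
    start: int
    signal: np.ndarray
    total_mapped_reads: float = 1e6

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be a 1-D array")
        if (self.signal < 0).any():
            raise ValueError("signal must be >= 0 everywhere")

    @property
    def end(self) -> int:
        return self.start + len(self.signal)

    def region(self, a: int, b: int) -> np.ndarray:
        """Signal over genomic interval [a, b); must lie within the track."""
        if not (self.start <= a <= b <= self.end):
            raise ValueError(f"[{a}, {b}) outside track [{self.start}, {self.end})")
        return self.signal[a - self.start : b - self.start]


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware transcription unit. For '+' TSS < TTS; for '-' TSS > TTS."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss == self.tts:
            raise ValueError("TSS must differ from TTS")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand requires TSS < TTS")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand requires TSS > TTS")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)

    def offset_interval(self, a: int, b: int) -> tuple[int, int]:
        """Genomic half-open interval for transcription-direction offsets [a, b).

        Offset 0 is the TSS base; positive offsets run downstream. A minus-
        strand window mirrors around the TSS so that its genomic extent covers
        exactly the same transcribed bases as the plus-strand equivalent.
        """
        if a >= b:
            raise ValueError("offset interval must be non-empty (a < b)")
        if self.strand == "+":
            return self.tss + a, self.tss + b
        return self.tss - b + 1, self.tss - a + 1


@dataclass(frozen=True)
class ElongationIndex:
    gene_id: str
    proximal: tuple[int, int]
    proximal_density: float
    body: tuple[int, int]
    body_density: float
    index: float | None  # None when the proximal density is 0 (undefined)

    @property
    def defined(self) -> bool:
        return self.index is not None


@dataclass
class MetageneProfile:
    """100-bin averaged, per-gene max-normalized coverage profile."""

    profile: np.ndarray
    n_genes: int
    upstream_bp: int
    skipped: list[str] = field(default_factory=list)


def rpm_normalize(counts: np.ndarray, total_mapped_reads: float, contig: str = "chr", start: int = 0) -> CoverageTrack:
    """Scale raw per-base counts to reads per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    counts = np.asarray(counts, dtype=float)
    return CoverageTrack(
        contig=contig, start=start,
        signal=counts * 1e6 / total_mapped_reads,
        total_mapped_reads=total_mapped_reads,
    )


def windowed_scores(
    track: CoverageTrack, window_bp: int, step_bp: int
) -> list[tuple[int, int, float]]:
    """Sum of per-base signal over (possibly overlapping) windows.

    Returns (genomic_start, genomic_end, score) per anchor; a trailing partial
    window is reported with its true width. This reproduces the wig-emission
    convention of windowed ChIP scores (e.g. 100-bp windows every 100 bp).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if not 1 <= step_bp <= window_bp:
        raise ValueError("step_bp must be in [1, window_bp]")
    n = len(track.signal)
    if window_bp > n:
        warnings.warn("window exceeds track length; emitting one whole-track window")
        return [(track.start, track.end, float(track.signal.sum()))]
    csum = np.concatenate([[0.0], np.cumsum(track.signal)])
    out = []
    pos = 0
    while pos < n:
        hi = min(pos + window_bp, n)
        out.append((track.start + pos, track.start + hi, float(csum[hi] - csum[pos])))
        if hi == n:
            break
        pos += step_bp
    return out


def region_density(track: CoverageTrack, interval: tuple[int, int]) -> float:
    """Total RPM in the interval divided by its length in kb."""
    a, b = interval
    if b <= a:
        raise ValueError("interval must be non-empty")
    return float(track.region(a, b).sum()) / ((b - a) / 1000.0)


def elongation_index(
    track: CoverageTrack,
    region_proximal: tuple[int, int],
    region_body: tuple[int, int],
    gene_id: str = "region",
) -> ElongationIndex:
    """Body density / promoter-proximal density (both RPM per kb).

    A zero proximal density yields an undefined (None) index rather than an
    infinity, so degenerate genes cannot skew downstream summaries.
    """
    pa, pb = region_proximal
    ba, bb = region_body
    if max(pa, ba) < min(pb, bb):
        raise ValueError("proximal and body regions may not overlap")
    dp = region_density(track, region_proximal)
    db = region_density(track, region_body)
    index = db / dp if dp > 0 else None
    return ElongationIndex(
        gene_id=gene_id, proximal=region_proximal, proximal_density=dp,
        body=region_body, body_density=db, index=index,
    )


def gfp_elongation_index(track: CoverageTrack, gene: GeneModel) -> ElongationIndex:
    """GFP-cassette convention: proximal TSS +/- 100 bp, body +101 to gene end."""
    prox = gene.offset_interval(*GFP_PROXIMAL)
    body = gene.offset_interval(GFP_BODY_START, gene.length)
    return elongation_index(track, prox, body, gene_id=gene.gene_id)


def gene_elongation_indexes(
    track: CoverageTrack,
    genes: list[GeneModel],
    proximal_def: tuple[int, int] = GENE_PROXIMAL,
    body_start: int = GENE_BODY_START,
) -> tuple[list[ElongationIndex], list[str]]:
    """Per-gene elongation indexes with strand-aware windows.

    Genes whose body would be empty after applying the offsets (shorter than
    ``body_start``) are skipped and returned in the skip log.
    """
    out: list[ElongationIndex] = []
    skipped: list[str] = []
    for g in genes:
        if g.contig != track.contig:
            skipped.append(g.gene_id)
            continue
        if g.length <= body_start:
            skipped.append(g.gene_id)
            continue
        prox = g.offset_interval(*proximal_def)
        body = g.offset_interval(body_start, g.length)
        try:
            out.append(elongation_index(track, prox, body, gene_id=g.gene_id))
        except ValueError:
            skipped.append(g.gene_id)
    return out, skipped


def select_top_overlap(sample_scores: list[dict[str, float]], n_top: int) -> list[str]:
    """Genes in the top ``n_top`` by score in every sample.

    Mirrors top-200-in-all-lines gene selection: each sample's genes are
    ranked by score (descending, gene id ascending for ties), the top n taken,
    and the per-sample sets intersected. Returns sorted gene ids.
    """
    if len(sample_scores) < 2:
        raise ValueError("need >= 2 samples to intersect")
    universe = set(sample_scores[0])
    for s in sample_scores[1:]:
        if set(s) != universe:
            raise ValueError("samples must share a gene universe")
    if n_top > len(universe):
        warnings.warn("n_top exceeds gene universe; using all genes per sample")
        n_top = len(universe)
    tops = []
    for s in sample_scores:
        ranked = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
        tops.append({g for g, _ in ranked[:n_top]})
    return sorted(set.intersection(*tops))


def percentile_rank(value: float, distribution: list[float] | np.ndarray) -> float:
    """Mid-rank percentile of ``value`` within ``distribution`` (0..100)."""
    dist = np.asarray(distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("distribution must be non-empty")
    below = (dist < value).sum()
    ties = (dist == value).sum()
    return 100.0 * (below + 0.5 * ties) / dist.size


def _bin_edges(total: int, n_bins: int) -> np.ndarray:
    """Bin boundaries at rounded equal fractions of ``total``."""
    return np.round(np.linspace(0, total, n_bins + 1)).astype(int)


def metagene_bins(track: CoverageTrack, gene: GeneModel, upstream_bp: int = 100, n_bins: int = 100) -> np.ndarray:
    """Per-bin reads-per-bp from -upstream_bp of the TSS to the TTS.

    Bin 1 is most upstream regardless of strand; per-bin density uses each
    bin's true bp width, so unequal widths from rounding stay unbiased.
    """
    total = upstream_bp + gene.length
    edges = _bin_edges(total, n_bins)
    if np.any(np.diff(edges) < 1):
        raise ValueError(f"{gene.gene_id}: too short to form {n_bins} >=1-bp bins")
    vals = np.empty(n_bins)
    for i in range(n_bins):
        a, b = gene.offset_interval(int(edges[i]) - upstream_bp, int(edges[i + 1]) - upstream_bp)
        region = track.region(a, b)
        if gene.strand == "-":
            region = region[::-1]
        vals[i] = region.mean()
    return vals


def metagene_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    upstream_bp: int = 100,
    n_bins: int = 100,
    pooled_normalization: bool = False,
) -> MetageneProfile:
    """Average max-normalized binned profile over a gene set.

    Each gene's 100-bin reads-per-bp vector is scaled so its maximum is 1,
    then vectors are averaged elementwise (genes with all-zero signal are
    skipped and logged). With ``pooled_normalization`` the raw vectors are
    averaged first and the average scaled to max 1 instead.
    """
    vectors = []
    skipped: list[str] = []
    for g in genes:
        try:
            v = metagene_bins(track, g, upstream_bp=upstream_bp, n_bins=n_bins)
        except ValueError:
            skipped.append(g.gene_id)
            continue
        if v.max() <= 0:
            skipped.append(g.gene_id)
            continue
        vectors.append(v if pooled_normalization else v / v.max())
    if not vectors:
        raise ValueError("no gene contributed a non-zero profile")
    profile = np.mean(vectors, axis=0)
    if pooled_normalization:
        profile = profile / profile.max()
    return MetageneProfile(profile=profile, n_genes=len(vectors), upstream_bp=upstream_bp, skipped=skipped)
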