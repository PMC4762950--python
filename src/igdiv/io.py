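"""Readers and writers for the interchange formats.

FASTA carries ``key=value`` tokens (subclone=, group=, strand=) in record
descriptions; coverage moves as bedGraph or fixedStep wiggle (wiggle is
1-based per the standard and converted to the internal 0-based half-open
convention on read); gene models as BED6; tables as tab-separated files with
``#``-prefixed header metadata; the simulation truth ledger as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip import CoverageTrack, GeneModel
from .synth import BisulfiteRead, CloneRecord, PlantedTruth, ReferenceLocus

logger = logging.getLogger("igdiv")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_clone_fasta",
    "write_clone_fasta",
    "write_bisulfite_fasta",
    "write_locus_fasta",
    "read_coverage",
    "write_bedgraph",
    "write_wiggle",
    "read_bed6",
    "write_bed6",
    "write_tsv",
    "write_truth_json",
    "read_truth_json",
]


class FormatError(ValueError):
    pass


def _parse_tokens(description: str) -> dict[str, str]:
    tokens: dict[str, str] = {}
    for field in description.split()[1:]:  # first word is the record id
        if "=" not in field:
            logger.warning("ignoring malformed description token %r", field)
            continue
        key, _, value = field.partition("=")
        if not key or not value:
            logger.warning("ignoring malformed description token %r", field)
            continue
        tokens[key] = value
    return tokens


def read_fasta(path: str | Path) -> list[tuple[str, str, dict[str, str]]]:
    """FASTA records as (id, uppercased sequence, token map), in file order."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or malformed FASTA")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.warning("%s: lowercase bases in %s uppercased", path.name, rec.id)
            seq = seq.upper()
        out.append((rec.id, seq, _parse_tokens(rec.description)))
    return out


def write_fasta(path: str | Path, records: list[tuple[str, str, dict[str, str]]]) -> None:
    seqrecords = []
    for rec_id, seq, tokens in records:
        desc = " ".join(f"{k}={v}" for k, v in tokens.items())
        seqrecords.append(SeqRecord(Seq(seq), id=rec_id, description=desc))
    SeqIO.write(seqrecords, str(path), "fasta")


def write_clone_fasta(path: str | Path, records: list[CloneRecord]) -> None:
    write_fasta(path, [
        (r.seq_id, r.sequence, {"subclone": r.subclone, "group": r.group})
        for r in records
    ])


def read_clone_fasta(path: str | Path) -> list[CloneRecord]:
    out = []
    for rec_id, seq, tokens in read_fasta(path):
        out.append(CloneRecord(
            seq_id=rec_id,
            subclone=tokens.get("subclone", "sc01"),
            group=tokens.get("group", rec_id),
            sequence=seq,
        ))
    return out


def write_bisulfite_fasta(path: str | Path, reads: list[BisulfiteRead]) -> None:
    write_fasta(path, [(r.seq_id, r.sequence, {"strand": r.strand}) for r in reads])


def write_locus_fasta(path: str | Path, locus: ReferenceLocus) -> None:
    write_fasta(path, [(locus.name, locus.sequence, {})])


def write_bedgraph(path: str | Path, track: CoverageTrack) -> None:
    """Run-length-compressed bedGraph (0-based half-open intervals)."""
    sig = track.signal
    with open(path, "w") as fh:
        fh.write(f"# total_mapped_reads={track.total_mapped_reads:g}\n")
        i = 0
        while i < len(sig):
            j = i
            while j < len(sig) and sig[j] == sig[i]:
                j += 1
            fh.write(f"{track.contig}\t{track.start + i}\t{track.start + j}\t{sig[i]:.6g}\n")
            i = j


def write_wiggle(path: str | Path, track: CoverageTrack, span: int = 1) -> None:
    """fixedStep wiggle, 1-based start per the wiggle standard."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={track.contig} start={track.start + 1} step={span} span={span}\n")
        for i in range(0, len(track.signal), span):
            fh.write(f"{track.signal[i:i + span].mean():.6g}\n")


def read_coverage(path: str | Path, format: str | None = None, total_mapped_reads: float = 1e6) -> CoverageTrack:
    """Per-base coverage from bedGraph or fixedStep wiggle.

    Format is sniffed from the first data line when not declared. bedGraph
    intervals must be sorted and non-overlapping; wiggle 1-based starts are
    converted to the 0-based internal convention.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    data = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith(("#", "track"))]
    if not data:
        raise FormatError(f"{path}: no data lines")
    if format is None:
        format = "wiggle" if data[0][1].startswith(("fixedStep", "variableStep")) else "bedgraph"
    for ln in lines:
        if ln.startswith("# total_mapped_reads="):
            total_mapped_reads = float(ln.split("=", 1)[1])
    if format == "bedgraph":
        intervals = []
        for lineno, ln in data:
            parts = ln.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            contig, a, b, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            intervals.append((lineno, contig, a, b, v))
        contig = intervals[0][1]
        for lineno, c, a, b, _ in intervals:
            if c != contig:
                raise FormatError(f"{path}:{lineno}: multiple contigs not supported")
            if b <= a:
                raise FormatError(f"{path}:{lineno}: empty interval")
        prev_end = None
        for lineno, _, a, b, _ in intervals:
            if prev_end is not None and a < prev_end:
                raise FormatError(f"{path}:{lineno}: overlapping or out-of-order interval")
            prev_end = b
        start = intervals[0][2]
        end = intervals[-1][3]
        signal = np.zeros(end - start)
        for _, _, a, b, v in intervals:
            signal[a - start:b - start] = v
        return CoverageTrack(contig=contig, start=start, signal=signal,
                             total_mapped_reads=total_mapped_reads)
    if format == "wiggle":
        contig, start0, step, span = None, None, 1, 1
        values: list[float] = []
        mode = None
        per_base: dict[int, float] = {}
        for lineno, ln in data:
            if ln.startswith("fixedStep"):
                fields = dict(f.split("=") for f in ln.split()[1:])
                contig = fields["chrom"]
                start0 = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                mode = "fixed"
                values = []
                base = start0
                continue
            if ln.startswith("variableStep"):
                fields = dict(f.split("=") for f in ln.split()[1:])
                contig = fields["chrom"]
                span = int(fields.get("span", 1))
                mode = "variable"
                continue
            if mode == "fixed":
                v = float(ln)
                for k in range(span):
                    per_base[base + k] = v
                base += step
            elif mode == "variable":
                p, v = ln.split()
                p0 = int(p) - 1
                for k in range(span):
                    per_base[p0 + k] = float(v)
            else:
                raise FormatError(f"{path}:{lineno}: data before wiggle header")
        if not per_base:
            raise FormatError(f"{path}: wiggle file with no values")
        lo, hi = min(per_base), max(per_base) + 1
        signal = np.zeros(hi - lo)
        for p, v in per_base.items():
            signal[p - lo] = v
        return CoverageTrack(contig=contig or "chr", start=lo, signal=signal,
                             total_mapped_reads=total_mapped_reads)
    raise ValueError(f"unknown coverage format {format!r}")


def read_bed6(path: str | Path) -> list[GeneModel]:
    """Gene models from BED6 (0-based half-open; TSS depends on strand)."""
    out = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "track")):
            continue
        parts = ln.split("\t")
        if len(parts) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
        contig, a, b, name, _score, strand = parts[:6]
        a, b = int(a), int(b)
        if strand == "+":
            tss, tts = a, b
        elif strand == "-":
            tss, tts = b - 1, a - 1
        else:
            raise FormatError(f"{path}:{lineno}: strand must be + or -")
        out.append(GeneModel(gene_id=name, contig=contig, strand=strand, tss=tss, tts=tts))
    return out


def write_bed6(path: str | Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                a, b = g.tss, g.tts
            else:
                a, b = g.tts + 1, g.tss + 1
            fh.write(f"{g.contig}\t{a}\t{b}\t{g.gene_id}\t0\t{g.strand}\n")


def write_tsv(path: str | Path, rows: list[dict], header_meta: dict | None = None) -> None:
    """Tab-separated table with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        if not rows:
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_truth_json(path: str | Path, truth: PlantedTruth) -> None:
    payload = {
        "events": [asdict(e) for e in truth.events],
        "groups": truth.groups,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
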