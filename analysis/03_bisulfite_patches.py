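"""Single-stranded-DNA patch detection in the bisulfite read set.

Profiles every read from step 01 against the locus, calls patches (runs of
>= 2 successive transitions), and reports per-strand counts and the
% single-stranded patches statistic, cross-checked against the planted truth.

Run after 01:  python analysis/03_bisulfite_patches.py
"""

import json
from pathlib import Path

from igdiv import bisulfite as bs, io as igio, synth

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    locus_rec = igio.read_fasta(DATA / "locus.fasta")[0]
    locus = synth.ReferenceLocus(name=locus_rec[0], sequence=locus_rec[1])
    rows = []
    per_strand = {"top": 0, "bottom": 0}
    bp = 0
    for rid, seq, tokens in igio.read_fasta(DATA / "bisulfite_reads.fasta"):
        prof = bs.profile_conversions(seq, locus, strand=tokens.get("strand"),
                                      read_id=rid)
        bp += len(seq)
        for p in bs.call_patches(prof):
            per_strand[p.strand] += 1
            rows.append({
                "read_id": rid, "strand": p.strand, "first": p.first,
                "last": p.last, "run_length": p.run_length,
                "boundary5": "start" if p.boundary5 is None else p.boundary5,
                "boundary3": "end" if p.boundary3 is None else p.boundary3})
    pct = bs.patch_frequency(len(rows), bp)
    planted = json.loads((DATA / "bisulfite_truth.json").read_text())
    igio.write_tsv(OUT / "ssdna_patches.tsv", rows, {
        "bp_sequenced": bp, "percent_ssdna_patches": f"{pct:.4f}",
        "top": per_strand["top"], "bottom": per_strand["bottom"],
        "planted": len(planted)})
    print(f"{len(rows)} patches ({per_strand['top']} top / "
          f"{per_strand['bottom']} bottom) over {bp} bp -> {pct:.4f}% "
          f"ssDNA patches ({len(planted)} planted)")


if __name__ == "__main__":
    main()
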