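"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/: the V-like target locus and its 25-donor
pseudo-V repertoire, clone-sequencing FASTAs for a diversifying ("wt") and a
diversification-deficient ("bcl6_null") line with truth ledgers, bisulfite
read sets, ChIP-style coverage tracks for three lines with planted
elongation indexes (1.1 / 0.05 / 0.275), and GFP-loss fluctuation tables.

Run:  python analysis/01_simulate_inputs.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from igdiv import chip, io as igio, synth

DATA = Path("results/data")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    s = args.seed
    DATA.mkdir(parents=True, exist_ok=True)

    locus = synth.make_locus(500, 0.5, s, name="V_target")
    donors = synth.make_donor_set(locus, 25, 0.05, s + 1)
    igio.write_locus_fasta(DATA / "locus.fasta", locus)
    igio.write_fasta(DATA / "donors.fasta", [(n, q, {}) for n, q in donors.donors])

    # clone sequencing: active line mutates at ~1e-3 events/bp (points +
    # conversion tracts), deficient line at background, 6.5x lower, no GCV
    lines = {
        "wt": dict(point_rate=6e-4, gcv_rate=0.2),
        "bcl6_null": dict(point_rate=1e-3 / 6.5, gcv_rate=0.0),
    }
    for k, (name, rates) in enumerate(lines.items()):
        recs, truth = synth.simulate_clone_set(
            locus, donors, n_subclones=8, seqs_per_subclone=50,
            tract_length=(30, 60), clonal_dup_prob=0.3, seed=s + 2 + k, **rates)
        igio.write_clone_fasta(DATA / f"clones_{name}.fasta", recs)
        igio.write_truth_json(DATA / f"truth_{name}.json", truth)
        print(f"{name}: {len(recs)} sequences, {len(truth.events)} planted events")

    reads, planted = synth.simulate_bisulfite_reads(
        locus, n_reads=50, strand_mix=0.5, patch_rate=0.5,
        patch_c_run=(2, 5), background_conversion=0.005, seed=s + 10)
    igio.write_bisulfite_fasta(DATA / "bisulfite_reads.fasta", reads)
    (DATA / "bisulfite_truth.json").write_text(json.dumps(
        [{"read_id": p.read_id, "strand": p.strand, "positions": list(p.positions)}
         for p in planted], indent=1))
    print(f"bisulfite: {len(reads)} reads, {len(planted)} planted patches")

    gene = chip.GeneModel("GFP", "reporter", "+", 1000, 1700)
    igio.write_bed6(DATA / "reporter.bed", [gene])
    for name, body in (("wt", 110.0), ("bcl6_null", 5.0), ("bcl6_recon", 27.5)):
        track = synth.simulate_coverage(gene, 100.0, body, 0.2, 1.0, seed=s + 20 + int(body))
        igio.write_bedgraph(DATA / f"spt5_{name}.bedgraph", track)
    print("coverage: 3 Spt5-like tracks with planted indexes 1.1 / 0.05 / 0.275")

    # fluctuation assay: per-generation loss rates derived from target
    # 14-generation GFP-negative fractions (see docs/methods.md)
    targets = {"wt_no_divac": 0.0021, "wt_super_divac": 9 * 0.0021,
               "aid_oe_no_divac": 5 * 0.0021, "aid_oe_super_divac": 150 * 0.0021}
    rows = []
    for k, (label, frac) in enumerate(targets.items()):
        rate = 1 - (1 - frac) ** (1 / 14)
        for i, v in enumerate(synth.simulate_gfp_loss(10, rate, 14, 10_000, s + 30 + k)):
            rows.append({"label": label, "subclone": i + 1, "gfp_negative_percent": v})
    igio.write_tsv(DATA / "gfp_loss.tsv", rows, {"seed": s})
    print(f"gfp loss: {len(rows)} subclone measurements over {len(targets)} lines")


if __name__ == "__main__":
    main()
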