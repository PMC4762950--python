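"""Mutation-event frequencies and the event spectrum for both cell lines.

Aligns every clone FASTA from step 01 to the locus, applies clonal
correction, classifies events against the pseudo-V donors, and reports
per-line event frequencies, their fold difference, the two-proportion z-test
between lines, and the spectrum (pie-chart) table.

Run after 01:  python analysis/02_mutation_frequencies.py
"""

from pathlib import Path

from igdiv import calling, gcv, io as igio, stats as st, synth

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    locus_rec = igio.read_fasta(DATA / "locus.fasta")[0]
    locus = synth.ReferenceLocus(name=locus_rec[0], sequence=locus_rec[1])
    donors = synth.DonorSet(donors=tuple(
        (n, q) for n, q, _ in igio.read_fasta(DATA / "donors.fasta")))

    per_line = {}
    for name in ("wt", "bcl6_null"):
        recs = igio.read_clone_fasta(DATA / f"clones_{name}.fasta")
        cs = calling.call_clone_set(recs, locus)
        events = gcv.classify_events(cs, donors)
        freq, per1e4 = calling.event_frequency(len(events), cs.total_bp)
        per_line[name] = (len(events), cs.total_bp, float(freq))
        spectrum = gcv.summarize_spectrum(events)
        igio.write_tsv(OUT / f"spectrum_{name}.tsv", [
            {"category": cat, "count": n,
             "proportion": float(spectrum.proportions.get(cat, 0))}
            for cat, n in spectrum.counts.items()])
        print(f"{name}: {len(events)} events / {cs.total_bp} bp "
              f"= {per1e4:.2f} per 10^4 bp; spectrum {spectrum.counts}")

    (e1, n1, f1), (e2, n2, f2) = per_line["wt"], per_line["bcl6_null"]
    z = st.two_proportion_z(e1, n1, e2, n2)
    print(f"fold wt/bcl6_null = {f1 / f2:.2f}; z = {z.statistic:.2f}, "
          f"p = {z.p_value:.3g} {z.stars}")
    igio.write_tsv(OUT / "mutation_frequencies.tsv", [
        {"line": name, "events": e, "bp_sequenced": n, "freq_per_bp": f}
        for name, (e, n, f) in per_line.items()],
        {"fold_wt_over_null": f"{f1 / f2:.4f}", "z": f"{z.statistic:.4f}",
         "p": f"{z.p_value:.4g}", "stars": z.stars})


if __name__ == "__main__":
    main()
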