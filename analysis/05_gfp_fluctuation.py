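"""GFP-loss fluctuation summary for the simulated reporter lines.

Applies the >50% exclusion rule, reports per-line medians, fold
stimulations (DIVAC-containing over DIVAC-less, per AID level), and the
pairwise Mann-Whitney comparisons.

Run after 01:  python analysis/05_gfp_fluctuation.py
"""

from pathlib import Path

from igdiv import io as igio, stats as st

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    groups: dict[str, list[float]] = {}
    for ln in (DATA / "gfp_loss.tsv").read_text().splitlines():
        if ln.startswith(("#", "label")) or not ln.strip():
            continue
        label, _, value = ln.split("\t")
        groups.setdefault(label, []).append(float(value))
    samples = {k: st.FluctuationSample(k, v) for k, v in groups.items()}
    pairs = [("wt_super_divac", "wt_no_divac"),
             ("aid_oe_super_divac", "aid_oe_no_divac"),
             ("aid_oe_no_divac", "wt_no_divac")]
    summary = st.gfp_loss_summary(list(samples.values()), pairs=pairs)
    rows = []
    for label, med in summary["medians"].items():
        print(f"{label}: median {med:.3f}% GFP-negative "
              f"({summary['exclusions'][label]} excluded)")
        rows.append({"label": label, "median_percent": med,
                     "n_retained": len(samples[label].values),
                     "n_excluded": summary["exclusions"][label]})
    meta = {}
    for pair in pairs:
        fold = summary["fold_stimulation"][pair]
        mw = summary["mann_whitney"][pair]
        print(f"{pair[0]} / {pair[1]}: fold {fold:.2f}, "
              f"Mann-Whitney p = {mw.p_value:.4g} {mw.stars}")
        meta[f"fold_{pair[0]}_over_{pair[1]}"] = f"{fold:.4f}"
        meta[f"p_{pair[0]}_vs_{pair[1]}"] = f"{mw.p_value:.4g}"
    igio.write_tsv(OUT / "gfp_loss_summary.tsv", rows, meta)


if __name__ == "__main__":
    main()
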