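"""RPM normalization, windowed scores, elongation indexes, top-gene
intersections, percentile ranks, and metagene profiles against direct
summation oracles."""

import numpy as np
import pytest

from igdiv import chip, synth


def uniform_track(value=0.1, n=2000, start=0):
    return chip.CoverageTrack(contig="chr", start=start, signal=np.full(n, value))


class TestRpmNormalize:
    def test_zero_counts(self):
        t = chip.rpm_normalize(np.zeros(100), 1e6)
        assert not t.signal.any()

    def test_arithmetic(self):
        t = chip.rpm_normalize(np.array([2.0]), 2e6)
        assert t.signal[0] == pytest.approx(1.0)

    def test_conservation(self, rng):
        counts = rng.integers(0, 50, size=500).astype(float)
        t = chip.rpm_normalize(counts, 3.7e6)
        assert t.signal.sum() * 3.7e6 / 1e6 == pytest.approx(counts.sum())

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chip.rpm_normalize(np.ones(10), 0)


class TestWindowedScores:
    def test_uniform_full_windows(self):
        scores = chip.windowed_scores(uniform_track(0.1, 1000), 100, 100)
        assert all(s == pytest.approx(10.0) for _, _, s in scores[:-1])

    def test_nonoverlapping_tiling_conserves_total(self, rng):
        t = chip.CoverageTrack("chr", 0, rng.random(997))
        scores = chip.windowed_scores(t, 100, 100)
        assert sum(s for _, _, s in scores) == pytest.approx(t.signal.sum())
        assert scores[-1][1] - scores[-1][0] == 97  # true width of partial window

    def test_overlapping_windows_match_direct_sum(self, rng):
        t = chip.CoverageTrack("chr", 10, rng.random(500))
        for a, b, s in chip.windowed_scores(t, 100, 50):
            assert s == pytest.approx(t.signal[a - 10:b - 10].sum())

    def test_window_longer_than_track_warns(self):
        t = uniform_track(1.0, 50)
        with pytest.warns(UserWarning):
            scores = chip.windowed_scores(t, 100, 100)
        assert scores == [(0, 50, pytest.approx(50.0))]


class TestElongationIndex:
    def test_uniform_track_gives_exactly_one(self):
        t = uniform_track(0.37)
        ei = chip.elongation_index(t, (100, 300), (301, 901))
        assert ei.index == pytest.approx(1.0)

    def test_hand_computed_density_ratio(self):
        # proximal 200 bp holding 20 RPM (100 RPM/kb); body 600 bp holding
        # 30 RPM (50 RPM/kb) -> index 0.5
        sig = np.zeros(1200)
        sig[100:300] = 20 / 200
        sig[301:901] = 30 / 600
        t = chip.CoverageTrack("chr", 0, sig)
        ei = chip.elongation_index(t, (100, 300), (301, 901))
        assert ei.proximal_density == pytest.approx(100.0)
        assert ei.body_density == pytest.approx(50.0)
        assert ei.index == pytest.approx(0.5)

    def test_zero_proximal_flagged_undefined(self):
        sig = np.zeros(1000)
        sig[500:600] = 1.0
        t = chip.CoverageTrack("chr", 0, sig)
        ei = chip.elongation_index(t, (0, 100), (500, 600))
        assert ei.index is None and not ei.defined

    def test_scale_invariance(self, rng):
        sig = rng.random(1000) + 0.01
        a = chip.elongation_index(chip.CoverageTrack("chr", 0, sig), (0, 200), (300, 900))
        b = chip.elongation_index(chip.CoverageTrack("chr", 0, sig * 7.3), (0, 200), (300, 900))
        assert a.index == pytest.approx(b.index)

    def test_simulated_low_index_recovered(self):
        gene = chip.GeneModel("GFP", "reporter", "+", 1000, 1700)
        vals = []
        for rep in range(100):
            t = synth.simulate_coverage(gene, 100.0, 5.0, 0.2, 1.0, seed=600 + rep)
            vals.append(chip.gfp_elongation_index(t, gene).index)
        assert abs(np.mean(vals) - 0.05) <= 3 * np.std(vals, ddof=1) / np.sqrt(100)


class TestGeneElongationIndexes:
    def test_minus_strand_mirror_equals_plus_strand(self):
        sig = np.zeros(3000)
        sig[1000:1100] = 2.0  # promoter peak on + gene at tss=1050
        sig[1350:1950] = 0.5
        plus = chip.GeneModel("gP", "chr", "+", 1050, 2050)
        t_plus = chip.CoverageTrack("chr", 0, sig)
        minus = chip.GeneModel("gM", "chr", "-", 3000 - 1 - 1050, 3000 - 1 - 2050)
        t_minus = chip.CoverageTrack("chr", 0, sig[::-1].copy())
        (ei_p,), _ = chip.gene_elongation_indexes(t_plus, [plus])
        (ei_m,), _ = chip.gene_elongation_indexes(t_minus, [minus])
        assert ei_p.proximal_density == pytest.approx(ei_m.proximal_density)
        assert ei_p.index == pytest.approx(ei_m.index)

    def test_short_gene_skipped_and_logged(self):
        t = uniform_track(1.0, 1000)
        short = chip.GeneModel("tiny", "chr", "+", 400, 650)  # body would be empty
        indexes, skipped = chip.gene_elongation_indexes(t, [short])
        assert indexes == [] and skipped == ["tiny"]

    def test_planted_index_recovered_across_genes(self):
        rng = np.random.default_rng(61)
        indexes = []
        for k in range(20):
            gene = chip.GeneModel(f"g{k}", "reporter", "+", 1000, 1000 + int(rng.integers(2000, 6000)))
            # gene windows: proximal [-100,300) at 100 RPM/kb, body 30 RPM/kb
            t = synth.simulate_coverage(gene, 100.0, 30.0, 0.1, 100.0, seed=700 + k)
            # simulate_coverage's proximal block is TSS+/-100; fill [100,300) densely too
            a, b = gene.offset_interval(100, 300)
            t.signal[a - t.start:b - t.start] = 100.0 / 1000
            (ei,), _ = chip.gene_elongation_indexes(t, [gene])
            indexes.append(ei.index)
        assert abs(np.median(indexes) - 0.3) <= 3 * np.std(indexes, ddof=1)


class TestSelectTopOverlap:
    def test_identical_rankings_full_intersection(self):
        scores = {f"g{i}": float(i) for i in range(50)}
        out = chip.select_top_overlap([scores, dict(scores), dict(scores)], 10)
        assert len(out) == 10

    def test_disjoint_top_sets_empty(self):
        a = {"g1": 10.0, "g2": 1.0}
        b = {"g1": 1.0, "g2": 10.0}
        assert chip.select_top_overlap([a, b], 1) == []

    def test_matches_brute_force_sort_and_intersect(self, rng):
        genes = [f"g{i:03d}" for i in range(500)]
        for _ in range(100):
            samples = [dict(zip(genes, rng.random(500))) for _ in range(3)]
            got = chip.select_top_overlap(samples, 200)
            tops = [
                {g for g, _ in sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))[:200]}
                for s in samples
            ]
            assert got == sorted(tops[0] & tops[1] & tops[2])


class TestPercentileRank:
    def test_below_all_is_zero(self):
        assert chip.percentile_rank(-1.0, [1, 2, 3]) == 0.0

    def test_single_tie_is_midrank_fifty(self):
        assert chip.percentile_rank(5.0, [5.0]) == 50.0

    def test_matches_counting_oracle(self, rng):
        dist = rng.random(124)
        for v in [0.0, 0.5, 1.0, float(dist[3])]:
            below = sum(1 for d in dist if d < v)
            ties = sum(1 for d in dist if d == v)
            assert chip.percentile_rank(v, dist) == pytest.approx(
                100 * (below + 0.5 * ties) / 124)


class TestMetageneProfile:
    def test_uniform_track_all_ones(self):
        gene = chip.GeneModel("g", "chr", "+", 500, 1500)
        prof = chip.metagene_profile(uniform_track(0.2, 3000), [gene])
        assert np.allclose(prof.profile, 1.0)

    def test_tss_spike_dominates_one_bin(self):
        sig = np.full(3000, 1e-6)
        sig[500] = 5.0
        gene = chip.GeneModel("g", "chr", "+", 500, 1500)
        prof = chip.metagene_profile(chip.CoverageTrack("chr", 0, sig), [gene])
        spike_bin = np.argmax(prof.profile)
        # TSS sits 100 bp into the 1100 bp window: bin index 9 of 100
        assert spike_bin == 9
        assert prof.profile[spike_bin] == pytest.approx(1.0)
        assert np.sum(prof.profile > 0.5) == 1

    def test_per_gene_vectors_match_direct_binning_oracle(self, rng):
        sig = rng.random(6000)
        t = chip.CoverageTrack("chr", 0, sig)
        for strand, tss, tts in [("+", 700, 3200), ("-", 3200, 700)]:
            gene = chip.GeneModel("g", "chr", strand, tss, tts)
            v = chip.metagene_bins(t, gene, upstream_bp=100)
            total = 100 + gene.length
            edges = np.round(np.linspace(0, total, 101)).astype(int)
            if strand == "+":
                window = sig[tss - 100: tss - 100 + total]
            else:
                window = sig[tss + 100 - total + 1: tss + 101][::-1]
            expect = [window[edges[i]:edges[i + 1]].mean() for i in range(100)]
            assert np.allclose(v, expect)

    def test_max_is_exactly_one_before_averaging(self, rng):
        t = chip.CoverageTrack("chr", 0, rng.random(5000))
        genes = [chip.GeneModel(f"g{k}", "chr", "+", 300 + k * 400, 300 + k * 400 + 3000)
                 for k in range(4)]
        for g in genes:
            v = chip.metagene_bins(t, g)
            assert (v / v.max()).max() == 1.0
        prof = chip.metagene_profile(t, genes)
        assert prof.profile.max() <= 1.0 and prof.n_genes == 4

    def test_all_zero_gene_skipped(self):
        sig = np.zeros(4000)
        sig[200:1500] = 1.0
        live = chip.GeneModel("live", "chr", "+", 300, 1400)
        dead = chip.GeneModel("dead", "chr", "+", 2500, 3600)
        prof = chip.metagene_profile(chip.CoverageTrack("chr", 0, sig), [live, dead])
        assert prof.n_genes == 1 and prof.skipped == ["dead"]

    def test_too_short_gene_rejected(self):
        t = uniform_track(1.0, 1000)
        micro = chip.GeneModel("micro", "chr", "+", 500, 530)
        with pytest.raises(ValueError):
            chip.metagene_bins(t, micro, upstream_bp=0)

    def test_scale_invariance(self, rng):
        sig = rng.random(4000) + 0.01
        gene = chip.GeneModel("g", "chr", "+", 500, 3000)
        a = chip.metagene_profile(chip.CoverageTrack("chr", 0, sig), [gene])
        b = chip.metagene_profile(chip.CoverageTrack("chr", 0, sig * 11.0), [gene])
        assert np.allclose(a.profile, b.profile)
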