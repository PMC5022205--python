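import numpy as np
import pandas as pd
import pytest

from regcap.ase import (
    AseError,
    adjusted_ai_proportions,
    ai_class,
    ai_enrichment,
    ai_enrichment_trend,
    annotate_records,
    compute_fold_difference,
    correlate_promoter_dhs,
    count_dose_response,
    filter_transcripts,
    hic_promoter_links,
    pool_by_transcript,
    residual_variance_explained,
    stratify_homozygous,
    tss_distance_enrichment,
    variant_in_linked_regions,
    vicinity_variant_counts,
)
from regcap.intervals import BinGrid
from regcap.simulate import (
    AseEffectConfig,
    make_transcripts,
    simulate_ase,
    simulate_residual_ai,
)
from regcap.variants import TranscriptModel


class TestFoldDifference:
    @pytest.mark.parametrize("a,b,fold,cls", [
        (50, 50, 1.0, "equal"),
        (30, 10, 3.0, "ai"),
        (100, 10, 10.0, "excluded"),
        (15, 10, 1.5, "equal"),          # boundary: equal is <= 1.5
        (20, 10, 2.0, "ai"),             # boundary: AI band is [2, 9]
        (90, 10, 9.0, "ai"),
        (18, 10, 1.8, "intermediate"),
    ])
    def test_fold_and_class(self, a, b, fold, cls):
        f, c = compute_fold_difference(a, b)
        assert f == pytest.approx(fold) and c == cls

    def test_symmetric_and_at_least_one(self, rng):
        for _ in range(50):
            a, b = (int(x) for x in rng.integers(1, 500, 2))
            fa, _ = compute_fold_difference(a, b)
            fb, _ = compute_fold_difference(b, a)
            assert fa == fb >= 1.0

    def test_zero_handling(self):
        assert compute_fold_difference(0, 0) == (None, None)
        f, _ = compute_fold_difference(0, 9)      # pseudocount -> 10/1
        assert f == pytest.approx(10.0)
        assert compute_fold_difference(0, 9, zero_policy="drop") == (None, None)

    def test_partition_exhaustive(self, rng):
        folds = np.concatenate([rng.uniform(1, 12, 200), [1.5, 2.0, 9.0, 9.0001]])
        for f in folds:
            assert ai_class(float(f)) in {"equal", "intermediate", "ai", "excluded"}


class TestFilterTranscripts:
    TABLE = pd.DataFrame({
        "gene": ["g1", "g1", "g2", "g3", "g3", "g4"],
        "transcript": ["t1a", "t1b", "t2", "t3a", "t3b", "t4"],
        "assoc_p": [1e-7, 1e-7, 1e-6, 1e-5, 2e-6, 0.5],
        "total_count": [500, 200, 300, 900, 100, 800],
    })

    def test_best_covered_isoform_kept(self):
        out = filter_transcripts(self.TABLE)
        assert set(out["transcript"]) == {"t1a", "t2", "t3b"}

    def test_threshold_is_strict(self):
        # g3 isoform t3a has p exactly 1e-5 -> dropped; t3b kept instead
        out = filter_transcripts(self.TABLE)
        assert "t3a" not in set(out["transcript"])

    def test_hand_filtered_toy_table(self):
        out = filter_transcripts(self.TABLE, association_p_max=1e-6)
        assert set(out["transcript"]) == {"t1a"}


class TestVicinity:
    @pytest.fixture
    def gene(self):
        return TranscriptModel("t1", "g1", "chr1", "+", exons=[(50_000, 60_000)],
                               cds_start=50_000, cds_end=50_000)

    def _variants(self, positions, cls="rare"):
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(len(positions))],
            "chrom": "chr1", "pos": positions, "freq_class": cls,
        })

    def test_closed_boundary_at_window_edge(self, gene):
        # gene end (0-based last base) 59_999; +20 kb closed boundary 79_999
        v = self._variants([80_000, 80_001])  # 1-based: pos0 79_999 and 80_000
        out = vicinity_variant_counts([gene], v)
        assert out["n_rare"].iloc[0] == 1

    def test_empty_window_zero_vector(self, gene):
        out = vicinity_variant_counts([gene], self._variants([500_000]))
        assert out[["n_common", "n_rare", "n_novel"]].iloc[0].sum() == 0

    def test_matches_naive_scan(self, gene, rng):
        positions = rng.integers(1, 200_000, 50)
        classes = rng.choice(["common", "rare", "novel"], 50)
        v = pd.DataFrame({"variant_id": range(50), "chrom": "chr1",
                          "pos": positions, "freq_class": classes})
        out = vicinity_variant_counts([gene], v).iloc[0]
        for cls in ("common", "rare", "novel"):
            expected = sum(
                1 for p, c in zip(positions, classes)
                if c == cls and 30_000 <= p - 1 <= 79_999)
            assert out[f"n_{cls}"] == expected


class TestAdjustedProportions:
    def _table(self, folds, n_snps, n_rare):
        return pd.DataFrame({
            "transcript": [f"t{i}" for i in range(len(folds))],
            "fold": folds, "n_snps": n_snps, "n_rare": n_rare,
            "n_common": 1, "n_novel": 0, "n_rare_novel": n_rare,
        })

    def test_equal_snp_counts_mean_no_adjustment(self):
        tab = self._table([1.2, 1.8, 2.5, 3.2], [4, 4, 4, 4], [0, 1, 1, 0])
        out = adjusted_ai_proportions(tab, ai_levels=[1.5, 2.0], classes=["rare"])
        assert np.allclose(out["adjusted_proportion"], out["raw_proportion"])

    def test_hand_arithmetic_small_table(self):
        folds = [1.0, 1.6, 2.1, 2.6, 3.1, 9.5]     # last excluded
        n_snps = [2, 4, 6, 2, 6, 100]
        n_rare = [0, 1, 1, 0, 1, 1]
        tab = self._table(folds, n_snps, n_rare)
        out = adjusted_ai_proportions(tab, ai_levels=[2.0], classes=["rare"])
        # kept transcripts: folds <= 9 -> first five; grand mean snps = 4
        # level 2.0 subset: folds 2.1, 2.6, 3.1 -> mean snps 14/3, raw 2/3
        row = out.iloc[0]
        assert row["raw_proportion"] == pytest.approx(2 / 3)
        assert row["adjusted_proportion"] == pytest.approx((2 / 3) * 4 / (14 / 3))

    def test_planted_effects_make_rare_proportion_rise(self):
        wins = 0
        n_runs = 40
        for seed in range(n_runs):
            rec, _, truth = simulate_ase(
                AseEffectConfig(n_transcripts=150, n_affected=50,
                                log2_effect=1.5, carrier_fraction=1.0),
                overdispersion=0.1, n_individuals=8, seed=seed)
            per = pool_by_transcript(annotate_records(rec))
            affected = {e[0] for e in truth.planted_cis_effects}
            per["n_rare"] = per["transcript"].isin(affected).astype(int)
            out = adjusted_ai_proportions(per, ai_levels=[1.5, 2.0, 2.5],
                                          classes=["rare"])
            props = out["adjusted_proportion"].to_numpy()
            if np.all(np.diff(props) > 0):
                wins += 1
        assert wins >= 0.9 * n_runs


class TestPromoterCorrelation:
    def test_identical_signal_gives_r_one(self):
        grid = BinGrid({"chr1": 5_000}, bin_size=100)
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(1_000, 2_000)],
                            cds_start=1_000, cds_end=1_000)
        rng = np.random.default_rng(1)
        mat = rng.random((5, grid.n_bins))
        prom_bins = grid.overlapping_bins("chr1", 500, 1_501)
        mat[:, 40] = mat[:, prom_bins].mean(axis=1)  # bin 40 mirrors promoter
        links = correlate_promoter_dhs(mat, grid, [t])
        r40 = links[links["bin"] == 40]["r"].iloc[0]
        assert r40 == pytest.approx(1.0)

    def test_independent_bins_rarely_exceed_half(self):
        grid = BinGrid({"chr1": 3_000}, bin_size=100)
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(1_000, 1_500)],
                            cds_start=1_000, cds_end=1_000)
        hits = total = 0
        for seed in range(40):
            mat = np.random.default_rng(seed).random((20, grid.n_bins))
            links = correlate_promoter_dhs(mat, grid, [t])
            hits += int((links["r"].abs() >= 0.5).sum())
            total += len(links)
        assert hits / total < 0.05

    def test_toy_matrix_matches_closed_form_pearson(self):
        grid = BinGrid({"chr1": 300}, bin_size=100)
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(0, 100)],
                            cds_start=0, cds_end=0)
        # 4 datasets x 3 bins; promoter = bin 0 (TSS=0, halfwidth 50)
        mat = np.array([[1.0, 2.0, 1.0],
                        [2.0, 4.0, 1.0],
                        [3.0, 6.0, 2.0],
                        [4.0, 8.0, 2.0]])
        links = correlate_promoter_dhs(mat, grid, [t], promoter_halfwidth=49)
        by_bin = links.set_index("bin")["r"]
        assert by_bin[1] == pytest.approx(1.0)
        x, y = mat[:, 0], mat[:, 2]
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert by_bin[2] == pytest.approx(r_manual)

    def test_requires_three_datasets(self):
        grid = BinGrid({"chr1": 300}, bin_size=100)
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(0, 100)],
                            cds_start=0, cds_end=0)
        with pytest.raises(AseError):
            correlate_promoter_dhs(np.ones((2, grid.n_bins)), grid, [t])


class TestAiEnrichment:
    def test_identity_when_sets_coincide(self, rng):
        presence = rng.random(100) < 0.4
        is_ai = np.ones(100, dtype=bool)
        assert ai_enrichment(is_ai, presence) == pytest.approx(1.0)

    def test_toy_sets_match_hand_ratio(self):
        # 20 transcripts; 5 AI of which 4 have variants; 10 of 20 overall
        is_ai = np.array([True] * 5 + [False] * 15)
        presence = np.array([True] * 4 + [False] * 1
                            + [True] * 6 + [False] * 9)
        assert ai_enrichment(is_ai, presence) == pytest.approx((4 / 5) / (10 / 20))

    def test_trend_recovers_planted_rise(self):
        rng = np.random.default_rng(7)
        wins = 0
        n_runs = 40
        thresholds = [0.5, 0.6, 0.7, 0.8, 0.9]
        for _ in range(n_runs):
            n = 400
            is_ai = rng.random(n) < 0.3
            presence = {}
            for i, t in enumerate(thresholds):
                # presence rate rises with threshold for AI transcripts only
                p_ai, p_bg = 0.2 + 0.12 * i, 0.2
                presence[t] = np.where(is_ai, rng.random(n) < p_ai,
                                       rng.random(n) < p_bg)
            res = ai_enrichment_trend(is_ai, presence, n_permutations=99,
                                      seed=int(rng.integers(2**31)))
            if res.slope > 0 and res.permutation_p < 0.05:
                wins += 1
        assert wins >= 0.85 * n_runs


class TestHomStratification:
    GENO = pd.DataFrame({
        "transcript": ["t1", "t1", "t2", "t2"],
        "individual": ["i1", "i2", "i1", "i2"],
        "gt": ["0/0", "0/1", "1/1", "0/1"],
    })

    def test_hom_kept_het_dropped(self):
        rec = pd.DataFrame({
            "transcript": ["t1", "t1", "t2", "t2"],
            "individual": ["i1", "i2", "i1", "i2"],
            "fold": [2.0] * 4, "n_snps": [3] * 4,
        })
        out = stratify_homozygous(rec, self.GENO)
        assert set(zip(out["transcript"], out["individual"])) == \
            {("t1", "i1"), ("t2", "i1")}

    def test_all_het_empty_with_warning(self):
        geno = self.GENO.assign(gt="0/1")
        rec = pd.DataFrame({"transcript": ["t1"], "individual": ["i1"],
                            "fold": [2.0], "n_snps": [3]})
        with pytest.warns(UserWarning, match="empty"):
            out = stratify_homozygous(rec, geno)
        assert out.empty

    def test_unannotated_transcript_excluded(self):
        rec = pd.DataFrame({"transcript": ["t9"], "individual": ["i1"],
                            "fold": [2.0], "n_snps": [3]})
        assert stratify_homozygous(rec, self.GENO).empty


class TestDoseResponse:
    def test_toy_strata_match_hand_arithmetic(self):
        tab = pd.DataFrame({
            "transcript": list("abcdef"),
            "fold": [1.2, 2.5, 1.3, 2.1, 3.0, 1.1],
            "n_snps": [4.0] * 6,
            "n_rare_novel": [0, 0, 1, 1, 2, 2],
        })
        out = count_dose_response(tab).set_index("stratum")
        assert out.loc[0, "raw_ai_proportion"] == pytest.approx(0.5)
        assert out.loc[1, "raw_ai_proportion"] == pytest.approx(0.5)
        assert out.loc[2, "raw_ai_proportion"] == pytest.approx(0.5)

    def test_planted_additive_effects_give_rising_profile(self):
        from scipy.stats import spearmanr

        wins = 0
        n_runs = 30
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n = 600
            x = rng.poisson(1.2, n)
            mu = 0.4 + 0.45 * x
            fold = 2.0 ** np.abs(mu + rng.normal(0, 0.3, n))
            tab = pd.DataFrame({"transcript": range(n), "fold": fold,
                                "n_snps": 4.0, "n_rare_novel": x})
            out = count_dose_response(tab, max_count=3)
            rho = spearmanr(out["stratum"], out["adjusted_ai_proportion"]).statistic
            if rho > 0:
                wins += 1
        assert wins >= 0.9 * n_runs


class TestTssProfile:
    def _transcripts(self, n, chrom="chr1", spacing=500_000):
        return [TranscriptModel(f"t{i}", f"g{i}", chrom, "+",
                                exons=[(i * spacing + 1_000_000,
                                        i * spacing + 1_000_000 + 10_000)],
                                cds_start=0, cds_end=0)
                for i in range(n)]

    def test_single_window_fold_is_hand_ratio(self):
        ts = self._transcripts(2)
        ai, bg = [ts[0]], ts
        v = pd.DataFrame({"variant_id": [0, 1], "chrom": "chr1",
                          "pos": [1_000_001, 1_500_001], "freq_class": "rare"})
        out = tss_distance_enrichment(v, ai, bg, window=10_000, step=10_000,
                                      max_dist=0)
        # center 0 window +/-5 kb: AI transcript has 1 variant at TSS; the
        # other transcript also has its variant at its own TSS
        assert out.iloc[0]["fold"] == pytest.approx(1.0 / 1.0)

    def test_uniform_placement_gives_flat_profile(self):
        rng = np.random.default_rng(3)
        ts = self._transcripts(30)
        ai = ts[:10]
        pos = rng.integers(500_000, 16_000_000, 8_000)
        v = pd.DataFrame({"variant_id": range(len(pos)), "chrom": "chr1",
                          "pos": pos, "freq_class": "rare"})
        out = tss_distance_enrichment(v, ai, ts, max_dist=100_000)
        assert abs(out["fold"].mean() - 1.0) < 0.15

    def test_planted_near_tss_enrichment_peaks_centrally(self):
        rng = np.random.default_rng(4)
        ts = self._transcripts(40)
        ai, bg = ts[:20], ts
        rows = []
        for t in ai:     # plant variants within +/-50 kb of AI TSSs only
            for p in rng.integers(t.tss - 50_000, t.tss + 50_000, 10):
                rows.append(int(p) + 1)
        # uniform background so no sliding window has zero density
        rows.extend(int(p) for p in rng.integers(500_000, 22_000_000, 4_000))
        v = pd.DataFrame({"variant_id": range(len(rows)), "chrom": "chr1",
                          "pos": rows, "freq_class": "rare"})
        out = tss_distance_enrichment(v, ai, bg, max_dist=150_000)
        near = out[out["center"].abs() <= 50_000]["fold"].mean()
        far = out[out["center"].abs() >= 120_000]["fold"].mean()
        assert near > far


class TestResidualVariance:
    def test_perfect_fit_r2_one(self):
        df = pd.DataFrame({"fold": 2.0 ** (1 + 0.3 * np.arange(20)),
                           "n_rare_novel": np.arange(20)})
        assert residual_variance_explained(df) == pytest.approx(1.0)

    def test_independent_response_r2_near_zero(self):
        rng = np.random.default_rng(0)
        r2s = [residual_variance_explained(pd.DataFrame({
            "fold": 2.0 ** rng.uniform(0.5, 2, 2_000),
            "n_rare_novel": rng.poisson(2, 2_000)})) for _ in range(20)]
        assert float(np.mean(r2s)) < 0.01

    def test_planted_share_recovered(self):
        for target in (0.14, 0.3):
            r2s = [residual_variance_explained(
                simulate_residual_ai(5_000, target, seed=s))
                for s in range(10)]
            assert abs(float(np.mean(r2s)) - target) < 0.05

    def test_too_few_records_rejected(self):
        with pytest.raises(AseError):
            residual_variance_explained(pd.DataFrame({
                "fold": [2.0] * 5, "n_rare_novel": [1] * 5}))


class TestHicLinks:
    PAIRS = pd.DataFrame({
        "chrom1": ["chr1"], "start1": [9_000], "end1": [11_000],
        "chrom2": ["chr1"], "start2": [500_000], "end2": [510_000],
    })

    def test_promoter_anchor_maps_to_distal_region(self):
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(10_000, 20_000)],
                            cds_start=0, cds_end=0)
        links = hic_promoter_links(self.PAIRS, [t])
        assert len(links) == 1
        assert (links.iloc[0]["start"], links.iloc[0]["end"]) == (500_000, 510_000)

    def test_variant_presence_in_linked_region(self):
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(10_000, 20_000)],
                            cds_start=0, cds_end=0)
        links = hic_promoter_links(self.PAIRS, [t])
        v = pd.DataFrame({"variant_id": [0], "chrom": "chr1",
                          "pos": [505_001], "freq_class": "rare"})
        flags = variant_in_linked_regions(v, links, [t])
        assert bool(flags["t"])

    def test_non_overlapping_promoter_yields_no_link(self):
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(100_000, 110_000)],
                            cds_start=0, cds_end=0)
        assert hic_promoter_links(self.PAIRS, [t]).empty


class TestSimulateAseContracts:
    def test_negative_overdispersion_rejected(self):
        with pytest.raises(Exception, match="overdispersion"):
            simulate_ase(AseEffectConfig(), overdispersion=-0.1,
                         n_individuals=5, seed=1)

    def test_planted_twofold_effect_detected_by_enrichment(self):
        wins = 0
        n_runs = 30
        for seed in range(n_runs):
            rec, _, truth = simulate_ase(
                AseEffectConfig(n_transcripts=200, n_affected=60,
                                log2_effect=1.0, carrier_fraction=1.0),
                overdispersion=0.02, n_individuals=10, seed=seed)
            per = pool_by_transcript(annotate_records(rec))
            affected = {e[0] for e in truth.planted_cis_effects}
            presence = per["transcript"].isin(affected).to_numpy()
            is_ai = (per["ai_class"] == "ai").to_numpy()
            if is_ai.sum() and ai_enrichment(is_ai, presence) > 1:
                wins += 1
        assert wins >= 0.9 * n_runs
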