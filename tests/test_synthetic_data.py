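import numpy as np
import pandas as pd
import pytest

from ladscreen import differential_response as deresp
from ladscreen import synthetic_data as sd
from ladscreen import trip_analysis as ta
from ladscreen.screen_stats import build_counting_regions, count_sense_insertions


def _pools_equal(a, b) -> bool:
    return (
        np.array_equal(a.chrom, b.chrom)
        and np.array_equal(a.pos, b.pos)
        and np.array_equal(a.orientation, b.orientation)
    )


class TestDeterminism:
    def test_screen_identical_for_identical_seed(self):
        layout, models = sd.synthetic_gene_models(n_genes=50, seed=3)
        cfg = sd.ScreenSimConfig(mean_sense_per_gene=20, seed=11)
        h1, l1, t1 = sd.simulate_screen(cfg, models, layout)
        h2, l2, t2 = sd.simulate_screen(cfg, models, layout)
        assert _pools_equal(h1, h2) and _pools_equal(l1, l2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_track_and_counts_and_trip_identical_for_identical_seed(self):
        layout, _ = sd.synthetic_gene_models(n_genes=30, seed=3)
        lads = sd.synthetic_lads(layout, seed=5)
        cfg = sd.LadSimConfig(lads=lads, seed=5)
        t1, _ = sd.simulate_damid_track(cfg, layout)
        t2, _ = sd.simulate_damid_track(cfg, layout)
        assert t1 == t2
        labels = {f"g{i}": i % 3 == 0 for i in range(200)}
        dcfg = sd.DESimConfig(n_replicates=2, seed=5)
        c1, r1 = sd.simulate_de_counts(dcfg, labels)
        c2, r2 = sd.simulate_de_counts(dcfg, labels)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(r1, r2)
        tcfg = sd.TripSimConfig(n_barcodes=50, n_replicates=2, seed=5)
        b1, u1 = sd.simulate_trip(tcfg, lads, layout)
        b2, u2 = sd.simulate_trip(tcfg, lads, layout)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(u1, u2)

    def test_substreams_are_distinct(self):
        a = sd.rng_for(1, "screen").integers(0, 2**31)
        b = sd.rng_for(1, "damid").integers(0, 2**31)
        assert a != b


class TestScreenGenerator:
    def test_neutral_genome_splits_pools_evenly(self):
        layout, models = sd.synthetic_gene_models(n_genes=100, seed=0)
        cfg = sd.ScreenSimConfig(
            mean_sense_per_gene=500, duplicate_rate=0.0, seed=2
        )
        high, low, _ = sd.simulate_screen(cfg, models, layout)
        n = high.size + low.size
        frac = high.size / n
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_planted_odds_drive_pool_assignment(self):
        layout, models = sd.synthetic_gene_models(n_genes=20, seed=0)
        theta = {m.gene_id: 4.0 for m in models}
        cfg = sd.ScreenSimConfig(
            mean_sense_per_gene=500, intergenic_fraction=0.0,
            antisense_fraction=0.0, duplicate_rate=0.0, theta=theta, seed=4,
        )
        high, low, _ = sd.simulate_screen(cfg, models, layout)
        regions = build_counting_regions(models)
        _, t_high = count_sense_insertions(high, regions)
        _, t_low = count_sense_insertions(low, regions)
        # theta = 4 sends each disruptive insertion HIGH with odds 4:1;
        # 0.01 covers 3-sigma sampling noise plus the small asymmetric loss
        # of duplicate positions to within-pool dedup
        frac = t_high / (t_high + t_low)
        assert abs(frac - 0.8) < 0.01

    def test_duplicate_rate_shrinks_unique_pools(self):
        layout, models = sd.synthetic_gene_models(n_genes=100, seed=0)
        expected = sd.ScreenSimConfig(mean_sense_per_gene=100).resolved_expectation(100)
        no_dup = sd.ScreenSimConfig(mean_sense_per_gene=100, duplicate_rate=0.0, seed=6)
        dup = sd.ScreenSimConfig(mean_sense_per_gene=100, duplicate_rate=0.1, seed=6)
        h0, l0, _ = sd.simulate_screen(no_dup, models, layout)
        h1, l1, _ = sd.simulate_screen(dup, models, layout)
        # with ~10^4 insertions per pool a 10% duplication rate is detected
        # with near-certainty (binomial tail < 1e-100)
        assert h1.size + l1.size < 0.95 * (h0.size + l0.size)
        assert h0.size + l0.size > 1.9 * expected * 0.93

    def test_intergenic_space_is_the_exact_gene_complement(self):
        layout, models = sd.synthetic_gene_models(n_genes=40, seed=0)
        chroms, starts, cum = sd._intergenic_space(layout, models)
        lengths = np.diff(np.concatenate([[0], cum]))
        gene_bp = sum(m.length for m in models)
        assert int(cum[-1]) == layout.total_bp - gene_bp
        for chrom, start, length in zip(chroms, starts, lengths):
            for m in models:
                if m.chrom == chrom:
                    assert start + length <= m.region_start or start >= m.region_end


class TestDamidGenerator:
    def test_noiseless_track_is_two_level_step(self, tiny_layout):
        lads = {"chr1": [(20_000, 60_000)], "chr2": []}
        cfg = sd.LadSimConfig(lads=lads, bin_size=10_000, sigma=0.0, seed=0)
        track, _ = sd.simulate_damid_track(cfg, tiny_layout)
        values = {(c, s): v for c, s, _e, v in track.bins()}
        assert values[("chr1", 20_000)] == 1.0 and values[("chr1", 50_000)] == 1.0
        assert values[("chr1", 0)] == -1.0 and values[("chr1", 90_000)] == -1.0
        assert all(v == -1.0 for (c, _), v in values.items() if c == "chr2")

    def test_no_lads_means_all_background(self, tiny_layout):
        cfg = sd.LadSimConfig(lads={}, bin_size=10_000, sigma=0.0, seed=0)
        track, _ = sd.simulate_damid_track(cfg, tiny_layout)
        assert {v for *_, v in track.bins()} == {-1.0}

    def test_in_lad_bin_mean_approaches_mu_in(self, tiny_layout):
        lads = {"chr1": [(0, 100_000)]}
        cfg = sd.LadSimConfig(lads=lads, bin_size=1_000, sigma=0.5, seed=1)
        track, _ = sd.simulate_damid_track(cfg, tiny_layout)
        vals = np.array([v for c, *_, v in track.bins() if c == "chr1"])
        assert abs(vals.mean() - 1.0) < 3 * 0.5 / np.sqrt(len(vals))

    def test_lad_outside_chromosome_is_config_error(self, tiny_layout):
        cfg = sd.LadSimConfig(lads={"chr1": [(50_000, 200_000)]}, seed=0)
        with pytest.raises(ValueError, match="outside"):
            sd.simulate_damid_track(cfg, tiny_layout)


class TestDEGenerator:
    def test_zero_fractions_plant_no_responders(self):
        labels = {f"g{i}": i < 30 for i in range(120)}
        cfg = sd.DESimConfig(
            n_replicates=2, frac_up_lad=0, frac_down_lad=0,
            frac_up_ilad=0, frac_down_ilad=0, seed=0,
        )
        _, truth = sd.simulate_de_counts(cfg, labels)
        assert (truth["label"] == "ns").all() and (truth["lfc"] == 0).all()

    def test_low_dispersion_counts_track_expected_means(self):
        labels = {f"g{i}": False for i in range(300)}
        cfg = sd.DESimConfig(n_replicates=6, dispersion=0.0, seed=1,
                             frac_up_ilad=0, frac_down_ilad=0)
        counts, truth = sd.simulate_de_counts(cfg, labels)
        mean_expected = cfg.depth * truth["tpm"].to_numpy() / 1e6
        ctrl = counts[[c for c in counts.columns if c.startswith("ctrl_")]].mean(axis=1)
        big = mean_expected > 500
        sigma = np.sqrt(mean_expected[big] / cfg.n_replicates)
        z = (ctrl.to_numpy()[big] - mean_expected[big]) / sigma
        assert np.all(np.abs(z) < 5)

    def test_planted_twofold_gene_is_detected_by_caller(self):
        # scaled-down power check: a 4x effect at low dispersion is caught
        # by the simple caller in virtually every trial
        detected = 0
        n_trials = 20
        for seed in range(n_trials):
            labels = {f"g{i}": False for i in range(400)}
            cfg = sd.DESimConfig(
                n_replicates=6, dispersion=0.01, frac_up_ilad=0.0,
                frac_down_ilad=0.0, lfc_mean=2.0, lfc_sd=0.0, seed=seed,
            )
            rng = sd.rng_for(seed, "de")
            counts, truth = sd.simulate_de_counts(cfg, labels, rng=rng)
            gene = truth.loc[truth["tpm"].idxmax(), "gene_id"]
            counts.loc[gene, [c for c in counts.columns if c.startswith("treat_")]] = (
                sd._nb_counts(
                    rng,
                    np.full(cfg.n_replicates, 4 * cfg.depth * truth["tpm"].max() / 1e6),
                    cfg.dispersion,
                )
            )
            de = deresp.simple_de_caller(
                counts, [f"ctrl_{i+1}" for i in range(6)], [f"treat_{i+1}" for i in range(6)]
            )
            row = de[de["gene_id"] == gene].iloc[0]
            detected += int(row["padj"] < 0.05 and row["log2fc"] > 0)
        assert detected >= int(0.95 * n_trials)


class TestTripGenerator:
    def test_configured_low_gdna_barcodes_are_exactly_the_filtered_ones(self, tiny_layout):
        lads = {"chr1": [(0, 50_000)], "chr2": []}
        cfg = sd.TripSimConfig(n_barcodes=200, low_gdna_fraction=0.1, seed=2)
        table, truth = sd.simulate_trip(cfg, lads, tiny_layout)
        kept = ta.filter_barcodes(table, min_gdna=100)
        removed = set(table["barcode"]) - set(kept["barcode"])
        assert removed == set(truth.loc[truth["low_gdna"], "barcode"])

    def test_planted_delta_recovered_in_group_means(self, tiny_layout):
        lads = {"chr1": [(0, 100_000)], "chr2": []}  # chr1 fully LAD
        cfg = sd.TripSimConfig(n_barcodes=600, delta=0.5, low_gdna_fraction=0.0, seed=3)
        table, truth = sd.simulate_trip(cfg, lads, tiny_layout)
        lfc = ta.barcode_lfc(table, ["kd_r1", "kd_r2", "kd_r3"], ["ctrl_r1", "ctrl_r2", "ctrl_r3"])
        contrast = ta.lad_contrast(lfc["log2fc"], truth["is_lad"])
        se = cfg.expr_sigma * np.sqrt(2 / 3) * np.sqrt(1 / contrast.n_lad + 1 / contrast.n_ilad)
        assert abs(contrast.mean_difference - 0.5) < 4 * se

    def test_null_delta_gives_no_systematic_contrast(self, tiny_layout):
        lads = {"chr1": [(0, 100_000)], "chr2": []}
        hits = 0
        for seed in range(10):
            cfg = sd.TripSimConfig(n_barcodes=300, delta=0.0, low_gdna_fraction=0.0, seed=seed)
            table, truth = sd.simulate_trip(cfg, lads, tiny_layout)
            lfc = ta.barcode_lfc(
                table, ["kd_r1", "kd_r2", "kd_r3"], ["ctrl_r1", "ctrl_r2", "ctrl_r3"]
            )
            p = ta.lad_contrast(lfc["log2fc"], truth["is_lad"]).ranksum_p
            hits += int(p < 0.05)
        assert hits <= 3
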