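"""Generator contracts: determinism, effect structure, count laws, traits,
and the two-population haplotype panel."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from medito.popgen import fst
from medito.simulate import (
    PopGenSimConfig,
    ShiftSpec,
    SimulationConfig,
    TraitEffect,
    resolve_trait_effects,
    simulate_counts,
    simulate_de_table,
    simulate_editing_truth,
    simulate_haplotype_panel,
    simulate_popgen_dataset,
    simulate_site_panel,
    simulate_traits,
)


class TestSitePanel:
    def test_study_scale_panel_shape(self):
        cfg = SimulationConfig(seed=3)
        panel = simulate_site_panel(cfg)
        assert panel.n_sites == 426
        assert len(panel.genes) == 31
        assert set(panel.sites["ref_base"]) <= {"C", "G"}

    def test_positions_strictly_increasing_within_gene(self, small_dataset):
        for _, grp in small_dataset["panel"].sites.groupby("gene_id"):
            assert grp["gene_position"].is_monotonic_increasing
            assert grp["gene_position"].is_unique

    def test_single_site_panel_has_valid_codon_frame(self):
        cfg = SimulationConfig(n_genes=1, sites_per_gene=1, seed=0)
        panel = simulate_site_panel(cfg)
        assert panel.n_sites == 1
        assert int(panel.sites["codon_position"].iloc[0]) in (1, 2, 3)

    def test_ref_base_matches_reference_sequence(self, small_dataset):
        panel = small_dataset["panel"]
        for _, s in panel.sites.iterrows():
            assert panel.sequences[s["gene_id"]][s["gene_position"] - 1] == s["ref_base"]

    def test_same_seed_same_panel(self):
        cfg = SimulationConfig(n_genes=4, sites_per_gene=3, seed=9)
        a = simulate_site_panel(cfg)
        b = simulate_site_panel(cfg)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert a.sequences == b.sequences

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(sites_per_gene=0)


class TestEditingTruth:
    def test_zero_drought_shift_makes_conditions_identical(self):
        cfg = SimulationConfig(n_genes=3, sites_per_gene=4, drought_shift=0.0,
                               ecotype_shift=0.0, seed=1)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        np.testing.assert_array_equal(truth.values[:, :, 0], truth.values[:, :, 1])

    def test_logit_shift_moves_efficiency_as_logistic(self):
        # a site at CK 0.5 shifted by +1.0 must land at expit(1.0) ~ 0.731
        cfg = SimulationConfig(n_genes=2, sites_per_gene=3, drought_shift=1.0,
                               ecotype_shift=0.0, genotype_sd=0.0, gene_factor_sd=0.0,
                               global_factor_sd=0.0, seed=5)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        ck = truth.values[0, :, 0]
        dt = truth.values[0, :, 1]
        from scipy.special import logit
        np.testing.assert_allclose(dt, expit(logit(ck) + 1.0), atol=1e-12)
        assert expit(1.0) == pytest.approx(0.7310585786)

    def test_planted_always_edited_site_is_exactly_one(self):
        cfg = SimulationConfig(n_genes=2, sites_per_gene=3, always_edited_sites=(0,),
                               never_edited_sites=(5,), seed=2)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        assert (truth.values[:, 0, :] == 1.0).all()
        assert (truth.values[:, 5, :] == 0.0).all()

    def test_ecotype_shift_only_moves_upland(self):
        cfg = SimulationConfig(n_upland=5, n_lowland=5, n_genes=2, sites_per_gene=2,
                               drought_shift=0.0, ecotype_shift=2.0, genotype_sd=0.0,
                               gene_factor_sd=0.0, global_factor_sd=0.0, seed=7)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        upland = truth.values[truth.ecotypes == "upland", :, 0]
        lowland = truth.values[truth.ecotypes == "lowland", :, 0]
        assert (upland > lowland).all()


class TestCounts:
    def test_conservation_and_determinism(self, small_dataset):
        counts = small_dataset["counts"]
        assert (counts["ref_count"] >= 0).all() and (counts["alt_count"] >= 0).all()
        c2, _ = simulate_counts(small_dataset["truth"], small_dataset["config"])
        pd.testing.assert_frame_equal(counts, c2)

    def test_full_editing_zero_error_gives_all_alt(self):
        cfg = SimulationConfig(n_upland=3, n_lowland=2, n_genes=1, sites_per_gene=2,
                               always_edited_sites=(0, 1), sequencing_error_rate=0.0,
                               missing_rate=0.0, seed=4)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        counts, _ = simulate_counts(truth, cfg)
        assert (counts["ref_count"] == 0).all()
        assert (counts["alt_count"] > 0).all()

    def test_binomial_mean_recovers_half(self):
        # p = 0.5 at depth 500: mean estimate over ~1000 draws within ±0.01
        cfg = SimulationConfig(n_upland=250, n_lowland=250, n_genes=1, sites_per_gene=1,
                               genotype_sd=0.0, gene_factor_sd=0.0, global_factor_sd=0.0,
                               drought_shift=0.0, ecotype_shift=0.0, missing_rate=0.0,
                               sequencing_error_rate=0.0, mean_depth=500.0, seed=8)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        truth.values[:] = 0.5
        counts, _ = simulate_counts(truth, cfg)
        est = counts["alt_count"] / (counts["ref_count"] + counts["alt_count"])
        assert est.mean() == pytest.approx(0.5, abs=0.01)

    def test_missing_fraction_matches_rate(self):
        cfg = SimulationConfig(missing_rate=0.10, seed=6)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        counts, _ = simulate_counts(truth, cfg)
        frac = ((counts["ref_count"] + counts["alt_count"]) == 0).mean()
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_high_depth_recovers_truth(self):
        # recovery contract: depth 1e4 gives abs error < 0.02 at every site
        cfg = SimulationConfig(n_upland=10, n_lowland=10, n_genes=2, sites_per_gene=5,
                               mean_depth=1e4, depth_dispersion=1e6, missing_rate=0.0,
                               sequencing_error_rate=0.0, seed=11)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        counts, _ = simulate_counts(truth, cfg)
        est = (counts["alt_count"] / (counts["ref_count"] + counts["alt_count"])).to_numpy()
        true_flat = np.concatenate([truth.values[:, :, 0].ravel(), truth.values[:, :, 1].ravel()])
        assert np.abs(est - true_flat).max() < 0.02


class TestTraits:
    def test_planted_pcc_recovered(self):
        cfg = SimulationConfig(trait_effects=(TraitEffect("RWC", -0.5, 1, "DT"),), seed=13)
        truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
        traits = simulate_traits(truth, cfg)
        eff = resolve_trait_effects(cfg, truth.site_ids)[0]
        j = truth.site_ids.index(eff["driver_sites"][0])
        dt = traits[traits["condition"] == "DT"].set_index("genotype")
        r = np.corrcoef(truth.values[:, j, 1], dt.loc[truth.genotypes, "RWC"])[0, 1]
        assert r == pytest.approx(-0.5, abs=0.15)

    def test_null_trait_uncorrelated(self):
        # no planted effect: |r| < 0.2 in >= 95% of seeds (checked over 20)
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_upland=64, n_lowland=60, n_genes=1, sites_per_gene=1,
                                   trait_effects=(), seed=seed)
            truth = simulate_editing_truth(simulate_site_panel(cfg), cfg)
            traits = simulate_traits(truth, cfg)
            dt = traits[traits["condition"] == "DT"].set_index("genotype")
            r = np.corrcoef(truth.values[:, 0, 1], dt.loc[truth.genotypes, "GY"])[0, 1]
            hits += abs(r) < 0.2
        assert hits >= 19

    def test_rwc_stays_in_unit_interval(self, small_dataset):
        traits = simulate_traits(small_dataset["truth"], small_dataset["config"])
        assert traits["RWC"].between(0, 1).all()

    def test_target_pcc_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TraitEffect("RWC", -1.0)


class TestHaplotypePanel:
    def test_zero_divergence_gives_near_zero_fst(self):
        panel = simulate_haplotype_panel(60, 60, 2000, 0.0, seed=1)
        assert abs(fst(panel, "sim", "upland", "lowland")) < 0.02

    def test_full_divergence_gives_fst_one(self):
        panel = simulate_haplotype_panel(30, 30, 200, 1.0, seed=2)
        assert fst(panel, "sim", "upland", "lowland") == pytest.approx(1.0)

    def test_intermediate_divergence_matches_frequency_oracle(self):
        # brute-force Hudson from realized per-SNP allele counts
        panel = simulate_haplotype_panel(50, 50, 10_000, 0.4, seed=3)
        g = panel.genotypes
        a, b = g[:50], g[50:]
        p1, p2 = a.mean(0), b.mean(0)
        n1 = n2 = 50
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        oracle = num.sum() / den.sum()
        assert fst(panel, "sim", "upland", "lowland") == pytest.approx(oracle, abs=0.05)

    def test_counts_below_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_haplotype_panel(1, 5, 10, 0.1, seed=0)


class TestPopgenDataset:
    def test_focal_genes_more_differentiated_than_background(self):
        cfg = PopGenSimConfig(n_background_genes=40, seed=5)
        panel = simulate_popgen_dataset(cfg)
        assert panel.genotypes.shape[0] == 64 + 60 + 45
        f035 = fst(panel, "PPR035", "upland", "lowland")
        bg = [fst(panel, f"gene{i:04d}", "upland", "lowland") for i in range(1, 21)]
        assert f035 > np.percentile(bg, 95)


class TestDETable:
    def test_planted_core_deg_counts(self):
        from medito.degrules import classify_core_degs

        table, mapping = simulate_de_table(n_genes=800, n_type1=20, n_type2=10,
                                           n_single=50, seed=3)
        calls = classify_core_degs(table, mapping)
        assert (calls["call"] == "TypeI").sum() == 20
        assert (calls["call"] == "TypeII").sum() == 10
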