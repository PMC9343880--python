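"""Informative filter, drought/ecotype tests, pattern calls, consequences."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from medito.classify import (
    annotate_consequence,
    classify_drought_response,
    classify_pattern,
    ecotype_differentiation,
    gene_pattern_summary,
    informative_filter,
)
from medito.core import InsufficientDataError, SitePanel
from medito.simulate import (
    ShiftSpec,
    SimulationConfig,
    simulate_counts,
    simulate_editing_truth,
    simulate_site_panel,
)
from medito.quantify import editing_efficiency

from conftest import make_matrix


def two_site_panel(ref_bases=("C", "C")):
    df = pd.DataFrame(
        {
            "site_id": ["s0", "s1"],
            "gene_id": ["g", "g"],
            "gene_position": [1, 4],
            "ref_base": list(ref_bases),
            "codon_index": [1, 2],
            "codon_position": [1, 1],
            "display_name": ["g-1", "g-4"],
        }
    )
    return SitePanel(df)


class TestInformativeFilter:
    def _panel_for(self, n_sites):
        df = pd.DataFrame(
            {
                "site_id": [f"s{j}" for j in range(n_sites)],
                "gene_id": "g",
                "gene_position": np.arange(1, n_sites + 1),
                "ref_base": "C",
                "codon_index": 1,
                "codon_position": 1,
                "display_name": [f"g-{j+1}" for j in range(n_sites)],
            }
        )
        return SitePanel(df)

    def test_invariant_fraction_boundary(self):
        # 120/124 genotypes exactly 1.0 (96.8% >= 95%) -> excluded
        vals = np.full((124, 1), 1.0)
        vals[:4, 0] = 0.5
        ck = make_matrix(vals, sites=["s0"])
        dt = make_matrix(vals, sites=["s0"], condition="DT")
        rep = informative_filter(ck, dt, self._panel_for(1))
        assert not rep["informative"].iloc[0]
        assert rep["reasons"].iloc[0] == "invariant-fraction"

    def test_missingness_boundary(self):
        # 13 of 124 genotypes missing in both conditions (10.5%) -> excluded
        vals = np.linspace(0.1, 0.9, 124).reshape(-1, 1)
        vals[:13] = np.nan
        ck = make_matrix(vals, sites=["s0"])
        dt = make_matrix(vals, sites=["s0"], condition="DT")
        rep = informative_filter(ck, dt, self._panel_for(1))
        assert not rep["informative"].iloc[0]
        assert rep["reasons"].iloc[0] == "missingness"

    def test_clean_site_retained(self):
        vals = np.linspace(0.05, 0.95, 124).reshape(-1, 1)
        vals[:2] = np.nan  # 1.6% missing
        ck = make_matrix(vals, sites=["s0"])
        dt = make_matrix(vals, sites=["s0"], condition="DT")
        rep = informative_filter(ck, dt, self._panel_for(1))
        assert rep["informative"].iloc[0]

    def test_non_canonical_site_rejected(self):
        vals = np.linspace(0.1, 0.9, 30).reshape(-1, 1)
        ck = make_matrix(vals, sites=["s0"])
        dt = make_matrix(vals, sites=["s0"], condition="DT")
        panel = self._panel_for(1)
        with pytest.warns(UserWarning):
            bad = SitePanel(panel.sites.assign(ref_base=["A"]))
        rep = informative_filter(ck, dt, bad)
        assert rep["reasons"].iloc[0] == "non-canonical"

    def test_relaxing_thresholds_never_shrinks_the_set(self, small_dataset):
        m = small_dataset["matrices"]
        panel = small_dataset["panel"]
        strict = informative_filter(m["CK"], m["DT"], panel, 0.5, 0.01)
        loose = informative_filter(m["CK"], m["DT"], panel, 0.95, 0.10)
        assert set(strict.loc[strict["informative"], "site_id"]) <= set(
            loose.loc[loose["informative"], "site_id"]
        )


class TestDroughtResponse:
    def test_identical_conditions_give_na(self):
        vals = np.linspace(0.2, 0.8, 20).reshape(-1, 1)
        ck = make_matrix(vals, sites=["s0"])
        dt = make_matrix(vals, sites=["s0"], condition="DT")
        out = classify_drought_response(ck, dt)
        assert np.isnan(out["drought_p"].iloc[0])
        assert not out["drought_responsive"].iloc[0]

    def test_constant_increase_is_flagged(self):
        rng = np.random.default_rng(0)
        ck_vals = np.linspace(0.2, 0.6, 124).reshape(-1, 1)
        dt_vals = ck_vals + 0.1 + rng.normal(0, 1e-3, (124, 1))
        out = classify_drought_response(
            make_matrix(ck_vals, sites=["s0"]), make_matrix(dt_vals, sites=["s0"], condition="DT")
        )
        assert out["drought_responsive"].iloc[0]
        assert out["drought_direction"].iloc[0] == "increase"

    def test_too_few_pairs_gives_na(self):
        vals = np.array([[0.2], [0.4], [0.6]])
        out = classify_drought_response(
            make_matrix(vals, sites=["s0"]), make_matrix(vals + 0.2, sites=["s0"], condition="DT")
        )
        assert np.isnan(out["drought_p"].iloc[0])

    def test_no_overlapping_genotypes_is_an_error(self):
        ck = make_matrix(np.array([[0.5]]), genotypes=["a"], sites=["s0"])
        dt = make_matrix(np.array([[0.5]]), genotypes=["b"], sites=["s0"], condition="DT")
        with pytest.raises(InsufficientDataError):
            classify_drought_response(ck, dt)

    def test_planted_shift_detected_with_high_power(self):
        cfg = SimulationConfig(drought_shift=ShiftSpec(50, 0.5), ecotype_shift=0.0,
                               mean_depth=500.0, seed=17)
        panel = simulate_site_panel(cfg)
        truth = simulate_editing_truth(panel, cfg)
        counts, meta = simulate_counts(truth, cfg)
        m = editing_efficiency(counts, meta)
        out = classify_drought_response(m["CK"], m["DT"]).set_index("site_id")
        shifted = np.array(truth.site_ids)[truth.drought_shift > 0]
        null = np.array(truth.site_ids)[truth.drought_shift == 0]
        hit = out.loc[shifted]
        power = (hit["drought_responsive"] & (hit["drought_direction"] == "increase")).mean()
        assert power >= 0.90
        assert out.loc[null, "drought_responsive"].mean() <= 0.07


class TestPatternCalls:
    @pytest.mark.parametrize(
        "ew,ed,expected",
        [
            (0.5, 0.65, "upregulated"),     # ratio 0.30
            (0.5, 0.40, "unchanged"),       # ratio exactly -0.2: boundary
            (0.5, 0.60, "unchanged"),       # ratio exactly +0.2: boundary
            (0.0, 0.0, "unchanged"),        # degenerate rule
            (0.0, 0.10, "upregulated"),     # E_w = 0 with E_d >= 0.05
            (0.0, 0.01, "unchanged"),       # E_w = 0 with tiny E_d
            (0.5, 0.30, "downregulated"),   # ratio -0.4
        ],
    )
    def test_category_rules(self, ew, ed, expected):
        ck = make_matrix(np.array([[ew]]), sites=["s0"])
        dt = make_matrix(np.array([[ed]]), sites=["s0"], condition="DT")
        out = classify_pattern(ck, dt)
        assert out["category"].iloc[0] == expected

    def test_missing_value_gives_undefined(self):
        ck = make_matrix(np.array([[np.nan]]), sites=["s0"])
        dt = make_matrix(np.array([[0.5]]), sites=["s0"], condition="DT")
        out = classify_pattern(ck, dt)
        assert out["category"].iloc[0] == "undefined"
        assert np.isnan(out["alteration_ratio"].iloc[0])

    def test_categories_partition_defined_combinations(self, small_dataset):
        m = small_dataset["matrices"]
        out = classify_pattern(m["CK"], m["DT"])
        defined = out[out["category"] != "undefined"]
        n = defined["category"].isin(["upregulated", "downregulated", "unchanged"]).sum()
        assert n == len(defined)
        assert len(out) == len(m["CK"].genotypes) * len(m["CK"].site_ids)


class TestGenePatternSummary:
    def test_proportions_from_known_calls(self):
        calls = pd.DataFrame(
            {
                "genotype": ["a", "b", "c", "d"],
                "site_id": ["s0", "s0", "s1", "s1"],
                "alteration_ratio": [0.5, 0.6, 0.0, -0.5],
                "category": ["upregulated", "upregulated", "unchanged", "downregulated"],
            }
        )
        out = gene_pattern_summary(calls, two_site_panel()).set_index("gene_id")
        assert out.loc["g", "upregulated"] == 0.5
        assert out.loc["g", "downregulated"] == 0.25
        assert out.loc["g", "unchanged"] == 0.25

    def test_all_na_gene_warns_and_reports_na(self):
        calls = pd.DataFrame(
            {
                "genotype": ["a"],
                "site_id": ["s0"],
                "alteration_ratio": [np.nan],
                "category": ["undefined"],
            }
        )
        with pytest.warns(UserWarning):
            out = gene_pattern_summary(calls, two_site_panel()).set_index("gene_id")
        assert np.isnan(out.loc["g", "upregulated"])

    def test_proportions_sum_to_one(self, small_dataset):
        m = small_dataset["matrices"]
        calls = classify_pattern(m["CK"], m["DT"])
        out = gene_pattern_summary(calls, small_dataset["panel"])
        sums = out[["upregulated", "downregulated", "unchanged"]].sum(axis=1)
        assert np.allclose(sums[out["n_combinations"] > 0], 1.0)


class TestEcotypeDifferentiation:
    def test_shifted_means_are_detected(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0.4, 0.1, 64), rng.normal(0.6, 0.1, 60)])
        m = make_matrix(np.clip(vals, 0, 1).reshape(-1, 1), sites=["s0"])
        eco = pd.Series(["upland"] * 64 + ["lowland"] * 60, index=m.genotypes)
        out = ecotype_differentiation(m, eco)
        assert out["ecotype_differentiated"].iloc[0]

    def test_equal_means_type_i_error_controlled(self):
        # 20 null datasets: flag rate should be near alpha, not above 3x
        flags = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.clip(rng.normal(0.5, 0.1, 124), 0, 1).reshape(-1, 1)
            m = make_matrix(vals, sites=["s0"])
            eco = pd.Series(["upland"] * 64 + ["lowland"] * 60, index=m.genotypes)
            flags += int(ecotype_differentiation(m, eco)["ecotype_differentiated"].iloc[0])
        assert flags <= 4

    def test_one_group_absent_is_an_error(self):
        m = make_matrix(np.array([[0.5], [0.6]]), sites=["s0"])
        eco = pd.Series(["upland", "upland"], index=m.genotypes)
        with pytest.raises(InsufficientDataError):
            ecotype_differentiation(m, eco)

    def test_all_missing_group_gives_na(self):
        vals = np.full((30, 1), 0.5)
        vals[:15] = np.nan
        m = make_matrix(vals, sites=["s0"])
        eco = pd.Series(["upland"] * 15 + ["lowland"] * 15, index=m.genotypes)
        out = ecotype_differentiation(m, eco)
        assert np.isnan(out["ecotype_p"].iloc[0])


class TestConsequence:
    def _panel(self, seq, pos, ref, gene="rps4"):
        df = pd.DataFrame(
            {
                "site_id": ["s0"],
                "gene_id": [gene],
                "gene_position": [pos],
                "ref_base": [ref],
                "codon_index": [(pos + 2) // 3],
                "codon_position": [(pos - 1) % 3 + 1],
                "display_name": [f"{gene}-{pos}"],
            }
        )
        return SitePanel(df, sequences={gene: seq})

    def test_ser_to_leu_nonsynonymous(self):
        # TCA -> TTA at codon position 2: Ser -> Leu
        out = annotate_consequence(self._panel("TCA", 2, "C"))
        assert out["consequence"].iloc[0] == "nonsynonymous"
        assert out["aa_change"].iloc[0] == "S1L"

    def test_pro_synonymous_third_position(self):
        out = annotate_consequence(self._panel("CCC", 3, "C"))
        assert out["consequence"].iloc[0] == "synonymous"

    def test_noncoding_site(self):
        df = pd.DataFrame(
            {
                "site_id": ["s0"],
                "gene_id": ["g"],
                "gene_position": [2],
                "ref_base": ["C"],
                "codon_index": [np.nan],
                "codon_position": [np.nan],
                "display_name": ["g-2"],
            }
        )
        out = annotate_consequence(SitePanel(df, sequences={"g": "TCA"}))
        assert out["consequence"].iloc[0] == "noncoding"

    def test_frame_inconsistency_is_an_error(self):
        panel = self._panel("TCATCA", 5, "C")
        panel.sites.loc[0, "codon_position"] = 1  # truly position 2 of codon 2
        with pytest.raises(ValueError):
            annotate_consequence(panel)

    def test_agrees_with_full_cds_translation_oracle(self, small_dataset):
        # brute force: mutate the whole CDS and translate everything
        panel = small_dataset["panel"]
        out = annotate_consequence(panel).set_index("site_id")
        from medito.core import CANONICAL_EDITS

        for _, s in panel.sites.iterrows():
            seq = panel.sequences[s["gene_id"]]
            pos = int(s["gene_position"])
            mutated = seq[: pos - 1] + CANONICAL_EDITS[s["ref_base"]] + seq[pos:]
            n = 3 * (len(seq) // 3)
            aa_ref = str(Seq(seq[:n]).translate())
            aa_alt = str(Seq(mutated[:n]).translate())
            expected = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
            assert out.loc[s["site_id"], "consequence"] == expected
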