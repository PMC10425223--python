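import dataclasses

import numpy as np
import pandas as pd
import pytest

from dysbiome import (SimulationConfig, adjusted_spearman,
                      generate_abundance_tables, generate_cytokines,
                      generate_gene_family_matrix, generate_metadata,
                      simulate_all)
from dysbiome.simulate import GroundTruth


class TestConfigValidation:
    def test_zero_cases_rejected_naming_field(self):
        cfg = SimulationConfig(n_cases=0)
        with pytest.raises(ValueError, match="n_cases"):
            cfg.validate()

    @pytest.mark.parametrize("field,value,match", [
        ("cluster_mixing", 1.5, "cluster_mixing"),
        ("gene_flip_rate", 0.5, "gene_flip_rate"),
        ("cytokine_assoc_rho", 1.0, "cytokine_assoc_rho"),
        ("sparsity", 1.0, "sparsity"),
        ("n_enriched", -1, "n_enriched"),
    ])
    def test_bad_values_rejected(self, field, value, match):
        cfg = dataclasses.replace(SimulationConfig(), **{field: value})
        with pytest.raises(ValueError, match=match):
            cfg.validate()

    def test_planted_counts_exceeding_features_rejected(self):
        cfg = SimulationConfig(n_features=5, n_enriched=3, n_depleted=3)
        with pytest.raises(ValueError, match="n_enriched"):
            cfg.validate()

    def test_null_counts_allowed(self):
        SimulationConfig(n_enriched=0, n_depleted=0, n_diff_gene_families=0,
                         n_cytokine_targets=0).validate()


class TestMetadata:
    def test_counts_forced(self):
        cfg = SimulationConfig(n_cases=5, n_controls=5, seed=1)
        md = generate_metadata(cfg)
        assert len(md) == 10
        assert (md["cohort"] == "case").sum() == 5
        assert (md["cohort"] == "control").sum() == 5

    def test_deterministic(self):
        cfg = SimulationConfig(n_cases=5, n_controls=5, seed=1)
        pd.testing.assert_frame_equal(generate_metadata(cfg), generate_metadata(cfg))

    def test_clinical_fields_cases_only(self):
        md = generate_metadata(SimulationConfig(n_cases=20, n_controls=20, seed=2))
        case = md["cohort"] == "case"
        for col in ("cd4_count", "ca_hiv_dna", "ca_hiv_rna"):
            assert md.loc[case, col].notna().all()
            assert md.loc[~case, col].isna().all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_cases"):
            generate_metadata(SimulationConfig(n_cases=0))


class TestAbundance:
    def test_rows_sum_to_one(self, small_bundle):
        sums = small_bundle["species"].data.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_ground_truth_sets_disjoint(self, small_bundle):
        truth = small_bundle["ground_truth"]
        assert not truth.enriched_features & truth.depleted_features
        with pytest.raises(ValueError, match="overlap"):
            GroundTruth(enriched_features=frozenset({"a"}),
                        depleted_features=frozenset({"a"}))

    def test_null_table_has_no_group_shift(self):
        cfg = SimulationConfig(n_cases=200, n_controls=200, n_features=30,
                               n_enriched=0, n_depleted=0, seed=3)
        md = generate_metadata(cfg)
        table, truth = generate_abundance_tables(cfg, md)
        assert not truth.enriched_features and not truth.depleted_features
        case = md["cohort"] == "case"
        log_ratio = np.log(
            table.data[case].mean() / table.data[~case].mean())
        assert np.abs(log_ratio).mean() < 0.2

    def test_planted_log2fc_recovered_at_scale(self):
        # one enriched feature among many: closure distortion negligible,
        # case/control mean ratio ~ 2 at effect_log2fc=1
        cfg = SimulationConfig(n_cases=500, n_controls=500, n_features=100,
                               n_enriched=1, n_depleted=1, effect_log2fc=1.0,
                               sparsity=0.0, seed=4)
        md = generate_metadata(cfg)
        table, truth = generate_abundance_tables(cfg, md)
        feature = next(iter(truth.enriched_features))
        case = md["cohort"] == "case"
        ratio = table.data.loc[case, feature].mean() / \
            table.data.loc[~case, feature].mean()
        assert ratio == pytest.approx(2.0, abs=0.35)

    def test_mismatched_metadata_rejected(self):
        cfg = SimulationConfig(seed=1)
        md = generate_metadata(cfg)
        dup = pd.concat([md, md])
        with pytest.raises(ValueError, match="unique"):
            generate_abundance_tables(cfg, dup)

    def test_deterministic(self):
        cfg = SimulationConfig(n_cases=10, n_controls=10, n_features=20,
                               n_enriched=4, n_depleted=2, seed=6)
        md = generate_metadata(cfg)
        t1, _ = generate_abundance_tables(cfg, md)
        t2, _ = generate_abundance_tables(cfg, md)
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestGeneFamilies:
    def test_degenerate_noise_gives_exact_archetypes(self):
        cfg = SimulationConfig(n_cases=10, n_controls=10, n_gene_families=50,
                               n_diff_gene_families=20, gene_flip_rate=0.0,
                               cluster_mixing=0.0, seed=7)
        md = generate_metadata(cfg)
        matrix, truth = generate_gene_family_matrix(cfg, md)
        case = md["cohort"] == "case"
        case_profiles = matrix.data[case.reindex(matrix.data.index)]
        control_profiles = matrix.data[~case.reindex(matrix.data.index)]
        assert (case_profiles.nunique(axis=0) <= 1).all()
        assert (control_profiles.nunique(axis=0) <= 1).all()
        diff_cols = case_profiles.iloc[0] != control_profiles.iloc[0]
        assert set(matrix.data.columns[diff_cols]) == set(truth.diff_gene_families)

    def test_null_archetypes_identical(self):
        cfg = SimulationConfig(n_cases=8, n_controls=8, n_gene_families=40,
                               n_diff_gene_families=0, gene_flip_rate=0.0,
                               cluster_mixing=0.0, seed=8)
        md = generate_metadata(cfg)
        matrix, _ = generate_gene_family_matrix(cfg, md)
        assert (matrix.data.nunique(axis=0) <= 1).all()

    def test_archetype_jaccard_matches_set_oracle(self):
        cfg = SimulationConfig(n_cases=2, n_controls=2, n_gene_families=60,
                               n_diff_gene_families=30, gene_flip_rate=0.0,
                               cluster_mixing=0.0, seed=9)
        md = generate_metadata(cfg)
        matrix, _ = generate_gene_family_matrix(cfg, md)
        from dysbiome import jaccard_distance_matrix

        case_row = matrix.data.iloc[0].to_numpy()
        control_row = matrix.data.iloc[-1].to_numpy()
        a = {j for j, v in enumerate(case_row) if v}
        b = {j for j, v in enumerate(control_row) if v}
        expected = 1 - len(a & b) / len(a | b)
        d = jaccard_distance_matrix(matrix)
        assert d.values[0, -1] == pytest.approx(expected, abs=1e-12)

    def test_mixing_sends_cases_to_control_strain(self):
        cfg = SimulationConfig(n_cases=300, n_controls=50, cluster_mixing=0.3,
                               seed=10)
        md = generate_metadata(cfg)
        _, truth = generate_gene_family_matrix(cfg, md)
        case = md["cohort"] == "case"
        frac = (truth.true_strain_labels[case] == "control_strain").mean()
        assert frac == pytest.approx(0.3, abs=0.08)
        assert (truth.true_strain_labels[~case] == "control_strain").all()

    def test_pfam_map_concentrates_diff_genes(self, small_bundle):
        matrix = small_bundle["gene_matrix"]
        truth = small_bundle["ground_truth"]
        hot = {p for g in truth.diff_gene_families
               for p in matrix.pfam_map.get(g, ())}
        assert any(p.startswith("PF9") for p in hot)


class TestCytokines:
    def test_planted_rho_recovered(self):
        cfg = SimulationConfig(n_cases=150, n_controls=150, n_features=40,
                               cytokine_assoc_rho=0.9, n_cytokine_targets=1,
                               confounder_strength=0.5, seed=12)
        md = generate_metadata(cfg)
        table, _ = generate_abundance_tables(cfg, md)
        md2, pairs = generate_cytokines(cfg, md, table)
        feature, pheno, sign = pairs[0]
        rho, _, _ = adjusted_spearman(
            table.data[feature], md2[pheno],
            pd.DataFrame({"age": md2["age"],
                          "sex": (md2["sex"] == "male").astype(float)}))
        assert sign * rho == pytest.approx(0.9, abs=0.1)

    def test_null_targets_independent(self):
        cfg = SimulationConfig(n_cases=100, n_controls=100, n_features=30,
                               n_cytokine_targets=0, seed=13)
        md = generate_metadata(cfg)
        table, _ = generate_abundance_tables(cfg, md)
        md2, pairs = generate_cytokines(cfg, md, table)
        assert pairs == []
        rho, p, _ = adjusted_spearman(
            table.data.iloc[:, 0], md2["Pam3Cys_IL10"],
            pd.DataFrame({"age": md2["age"],
                          "sex": (md2["sex"] == "male").astype(float)}))
        assert abs(rho) < 0.2

    def test_no_confounding_plain_equals_adjusted(self):
        cfg = SimulationConfig(n_cases=150, n_controls=150, n_features=30,
                               cytokine_assoc_rho=0.6, n_cytokine_targets=1,
                               confounder_strength=0.0, seed=14)
        md = generate_metadata(cfg)
        table, _ = generate_abundance_tables(cfg, md)
        md2, pairs = generate_cytokines(cfg, md, table)
        feature, pheno, sign = pairs[0]
        plain, _, _ = adjusted_spearman(table.data[feature], md2[pheno])
        adj, _, _ = adjusted_spearman(
            table.data[feature], md2[pheno],
            pd.DataFrame({"age": md2["age"]}))
        assert plain == pytest.approx(adj, abs=0.05)

    def test_misaligned_table_rejected(self):
        cfg = SimulationConfig(n_cases=5, n_controls=5, seed=1)
        md = generate_metadata(cfg)
        table, _ = generate_abundance_tables(cfg, md)
        with pytest.raises(ValueError, match="sample ids"):
            generate_cytokines(cfg, md.iloc[::-1], table)


class TestBundleDeterminism:
    def test_simulate_all_bit_identical(self, small_config):
        b1 = simulate_all(small_config)
        b2 = simulate_all(small_config)
        pd.testing.assert_frame_equal(b1["metadata"], b2["metadata"])
        pd.testing.assert_frame_equal(b1["species"].data, b2["species"].data)
        pd.testing.assert_frame_equal(b1["gene_matrix"].data, b2["gene_matrix"].data)
        assert b1["ground_truth"].cytokine_target_pairs == \
            b2["ground_truth"].cytokine_target_pairs

    def test_different_seeds_differ(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        b1 = simulate_all(small_config)
        b2 = simulate_all(other)
        assert not b1["species"].data.equals(b2["species"].data)
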