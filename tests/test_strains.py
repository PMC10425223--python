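import numpy as np
import pandas as pd
import pytest

from dysbiome import SimulationConfig, generate_gene_family_matrix, generate_metadata
from dysbiome.strains import (GeneFamilyMatrix, cluster_and_cut,
                              cluster_cohort_enrichment,
                              differential_gene_families, jaccard_distance_matrix,
                              pfam_enrichment, strain_phenotype_association)
from tests.oracles import fisher_exact_two_sided, hypergeom_sf


def gene_matrix(rows, sample_ids=None, pfam_map=None):
    rows = np.asarray(rows, dtype=int)
    n, g = rows.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    genes = [f"g{j}" for j in range(g)]
    return GeneFamilyMatrix(
        pd.DataFrame(rows, index=sample_ids, columns=genes), pfam_map=pfam_map)


class TestJaccard:
    def test_identical_zero(self):
        d = jaccard_distance_matrix(gene_matrix([[1, 1, 0], [1, 1, 0]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_one(self):
        d = jaccard_distance_matrix(gene_matrix([[1, 0, 0], [0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_two_thirds_example(self):
        d = jaccard_distance_matrix(gene_matrix([[1, 1, 0], [1, 0, 1]]))
        assert d.values[0, 1] == pytest.approx(2.0 / 3.0)

    def test_joint_absences_ignored(self, rng):
        base = (rng.random((6, 20)) < 0.5).astype(int)
        base[:, 0] = 1  # keep everyone non-empty
        padded = np.hstack([base, np.zeros((6, 30), dtype=int)])
        d1 = jaccard_distance_matrix(gene_matrix(base))
        d2 = jaccard_distance_matrix(gene_matrix(padded))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-15)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            gene_matrix([[0, 2], [1, 1]])

    def test_all_absent_sample_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no present gene"):
            m = gene_matrix([[1, 1], [0, 0]])
        assert m.sample_ids == ["s0"]


class TestClusterAndCut:
    def test_two_blocks_recovered_exactly(self):
        block_a = np.tile([1, 1, 1, 0, 0, 0, 1, 0, 1, 1], (5, 1))
        block_b = np.tile([0, 0, 0, 1, 1, 1, 0, 1, 1, 1], (5, 1))
        m = gene_matrix(np.vstack([block_a, block_b]))
        d = jaccard_distance_matrix(m)
        assert d.values[0, 5] > 0.3
        clustering = cluster_and_cut(d, cut_height=0.3, min_cluster_size=2)
        labels = clustering.cluster_labels
        assert labels.nunique() == 2
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1
        assert clustering.excluded_samples == []

    def test_cut_above_root_single_cluster(self, rng):
        rows = (rng.random((8, 30)) < 0.5).astype(int)
        rows[:, 0] = 1
        d = jaccard_distance_matrix(gene_matrix(rows))
        clustering = cluster_and_cut(d, cut_height=1.01, min_cluster_size=1)
        assert clustering.cluster_labels.nunique() == 1

    def test_cut_below_every_merge_excludes_all(self, rng):
        rows = (rng.random((6, 40)) < 0.5).astype(int)
        rows[:, 0] = 1
        d = jaccard_distance_matrix(gene_matrix(rows))
        with pytest.raises(ValueError, match="all samples excluded"):
            cluster_and_cut(d, cut_height=1e-9, min_cluster_size=2)

    def test_small_cluster_excluded(self):
        block_a = np.tile([1, 1, 1, 1, 0, 0, 0, 0], (6, 1))
        block_b = np.tile([0, 0, 0, 0, 1, 1, 1, 1], (2, 1))
        d = jaccard_distance_matrix(gene_matrix(np.vstack([block_a, block_b])))
        clustering = cluster_and_cut(d, cut_height=0.3, min_cluster_size=3)
        assert len(clustering.excluded_samples) == 2
        assert clustering.cluster_labels.nunique() == 1

    def test_merge_heights_nondecreasing(self, small_bundle):
        d = jaccard_distance_matrix(small_bundle["gene_matrix"])
        clustering = cluster_and_cut(d, 0.3, min_cluster_size=5)
        heights = clustering.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_two_strain_recovery(self, seed):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(n_cases=30, n_controls=30, n_gene_families=300,
                               n_diff_gene_families=180, gene_flip_rate=0.02,
                               cluster_mixing=0.2, seed=seed)
        metadata = generate_metadata(cfg)
        matrix, truth = generate_gene_family_matrix(cfg, metadata)
        d = jaccard_distance_matrix(matrix)
        clustering = cluster_and_cut(d, 0.3, min_cluster_size=2)
        ari = adjusted_rand_score(
            truth.true_strain_labels.reindex(clustering.cluster_labels.index),
            clustering.cluster_labels)
        assert ari == 1.0


class TestClusterCohortEnrichment:
    def _clustering(self, labels, ids):
        from dysbiome.strains import StrainClustering

        return StrainClustering(
            linkage_matrix=np.empty((0, 4)), cut_height=0.3,
            cluster_labels=pd.Series(labels, index=ids), excluded_samples=[])

    def test_perfect_split_p(self):
        ids = [f"s{i}" for i in range(20)]
        clustering = self._clustering([1] * 10 + [2] * 10, ids)
        cohorts = pd.Series(["case"] * 10 + ["control"] * 10, index=ids)
        out = cluster_cohort_enrichment(clustering, cohorts)
        expected = float(fisher_exact_two_sided([[10, 0], [0, 10]]))
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert out["p"].iloc[0] == pytest.approx(1.082e-5, rel=1e-3)

    def test_balanced_table_p_one(self):
        ids = [f"s{i}" for i in range(20)]
        clustering = self._clustering([1] * 10 + [2] * 10, ids)
        cohorts = pd.Series((["case"] * 5 + ["control"] * 5) * 2, index=ids)
        out = cluster_cohort_enrichment(clustering, cohorts)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_contingency_recorded(self):
        ids = [f"s{i}" for i in range(12)]
        clustering = self._clustering([1] * 8 + [2] * 4, ids)
        cohorts = pd.Series(["case"] * 6 + ["control"] * 6, index=ids)
        cluster_cohort_enrichment(clustering, cohorts)
        assert clustering.cohort_contingency.to_numpy().sum() == 12


class TestFisherOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_tables_match_enumeration(self, seed):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(seed)
        table = rng.integers(0, 8, size=(2, 2))
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() \
           or (table.sum(axis=1) == 0).any():
            table = table + 1
        _, p = fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(float(fisher_exact_two_sided(table)), rel=1e-9)


class TestDifferentialGeneFamilies:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        cfg = SimulationConfig(n_cases=50, n_controls=50, n_gene_families=120,
                               n_diff_gene_families=60, gene_flip_rate=0.05,
                               cluster_mixing=0.2, seed=17)
        metadata = generate_metadata(cfg)
        matrix, truth = generate_gene_family_matrix(cfg, metadata)
        d = jaccard_distance_matrix(matrix)
        clustering = cluster_and_cut(d, 0.3, min_cluster_size=5)
        diff = differential_gene_families(matrix, clustering, metadata)
        return diff, truth, matrix, clustering

    def test_planted_genes_recovered(self, planted):
        diff, truth, *_ = planted
        hits = set(diff.loc[diff["significant"].fillna(False), "gene_family_id"])
        planted_hit = len(hits & truth.diff_gene_families)
        assert planted_hit / len(truth.diff_gene_families) >= 0.8
        # precision >= 1 - FDR on average (allow slack for one run)
        if hits:
            assert planted_hit / len(hits) >= 0.85

    def test_constant_genes_excluded(self, planted):
        diff, *_ = planted
        constant = diff[diff["constant"]]
        assert constant["q"].isna().all()

    def test_always_present_gene_excluded(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((40, 30)) < 0.5).astype(int)
        rows[:, 0] = 1  # constant gene
        m = gene_matrix(rows)
        idx = m.data.index
        metadata = pd.DataFrame({"age": rng.normal(50, 5, 40),
                                 "sex": rng.choice(["male", "female"], 40),
                                 "read_count": rng.normal(2.5e7, 1e6, 40)},
                                index=idx)
        from dysbiome.strains import StrainClustering

        clustering = StrainClustering(
            np.empty((0, 4)), 0.3,
            pd.Series([1] * 20 + [2] * 20, index=idx), [])
        diff = differential_gene_families(m, clustering, metadata)
        assert bool(diff.set_index("gene_family_id").loc["g0", "constant"])

    def test_separation_flag_gets_fisher_p(self, planted):
        diff, *_ = planted
        separated = diff[diff["separation"]]
        if len(separated):
            assert separated["p"].between(0, 1).all()


class TestPfamEnrichment:
    def _matrix(self):
        rows = np.ones((3, 10), dtype=int)
        pfam_map = {f"g{j}": frozenset({"PFA" if j < 5 else "PFB"})
                    for j in range(10)}
        return gene_matrix(rows, pfam_map=pfam_map)

    def test_whole_universe_draw_gives_p_one(self):
        m = self._matrix()
        out = pfam_enrichment([f"g{j}" for j in range(10)], m)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_frozen_1_over_252(self):
        m = self._matrix()
        out = pfam_enrichment([f"g{j}" for j in range(5)], m).set_index("pfam_label")
        assert out.loc["PFA", "p"] == pytest.approx(1.0 / 252.0, rel=1e-12)
        assert out.loc["PFA", "p"] == pytest.approx(
            float(hypergeom_sf(5, 10, 5, 5)), rel=1e-12)

    def test_zero_overlap_p_one(self):
        m = self._matrix()
        out = pfam_enrichment([f"g{j}" for j in range(5, 10)], m).set_index("pfam_label")
        assert out.loc["PFA", "p"] == pytest.approx(1.0)

    def test_empty_hits_warn(self):
        m = self._matrix()
        with pytest.warns(UserWarning, match="empty hit set"):
            out = pfam_enrichment([], m)
        assert out.empty

    def test_no_map_rejected(self):
        m = gene_matrix(np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError, match="pfam_map"):
            pfam_enrichment(["g0"], m)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(seed)
        universe = int(rng.integers(5, 25))
        category = int(rng.integers(1, universe + 1))
        draw = int(rng.integers(1, universe + 1))
        k = int(rng.integers(0, min(category, draw) + 1))
        ours = float(hypergeom.sf(k - 1, universe, category, draw))
        oracle = float(hypergeom_sf(k, universe, category, draw))
        assert ours == pytest.approx(oracle, rel=1e-10)


class TestStrainPhenotypeAssociation:
    def _setup(self, rho=0.0, seed=0, n=120):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)])
        from dysbiome.strains import StrainClustering

        labels = pd.Series(rng.permutation([1] * (n // 2) + [2] * (n - n // 2)),
                           index=idx)
        clustering = StrainClustering(np.empty((0, 4)), 0.3, labels, [])
        metadata = pd.DataFrame({
            "age": rng.normal(50, 10, n),
            "sex": rng.choice(["male", "female"], n),
            "read_count": rng.normal(2.5e7, 2e6, n)}, index=idx)
        signal = rho * (labels == 1).astype(float)
        phenos = pd.DataFrame({
            "target": signal + rng.normal(size=n),
            "noise": rng.normal(size=n)}, index=idx)
        return clustering, phenos, metadata

    def test_planted_slope_recovered(self):
        detected = 0
        for seed in range(10):
            clustering, phenos, metadata = self._setup(rho=1.2, seed=seed)
            out = strain_phenotype_association(clustering, phenos, metadata)
            hit = out[(out.cluster == 1) & (out.phenotype_id == "target")]
            if bool(hit["significant"].iloc[0]) and hit["beta"].iloc[0] > 0:
                detected += 1
        assert detected >= 9

    def test_null_calibrated(self):
        rates = []
        for seed in range(15):
            clustering, phenos, metadata = self._setup(rho=0.0, seed=100 + seed)
            out = strain_phenotype_association(clustering, phenos, metadata)
            rates.append(out["significant"].mean())
        assert np.mean(rates) <= 0.12

    def test_abundance_encoding(self):
        clustering, phenos, metadata = self._setup(rho=0.5, seed=4)
        abundance = pd.Series(
            np.random.default_rng(0).uniform(0, 0.2, len(metadata)),
            index=metadata.index)
        out = strain_phenotype_association(
            clustering, phenos, metadata, species_abundance=abundance,
            encoding="abundance")
        assert (out["encoding"] == "abundance").all()
        assert len(out)

    def test_unknown_encoding_rejected(self):
        clustering, phenos, metadata = self._setup()
        with pytest.raises(ValueError, match="encoding"):
            strain_phenotype_association(clustering, phenos, metadata,
                                         encoding="magic")
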