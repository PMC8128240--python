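import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from sepsismeta import (
    SimulationConfig,
    consolidate_labels,
    differential_expression,
    generate_meta_expression,
    hierarchical_cluster,
    merge_series,
)
from sepsismeta.diffexp import ClusteringError, ContrastError
from .conftest import make_eset
from .oracles import bh_stepup, ward_linkage_exhaustive


class TestBenjaminiHochberg:
    def test_three_gene_worked_example(self):
        """p = [0.01, 0.02, 0.04] adjusts to [0.03, 0.03, 0.04] by step-up."""
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])
        assert np.allclose(bh_stepup([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_matches_stepup_oracle_on_random_vectors(self):
        """The BH correction used by the pipeline equals a literal step-up
        re-derivation on 1,000 random p-vectors (n <= 20, with ties)."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 21)
            p = rng.random(n)
            if rng.random() < 0.3 and n > 2:  # inject ties
                p[rng.integers(n)] = p[rng.integers(n)]
            assert np.allclose(
                multipletests(p, method="fdr_bh")[1], bh_stepup(p), atol=1e-12
            )


class TestDifferentialExpression:
    def test_flat_gene_not_called(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (5, 40))
        X[0, :20] = X[0, 20:]  # identical group values -> logFC 0
        eset = make_eset(X, classes=["sepsis"] * 20 + ["healthy"] * 20)
        de = differential_expression(eset, consolidate_labels(eset.metadata))
        assert de.iloc[0]["logFC"] == pytest.approx(0.0)
        assert not de.iloc[0]["is_de"]

    def test_planted_recovery_with_fdr_control(self):
        """50 planted genes at logFC 2 among 2,000 (noise sd 1, 200 samples):
        at least 45 recovered and realized false-discovery fraction <= 0.10."""
        cfg = SimulationConfig(
            n_studies=1,
            samples_per_study=200,
            n_genes_per_platform=2000,
            common_gene_fraction=1.0,
            n_de_genes=50,
            de_logfc=2.0,
            n_weak_genes=0,
            overlap_fraction=0.0,
            attenuated_fraction=0.0,
            batch_location_sd=0.0,
            batch_scale_sd=0.0,
            noise_sd=1.0,
            n_modules=0,
            seed=21,
        )
        sets, truth = generate_meta_expression(cfg)
        merged = merge_series(sets)
        de = differential_expression(merged, consolidate_labels(merged.metadata))
        called = set(de.index[de["is_de"]])
        planted = set(truth.de_gene_ids)
        assert len(called & planted) >= 45
        false = len(called - planted)
        assert false <= 0.10 * max(len(called), 1)

    def test_invariant_to_sample_and_gene_order(self, small_merged, small_labels):
        de = differential_expression(small_merged, small_labels)
        rng = np.random.default_rng(2)
        gene_perm = rng.permutation(small_merged.n_genes)
        samp_perm = rng.permutation(small_merged.n_samples)
        shuffled = small_merged.subset_genes(
            small_merged.gene_ids[gene_perm]
        ).subset_samples(small_merged.sample_ids[samp_perm])
        de2 = differential_expression(
            shuffled, small_labels.loc[shuffled.sample_ids]
        )
        pd.testing.assert_frame_equal(de2.sort_index(), de.sort_index())

    def test_sensitivity_monotone_in_effect_size(self):
        """Recovery of planted genes grows with the planted effect size."""
        sens = []
        for logfc in (0.3, 0.6, 1.0):
            cfg = SimulationConfig(
                n_studies=1,
                samples_per_study=60,
                n_genes_per_platform=400,
                common_gene_fraction=1.0,
                n_de_genes=40,
                de_logfc=logfc,
                n_weak_genes=0,
                overlap_fraction=0.0,
                attenuated_fraction=0.0,
                batch_location_sd=0.0,
                batch_scale_sd=0.0,
                noise_sd=1.0,
                n_modules=0,
                seed=31,
            )
            sets, truth = generate_meta_expression(cfg)
            merged = merge_series(sets)
            de = differential_expression(
                merged,
                consolidate_labels(merged.metadata),
                logfc_threshold=0.0,
            )
            sens.append(de.loc[truth.de_gene_ids, "is_de"].mean())
        assert sens[0] < sens[1] < sens[2]

    def test_moderation_flag_tightens_variances(self, small_merged, small_labels):
        plain = differential_expression(small_merged, small_labels)
        mod = differential_expression(small_merged, small_labels, moderation=True)
        assert np.allclose(plain["logFC"], mod["logFC"])
        assert (mod["p_adj"] >= mod["p_raw"] - 1e-15).all()

    def test_zero_variance_gene_warns_p_one(self):
        X = np.vstack([np.full(10, 3.0), np.random.default_rng(3).normal(size=10)])
        eset = make_eset(X, classes=["sepsis"] * 5 + ["healthy"] * 5)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            de = differential_expression(eset, consolidate_labels(eset.metadata))
        assert de.iloc[0]["p_raw"] == 1.0

    def test_single_class_raises(self):
        eset = make_eset(np.zeros((3, 6)), classes=["sepsis"] * 6)
        with pytest.raises(ContrastError):
            differential_expression(eset, pd.Series(["sepsis"] * 6, index=eset.sample_ids))

    def test_padj_dominates_p_and_flags_consistent(self, small_merged, small_labels):
        de = differential_expression(small_merged, small_labels)
        assert (de["p_adj"] >= de["p_raw"] - 1e-15).all()
        expected = (de["logFC"].abs() >= 1.0) & (de["p_adj"] < 0.05)
        assert (de["is_de"] == expected).all()


class TestHierarchicalClustering:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_ward_matches_exhaustive_oracle(self, seed):
        """Ward merge heights on n <= 12 points equal a greedy exhaustive
        agglomeration re-derived from cluster members at every step."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        X = rng.normal(0, 1, (n, 3))
        eset = make_eset(X.T, classes=["sepsis"] * (n // 2) + ["healthy"] * (n - n // 2))
        res = hierarchical_cluster(eset, eset.gene_ids, k=1)
        oracle = ward_linkage_exhaustive(X)
        assert np.allclose(np.sort(res.merge_heights), np.sort(oracle[:, 2]), atol=1e-8)

    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        blob = np.repeat(np.arange(3), 4)
        X = centers[blob] + rng.normal(0, 1.0, (12, 2))
        eset = make_eset(X.T)
        res = hierarchical_cluster(eset, eset.gene_ids, k=3)
        for b in range(3):
            members = res.assignments.to_numpy()[blob == b]
            assert len(set(members)) == 1
        assert res.composition.to_numpy().sum() == 12

    def test_identical_samples_zero_heights(self):
        eset = make_eset(np.ones((4, 6)))
        res = hierarchical_cluster(eset, eset.gene_ids, k=1)
        assert np.allclose(res.merge_heights, 0.0)

    def test_k_one_single_cluster(self, small_merged):
        res = hierarchical_cluster(small_merged, small_merged.gene_ids[:10], k=1)
        assert set(res.assignments) == {1}
        assert res.composition.to_numpy().sum() == small_merged.n_samples

    def test_heights_non_decreasing(self, small_merged, small_labels):
        de = differential_expression(small_merged, small_labels)
        genes = de.index[de["is_de"]]
        res = hierarchical_cluster(small_merged, genes, k=3)
        assert (np.diff(res.merge_heights) >= -1e-9).all()
        assert res.composition.to_numpy().sum() == small_merged.n_samples

    def test_empty_gene_set_raises(self, small_merged):
        with pytest.raises(ClusteringError):
            hierarchical_cluster(small_merged, [], k=2)
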