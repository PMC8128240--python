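import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from sepsismeta import (
    ExpressionSet,
    SimulationConfig,
    average_probes,
    batch_labels,
    center_scale,
    combat_adjust,
    consolidate_labels,
    generate_meta_expression,
    merge_series,
)
from sepsismeta.preprocess import (
    AdjustmentError,
    MappingError,
    MergeError,
    ScalingError,
)
from .conftest import make_eset
from .oracles import combat_two_batch_location


def eset_from(genes, n_samples, study="s1", seed=0):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(8, 2, (len(genes), n_samples)),
        index=genes,
        columns=[f"{study}_x{j}" for j in range(n_samples)],
    )
    meta = pd.DataFrame(
        {
            "class": ["sepsis" if j % 2 else "healthy" for j in range(n_samples)],
            "study": study,
            "platform": "p_" + study,
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionSet(values, meta)


class TestMergeSeries:
    def test_intersection_of_gene_sets(self):
        a = eset_from(["A", "B", "C"], 4, "s1")
        b = eset_from(["B", "C", "D"], 5, "s2")
        merged = merge_series([a, b])
        assert list(merged.gene_ids) == ["B", "C"]
        assert merged.n_samples == 9

    def test_single_input_identity_with_sorted_genes(self):
        a = eset_from(["C", "A", "B"], 3, "s1")
        merged = merge_series([a])
        assert list(merged.gene_ids) == ["A", "B", "C"]
        pd.testing.assert_frame_equal(merged.values, a.values.loc[["A", "B", "C"]])

    def test_sample_concatenation_shape(self):
        genes = [f"g{i}" for i in range(10)]
        sets = [eset_from(genes, n, f"s{k}") for k, n in enumerate([5, 7, 9])]
        merged = merge_series(sets)
        assert merged.values.shape == (10, 21)

    def test_empty_intersection_raises(self):
        with pytest.raises(MergeError):
            merge_series([eset_from(["A"], 3, "s1"), eset_from(["B"], 3, "s2")])

    def test_gene_set_associativity(self):
        a = eset_from(["A", "B", "C", "D"], 3, "s1")
        b = eset_from(["B", "C", "D", "E"], 3, "s2")
        c = eset_from(["C", "D", "E", "F"], 3, "s3")
        left = merge_series([merge_series([a, b]), c])
        right = merge_series([a, merge_series([b, c])])
        assert list(left.gene_ids) == list(right.gene_ids)
        pd.testing.assert_frame_equal(left.values, right.values)


class TestAverageProbes:
    def test_multi_probe_mean_and_single_probe_identity(self):
        values = pd.DataFrame(
            {"x1": [4.0, 6.0, 7.0], "x2": [1.0, 2.0, 3.0]},
            index=["p1", "p2", "p3"],
        )
        mapping = {"p1": "gA", "p2": "gA", "p3": "gB"}
        meta = eset_from(["gA"], 2).metadata.iloc[:2]
        meta.index = pd.Index(["x1", "x2"], name="sample_id")
        out = average_probes(values, mapping, meta)
        assert out.values.loc["gA", "x1"] == pytest.approx(5.0)
        assert out.values.loc["gB", "x2"] == pytest.approx(3.0)

    def test_three_probes_average(self):
        values = pd.DataFrame({"x1": [1.0, 2.0, 3.0]}, index=["p1", "p2", "p3"])
        meta = eset_from(["g"], 2).metadata.iloc[:1]
        meta.index = pd.Index(["x1"], name="sample_id")
        out = average_probes(values, {"p1": "g", "p2": "g", "p3": "g"}, meta)
        assert out.values.loc["g", "x1"] == pytest.approx(2.0)

    def test_unmapped_probe_raises(self):
        values = pd.DataFrame({"x1": [1.0]}, index=["p_orphan"])
        with pytest.raises(MappingError, match="p_orphan"):
            average_probes(values, {"other": "g"}, pd.DataFrame())


def two_batch_eset(shift=0.0, scale=1.0, n=60, G=40, seed=0):
    """Two studies; batch 2 shifted/scaled on every gene; balanced classes."""
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 1, (G, 2 * n))
    base[:, n:] = (base[:, n:] - 8.0) * scale + 8.0 + shift
    genes = [f"g{i:03d}" for i in range(G)]
    samples = [f"b{1 + (j >= n)}_x{j:03d}" for j in range(2 * n)]
    classes = (["sepsis", "healthy"] * n)[: 2 * n]
    meta = pd.DataFrame(
        {
            "class": classes,
            "study": ["s1"] * n + ["s2"] * n,
            "platform": "p1",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionSet(pd.DataFrame(base, index=genes, columns=samples), meta)


class TestCombat:
    def test_single_batch_returns_input(self):
        eset = eset_from([f"g{i}" for i in range(10)], 12)
        out = combat_adjust(eset)
        assert np.allclose(out.values, eset.values, atol=1e-6)

    def test_additive_shift_removed_matches_location_oracle(self):
        """A pure +3 location shift on batch 2 is removed: per-gene
        between-batch mean difference < 0.1, matching the no-EB closed-form
        adjustment.  With a gene-constant shift the EB prior tightens and
        only half of each gene's sampling deviation is removed, so the 0.1
        contract needs batches large enough for those deviations to be small."""
        eset = two_batch_eset(shift=3.0, n=800, G=25)
        out = combat_adjust(eset, covariate=eset.metadata["class"])
        b = eset.metadata["study"].to_numpy()
        m1 = out.values.loc[:, b == "s1"].mean(axis=1)
        m2 = out.values.loc[:, b == "s2"].mean(axis=1)
        assert (m1 - m2).abs().max() < 0.1
        oracle = combat_two_batch_location(eset.values.to_numpy(), b)
        o1 = oracle[:, b == "s1"].mean(axis=1)
        o2 = oracle[:, b == "s2"].mean(axis=1)
        # oracle equalizes batch means exactly; adjusted means agree closely
        assert np.allclose(m1.to_numpy(), o1, atol=0.1)
        assert np.allclose(m2.to_numpy(), o2, atol=0.1)

    def test_scale_factor_equalized(self):
        """A 2x noise-scale factor on batch 2 is shrunk away: per-batch
        variances agree within 20% after adjustment."""
        eset = two_batch_eset(scale=2.0, n=100)
        out = combat_adjust(eset, covariate=eset.metadata["class"])
        b = eset.metadata["study"].to_numpy()
        v1 = out.values.loc[:, b == "s1"].var(axis=1, ddof=1)
        v2 = out.values.loc[:, b == "s2"].var(axis=1, ddof=1)
        ratio = (v2 / v1).median()
        assert 0.8 < ratio < 1.25

    def test_shape_metadata_and_grand_mean_preserved(self):
        eset = two_batch_eset(shift=2.0, scale=1.5)
        out = combat_adjust(eset, covariate=eset.metadata["class"])
        assert out.values.shape == eset.values.shape
        pd.testing.assert_frame_equal(out.metadata, eset.metadata)
        before = eset.values.mean(axis=1)
        after = out.values.mean(axis=1)
        assert (before - after).abs().max() < 0.2

    def test_batch_model_serializes_to_json(self, tmp_path):
        import json

        eset = two_batch_eset(shift=1.0, scale=1.2)
        _, model = combat_adjust(
            eset, covariate=eset.metadata["class"], return_model=True
        )
        path = tmp_path / "batch_model.json"
        model.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["batches"] == ["s1", "s2"]
        assert all(v > 0 for v in payload["delta"]["s2"].values())

    def test_small_batch_raises(self):
        eset = eset_from([f"g{i}" for i in range(5)], 9)
        batch = pd.Series(["a"] * 8 + ["b"], index=eset.sample_ids)
        with pytest.raises(AdjustmentError, match="fewer than 2"):
            combat_adjust(eset, batch=batch)

    def test_confounded_covariate_raises(self):
        eset = two_batch_eset()
        with pytest.raises(AdjustmentError, match="confounded"):
            combat_adjust(eset, covariate=eset.metadata["study"])

    def test_reduces_batch_f_preserves_class_effect(self):
        """On planted batch shifts with a true class effect, adjustment cuts
        the median between-batch F statistic by at least half while the
        sepsis-vs-rest difference on planted genes moves by under 25%."""
        cfg = SimulationConfig(
            n_studies=3,
            samples_per_study=60,
            n_genes_per_platform=200,
            common_gene_fraction=1.0,
            n_de_genes=40,
            de_logfc=2.0,
            n_weak_genes=0,
            overlap_fraction=0.0,
            attenuated_fraction=0.0,
            batch_location_sd=1.0,
            batch_scale_sd=0.2,
            noise_sd=1.0,
            n_modules=0,
            seed=9,
        )
        sets, truth = generate_meta_expression(cfg)
        merged = merge_series(sets)
        labels = consolidate_labels(merged.metadata)
        adj = combat_adjust(merged, covariate=labels)

        def median_batch_f(eset):
            groups = [
                eset.values.loc[:, (eset.metadata["study"] == s).to_numpy()]
                .to_numpy()
                .T
                for s in eset.metadata["study"].unique()
            ]
            return np.median(stats.f_oneway(*groups, axis=0).statistic)

        assert median_batch_f(adj) < 0.5 * median_batch_f(merged)

        pos = (labels == "sepsis").to_numpy()

        def de_diff(eset):
            v = eset.values.loc[truth.de_gene_ids]
            return (v.loc[:, pos].mean(axis=1) - v.loc[:, ~pos].mean(axis=1)).mean()

        assert de_diff(adj) == pytest.approx(de_diff(merged), rel=0.25)


def test_batch_labels_split_multi_platform_study():
    eset = eset_from([f"g{i}" for i in range(4)], 6, "s1")
    meta = eset.metadata.copy()
    meta.loc[meta.index[:3], "platform"] = "pA"
    meta.loc[meta.index[3:], "platform"] = "pB"
    labels = batch_labels(meta)
    assert set(labels) == {"s1:pA", "s1:pB"}
    # single-platform studies keep the plain study id
    assert set(batch_labels(eset.metadata)) == {"s1"}


class TestCenterScale:
    def test_simple_example(self):
        eset = make_eset([[1.0, 2.0, 3.0]])
        out, scaler = center_scale(eset)
        assert np.allclose(out.values.to_numpy(), [[-1.0, 0.0, 1.0]])
        assert scaler.means.iloc[0] == pytest.approx(2.0)
        assert scaler.sds.iloc[0] == pytest.approx(1.0)

    def test_idempotence(self, small_merged):
        once, _ = center_scale(small_merged)
        twice, _ = center_scale(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)
        assert np.abs(once.values.mean(axis=1)).max() < 1e-9

    def test_constant_gene_scaled_to_zero_with_warning(self):
        eset = make_eset([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out, _ = center_scale(eset)
        assert np.allclose(out.values.iloc[0], 0.0)

    def test_too_few_samples_raises(self):
        with pytest.raises(ScalingError):
            center_scale(make_eset([[1.0]], classes=["sepsis"]))

    def test_scaler_reused_on_new_samples(self):
        eset = make_eset(np.arange(12.0).reshape(3, 4))
        _, scaler = center_scale(eset)
        new = eset.values + 1.0
        transformed = scaler.transform(new)
        base = scaler.transform(eset.values)
        assert np.allclose(transformed - base, (1.0 / scaler.sds).to_numpy()[:, None])
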