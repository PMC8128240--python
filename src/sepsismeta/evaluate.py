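"""Experiment orchestration: stratified shuffle-split iteration, AUC / PCC
metrics, summary tables with t-based confidence intervals and between-method
t-tests, and the three experiments of the study design — native-data
classification, resilience under cumulative test-data degradation, and
DE-gene ablation.

Per iteration the meta-expression set is split into stratified train /
(validation) / test subsets, a classifier is trained on untouched training
data, and the SAME test split is evaluated natively and at every cumulative
degradation level (a paired design, so level effects are not confounded
with split-to-split noise).  Models and splits are discarded between
iterations.  The DNN workflow carves out an additional validation subset
(80/5/15) kept for parity with the workflow description; it is not used
during final training (no early stopping or validation callbacks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import classifiers as clf
from .containers import ExpressionSet
from .degrade import DegradationConfig, degrade
from .preprocess import center_scale
from .seeding import derive_seed
from .simulate import consolidate_labels

__all__ = [
    "SplitSpec",
    "SplitError",
    "MetricError",
    "SummaryError",
    "stratified_split",
    "auc",
    "pcc",
    "summarize",
    "run_experiment",
    "DNN_SPLIT",
    "DEFAULT_SPLIT",
    "LEVEL_NAMES",
]

LEVEL_NAMES = {0: "native", 1: "level1", 2: "level2", 3: "level3"}


class SplitError(ValueError):
    pass


class MetricError(ValueError):
    pass


class SummaryError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Stratified shuffle-split specification."""

    train_fraction: float = 0.85
    validation_fraction: float = 0.0
    test_fraction: float = 0.15
    n_iterations: int = 100
    seed: int = 0

    def validate(self) -> None:
        total = self.train_fraction + self.validation_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise SplitError("fractions must sum to 1")
        if min(self.train_fraction, self.validation_fraction, self.test_fraction) < 0:
            raise SplitError("fractions must be non-negative")
        if self.n_iterations < 1:
            raise SplitError("n_iterations must be >= 1")


DEFAULT_SPLIT = SplitSpec()  # 85 / 0 / 15, the DT/RF/SVM workflow
DNN_SPLIT = SplitSpec(0.80, 0.05, 0.15)  # 80 / 5 / 15, the DNN workflow


def stratified_split(
    labels, spec: SplitSpec, iteration: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train / validation / test positional indices.

    Within each class, validation and test sizes are floored to the
    configured fractions and the remainder goes to training, so per-class
    partition sizes match the fractions to within one sample.  Each iteration draws a
    fresh permutation from a seed derived from (spec.seed, iteration).
    """
    spec.validate()
    labels = pd.Series(labels).reset_index(drop=True)
    classes = labels.unique()
    if len(classes) < 2:
        raise SplitError("need both classes present")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(spec.seed), 77, int(iteration)))
    )
    train_idx, val_idx, test_idx = [], [], []
    for c in sorted(map(str, classes)):
        members = np.flatnonzero(labels.astype(str).to_numpy() == c)
        n_c = len(members)
        n_test = int(np.floor(spec.test_fraction * n_c))
        n_val = int(np.floor(spec.validation_fraction * n_c))
        n_train = n_c - n_test - n_val
        if (spec.test_fraction > 0 and n_test == 0) or (
            spec.validation_fraction > 0 and n_val == 0
        ) or n_train < 2:
            raise SplitError(f"class {c!r} too small ({n_c}) for the requested split")
        perm = rng.permutation(members)
        test_idx.append(perm[:n_test])
        val_idx.append(perm[n_test : n_test + n_val])
        train_idx.append(perm[n_test + n_val :])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(val_idx)),
        np.sort(np.concatenate(test_idx)),
    )


def auc(scores, truth) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counted one half."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise MetricError("truth contains a single class")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def pcc(predictions, truth) -> float:
    """Probability of correct classification: fraction of matching labels."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth) or len(truth) == 0:
        raise MetricError("predictions and truth must have equal positive length")
    return float((predictions == truth).mean())


def _ci95(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    m = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return float(m), float(m)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return float(m - half), float(m + half)


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        # near-constant AUC vectors trigger scipy precision warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def summarize(records: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Aggregate per-iteration records into a Tables-1/2-shaped summary.

    One row per (method, level, mode): mean AUC and PCC with t-based 95%
    confidence intervals, plus two-sided unpaired t-test p-values of each
    level against the same method's native performance and of each method
    against the DNN at the same level.
    """
    required = {"method", "level", "mode", "auc", "pcc"}
    if not required <= set(records.columns):
        raise SummaryError(f"records missing columns {required - set(records.columns)}")
    rows = []
    for (mode, method, level), grp in records.groupby(
        ["mode", "method", "level"], sort=True
    ):
        if len(grp) < 2:
            raise SummaryError(f"cell ({method}, {level}, {mode}) has fewer than 2 records")
        row = {"mode": mode, "method": method, "level": level, "n": len(grp)}
        for metric in ("auc", "pcc"):
            x = grp[metric].to_numpy()
            lo, hi = _ci95(x)
            row[f"{metric}_mean"] = float(x.mean())
            row[f"{metric}_ci_low"] = lo
            row[f"{metric}_ci_high"] = hi
            native = records.query(
                "mode == @mode and method == @method and level == 'native'"
            )[metric].to_numpy()
            row[f"{metric}_p_vs_native"] = (
                np.nan if level == "native" else _ttest(x, native, welch)
            )
            dnn = records.query(
                "mode == @mode and level == @level and method == 'DNN'"
            )[metric].to_numpy()
            row[f"{metric}_p_vs_dnn"] = (
                np.nan if method == "DNN" or len(dnn) == 0 else _ttest(x, dnn, welch)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index(["mode", "method", "level"]).sort_index()


def run_experiment(
    data: ExpressionSet,
    labels: pd.Series | None = None,
    methods: tuple[str, ...] = clf.METHODS,
    spec: SplitSpec = DEFAULT_SPLIT,
    degradation: DegradationConfig | None = None,
    mode: str = "full",
    de: pd.DataFrame | None = None,
    dnn_config=None,
    strict_scaling: bool = False,
    levels: tuple[int, ...] = (0, 1, 2, 3),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the iterated classification experiment on a merged set.

    Parameters
    ----------
    data : merged meta-expression set on the raw (log2-intensity-like)
        scale; gene-wise centering/scaling happens inside, on the full set
        by default (``strict_scaling=True`` refits the scaler on each
        iteration's training samples only, the leakage-safe variant).
    labels : binary labels; defaults to consolidating the metadata classes.
    degradation : cumulative degradation parameters; defaults to the study
        values (jitter factor 10,000; retain 25%; replace 50% at sd 20).
        Fresh degradation sub-seeds are derived per iteration and shared by
        all methods, so methods face identical corrupted test data.
    mode : 'full', or 'reduced' to remove the DE genes in ``de`` from the
        matrix before scaling and training (the ablation experiment).
    de : differential-expression result required in reduced mode.

    Returns the per-iteration records and their :func:`summarize` table.
    """
    if mode not in ("full", "reduced"):
        raise ValueError("mode must be 'full' or 'reduced'")
    if labels is None:
        labels = consolidate_labels(data.metadata)
    labels = pd.Series(labels, index=data.sample_ids)
    if degradation is None:
        degradation = DegradationConfig(seed=spec.seed)
    degradation.validate()
    unknown = set(methods) - set(clf.METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")

    if mode == "reduced":
        if de is None:
            raise ValueError("reduced mode requires a differential-expression result")
        de_genes = de.index[de["is_de"]]
        data = data.drop_genes(de_genes)

    y_all = (labels == "sepsis").to_numpy(dtype=int)
    raw_by_sample = data.values.T  # samples x genes, expression scale
    if not strict_scaling:
        scaled_set, scaler = center_scale(data)
        scaled_by_sample = scaled_set.values.T

    records = []
    for it in range(spec.n_iterations):
        deg_cfg = replace(degradation, seed=derive_seed(degradation.seed, 11, it))
        for m_idx, method in enumerate(methods):
            m_spec = DNN_SPLIT if method == "DNN" else spec
            m_spec = replace(m_spec, n_iterations=spec.n_iterations, seed=spec.seed)
            train_idx, _val_idx, test_idx = stratified_split(labels, m_spec, it)

            if strict_scaling:
                train_eset = data.subset_samples(data.sample_ids[train_idx])
                _, scaler = center_scale(train_eset)
                X_train = scaler.transform(train_eset.values).T
            else:
                X_train = scaled_by_sample.iloc[train_idx]
            y_train = y_all[train_idx]
            handle = clf.train(
                method,
                X_train,
                y_train,
                config=dnn_config if method == "DNN" else None,
                seed=derive_seed(spec.seed, 13, it, m_idx),
            )

            X_test_raw = raw_by_sample.iloc[test_idx]
            y_test = y_all[test_idx]
            for level in levels:
                # degradation corrupts the incoming (expression-scale) test
                # measurements; the deployment pipeline then standardizes
                # them with the stored per-gene parameters.  Training data
                # is never touched.
                X_deg = degrade(X_test_raw, level, deg_cfg)
                X_test = scaler.transform(X_deg.T).T
                s = clf.score(handle, X_test)
                records.append(
                    {
                        "iteration": it,
                        "method": method,
                        "level": LEVEL_NAMES[level],
                        "mode": mode,
                        "auc": auc(s, y_test),
                        "pcc": pcc((s >= 0.5).astype(int), y_test),
                        "seed": spec.seed,
                    }
                )
    records = pd.DataFrame(records)
    # confidence intervals need >= 2 iterations per cell
    summary = summarize(records) if spec.n_iterations >= 2 else None
    return records, summary
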