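"""Merging, probe averaging, empirical-Bayes batch adjustment and scaling.

Two preprocessing branches are supported, mirroring how merged microarray
collections are prepared in practice:

* the differential-expression branch applies parametric ComBat-style
  empirical-Bayes batch adjustment across the study/platform cohorts;
* the machine-learning branch applies gene-wise centering and scaling only,
  with the per-gene statistics retained so new samples can be transformed
  with the training-time parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionSet

__all__ = [
    "MergeError",
    "MappingError",
    "AdjustmentError",
    "ScalingError",
    "BatchModel",
    "GeneScaler",
    "merge_series",
    "average_probes",
    "batch_labels",
    "combat_adjust",
    "center_scale",
]


class MergeError(ValueError):
    pass


class MappingError(ValueError):
    pass


class AdjustmentError(ValueError):
    pass


class ScalingError(ValueError):
    pass


def merge_series(sets: Sequence[ExpressionSet]) -> ExpressionSet:
    """Merge per-study sets on the least common denominator of genes.

    The merged gene set is the intersection of all inputs' gene sets, in
    lexicographic order; samples are concatenated in input order.  No
    missing-data imputation is performed — every retained value is a real
    measurement.
    """
    if len(sets) == 0:
        raise MergeError("need at least one expression set")
    common = sets[0].gene_ids
    for s in sets[1:]:
        common = common.intersection(s.gene_ids)
    if len(common) == 0:
        raise MergeError("gene sets have an empty intersection")
    common = common.sort_values()
    values = pd.concat([s.values.loc[common] for s in sets], axis=1)
    metadata = pd.concat([s.metadata for s in sets], axis=0)
    return ExpressionSet(values, metadata)


def average_probes(
    values: pd.DataFrame,
    probe_to_gene: Mapping[str, str] | pd.Series,
    metadata: pd.DataFrame,
) -> ExpressionSet:
    """Collapse probe-level values to gene level by arithmetic mean.

    ``values`` is probe-by-sample; every probe must map to exactly one gene
    in ``probe_to_gene``.  Genes covered by several probes get the per-sample
    mean of their probes; single-probe genes pass through unchanged.
    """
    mapping = pd.Series(probe_to_gene)
    unmapped = values.index.difference(mapping.index)
    if len(unmapped):
        raise MappingError(f"probes mapped to no gene: {list(unmapped[:5])}")
    genes = mapping.loc[values.index]
    collapsed = values.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return ExpressionSet(collapsed, metadata)


def batch_labels(metadata: pd.DataFrame) -> pd.Series:
    """Per-sample batch identifiers: the study, split by platform when a
    single study spans several microarray platforms (so a 26-series
    collection with one four-platform study yields 29 cohorts)."""
    multi = metadata.groupby("study")["platform"].nunique()
    multi_studies = set(multi.index[multi > 1])

    def _label(row):
        if row["study"] in multi_studies:
            return f"{row['study']}:{row['platform']}"
        return row["study"]

    return metadata.apply(_label, axis=1).rename("batch")


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model (for audit / serialization).

    gamma / delta are the shrunken per-batch per-gene location and scale
    estimates; the prior hyperparameters are the moment-matched normal
    (location) and inverse-gamma (scale) parameters per batch.
    """

    gamma: pd.DataFrame  # genes x batches, shrunken locations
    delta: pd.DataFrame  # genes x batches, shrunken variance scales (> 0)
    gamma_bar: pd.Series  # per batch: location prior mean
    tau2: pd.Series  # per batch: location prior variance
    a_prior: pd.Series  # per batch: inverse-gamma shape
    b_prior: pd.Series  # per batch: inverse-gamma rate

    def __post_init__(self) -> None:
        if (self.delta.to_numpy() <= 0).any():
            raise AdjustmentError("scale estimates must be strictly positive")

    def to_json(self, path) -> None:
        payload = {
            "batches": list(self.gamma.columns),
            "gamma_bar": self.gamma_bar.to_dict(),
            "tau2": self.tau2.to_dict(),
            "a_prior": self.a_prior.to_dict(),
            "b_prior": self.b_prior.to_dict(),
            "gamma": {b: self.gamma[b].round(6).to_dict() for b in self.gamma.columns},
            "delta": {b: self.delta[b].round(6).to_dict() for b in self.delta.columns},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _postmean(g_hat, g_bar, n, d_old, t2):
    return (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def combat_adjust(
    eset: ExpressionSet,
    batch: pd.Series | None = None,
    covariate: pd.Series | None = None,
    *,
    conv: float = 1e-4,
    max_iter: int = 500,
    return_model: bool = False,
):
    """Parametric empirical-Bayes (ComBat-style) batch adjustment.

    Fits the gene-wise model  y = alpha + X beta + gamma_b + delta_b eps,
    standardizes each gene by its pooled variance, estimates per-batch
    location/scale, shrinks the estimates toward moment-matched parametric
    priors (normal on locations, inverse-gamma on variance scales), removes
    the shrunken batch effects, and restores the grand mean, pooled variance
    and covariate effects.  Output dimensions and metadata are unchanged.

    Parameters
    ----------
    batch : per-sample batch id; defaults to :func:`batch_labels` of the
        set's metadata (study, split by platform for multi-platform studies).
    covariate : per-sample biological covariate to protect (e.g. the class
        label); its effects are estimated alongside batch and restored.
    """
    if batch is None:
        batch = batch_labels(eset.metadata)
    batch = pd.Series(batch, index=eset.sample_ids).astype(str)
    counts = batch.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise AdjustmentError(f"batches with fewer than 2 samples: {small}")
    batches = sorted(counts.index)
    if len(batches) == 1:
        out = eset.copy()
        return (out, None) if return_model else out

    X = eset.values.to_numpy(dtype=float)  # G x N
    G, N = X.shape
    B = pd.get_dummies(batch, dtype=float)[batches].to_numpy()  # N x nb
    design_parts = [B]
    if covariate is not None:
        covariate = pd.Series(covariate, index=eset.sample_ids)
        C = pd.get_dummies(covariate.astype(str), drop_first=True, dtype=float)
        if C.shape[1] > 0:
            design_parts.append(C.to_numpy())
    design = np.hstack(design_parts)  # N x (nb + p)
    nb = len(batches)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise AdjustmentError(
            "covariate is confounded with batch; cannot separate the effects"
        )

    # gene-wise least squares for batch + covariate coefficients
    beta_hat = np.linalg.solve(design.T @ design, design.T @ X.T)  # (nb+p) x G
    n_b = B.sum(axis=0)  # samples per batch
    grand_mean = (n_b / N) @ beta_hat[:nb]  # G
    resid = X - (design @ beta_hat).T
    var_pooled = (resid**2).mean(axis=1)  # G

    degenerate = var_pooled <= 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) left unadjusted",
            RuntimeWarning,
            stacklevel=2,
        )
        var_pooled = np.where(degenerate, 1.0, var_pooled)

    stand_mean = grand_mean[:, None] * np.ones((1, N))
    if design.shape[1] > nb:
        stand_mean = stand_mean + (design[:, nb:] @ beta_hat[nb:]).T
    s_data = (X - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((G, nb))
    delta_star = np.empty((G, nb))
    gamma_bar = np.empty(nb)
    tau2 = np.empty(nb)
    a_prior = np.empty(nb)
    b_prior = np.empty(nb)
    batch_cols = [np.flatnonzero(B[:, i]) for i in range(nb)]

    for i, cols in enumerate(batch_cols):
        sb = s_data[:, cols]
        n = len(cols)
        g_hat = sb.mean(axis=1)
        d_hat = sb.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        gamma_bar[i] = g_hat.mean()
        tau2[i] = g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a_prior[i] = (2 * s2 + m**2) / s2
        b_prior[i] = (m * s2 + m**3) / s2

        g_old, d_old = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_new = _postmean(g_hat, gamma_bar[i], n, d_old, tau2[i])
            sum2 = ((sb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = _postvar(sum2, n, a_prior[i], b_prior[i])
            change = max(
                np.abs(g_new - g_old).max() / np.abs(g_old).max(),
                np.abs(d_new - d_old).max() / np.abs(d_old).max(),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        gamma_star[:, i] = g_old
        delta_star[:, i] = d_old

    adjusted = s_data.copy()
    for i, cols in enumerate(batch_cols):
        adjusted[:, cols] = (adjusted[:, cols] - gamma_star[:, i : i + 1]) / np.sqrt(
            delta_star[:, i : i + 1]
        )
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    adjusted[degenerate] = X[degenerate]

    out = ExpressionSet(
        pd.DataFrame(adjusted, index=eset.gene_ids, columns=eset.sample_ids),
        eset.metadata.copy(),
    )
    if not return_model:
        return out
    idx = eset.gene_ids
    model = BatchModel(
        gamma=pd.DataFrame(gamma_star, index=idx, columns=batches),
        delta=pd.DataFrame(np.maximum(delta_star, 1e-12), index=idx, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2=pd.Series(tau2, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
    )
    return out, model


@dataclass
class GeneScaler:
    """Per-gene centering/scaling parameters, reusable on new samples.

    Deployment contract: a new sample is restricted to the training gene
    list, centered with the stored per-gene means and divided by the stored
    per-gene standard deviations.
    """

    means: pd.Series
    sds: pd.Series  # sample sd (ddof=1); zero-variance genes stored as 0

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        if not values.index.equals(self.means.index):
            raise ScalingError("gene list does not match the fitted scaler")
        safe_sd = self.sds.replace(0.0, 1.0)
        return values.sub(self.means, axis=0).div(safe_sd, axis=0)


def center_scale(eset: ExpressionSet) -> tuple[ExpressionSet, GeneScaler]:
    """Gene-wise centering and scaling to unit sample variance.

    Zero-variance genes are mapped to all-zeros with a warning rather than
    raising: degradation and gene-subsetting can legitimately create
    constant genes and the pipeline must not abort on them.
    """
    if eset.n_samples < 2:
        raise ScalingError("centering/scaling needs at least 2 samples")
    means = eset.values.mean(axis=1)
    sds = eset.values.std(axis=1, ddof=1)
    n_zero = int((sds == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-variance gene(s) scaled to all-zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    scaler = GeneScaler(means=means, sds=sds)
    return ExpressionSet(scaler.transform(eset.values), eset.metadata.copy()), scaler
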