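"""Gene-wise differential expression (sepsis vs the non-septic entity) and
hierarchical clustering of samples on the differential genes.

The default per-gene statistic is the ordinary pooled-variance two-sample t
(the two-group linear model); an optional empirical-Bayes moderation shrinks
the per-gene variances toward a common prior value with moment-matched
hyperparameters, the standard variance-moderation used for microarray linear
models.  Multiple testing is controlled by Benjamini-Hochberg step-up, and a
gene is called differential when |logFC| >= logfc_threshold and the adjusted
p-value is below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionSet
from .simulate import consolidate_labels

__all__ = [
    "ContrastError",
    "ClusteringError",
    "differential_expression",
    "ClusteringResult",
    "hierarchical_cluster",
]

POSITIVE_CLASS = "sepsis"


class ContrastError(ValueError):
    pass


class ClusteringError(ValueError):
    pass


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Shrink per-gene sample variances toward a common value.

    Moment-matches a scaled-F prior on the variances via the distribution of
    log(s2): returns the posterior variances and the prior degrees of freedom
    d0 (np.inf when the observed spread is no larger than expected by chance,
    in which case all variances collapse to the common value).
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_var = np.var(e, ddof=1) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
        post = np.full_like(s2, s0_2)
        post[~ok] = s0_2
        return post, d0
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def differential_expression(
    eset: ExpressionSet,
    labels: pd.Series | None = None,
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
    moderation: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group differential expression with BH correction.

    Parameters
    ----------
    labels : binary per-sample labels ('sepsis' vs 'non-sepsis'); defaults to
        consolidating the metadata class column.  logFC is the sepsis mean
        minus the non-sepsis mean on the (log2-scale) expression values.
    moderation : apply empirical-Bayes variance moderation instead of the
        plain pooled-variance t statistic.

    Returns
    -------
    DataFrame indexed by gene with columns logFC, t_stat, p_raw, p_adj,
    is_de; is_de is True iff |logFC| >= logfc_threshold and p_adj < alpha.
    """
    if labels is None:
        labels = consolidate_labels(eset.metadata)
    labels = pd.Series(labels, index=eset.sample_ids)
    classes = labels.unique()
    if len(classes) != 2 or POSITIVE_CLASS not in classes:
        raise ContrastError(
            f"need exactly two classes including '{POSITIVE_CLASS}', got {list(classes)}"
        )
    pos = (labels == POSITIVE_CLASS).to_numpy()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ContrastError("each class needs at least 2 samples")

    X = eset.values.to_numpy(dtype=float)
    m1 = X[:, pos].mean(axis=1)
    m0 = X[:, ~pos].mean(axis=1)
    logfc = m1 - m0
    ss1 = X[:, pos].var(axis=1, ddof=1) * (n1 - 1)
    ss0 = X[:, ~pos].var(axis=1, ddof=1) * (n0 - 1)
    df = n1 + n0 - 2
    s2 = (ss1 + ss0) / df

    zero_var = s2 <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s): p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n0)
    if moderation:
        s2_post, d0 = _moderate_variances(s2, df)
        df_total = df + d0 if np.isfinite(d0) else np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (np.sqrt(s2_post) * se_factor)
        dist = stats.t(df_total) if np.isfinite(df_total) else stats.norm()
        p = 2.0 * dist.sf(np.abs(t))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (np.sqrt(s2) * se_factor)
        p = 2.0 * stats.t(df).sf(np.abs(t))

    t = np.where(zero_var & (logfc == 0), 0.0, t)
    p = np.where(zero_var, 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    is_de = (np.abs(logfc) >= logfc_threshold) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_stat": t,
            "p_raw": p,
            "p_adj": p_adj,
            "is_de": is_de,
        },
        index=eset.gene_ids,
    )


@dataclass
class ClusteringResult:
    """Ward dendrogram of samples plus the cut at k clusters."""

    linkage_matrix: np.ndarray  # scipy hierarchical linkage encoding
    assignments: pd.Series  # cluster id (1..k) per sample
    composition: pd.DataFrame  # cluster x {sepsis, non-sepsis} sample counts

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hierarchical_cluster(
    eset: ExpressionSet,
    genes,
    k: int = 3,
    labels: pd.Series | None = None,
) -> ClusteringResult:
    """Agglomerative clustering of samples on a differential gene set.

    Euclidean distances between samples restricted to ``genes``; Ward
    linkage in the ward.D2 convention (unsquared Euclidean input, squared
    within the Lance-Williams update); tree cut at ``k`` clusters; the
    per-cluster composition counts sepsis vs non-sepsis samples.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ClusteringError("empty gene set")
    if k < 1 or k > eset.n_samples:
        raise ClusteringError(f"k={k} outside [1, {eset.n_samples}]")
    sub = eset.subset_genes(genes)
    obs = sub.values.to_numpy(dtype=float).T  # samples x genes
    Z = linkage(obs, method="ward", metric="euclidean")
    assign = fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(assign, index=eset.sample_ids, name="cluster")
    if labels is None:
        labels = consolidate_labels(eset.metadata)
    labels = pd.Series(labels, index=eset.sample_ids)
    composition = (
        pd.crosstab(assignments, labels)
        .reindex(columns=["sepsis", "non-sepsis"], fill_value=0)
        .rename_axis(index="cluster", columns=None)
    )
    return ClusteringResult(Z, assignments, composition)
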