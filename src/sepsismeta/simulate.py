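"""Synthetic multi-study microarray meta-expression generator.

Emulates a collection of whole-blood microarray studies of sepsis patients,
healthy controls, SIRS and trauma patients, with known ground truth, so the
full merge / batch-adjust / differential-expression / classification pipeline
is testable without any repository download.

The generative model per study ``b`` follows the location-scale batch model
that empirical-Bayes batch adjustment assumes:

    y_gj = mu_g + effect_g(class_j) + gamma_gb + delta_gb * eps_gj

* ``mu_g`` — gene baseline, drawn once per gene from N(baseline_mean,
  baseline_sd^2); defaults (8, 2) put values on a typical normalized
  log2-intensity scale.
* ``effect_g(class)`` — sepsis samples receive ``de_logfc`` on the planted
  strongly differential genes and ``weak_logfc`` on a second tier of weakly
  informative genes (sub-threshold effects that a |logFC| cutoff will not
  flag but that still carry class signal, as real transcriptomes do).
  Trauma and SIRS samples receive a configurable partial effect on a
  configurable overlap of the strong genes, emulating their transcriptional
  similarity to sepsis.  A configurable fraction of sepsis patients are
  attenuated responders expressing only part of the effect — the
  hard-to-classify subpopulation that sample clustering on real collections
  exposes as a mixed subgroup.
* ``gamma_gb`` ~ N(0, batch_location_sd^2) — additive per-study batch offset.
* ``delta_gb = exp(N(0, batch_scale_sd^2))`` — multiplicative per-study
  noise-scale factor, strictly positive.
* ``eps_gj`` ~ N(0, noise_sd^2) i.i.d. measurement noise.
* in addition, genes belong to co-expression modules: each sample draws a
  latent activity per module and every module gene adds ``module_loading``
  times its module's activity (with a random sign per gene).  The strongly
  differential genes are concentrated in a few modules (the sepsis response
  is a handful of co-regulated programs — inflammation, interferon,
  coagulation — not hundreds of independent markers), the remaining null
  genes spread over the other modules, and the weak tier stays diffuse and
  independent.  This reproduces the correlated, low-effective-dimension
  structure of real transcriptomes, without which every classifier sits at
  a ceiling and acquires unrealistic noise immunity.

Each study measures a platform-specific gene panel: a common core shared by
all platforms plus platform-private genes; merged analysis is limited to the
core (the least common denominator of genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import VALID_CLASSES, ExpressionSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "InvalidConfigError",
    "LabelError",
    "generate_meta_expression",
    "consolidate_labels",
    "default_fixture_config",
]


class InvalidConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


class LabelError(ValueError):
    """Raised when a sample carries an unknown class label."""


#: class composition of the real collection: 1,354 sepsis, 457 healthy,
#: 86 SIRS, 520 trauma out of 2,417 samples
DEFAULT_CLASS_PROPORTIONS: Mapping[str, float] = {
    "sepsis": 1354 / 2417,
    "healthy": 457 / 2417,
    "SIRS": 86 / 2417,
    "trauma": 520 / 2417,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic meta-expression collection.

    ``samples_per_study`` may be a single count, a (low, high) inclusive
    range sampled uniformly per study, or an explicit per-study list.
    """

    n_studies: int = 6
    samples_per_study: int | tuple[int, int] | Sequence[int] = (140, 200)
    n_genes_per_platform: int = 2500
    common_gene_fraction: float = 0.8
    n_de_genes: int = 800
    de_logfc: float = 2.0
    n_weak_genes: int = 400
    weak_logfc: float = 0.5
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    overlap_fraction: float = 0.5  # fraction of strong DE genes shared by trauma/SIRS
    overlap_effect_fraction: float = 0.3  # their effect relative to de_logfc
    n_modules: int = 25  # co-expression modules (0 disables)
    n_de_modules: int = 5  # modules hosting the strong DE genes
    module_loading: float = 0.35  # per-gene loading on its module's activity
    attenuated_fraction: float = 0.2  # sepsis samples with a damped response
    attenuated_effect: float = 0.2  # their strong-program effect multiplier
    batch_location_sd: float = 0.3
    batch_scale_sd: float = 0.15
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise InvalidConfigError("n_studies must be >= 1")
        if self.n_genes_per_platform < 1:
            raise InvalidConfigError("n_genes_per_platform must be >= 1")
        for n in self._study_size_bounds():
            if n < 1:
                raise InvalidConfigError("sample counts must be positive")
        if not 0.0 < self.common_gene_fraction <= 1.0:
            raise InvalidConfigError("common_gene_fraction must be in (0, 1]")
        n_common = self.n_common_genes
        if self.n_de_genes < 0 or self.n_de_genes + self.n_weak_genes > n_common:
            raise InvalidConfigError(
                f"n_de_genes + n_weak_genes must fit in the {n_common} common genes"
            )
        props = dict(self.class_proportions)
        unknown = set(props) - set(VALID_CLASSES)
        if unknown:
            raise InvalidConfigError(f"unknown classes in proportions: {unknown}")
        if any(not 0.0 <= p <= 1.0 for p in props.values()):
            raise InvalidConfigError("class proportions must lie in [0, 1]")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("class proportions must sum to 1")
        for name in ("batch_location_sd", "batch_scale_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise InvalidConfigError("overlap_fraction must be in [0, 1]")
        if self.n_modules < 0 or self.module_loading < 0:
            raise InvalidConfigError("n_modules and module_loading must be >= 0")
        if self.n_modules > 0 and not 0 <= self.n_de_modules <= self.n_modules:
            raise InvalidConfigError("n_de_modules must be in [0, n_modules]")
        if not 0.0 <= self.attenuated_fraction <= 1.0:
            raise InvalidConfigError("attenuated_fraction must be in [0, 1]")
        if not 0.0 <= self.attenuated_effect <= 1.0:
            raise InvalidConfigError("attenuated_effect must be in [0, 1]")

    def _study_size_bounds(self) -> tuple[int, ...]:
        s = self.samples_per_study
        if isinstance(s, int):
            return (s,)
        return tuple(int(v) for v in s)

    @property
    def n_common_genes(self) -> int:
        return int(round(self.common_gene_fraction * self.n_genes_per_platform))


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    de_gene_ids: list[str]
    weak_gene_ids: list[str]
    common_gene_ids: list[str]
    batch_location: pd.DataFrame  # genes x studies additive offsets
    batch_scale: pd.DataFrame  # genes x studies positive scale factors
    classes: pd.Series  # true class per sample id

    def __post_init__(self) -> None:
        if (self.batch_scale.to_numpy() <= 0).any():
            raise ValueError("batch scale factors must be strictly positive")


def _study_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    s = config.samples_per_study
    if isinstance(s, int):
        return [s] * config.n_studies
    s = list(s)
    if len(s) == 2 and config.n_studies != 2:
        lo, hi = int(s[0]), int(s[1])
        return [int(rng.integers(lo, hi + 1)) for _ in range(config.n_studies)]
    if len(s) != config.n_studies:
        raise InvalidConfigError(
            "samples_per_study list length must equal n_studies"
        )
    return [int(v) for v in s]


def _class_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n samples to classes."""
    names = [c for c in VALID_CLASSES if c in proportions]
    raw = np.array([proportions[c] * n for c in names])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def generate_meta_expression(
    config: SimulationConfig,
) -> tuple[list[ExpressionSet], GroundTruth]:
    """Simulate the per-study expression sets plus ground truth.

    Deterministic for a fixed config (including seed): two calls with the
    same config return bit-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    n_common = config.n_common_genes
    n_extra_per_platform = config.n_genes_per_platform - n_common
    # gene universe: common core plus a pool of platform-private genes
    n_pool = max(2 * n_extra_per_platform, 1) * config.n_studies
    n_universe = n_common + n_pool
    width = len(str(n_universe))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, n_universe + 1)])
    common_genes = gene_ids[:n_common]
    pool_genes = gene_ids[n_common:]

    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, n_universe),
        index=gene_ids,
    )

    de_idx = rng.choice(n_common, size=config.n_de_genes, replace=False)
    remaining = np.setdiff1d(np.arange(n_common), de_idx)
    weak_idx = rng.choice(remaining, size=config.n_weak_genes, replace=False)
    de_genes = common_genes[np.sort(de_idx)]
    weak_genes = common_genes[np.sort(weak_idx)]
    n_overlap = int(round(config.overlap_fraction * len(de_genes)))
    overlap_genes = de_genes[
        np.sort(rng.choice(len(de_genes), size=n_overlap, replace=False))
    ]

    # per-gene class effect columns over the whole universe
    effect = pd.DataFrame(0.0, index=gene_ids, columns=list(VALID_CLASSES))
    effect.loc[de_genes, "sepsis"] += config.de_logfc
    effect.loc[weak_genes, "sepsis"] += config.weak_logfc
    partial = config.de_logfc * config.overlap_effect_fraction
    effect.loc[overlap_genes, "SIRS"] += partial
    effect.loc[overlap_genes, "trauma"] += partial

    # co-expression module structure: module id and signed loading per gene;
    # strong DE genes share the first n_de_modules modules, null genes spread
    # over the rest, the weak tier stays independent (loading 0)
    if config.n_modules > 0 and config.module_loading > 0:
        module_of = rng.integers(0, config.n_modules, size=n_universe)
        loading = config.module_loading * rng.choice([-1.0, 1.0], size=n_universe)
        de_pos = np.searchsorted(gene_ids, de_genes)
        weak_pos = np.searchsorted(gene_ids, weak_genes)
        if config.n_de_modules > 0:
            module_of[de_pos] = rng.integers(0, config.n_de_modules, size=len(de_pos))
            others = np.setdiff1d(np.arange(n_universe), np.concatenate([de_pos, weak_pos]))
            if config.n_de_modules < config.n_modules:
                module_of[others] = rng.integers(
                    config.n_de_modules, config.n_modules, size=len(others)
                )
        loading[weak_pos] = 0.0
    else:
        module_of = loading = None

    sizes = _study_sizes(config, rng)
    studies = [f"study{i + 1:02d}" for i in range(config.n_studies)]

    # platform-private genes: disjoint slices of a shuffled pool, so the
    # intersection of all panels is exactly the common core
    pool_order = rng.permutation(pool_genes)

    batch_loc = pd.DataFrame(
        rng.normal(0.0, config.batch_location_sd, (n_universe, config.n_studies)),
        index=gene_ids,
        columns=studies,
    )
    batch_scale = pd.DataFrame(
        np.exp(rng.normal(0.0, config.batch_scale_sd, (n_universe, config.n_studies))),
        index=gene_ids,
        columns=studies,
    )

    sets: list[ExpressionSet] = []
    all_classes: list[pd.Series] = []
    for s, (study, n) in enumerate(zip(studies, sizes)):
        platform = f"P{s + 1:02d}"
        if n_extra_per_platform > 0:
            extra = pool_order[s * n_extra_per_platform : (s + 1) * n_extra_per_platform]
            panel = np.concatenate([common_genes, extra])
        else:
            panel = common_genes.copy()
        panel = np.sort(panel)

        counts = _class_counts(n, config.class_proportions)
        labels = np.repeat(
            [c for c in counts], [counts[c] for c in counts]
        )
        rng.shuffle(labels)
        sample_ids = [f"{study}_S{j + 1:04d}" for j in range(n)]

        mu = baseline.loc[panel].to_numpy()[:, None]
        eff = effect.loc[panel, labels].to_numpy()
        # attenuated sepsis responders damp the strong co-regulated programs
        # while the diffuse weak signature persists
        damped = (labels == "sepsis") & (
            rng.random(n) < config.attenuated_fraction
        )
        strong_in_panel = np.isin(panel, de_genes)
        eff[np.ix_(strong_in_panel, damped)] *= config.attenuated_effect
        gamma = batch_loc.loc[panel, study].to_numpy()[:, None]
        delta = batch_scale.loc[panel, study].to_numpy()[:, None]
        noise = rng.normal(0.0, config.noise_sd, (len(panel), n))
        mat = mu + eff + gamma + delta * noise
        if module_of is not None:
            pos = np.searchsorted(gene_ids, panel)  # gene ids are sorted
            activity = rng.normal(0.0, 1.0, (config.n_modules, n))
            mat = mat + loading[pos, None] * activity[module_of[pos]]
        values = pd.DataFrame(mat, index=panel, columns=sample_ids)
        meta = pd.DataFrame(
            {"class": labels, "study": study, "platform": platform},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        sets.append(ExpressionSet(values, meta))
        all_classes.append(meta["class"])

    truth = GroundTruth(
        de_gene_ids=list(de_genes),
        weak_gene_ids=list(weak_genes),
        common_gene_ids=list(common_genes),
        batch_location=batch_loc,
        batch_scale=batch_scale,
        classes=pd.concat(all_classes),
    )
    return sets, truth


def consolidate_labels(metadata) -> pd.Series:
    """Collapse {sepsis, healthy, SIRS, trauma} to {sepsis, non-sepsis}.

    Healthy controls, SIRS and trauma patients form one composite non-septic
    entity, harmonizing the sample numbers of the two classification classes.

    Accepts a metadata DataFrame with a ``class`` column or a Series of
    labels; returns a Series of binary labels aligned to the input.
    """
    labels = metadata["class"] if isinstance(metadata, pd.DataFrame) else metadata
    labels = pd.Series(labels)
    unknown = set(labels.unique()) - set(VALID_CLASSES)
    if unknown:
        raise LabelError(f"unknown class label(s): {sorted(map(str, unknown))}")
    return labels.map(lambda c: "sepsis" if c == "sepsis" else "non-sepsis").rename(
        "label"
    )


def default_fixture_config(seed: int = 7) -> SimulationConfig:
    """The packaged synthetic fixture: ~1,000 samples x 2,000 merged genes,
    ~56/44 sepsis/non-sepsis split, 40% of the merged genes strongly
    differential, plus a weakly informative tier."""
    return SimulationConfig(seed=seed)
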