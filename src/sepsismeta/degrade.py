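"""Three cumulative levels of artificial test-data degradation.

Applied to test samples only (training data is never touched):

1. additive uniform noise on every expression value of every test sample,
   with the amplitude rule of the R base routine ``jitter`` at a given
   factor (the study value is 10,000);
2. randomized zero-replacement of a fixed fraction of the genes (75%
   removed, i.e. 25% retained — 1,483 of 5,932 genes), one shared gene mask
   per run;
3. replacement of a fixed fraction of ALL genes (50% — 2,966 of 5,932),
   hitting real and zero-replaced values alike, by independent normal draws
   with mean = the gene's median over the current test matrix and a fixed
   standard deviation (study value 20).

Level k always means the composition of levels 1..k; sub-seeds for the
three levels are derived independently from the run seed, so the level-2
mask does not depend on whether level 3 is applied afterwards.

Amplitude semantics of ``jitter`` (amount left at its default): with
``z = range(x)`` the values are rounded to ``3 - floor(log10(z))`` digits
and the amplitude is ``factor/5 * d`` where ``d`` is the smallest spacing
between the unique rounded values; a constant vector falls back to
``|x|/10`` (then ``z/10``).  On dense centered/scaled expression vectors
with range below 10 this gives half-width ``factor/5 * 0.001`` — 2.0 in
z-score units at the study's factor of 10,000.  The range-based rule
``factor * z/50`` (what ``jitter`` uses when ``amount=0`` is passed
explicitly) is available as ``amount_rule='range'``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DegradationConfig",
    "DegradationError",
    "jitter_amount",
    "degrade_level1",
    "degrade_level2",
    "degrade_level3",
    "degrade",
    "LEVELS",
]

LEVELS = (0, 1, 2, 3)  # 0 = native (untouched)


class DegradationError(ValueError):
    pass


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the cumulative degradation protocol (study defaults)."""

    jitter_factor: float = 10_000.0
    retain_fraction: float = 0.25
    replace_fraction: float = 0.5
    replace_sd: float = 20.0
    seed: int = 0
    amount_rule: Literal["min_spacing", "range"] = "min_spacing"
    shared_mask: bool = True  # one level-2 gene mask for all test samples
    median_basis: Literal["degraded", "native"] = "degraded"

    def validate(self) -> None:
        if self.jitter_factor < 0:
            raise DegradationError("jitter_factor must be >= 0")
        for name in ("retain_fraction", "replace_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DegradationError(f"{name} must be in [0, 1]")
        if self.replace_sd <= 0:
            raise DegradationError("replace_sd must be > 0")


def jitter_amount(x: np.ndarray, factor: float, rule: str = "min_spacing") -> float:
    """Noise half-width for one vector, per the cited routine's default."""
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    z = float(finite.max() - finite.min())
    if z == 0:
        z = abs(float(finite[0]))
    if z == 0:
        z = 1.0
    if rule == "range":
        return factor * z / 50.0
    digits = 3 - int(np.floor(np.log10(z)))
    xx = np.unique(np.round(x, digits))
    if len(xx) > 1:
        d = float(np.diff(xx).min())
    elif xx[0] != 0:
        d = abs(float(xx[0])) / 10.0
    else:
        d = z / 10.0
    return factor / 5.0 * d


def degrade_level1(
    X: pd.DataFrame,
    jitter_factor: float,
    seed,
    amount_rule: str = "min_spacing",
) -> pd.DataFrame:
    """Add i.i.d. uniform noise to every value, per test sample (row)."""
    if jitter_factor < 0:
        raise DegradationError("jitter_factor must be >= 0")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DegradationError("input contains non-finite values")
    rng = np.random.default_rng(seed)
    out = values.copy()
    for i in range(values.shape[0]):
        a = jitter_amount(values[i], jitter_factor, amount_rule)
        out[i] += rng.uniform(-a, a, size=values.shape[1])
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def degrade_level2(
    X: pd.DataFrame,
    retain_fraction: float,
    seed,
    shared_mask: bool = True,
) -> pd.DataFrame:
    """Zero-replace all but floor(retain_fraction * G) genes.

    The retained gene subset is drawn uniformly without replacement once per
    run and applied to every test sample (a single shared mask); per-sample
    masks are available for sensitivity analyses.
    """
    if not 0.0 <= retain_fraction <= 1.0:
        raise DegradationError("retain_fraction must be in [0, 1]")
    G = X.shape[1]
    n_retain = int(np.floor(retain_fraction * G))
    rng = np.random.default_rng(seed)
    out = X.to_numpy(dtype=float).copy()
    if shared_mask:
        retained = rng.choice(G, size=n_retain, replace=False)
        mask = np.zeros(G, dtype=bool)
        mask[retained] = True
        out[:, ~mask] = 0.0
    else:
        for i in range(out.shape[0]):
            retained = rng.choice(G, size=n_retain, replace=False)
            mask = np.zeros(G, dtype=bool)
            mask[retained] = True
            out[i, ~mask] = 0.0
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def degrade_level3(
    X: pd.DataFrame,
    replace_fraction: float,
    replace_sd: float,
    seed,
    medians: pd.Series | None = None,
) -> pd.DataFrame:
    """Replace floor(replace_fraction * G) genes by simulated values.

    Genes are drawn uniformly from ALL genes, overwriting real and
    zero-replaced values alike.  Each selected gene is refilled with
    independent N(median, replace_sd^2) draws, the median taken over the
    current test matrix unless precomputed medians are supplied.
    """
    if not 0.0 <= replace_fraction <= 1.0:
        raise DegradationError("replace_fraction must be in [0, 1]")
    if replace_sd <= 0:
        raise DegradationError("replace_sd must be > 0")
    if X.shape[0] < 1:
        raise DegradationError("need at least one test sample")
    G = X.shape[1]
    n_replace = int(np.floor(replace_fraction * G))
    rng = np.random.default_rng(seed)
    selected = rng.choice(G, size=n_replace, replace=False)
    if medians is None:
        med = X.median(axis=0).to_numpy()
    else:
        med = medians.loc[X.columns].to_numpy(dtype=float)
    out = X.to_numpy(dtype=float).copy()
    for g in selected:
        out[:, g] = rng.normal(med[g], replace_sd, size=X.shape[0])
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def _sub_seeds(seed: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(3)


def degrade(
    X: pd.DataFrame,
    level: int,
    config: DegradationConfig,
    return_provenance: bool = False,
):
    """Apply cumulative degradation up to ``level`` (0 = native copy).

    The three levels consume independent sub-seeds derived from
    ``config.seed``, so applying level k reproduces the composition of the
    first k operators bit-exactly regardless of the highest level requested.
    """
    if level not in LEVELS:
        raise DegradationError(f"level must be one of {LEVELS}")
    config.validate()
    s1, s2, s3 = _sub_seeds(config.seed)
    prov = {
        "seed": config.seed,
        "level": level,
        "jitter_factor": config.jitter_factor,
        "retain_fraction": config.retain_fraction,
        "replace_fraction": config.replace_fraction,
        "replace_sd": config.replace_sd,
    }
    out = X.copy()
    if level >= 1:
        out = degrade_level1(out, config.jitter_factor, s1, config.amount_rule)
    if level >= 2:
        out = degrade_level2(out, config.retain_fraction, s2, config.shared_mask)
    if level >= 3:
        medians = X.median(axis=0) if config.median_basis == "native" else None
        out = degrade_level3(
            out, config.replace_fraction, config.replace_sd, s3, medians=medians
        )
    if return_provenance:
        return out, prov
    return out


def write_provenance(prov: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(prov, fh, indent=2)
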