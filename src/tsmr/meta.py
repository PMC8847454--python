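"""Inverse-variance meta-analysis of study-level effects with subgroups.

Pools log hazard/odds ratios across cohort studies, stratified by a
subgroup label (here: ancestry), under either a fixed-effect model or a
DerSimonian-Laird random-effects model.  Study inputs are taken as a
point estimate with a symmetric 95% CI on the ratio scale; the log-scale
SE is recovered as (log upper - log lower) / (2 x 1.96).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimators import Z95, _two_sided_p

__all__ = ["StudyEffect", "MetaResult", "meta_pool", "read_study_table", "meta_table"]


@dataclass(frozen=True)
class StudyEffect:
    """One cohort's reported effect on the log scale."""

    study_label: str
    subgroup: str
    log_effect: float
    se_log: float
    effect_scale: str = "HR"

    def __post_init__(self) -> None:
        if not (self.se_log > 0):
            raise ValueError(f"{self.study_label}: se_log must be positive")

    @classmethod
    def from_ci(
        cls,
        study_label: str,
        subgroup: str,
        effect: float,
        ci_low: float,
        ci_high: float,
        effect_scale: str = "HR",
    ) -> "StudyEffect":
        """Build from a ratio-scale estimate and its 95% CI."""
        if not (0.0 < ci_low <= effect <= ci_high):
            raise ValueError(
                f"{study_label}: CI ({ci_low}, {ci_high}) must bracket {effect}"
            )
        se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
        return cls(study_label, subgroup, math.log(effect), se, effect_scale)


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one subgroup."""

    subgroup: str
    model: str
    pooled_log_effect: float
    se: float
    q_stat: float
    tau2: float
    k_studies: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pooled_effect: float = field(init=False)
    pvalue: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ci_low", self.pooled_log_effect - Z95 * self.se)
        object.__setattr__(self, "ci_high", self.pooled_log_effect + Z95 * self.se)
        object.__setattr__(self, "pooled_effect", math.exp(self.pooled_log_effect))
        object.__setattr__(
            self, "pvalue", _two_sided_p(self.pooled_log_effect / self.se)
        )


def _pool_one(studies: Sequence[StudyEffect], model: str) -> MetaResult:
    y = np.array([s.log_effect for s in studies])
    v = np.array([s.se_log ** 2 for s in studies])
    w = 1.0 / v
    k = y.size
    mu_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - mu_fixed) ** 2).sum())
    tau2 = 0.0
    if model == "random":
        if k < 2:
            warnings.warn(
                f"subgroup {studies[0].subgroup!r}: single study, "
                "random-effects model falls back to fixed",
                stacklevel=3,
            )
            model = "fixed"
        else:
            c = w.sum() - (w ** 2).sum() / w.sum()
            tau2 = max(0.0, (q - (k - 1)) / c)
    if model == "fixed" or tau2 == 0.0:
        w_star = w
    else:
        w_star = 1.0 / (v + tau2)
    mu = float((w_star * y).sum() / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    return MetaResult(studies[0].subgroup, model, mu, se, q, tau2, k)


def meta_pool(
    studies: Iterable[StudyEffect], model: str = "random"
) -> list[MetaResult]:
    """Pool study effects within each subgroup.

    ``model='fixed'`` uses weights se^-2; ``model='random'`` uses
    DerSimonian-Laird: tau^2 = max(0, (Q - (k-1)) / (Sum w - Sum w^2 /
    Sum w)) with Q computed under fixed weights, then weights
    (se^2 + tau^2)^-1.  A single-study subgroup under the random model
    falls back to fixed with a warning.  Results are returned in order
    of first appearance of each subgroup.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    groups: dict[str, list[StudyEffect]] = {}
    for s in studies:
        groups.setdefault(s.subgroup, []).append(s)
    if not groups:
        raise ValueError("no studies supplied")
    return [_pool_one(g, model) for g in groups.values()]


def read_study_table(path: str | Path) -> list[StudyEffect]:
    """Read a study table TSV: study, subgroup, effect, ci_low, ci_high, scale."""
    df = pd.read_csv(path, sep="\t")
    required = {"study", "subgroup", "effect", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"study table missing columns: {sorted(missing)}")
    return [
        StudyEffect.from_ci(
            str(r.study),
            str(r.subgroup),
            float(r.effect),
            float(r.ci_low),
            float(r.ci_high),
            str(getattr(r, "scale", "HR")),
        )
        for r in df.itertuples(index=False)
    ]


def meta_table(results: Sequence[MetaResult]) -> pd.DataFrame:
    """Flatten pooled results to a table (one row per subgroup)."""
    return pd.DataFrame(
        {
            "subgroup": [r.subgroup for r in results],
            "model": [r.model for r in results],
            "k_studies": [r.k_studies for r in results],
            "pooled_effect": [r.pooled_effect for r in results],
            "ci_low": [math.exp(r.ci_low) for r in results],
            "ci_high": [math.exp(r.ci_high) for r in results],
            "pooled_log_effect": [r.pooled_log_effect for r in results],
            "se_log": [r.se for r in results],
            "q_stat": [r.q_stat for r in results],
            "tau2": [r.tau2 for r in results],
            "pvalue": [r.pvalue for r in results],
        }
    )
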