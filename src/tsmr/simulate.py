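"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical regime of a summary-data MR study
of a metabolic exposure (type-2-diabetes liability, per 1 SD) on a binary
neurological outcome (log-odds): J independent clumped instruments with
per-variant exposure effects gamma_j scaled to a target variance
explained, a linear causal effect theta on the outcome log-odds, an
optional mixture of pleiotropic direct effects alpha_j (balanced or
directional; drawn independently of gamma_j when the InSIDE assumption is
imposed), and independent sampling noise in the two non-overlapping
samples:

    gamma_hat_j ~ N(gamma_j, sigma_Xj^2),
    Gamma_hat_j ~ N(theta * gamma_j + alpha_j, sigma_Yj^2),
    sigma_{.j}  = [2 p_j (1 - p_j) n]^{-1/2}.

The default configuration reproduces the scale of a European T2D -> ALS
analysis: 139 instruments explaining 19.6% of exposure variance in a
discovery sample of 659,316, an outcome sample of 80,610, and a true
odds ratio of 0.96 per SD.

True per-variant effects are oriented so gamma_j >= 0 with the effect
allele defined as the exposure-increasing allele; directional pleiotropy
is defined relative to that orientation (random allele relabelling would
otherwise cancel any directional component).  Emitted tables scramble
allele labels, strands and orientations to exercise harmonization;
harmonizing them recovers the unscrambled effects exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    Z95,
    _egger_point,
    _ivw_point,
    _weighted_median_point,
    _weighted_median_rows,
)

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample", "recovery_experiment"]

# non-palindromic allele pairs used for random labelling
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic two-sample MR dataset.

    Defaults are the European-scale study conditions; ``theta`` is the
    causal log-odds of outcome per SD of exposure, ``pleio_fraction`` the
    proportion of invalid instruments whose direct effects are drawn
    N(pleio_mean, pleio_sd^2).  ``inside=True`` draws those effects
    independently of instrument strength (the InSIDE assumption).
    """

    j_snps: int = 139
    n_exposure: int = 659_316
    n_outcome: int = 80_610
    maf_range: tuple[float, float] = (0.05, 0.5)
    r2_target: float = 0.196
    theta: float = math.log(0.96)
    pleio_fraction: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    inside: bool = True
    palindromic_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pleio_fraction <= 1.0):
            raise ValueError("pleio_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.r2_target < 1.0):
            raise ValueError("r2_target must lie in (0, 1)")
        if self.j_snps < 1:
            raise ValueError("need at least one instrument")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    config: SimConfig
    maf: np.ndarray
    true_gammas: np.ndarray
    true_alphas: np.ndarray
    theta: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "maf": self.maf.tolist(),
            "true_gammas": self.true_gammas.tolist(),
            "true_alphas": self.true_alphas.tolist(),
            "theta": self.theta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_truth(config: SimConfig, rng: np.random.Generator):
    """Draw MAFs and true effects; gamma rescaled so the variance explained
    Sum 2 p (1-p) gamma^2 hits r2_target exactly (exposure on the SD scale)."""
    J = config.j_snps
    p = rng.uniform(*config.maf_range, size=J)
    var_geno = 2.0 * p * (1.0 - p)
    gamma = np.abs(rng.standard_normal(J))  # oriented: effect allele increases exposure
    gamma *= math.sqrt(config.r2_target / float(var_geno @ (gamma * gamma)))
    alpha = np.zeros(J)
    invalid = rng.random(J) < config.pleio_fraction
    n_inv = int(invalid.sum())
    if n_inv:
        alpha[invalid] = rng.normal(config.pleio_mean, config.pleio_sd, size=n_inv)
        if not config.inside:
            # correlate direct effects with instrument strength (InSIDE broken)
            alpha[invalid] += 0.5 * config.pleio_sd * (
                gamma[invalid] / gamma[invalid].mean() - 1.0
            )
    return p, gamma, alpha


def _observe(config: SimConfig, rng: np.random.Generator, p, gamma, alpha):
    sx = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * config.n_exposure)
    sy = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * config.n_outcome)
    g_hat = gamma + rng.standard_normal(gamma.size) * sx
    G_hat = config.theta * gamma + alpha + rng.standard_normal(gamma.size) * sy
    return g_hat, sx, G_hat, sy


def simulate_two_sample(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate exposure and outcome summary tables plus the ground truth.

    Both tables follow the standard schema (snp, effect_allele,
    other_allele, eaf, beta, se, pval, n).  Allele pairs are assigned at
    random (non-palindromic unless ``palindromic_labels``), and each
    table's orientation is independently scrambled: a variant may report
    the other allele as effect allele (sign and frequency reflected) and
    the outcome may additionally report the complement strand.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p, gamma, alpha = _draw_truth(config, rng)
    g_hat, sx, G_hat, sy = _observe(config, rng, p, gamma, alpha)
    J = config.j_snps

    snps = [f"rs{1_000_001 + 17 * i}" for i in range(J)]
    pairs = _ALLELE_PAIRS + (_PALINDROMIC_PAIRS if config.palindromic_labels else [])
    pair_idx = rng.integers(0, len(pairs), size=J)
    ea = np.array([pairs[i][0] for i in pair_idx])
    oa = np.array([pairs[i][1] for i in pair_idx])

    def table(beta, se, n, flip_mask, strand_mask):
        eff, oth = ea.copy(), oa.copy()
        eaf = p.copy()
        b = beta.copy()
        eff[flip_mask], oth[flip_mask] = oth[flip_mask], eff[flip_mask]
        b[flip_mask] = -b[flip_mask]
        eaf[flip_mask] = 1.0 - eaf[flip_mask]
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        eff[strand_mask] = [comp[a] for a in eff[strand_mask]]
        oth[strand_mask] = [comp[a] for a in oth[strand_mask]]
        return pd.DataFrame(
            {
                "snp": snps,
                "effect_allele": eff,
                "other_allele": oth,
                "eaf": eaf,
                "beta": b,
                "se": se,
                # floored to keep extreme associations representable in (0, 1]
                "pval": np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0),
                "n": n,
            }
        )

    exp_flip = rng.random(J) < 0.5
    out_flip = rng.random(J) < 0.5
    out_strand = rng.random(J) < 0.5
    exposure = table(g_hat, sx, config.n_exposure, exp_flip, np.zeros(J, bool))
    outcome = table(G_hat, sy, config.n_outcome, out_flip, out_strand)
    truth = SimTruth(config, p, gamma, alpha, config.theta)
    return exposure, outcome, truth


def _orient(g, G):
    """Apply the gamma >= 0 sign convention (as harmonization would)."""
    s = np.where(g < 0, -1.0, 1.0)
    return g * s, G * s


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    methods: tuple[str, ...] = ("ivw", "simple_median", "weighted_median", "egger"),
    n_boot: int = 200,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo calibration study of the estimators under ``config``.

    Repeats the generative model ``n_reps`` times (child seeds spawned
    from ``config.seed``) and summarizes, per method: mean bias against
    the true theta, RMSE, the empirical SE of the point estimate, the
    mean model SE, 95% CI coverage of theta, and the rejection rate of
    H0: theta = 0.  For Egger an extra ``egger_intercept`` row reports
    the directional-pleiotropy test's rejection rate and the mean
    intercept.  Median SEs use a reduced parametric bootstrap
    (``n_boot``, default 200) suited to calibration studies; deterministic
    given the config seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    known = {"ivw", "simple_median", "weighted_median", "egger"}
    unknown = set(methods) - known
    if unknown:
        raise ValueError(f"unknown method labels: {sorted(unknown)}")

    seeds = np.random.SeedSequence(config.seed).spawn(n_reps)
    need_boot = bool({"simple_median", "weighted_median"} & set(methods))
    est = {m: np.empty(n_reps) for m in methods}
    se = {m: np.empty(n_reps) for m in methods}
    icpt = np.empty(n_reps)
    icpt_se = np.empty(n_reps)

    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        p, gamma, alpha = _draw_truth(config, rng)
        g, sx, G, sy = _observe(config, rng, p, gamma, alpha)
        g, G = _orient(g, G)
        ratios = G / g
        if "ivw" in est:
            est["ivw"][r], se["ivw"][r] = _ivw_point(g, G, sy)
        if "egger" in est:
            slope, slope_se, b0, b0_se = _egger_point(g, G, sy)
            est["egger"][r], se["egger"][r] = slope, slope_se
            icpt[r], icpt_se[r] = b0, b0_se
        if need_boot:
            boot_rng = np.random.default_rng(ss.spawn(1)[0])
            gs = g + boot_rng.standard_normal((n_boot, g.size)) * sx
            Gs = G + boot_rng.standard_normal((n_boot, g.size)) * sy
            rb = Gs / gs
            if "simple_median" in est:
                est["simple_median"][r] = float(np.median(ratios))
                se["simple_median"][r] = float(np.median(rb, axis=1).std(ddof=1))
            if "weighted_median" in est:
                est["weighted_median"][r] = _weighted_median_point(
                    ratios, (g / sy) ** 2
                )
                se["weighted_median"][r] = float(
                    _weighted_median_rows(rb, (gs / sy) ** 2).std(ddof=1)
                )

    z = stats.norm.ppf(1.0 - alpha_level / 2.0)
    rows = []
    for m in methods:
        b, s = est[m], se[m]
        rows.append(
            {
                "method": m,
                "mean_estimate": b.mean(),
                "mean_bias": b.mean() - config.theta,
                "rmse": float(np.sqrt(np.mean((b - config.theta) ** 2))),
                "empirical_se": b.std(ddof=1) if n_reps > 1 else math.nan,
                "mean_se": s.mean(),
                "coverage": float(np.mean(np.abs(b - config.theta) <= Z95 * s)),
                "reject_rate": float(np.mean(np.abs(b / s) > z)),
            }
        )
    if "egger" in methods:
        rows.append(
            {
                "method": "egger_intercept",
                "mean_estimate": icpt.mean(),
                "mean_bias": icpt.mean() - config.pleio_fraction * config.pleio_mean,
                "rmse": math.nan,
                "empirical_se": icpt.std(ddof=1) if n_reps > 1 else math.nan,
                "mean_se": icpt_se.mean(),
                "coverage": math.nan,
                "reject_rate": float(np.mean(np.abs(icpt / icpt_se) > z)),
            }
        )
    return pd.DataFrame(rows).set_index("method")
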