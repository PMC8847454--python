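"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume per-variant summary associations: an exposure
effect ``gamma_hat`` (SE ``sigma_x``) and an outcome effect ``Gamma_hat``
(SE ``sigma_y``) on a shared effect allele, as produced by
:func:`tsmr.harmonize.harmonize`.  Effects on a binary outcome are
log-odds; causal estimates are log-odds of the outcome per 1 SD of the
genetically predicted exposure, reported alongside the exponentiated
odds-ratio scale.

The estimators are scikit-learn compatible regressors: ``X`` is the
vector of exposure effects (shape ``(J,)`` or ``(J, 1)``), ``y`` the
vector of outcome effects, and the per-variant standard errors are passed
to :meth:`fit` as ``x_se`` / ``y_se``.  Module-level functions
(:func:`ivw_fixed`, :func:`egger_regression`, ...) are thin wrappers that
accept a harmonized instrument table and return result dataclasses.

Conventions
-----------
* Wald-ratio SEs use the first-order delta method, sigma_y / |gamma|,
  ignoring exposure-side uncertainty (appropriate for strong
  instruments, F >> 10).
* Confidence intervals are beta +/- 1.96 * se and p-values are two-sided
  normal throughout; no multiple-testing adjustment is applied.
* MR-Egger requires the gamma >= 0 orientation that harmonization
  enforces; point estimates of every estimator are invariant to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Z95",
    "RatioEstimate",
    "MREstimate",
    "EggerEstimate",
    "InvalidInstrumentError",
    "IVWEstimator",
    "SimpleMedianEstimator",
    "WeightedMedianEstimator",
    "EggerEstimator",
    "wald_ratio",
    "ratio_table",
    "ivw_fixed",
    "simple_median",
    "weighted_median",
    "egger_regression",
    "to_odds_scale",
    "estimate_all",
]

#: Normal quantile used for all 95% intervals (symmetric, 1.96-based).
Z95 = 1.96


class InvalidInstrumentError(ValueError):
    """An instrument violates an estimator precondition (e.g. gamma = 0)."""


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio: outcome effect divided by exposure effect."""

    snp_id: str
    beta_ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        """Inverse-variance weight, se_ratio**-2."""
        return self.se_ratio ** -2


@dataclass(frozen=True)
class MREstimate:
    """One estimator's pooled causal estimate on the log-odds-per-SD scale.

    ``odds_ratio`` and the OR-scale interval are exp() transforms of the
    log-scale fields, which are retained.
    """

    method: str
    beta: float
    se: float
    n_snp: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float = field(init=False)
    odds_ratio: float = field(init=False)
    or_ci_low: float = field(init=False)
    or_ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"standard error must be positive, got {self.se}")
        object.__setattr__(self, "ci_low", self.beta - Z95 * self.se)
        object.__setattr__(self, "ci_high", self.beta + Z95 * self.se)
        object.__setattr__(self, "pvalue", _two_sided_p(self.beta / self.se))
        object.__setattr__(self, "odds_ratio", math.exp(self.beta))
        object.__setattr__(self, "or_ci_low", math.exp(self.ci_low))
        object.__setattr__(self, "or_ci_high", math.exp(self.ci_high))


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger regression: causal slope plus directional-pleiotropy intercept.

    ``i2_gx`` quantifies relative exposure-measurement precision; values
    well below 1 indicate regression-dilution bias (Egger underpowered).
    It is NaN when exposure SEs were not supplied.
    """

    slope: MREstimate
    intercept: float
    intercept_se: float
    i2_gx: float
    intercept_p: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intercept_p", _two_sided_p(self.intercept / self.intercept_se)
        )


def to_odds_scale(est: MREstimate) -> MREstimate:
    """Return ``est`` with odds-ratio fields populated.

    Kept for API symmetry: :class:`MREstimate` computes the exponentiated
    scale eagerly, so this is the identity.
    """
    return est


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------


def _as_effect_vector(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a vector of exposure effects, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite exposure effects")
    return x


def _check_se(se, n: int, name: str) -> np.ndarray:
    if se is None:
        raise ValueError(f"{name} (per-variant standard errors) is required")
    s = np.asarray(se, dtype=float).ravel()
    if s.shape != (n,):
        raise ValueError(f"{name} has shape {s.shape}, expected ({n},)")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError(f"{name} must be finite and strictly positive")
    return s


def _unpack(instruments):
    """Accept an InstrumentSet, a harmonized DataFrame, or a 4-tuple of arrays."""
    table = getattr(instruments, "table", instruments)
    if isinstance(table, pd.DataFrame):
        return (
            table["gamma_hat"].to_numpy(float),
            table["Gamma_hat"].to_numpy(float),
            table["sigma_x"].to_numpy(float),
            table["sigma_y"].to_numpy(float),
            table["snp"].astype(str).tolist() if "snp" in table else None,
        )
    g, G, sx, sy = (np.asarray(a, dtype=float) for a in instruments)
    return g, G, sx, sy, None


# ---------------------------------------------------------------------------
# array-level kernels (shared by the sklearn classes and the Monte-Carlo code)
# ---------------------------------------------------------------------------


def _ivw_point(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW: weighted mean of Wald ratios, w = gamma^2 / sigma_y^2.

    Algebraically identical to weighted least squares of Gamma on gamma
    through the origin with weights sigma_y^-2.
    """
    w = g * g / (sy * sy)
    sw = w.sum()
    beta = float((g * G / (sy * sy)).sum() / sw)
    return beta, float(sw ** -0.5)


def _ivw_random_scale(g: np.ndarray, G: np.ndarray, sy: np.ndarray, beta: float) -> float:
    """Multiplicative random-effect inflation sqrt(max(1, Q/(J-1)))."""
    if g.size < 2:
        return 1.0
    ratios = G / g
    w = g * g / (sy * sy)
    q = float((w * (ratios - beta) ** 2).sum())
    return math.sqrt(max(1.0, q / (g.size - 1)))


def _egger_point(
    g: np.ndarray, G: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted regression of Gamma on gamma with free intercept, w = sigma_y^-2.

    Returns (slope, slope_se, intercept, intercept_se).  SEs carry the
    conventional multiplicative residual scale max(1, sigma_hat) on the
    (X'WX)^-1 covariance.
    """
    w = 1.0 / (sy * sy)
    sw = w.sum()
    swx = (w * g).sum()
    swxx = (w * g * g).sum()
    det = sw * swxx - swx * swx
    if det <= 0 or not np.isfinite(det):
        raise InvalidInstrumentError(
            "Egger slope unidentifiable: zero variance in exposure effects"
        )
    swy = (w * G).sum()
    swxy = (w * g * G).sum()
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = G - intercept - slope * g
    dof = g.size - 2
    sigma2 = float((w * resid * resid).sum() / dof) if dof > 0 else 1.0
    scale = max(1.0, sigma2)
    slope_se = math.sqrt(scale * sw / det)
    intercept_se = math.sqrt(scale * swxx / det)
    return float(slope), slope_se, float(intercept), intercept_se


def i_squared_gx(g: np.ndarray, sx: np.ndarray) -> float:
    """I2_GX regression-dilution diagnostic for MR-Egger.

    (Q_GX - (J-1)) / Q_GX with Q_GX the sigma_x^-2-weighted heterogeneity
    of the exposure effects about their weighted mean.  At most 1; low or
    negative values flag that exposure effects are measured too noisily
    for Egger to separate pleiotropy from slope.
    """
    g = np.asarray(g, dtype=float)
    sx = np.asarray(sx, dtype=float)
    w = 1.0 / (sx * sx)
    gbar = float((w * g).sum() / w.sum())
    q_gx = float((w * (g - gbar) ** 2).sum())
    if q_gx == 0.0:
        return -math.inf
    return (q_gx - (g.size - 1)) / q_gx


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with midpoint interpolation.

    Sort ratios ascending; place each at the cumulative-weight midpoint
    s_j = cum(w')_j - w'_j / 2 (w' normalized); linearly interpolate the
    sorted ratios against s at s = 0.5, clamping to the extremes when 0.5
    falls outside [s_1, s_J].
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for a (B, J) bootstrap matrix."""
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    B, J = r.shape
    # index of the first position with s >= 0.5, per row
    idx = np.clip((s < 0.5).sum(axis=1), 1, J - 1)
    rows = np.arange(B)
    s0, s1 = s[rows, idx - 1], s[rows, idx]
    r0, r1 = r[rows, idx - 1], r[rows, idx]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out = r0 + frac * (r1 - r0)
    out = np.where(s[:, 0] >= 0.5, r[:, 0], out)
    out = np.where(s[:, -1] <= 0.5, r[:, -1], out)
    return out


def _median_bootstrap_se(
    g: np.ndarray,
    G: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    weighted: bool,
) -> float:
    """Parametric-bootstrap SE of a median estimator.

    Resamples gamma* ~ N(gamma_hat, sigma_x^2), Gamma* ~ N(Gamma_hat,
    sigma_y^2) independently (the two-sample design) and recomputes the
    median estimator on every replicate.
    """
    gs = g + rng.standard_normal((n_boot, g.size)) * sx
    Gs = G + rng.standard_normal((n_boot, g.size)) * sy
    ratios = Gs / gs
    if weighted:
        meds = _weighted_median_rows(ratios, (gs / sy) ** 2)
    else:
        meds = np.median(ratios, axis=1)
    return float(meds.std(ddof=1))


# ---------------------------------------------------------------------------
# scikit-learn estimator classes
# ---------------------------------------------------------------------------


class _BaseMREstimator(RegressorMixin, BaseEstimator):
    """Shared fit/predict scaffolding for summary-data MR estimators."""

    _method: str = ""
    _min_instruments: int = 1
    _needs_x_se: bool = False

    def _point_and_se(self, g, G, sx, sy) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y, x_se=None, y_se=None):
        """Fit the causal effect from per-variant summary associations.

        Parameters
        ----------
        X : array-like of shape (J,) or (J, 1)
            Exposure effects gamma_hat.
        y : array-like of shape (J,)
            Outcome effects Gamma_hat on the same effect alleles.
        x_se, y_se : array-like of shape (J,)
            Standard errors of X and y.  ``y_se`` is always required;
            ``x_se`` is required by the bootstrap-based median estimators
            and used by Egger for the I2_GX diagnostic.
        """
        g = _as_effect_vector(X)
        G = _as_effect_vector(y)
        if G.shape != g.shape:
            raise ValueError("X and y must hold the same number of variants")
        if g.size < self._min_instruments:
            raise InvalidInstrumentError(
                f"{self._method} requires >= {self._min_instruments} instruments, "
                f"got {g.size}"
            )
        sy = _check_se(y_se, g.size, "y_se")
        sx = None
        if self._needs_x_se or x_se is not None:
            sx = _check_se(x_se, g.size, "x_se")
        if np.any(g == 0.0):
            raise InvalidInstrumentError(
                "instrument with zero exposure effect: Wald ratio undefined"
            )

        beta, se = self._point_and_se(g, G, sx, sy)
        self.effect_ = beta
        self.se_ = se
        self.n_snp_ = int(g.size)
        self.ci_ = (beta - Z95 * se, beta + Z95 * se)
        self.pvalue_ = _two_sided_p(beta / se)
        self.odds_ratio_ = math.exp(beta)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted outcome effects for exposure effects ``X`` (through origin)."""
        check_is_fitted(self, "effect_")
        return self.effect_ * _as_effect_vector(X)

    def to_estimate(self) -> MREstimate:
        """Package the fitted result as an :class:`MREstimate`."""
        check_is_fitted(self, "effect_")
        return MREstimate(self._method, self.effect_, self.se_, self.n_snp_)


class IVWEstimator(_BaseMREstimator):
    """Fixed-effect inverse-variance-weighted estimator.

    Pools per-variant Wald ratios with weights se_ratio^-2; equivalent to
    weighted least squares of outcome on exposure effects through the
    origin with weights sigma_y^-2.  With ``random_effects=True`` the SE
    is inflated by the multiplicative factor sqrt(max(1, Q/(J-1)))
    (point estimate unchanged); the fixed-effect model is the default and
    primary analysis.
    """

    _method = "IVW"

    def __init__(self, random_effects: bool = False):
        self.random_effects = random_effects

    def _point_and_se(self, g, G, sx, sy):
        beta, se = _ivw_point(g, G, sy)
        if self.random_effects:
            se *= _ivw_random_scale(g, G, sy, beta)
        return beta, se


class SimpleMedianEstimator(_BaseMREstimator):
    """Median of the per-variant Wald ratios (midpoint convention for even J).

    Consistent when at least half the instruments are valid.  The SE is
    the standard deviation of the median across ``n_boot`` parametric
    bootstrap replicates; ``random_state`` makes it reproducible.
    """

    _method = "simple_median"
    _min_instruments = 3
    _needs_x_se = True

    def __init__(self, n_boot: int = 10_000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    _weighted = False

    def _point(self, ratios, weights):
        return float(np.median(ratios))

    def _point_and_se(self, g, G, sx, sy):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        ratios = G / g
        beta = self._point(ratios, (g / sy) ** 2)
        rng = np.random.default_rng(self.random_state)
        se = _median_bootstrap_se(g, G, sx, sy, self.n_boot, rng, self._weighted)
        return beta, se


class WeightedMedianEstimator(SimpleMedianEstimator):
    """Inverse-variance-weighted median of the Wald ratios.

    Consistent when valid instruments carry >= 50% of the total weight
    (breakdown point one half); SE by the same parametric bootstrap as
    the simple median.
    """

    _method = "weighted_median"
    _weighted = True

    def _point(self, ratios, weights):
        return _weighted_median_point(ratios, weights)


class EggerEstimator(_BaseMREstimator):
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept (weights sigma_y^-2).

    The slope estimates the causal effect under the InSIDE assumption;
    a nonzero intercept indicates directional horizontal pleiotropy.
    Requires the gamma >= 0 orientation applied at harmonization.  When
    ``x_se`` is supplied the I2_GX regression-dilution diagnostic is
    computed.
    """

    _method = "egger_slope"
    _min_instruments = 3

    def _point_and_se(self, g, G, sx, sy):
        slope, slope_se, intercept, intercept_se = _egger_point(g, G, sy)
        self.intercept_ = intercept
        self.intercept_se_ = intercept_se
        self.intercept_pvalue_ = _two_sided_p(intercept / intercept_se)
        self.i2_gx_ = i_squared_gx(g, sx) if sx is not None else math.nan
        return slope, slope_se

    def predict(self, X):
        check_is_fitted(self, "effect_")
        return self.intercept_ + self.effect_ * _as_effect_vector(X)

    def to_estimate(self) -> EggerEstimate:
        check_is_fitted(self, "effect_")
        return EggerEstimate(
            slope=MREstimate(self._method, self.effect_, self.se_, self.n_snp_),
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            i2_gx=self.i2_gx_,
        )


# ---------------------------------------------------------------------------
# operation-style wrappers over harmonized instrument sets
# ---------------------------------------------------------------------------


def wald_ratio(inst) -> RatioEstimate:
    """Per-variant Wald ratio Gamma/gamma with delta-method SE sigma_y/|gamma|.

    ``inst`` is any mapping/row with fields ``snp``/``snp_id``,
    ``gamma_hat``, ``Gamma_hat`` and ``sigma_y``.
    """
    get = inst.get if hasattr(inst, "get") else lambda k, d=None: getattr(inst, k, d)
    gamma = float(get("gamma_hat"))
    Gamma = float(get("Gamma_hat"))
    sigma_y = float(get("sigma_y"))
    snp = str(get("snp", None) or get("snp_id", "?"))
    if gamma == 0.0:
        raise InvalidInstrumentError(f"{snp}: zero exposure effect, ratio undefined")
    return RatioEstimate(snp, Gamma / gamma, sigma_y / abs(gamma))


def ratio_table(instruments) -> pd.DataFrame:
    """Per-variant ratio estimates with OR-scale intervals (driver-SNP table)."""
    g, G, sx, sy, snps = _unpack(instruments)
    if np.any(g == 0.0):
        raise InvalidInstrumentError("instrument with zero exposure effect")
    beta = G / g
    se = sy / np.abs(g)
    df = pd.DataFrame(
        {
            "snp": snps if snps is not None else [f"iv{i}" for i in range(g.size)],
            "beta_ratio": beta,
            "se_ratio": se,
            "weight": se ** -2.0,
            "or": np.exp(beta),
            "or_ci_low": np.exp(beta - Z95 * se),
            "or_ci_high": np.exp(beta + Z95 * se),
            "pvalue": 2.0 * stats.norm.sf(np.abs(beta / se)),
        }
    )
    return df


def _fit_wrapper(cls_kwargs_pairs, instruments):
    g, G, sx, sy, _ = _unpack(instruments)
    cls, kwargs = cls_kwargs_pairs
    est = cls(**kwargs).fit(g.reshape(-1, 1), G, x_se=sx, y_se=sy)
    return est


def ivw_fixed(instruments, random_effects: bool = False) -> MREstimate:
    """Fixed-effect IVW pooled estimate over a harmonized instrument set."""
    est = _fit_wrapper((IVWEstimator, {"random_effects": random_effects}), instruments)
    return est.to_estimate()


def simple_median(instruments, n_boot: int = 10_000, seed: int | None = None) -> MREstimate:
    """Simple-median estimate with parametric-bootstrap SE (seeded)."""
    est = _fit_wrapper(
        (SimpleMedianEstimator, {"n_boot": n_boot, "random_state": seed}), instruments
    )
    return est.to_estimate()


def weighted_median(instruments, n_boot: int = 10_000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE (seeded)."""
    est = _fit_wrapper(
        (WeightedMedianEstimator, {"n_boot": n_boot, "random_state": seed}), instruments
    )
    return est.to_estimate()


def egger_regression(instruments) -> EggerEstimate:
    """MR-Egger slope + directional-pleiotropy intercept + I2_GX."""
    est = _fit_wrapper((EggerEstimator, {}), instruments)
    return est.to_estimate()


_METHODS = {
    "ivw": ivw_fixed,
    "simple_median": simple_median,
    "weighted_median": weighted_median,
    "egger": egger_regression,
}


def estimate_all(
    instruments,
    methods: Sequence[str] = ("ivw", "simple_median", "weighted_median", "egger"),
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the requested estimators and return one flat result row per method.

    Egger contributes both its slope row and the intercept diagnostics
    (egger_intercept / intercept_se / intercept_p / i2_gx columns on the
    egger row).  A method whose preconditions fail (e.g. a median with
    fewer than 3 instruments) yields an explicit error row rather than a
    silent omission.
    """
    rows = []
    for name in methods:
        if name not in _METHODS:
            raise ValueError(f"unknown method {name!r}; choose from {sorted(_METHODS)}")
        try:
            if name in ("simple_median", "weighted_median"):
                res = _METHODS[name](instruments, n_boot=n_boot, seed=seed)
            else:
                res = _METHODS[name](instruments)
        except InvalidInstrumentError as exc:
            rows.append({"method": name, "error": str(exc)})
            continue
        if isinstance(res, EggerEstimate):
            row = _estimate_row("egger", res.slope)
            row.update(
                egger_intercept=res.intercept,
                egger_intercept_se=res.intercept_se,
                egger_intercept_p=res.intercept_p,
                i2_gx=res.i2_gx,
            )
        else:
            row = _estimate_row(name, res)
        rows.append(row)
    return pd.DataFrame(rows)


def _estimate_row(name: str, est: MREstimate) -> dict:
    return {
        "method": name,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "or": est.odds_ratio,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "pvalue": est.pvalue,
    }
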