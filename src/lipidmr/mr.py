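"""Two-sample Mendelian randomization estimators on harmonized instruments.

Each genetic instrument j contributes a Wald ratio θ̂_j = β̂_out,j / β̂_exp,j
(log-odds of the outcome per 1 SD of the exposure) with first-order standard
error se_out,j / |β̂_exp,j|. The estimators differ in how they pool the
ratios:

* ``ivw`` — fixed-effect inverse-variance weighting, equivalently weighted
  least squares of β̂_out on β̂_exp through the origin with weights 1/se_out².
  Consistent when every instrument is valid.
* ``mr_egger`` — the same weighted regression with a free intercept, on data
  oriented so every β̂_exp ≥ 0. The slope is robust to directional pleiotropy
  under the InSIDE assumption; a non-zero intercept is evidence of it.
* ``weighted_median`` — the weighted median of the ratios; consistent while
  valid instruments carry more than half the total weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm, t as t_dist

from .summary import HarmonizedInstrument

Z95 = 1.96  # 95% interval multiplier, matching two-decimal table reporting


class MRInputError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """Causal-effect estimate from one method.

    ``beta`` is the log odds ratio per 1 SD of exposure unless
    ``scale == "odds_ratio"`` (see :func:`to_odds_ratio`); the confidence
    bounds are beta ± 1.96·se on the estimation scale.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    scale: str = "log"
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "k": self.k,
            "scale": self.scale,
        }
        d.update({f"extra_{k}": v for k, v in self.extras.items()})
        return d


@dataclass(frozen=True)
class RatioEstimates:
    """Per-instrument Wald ratios and their first-order standard errors."""

    variant_ids: tuple[str, ...]
    ratio: np.ndarray
    ratio_se: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in instruments], dtype=float)
    sx = np.array([h.se_exp for h in instruments], dtype=float)
    by = np.array([h.beta_out for h in instruments], dtype=float)
    sy = np.array([h.se_out for h in instruments], dtype=float)
    ids = tuple(h.variant_id for h in instruments)
    return ids, bx, sx, by, sy


def ratio_estimates(instruments: Sequence[HarmonizedInstrument]) -> RatioEstimates:
    """Wald ratio β_out/β_exp per instrument; SE = se_out/|β_exp| (first order)."""
    ids, bx, _, by, sy = _arrays(instruments)
    zero = [i for i, b in zip(ids, bx) if b == 0.0]
    if zero:
        raise MRInputError(f"zero exposure effect for: {', '.join(zero)}")
    return RatioEstimates(variant_ids=ids, ratio=by / bx, ratio_se=sy / np.abs(bx))


def _estimate(method, beta, se, pvalue, k, extras=None) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(max(pvalue, 1e-300)),
        k=int(k),
        extras=extras or {},
    )


def ratio_single(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-instrument Wald ratio with first-order SE and normal inference."""
    r = ratio_estimates([instrument])
    beta = float(r.ratio[0])
    se = float(r.ratio_se[0])
    return _estimate("ratio_single", beta, se, 2 * norm.sf(abs(beta) / se), 1)


def ivw(instruments: Sequence[HarmonizedInstrument], random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    β̂ = Σ w_j θ̂_j / Σ w_j with w_j = 1/se(θ̂_j)², SE = (Σ w_j)^{−1/2}, normal
    two-sided p. Algebraically identical to WLS of β_out on β_exp through the
    origin with weights 1/se_out². With ``random_effects=True`` the SE is
    inflated by the residual dispersion √(Q/(k−1)) when that exceeds 1
    (multiplicative random effects).
    """
    if len(instruments) < 2:
        raise MRInputError("ivw needs at least 2 instruments; use ratio_single for k=1")
    r = ratio_estimates(instruments)
    w = r.weights
    beta = float(np.sum(w * r.ratio) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    k = len(instruments)
    extras = {"model": "fixed"}
    if random_effects:
        q = float(np.sum(w * (r.ratio - beta) ** 2))
        phi = max(1.0, math.sqrt(q / (k - 1)))
        se *= phi
        extras = {"model": "multiplicative_random", "dispersion": phi}
    return _estimate("ivw", beta, se, 2 * norm.sf(abs(beta) / se), k, extras)


def _weighted_line(x, y, w, intercept: bool):
    """Normal-equation WLS; returns coefs and unit-dispersion covariance."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    xtwx = (X.T * w) @ X
    coef = np.linalg.solve(xtwx, (X.T * w) @ y)
    cov_unit = np.linalg.inv(xtwx)
    resid = y - X @ coef
    return coef, cov_unit, resid


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
    constrain_intercept: bool = False,
    normal_inference: bool = False,
) -> MREstimate:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Instruments are oriented so β_exp ≥ 0 (both betas negated where needed);
    β_out is regressed on β_exp with intercept, weights 1/se_out². The slope
    estimates the causal effect; the intercept estimates the average
    directional pleiotropic effect. Coefficient SEs are scaled by
    max(1, residual SD) — multiplicative overdispersion truncated below at
    one — and p-values use the t distribution with k−2 df (normal by flag).

    ``constrain_intercept=True`` is a test hook: it forces the line through
    the origin with unit dispersion and normal inference, which reproduces
    the fixed-effect IVW estimate exactly.
    """
    k = len(instruments)
    if constrain_intercept:
        if k < 2:
            raise MRInputError("need at least 2 instruments")
        ids, bx, sx, by, sy = _arrays(instruments)
        flip = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * flip, by * flip
        w = 1.0 / sy**2
        coef, cov_unit, _ = _weighted_line(bx, by, w, intercept=False)
        beta, se = float(coef[0]), math.sqrt(cov_unit[0, 0])
        return _estimate("ivw", beta, se, 2 * norm.sf(abs(beta) / se), k,
                         {"model": "egger_constrained"})
    if k < 3:
        raise MRInputError("mr_egger needs at least 3 instruments")
    ids, bx, sx, by, sy = _arrays(instruments)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0.0:
        raise MRInputError("all |beta_exp| equal; Egger slope unidentifiable")
    w = 1.0 / sy**2
    coef, cov_unit, resid = _weighted_line(bx, by, w, intercept=True)
    df = k - 2
    dispersion = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / df))
    se_slope = dispersion * math.sqrt(cov_unit[1, 1])
    se_int = dispersion * math.sqrt(cov_unit[0, 0])
    slope, intercept = float(coef[1]), float(coef[0])
    if normal_inference:
        p_slope = 2 * norm.sf(abs(slope) / se_slope)
        p_int = 2 * norm.sf(abs(intercept) / se_int)
    else:
        p_slope = 2 * t_dist.sf(abs(slope) / se_slope, df=df)
        p_int = 2 * t_dist.sf(abs(intercept) / se_int, df=df)
    extras = {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_ci": (intercept - Z95 * se_int, intercept + Z95 * se_int),
        "intercept_p": float(max(p_int, 1e-300)),
        "dispersion": dispersion,
        "df": df,
    }
    return _estimate("egger", slope, se_slope, p_slope, k, extras)


def weighted_median_point(ratio: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of cumulative weight midpoints.

    Ratios are sorted ascending; with normalized weights w'_j, the cumulative
    midpoint is s_j = Σ_{i≤j} w'_i − w'_j/2 and the estimate interpolates
    ratio against s at s = 0.5, clamped to the extreme ratios outside the
    midpoint range.
    """
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Weights are the inverse-variance weights of the Wald ratios. The SE is
    the standard deviation of the estimate over ``n_boot`` replicates that
    redraw β_exp,j ~ N(β̂_exp,j, se_exp,j) and β_out,j ~ N(β̂_out,j, se_out,j);
    the seed is mandatory for reproducibility.
    """
    k = len(instruments)
    if k < 3:
        raise MRInputError("weighted_median needs at least 3 instruments")
    if n_boot < 100:
        raise MRInputError("n_boot must be at least 100")
    if seed is None:
        raise MRInputError("weighted_median requires an explicit seed")
    ids, bx, sx, by, sy = _arrays(instruments)
    if np.any(bx == 0.0):
        raise MRInputError("zero exposure effect among instruments")
    ratio = by / bx
    w = (np.abs(bx) / sy) ** 2
    beta = weighted_median_point(ratio, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b = np.where(bx_b == 0.0, np.finfo(float).tiny, bx_b)
    ratios_b = by_b / bx_b
    w_b = (np.abs(bx_b) / sy) ** 2
    boots = np.array(
        [weighted_median_point(ratios_b[i], w_b[i]) for i in range(n_boot)]
    )
    se = float(boots.std(ddof=1))
    if se == 0.0:
        se = np.finfo(float).tiny
    return _estimate(
        "weighted_median",
        beta,
        se,
        2 * norm.sf(abs(beta) / se),
        k,
        {"n_boot": n_boot, "seed": seed},
    )


def to_odds_ratio(estimate: MREstimate) -> MREstimate:
    """Exponentiate a log-scale estimate to the odds-ratio scale.

    The point estimate and CI bounds are exponentiated; the SE stays on the
    log scale (where inference happened) and the p-value is unchanged.
    """
    if estimate.scale != "log":
        raise MRInputError("estimate already on odds-ratio scale")
    extras = dict(estimate.extras)
    return replace(
        estimate,
        beta=math.exp(estimate.beta),
        ci_low=math.exp(estimate.ci_low),
        ci_high=math.exp(estimate.ci_high),
        scale="odds_ratio",
        extras=extras,
    )
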