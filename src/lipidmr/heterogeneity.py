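"""Heterogeneity and directional-pleiotropy diagnostics for the pooled fits.

Cochran's Q measures dispersion of the per-instrument Wald ratios about the
pooled estimate on the inverse-variance metric; I² = (Q − df)/Q expresses the
share of that dispersion beyond chance. A non-zero MR-Egger intercept signals
directional pleiotropy (instruments affecting the outcome not through the
exposure, with a common sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .mr import MREstimate, MRInputError, ratio_estimates
from .summary import HarmonizedInstrument

Z95 = 1.96


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q with its chi-square p, and I² with a 95% CI (percent)."""

    Q: float
    df: int
    p_q: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], pooled_beta: float
) -> HeterogeneityReport:
    """Q = Σ w_j (θ̂_j − pooled)² over the Wald ratios, w_j = 1/se(θ̂_j)².

    P-value from chi-square with k−1 df. I² = max(0, (Q−df)/Q)·100. The I²
    interval is the test-based interval on ln H (H² = Q/df): se(ln H) is
    ½(ln Q − ln df)/(√(2Q) − √(2df−1)) when Q > k, else the small-Q
    approximation √(1/(2(k−2))·(1 − 1/(3(k−2)²))); H bounds are exponentiated
    and mapped through I² = (H²−1)/H², truncated to [0, 100].
    """
    k = len(instruments)
    if k < 2:
        raise MRInputError("heterogeneity needs at least 2 instruments")
    r = ratio_estimates(instruments)
    w = r.weights
    q = float(np.sum(w * (r.ratio - pooled_beta) ** 2))
    df = k - 1
    p_q = float(max(chi2.sf(q, df), 1e-300))
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0

    h = math.sqrt(q / df)
    if k > 2 and q > k:
        se_lnh = 0.5 * (math.log(q) - math.log(df)) / (
            math.sqrt(2.0 * q) - math.sqrt(2.0 * df - 1.0)
        )
    elif k > 2:
        se_lnh = math.sqrt(1.0 / (2.0 * (k - 2)) * (1.0 - 1.0 / (3.0 * (k - 2) ** 2)))
    else:
        se_lnh = float("inf")  # k = 2: interval uninformative
    lnh = math.log(max(h, 1.0))
    h_lo = math.exp(lnh - Z95 * se_lnh)
    h_hi = math.exp(lnh + Z95 * se_lnh)

    def h_to_i2(hv: float) -> float:
        if hv <= 1.0:
            return 0.0
        return min(100.0, 100.0 * (hv**2 - 1.0) / hv**2)

    return HeterogeneityReport(
        Q=q,
        df=df,
        p_q=p_q,
        i2=i2,
        i2_ci_low=min(h_to_i2(h_lo), i2),
        i2_ci_high=max(h_to_i2(h_hi), i2),
    )


def egger_intercept_test(
    egger_fit: MREstimate, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float, bool]:
    """Surface the MR-Egger intercept, its 95% CI and p; flag pleiotropy at p < alpha."""
    if egger_fit.method != "egger":
        raise MRInputError(f"expected an egger fit, got {egger_fit.method!r}")
    ex = egger_fit.extras
    intercept = ex["intercept"]
    ci = tuple(ex["intercept_ci"])
    p = ex["intercept_p"]
    return intercept, ci, p, p < alpha
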