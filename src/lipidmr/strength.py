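"""Weak-instrument and sample-overlap diagnostics.

When the exposure and outcome samples share participants, weak instruments
bias the two-sample estimate toward the confounded observational association
rather than toward the null; the expected bias under the null causal
hypothesis is overlap · β_obs / F, and the corresponding inflation of the
nominal type-I error rate follows from shifting the null sampling
distribution of the IV estimate by that bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm


class StrengthInputError(ValueError):
    pass


@dataclass(frozen=True)
class InstrumentStrengthReport:
    """One exposure/source row of the weak-instrument diagnostic table."""

    exposure: str
    source: str
    r2: float
    k: int
    n_exposure: int
    F: float
    overlap: float
    beta_obs: float
    bias_null: float
    type1_error: float
    n_outcome: int
    case_fraction: float


def variance_explained(instruments: Sequence[tuple[float, float]]) -> float:
    """Variance of a unit-SD exposure explained by independent instruments.

    Each instrument contributes 2p(1−p)β² where p is the effect-allele
    frequency and β the per-allele effect in SD units (Hardy–Weinberg
    genotype variance times the squared effect). Clipped at 1.
    """
    total = 0.0
    for beta, eaf in instruments:
        if eaf is None or not 0.0 <= eaf <= 1.0:
            raise StrengthInputError("each instrument needs an allele frequency in [0, 1]")
        total += 2.0 * eaf * (1.0 - eaf) * beta * beta
    return min(total, 1.0)


def f_statistic(r2: float, k: int, n: int) -> float:
    """Joint instrument-strength F statistic: (n−k−1)/k · r²/(1−r²)."""
    if not 0.0 <= r2 < 1.0:
        raise StrengthInputError(f"r2 must be in [0, 1), got {r2}")
    if k < 1:
        raise StrengthInputError("k must be at least 1")
    if n <= k + 1:
        raise StrengthInputError(f"n = {n} must exceed k + 1 = {k + 1}")
    return (n - k - 1) / k * r2 / (1.0 - r2)


def overlap_bias_null(beta_obs: float, overlap: float, F: float) -> float:
    """Expected IV-estimate bias under the null: overlap · β_obs / F.

    β_obs is the confounded observational log-odds per SD of exposure;
    full overlap and weak instruments (small F) pull the IV estimate toward
    it.
    """
    if F <= 0:
        raise StrengthInputError("F must be positive")
    if not 0.0 <= overlap <= 1.0:
        raise StrengthInputError("overlap must be a proportion")
    return overlap * beta_obs / F

def overlap_type1_error(
    bias_null: float,
    r2: float,
    n_outcome: int,
    case_fraction: float,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the nominal level-``alpha`` two-sided IV test under null bias.

    The IV log-OR estimate for a binary outcome has approximate null SE
    s = (r² · n · v(1−v))^(−1/2) with v the case fraction; shifting the null
    distribution by ``bias_null`` gives rejection probability
    Φ(−z − b/s) + 1 − Φ(z − b/s) with z the two-sided normal quantile.
    """
    if not 0.0 < case_fraction < 1.0:
        raise StrengthInputError("case_fraction must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise StrengthInputError("alpha must be in (0, 1)")
    if not 0.0 < r2 < 1.0:
        raise StrengthInputError("r2 must be in (0, 1)")
    if n_outcome <= 0:
        raise StrengthInputError("n_outcome must be positive")
    s = (r2 * n_outcome * case_fraction * (1.0 - case_fraction)) ** -0.5
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = bias_null / s
    return float(norm.cdf(-z - shift) + norm.sf(z - shift))


def strength_report(
    exposure: str,
    source: str,
    n_exposure: int,
    overlap: float,
    beta_obs: float,
    n_outcome: int,
    case_fraction: float,
    k: int,
    instruments: Sequence[tuple[float, float]] | None = None,
    r2: float | None = None,
    alpha: float = 0.05,
) -> InstrumentStrengthReport:
    """Assemble one diagnostic row: r² (supplied or from instruments), F, bias, type-I error."""
    if r2 is None:
        if instruments is None:
            raise StrengthInputError("supply either r2 or instruments")
        r2 = variance_explained(instruments)
    F = f_statistic(r2, k, n_exposure)
    bias = overlap_bias_null(beta_obs, overlap, F)
    t1 = overlap_type1_error(bias, r2, n_outcome, case_fraction, alpha)
    return InstrumentStrengthReport(
        exposure=exposure,
        source=source,
        r2=r2,
        k=k,
        n_exposure=n_exposure,
        F=F,
        overlap=overlap,
        beta_obs=beta_obs,
        bias_null=bias,
        type1_error=t1,
        n_outcome=n_outcome,
        case_fraction=case_fraction,
    )
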