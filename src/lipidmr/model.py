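"""Model/Results surface over the MR estimators, in the statsmodels idiom.

:class:`MRModel` holds a set of harmonized instruments; ``fit()`` runs one or
all estimators and returns :class:`MRResults`, which carries the estimates,
their uncertainties, the heterogeneity and pleiotropy diagnostics, and a
``summary()`` table mirroring the usual reporting layout (OR with 95% CI per
1 SD of exposure, I² with CI, Q-test p, Egger intercept).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import heterogeneity as het
from . import mr
from .summary import HarmonizedInstrument, instruments_to_dataframe

_METHODS = ("ivw", "egger", "weighted_median")


class MRModel:
    """Two-sample Mendelian randomization model on harmonized instruments."""

    def __init__(self, instruments: Sequence[HarmonizedInstrument], exposure: str = "exposure"):
        if not instruments:
            raise mr.MRInputError("no instruments supplied")
        self.instruments = list(instruments)
        self.exposure = exposure

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure: str = "exposure") -> "MRModel":
        """Build from a frame with columns variant_id, beta_exp, se_exp, beta_out, se_out."""
        instruments = [
            HarmonizedInstrument(
                variant_id=str(r["variant_id"]),
                effect_allele=str(r.get("effect_allele", "A")),
                beta_exp=float(r["beta_exp"]),
                se_exp=float(r["se_exp"]),
                beta_out=float(r["beta_out"]),
                se_out=float(r["se_out"]),
            )
            for r in df.to_dict("records")
        ]
        return cls(instruments, exposure=exposure)

    @property
    def k(self) -> int:
        return len(self.instruments)

    def fit(
        self,
        method: str = "all",
        n_boot: int = 1000,
        seed: int | None = None,
        random_effects: bool = False,
    ) -> "MRResults":
        """Run one estimator (``ivw``/``egger``/``weighted_median``) or ``all``.

        The weighted-median bootstrap requires ``seed`` whenever that method
        runs. Heterogeneity (Q, I²) is computed about the IVW pooled estimate
        whenever IVW runs.
        """
        methods = _METHODS if method == "all" else (method,)
        estimates: dict[str, mr.MREstimate] = {}
        for m in methods:
            if m == "ivw":
                estimates[m] = mr.ivw(self.instruments, random_effects=random_effects)
            elif m == "egger":
                estimates[m] = mr.mr_egger(self.instruments)
            elif m == "weighted_median":
                estimates[m] = mr.weighted_median(self.instruments, n_boot=n_boot, seed=seed)
            else:
                raise mr.MRInputError(f"unknown method {m!r}")
        heterogeneity = None
        if "ivw" in estimates and self.k >= 2:
            heterogeneity = het.cochran_q(self.instruments, estimates["ivw"].beta)
        return MRResults(self, estimates, heterogeneity)


class MRResults:
    """Fitted estimates with diagnostics and a report table."""

    def __init__(self, model: MRModel, estimates, heterogeneity):
        self.model = model
        self.estimates = estimates
        self.heterogeneity = heterogeneity

    def __getitem__(self, method: str) -> mr.MREstimate:
        return self.estimates[method]

    @property
    def egger_intercept(self):
        """(intercept, 95% CI, p, flagged) from the Egger fit, if present."""
        if "egger" not in self.estimates:
            return None
        return het.egger_intercept_test(self.estimates["egger"])

    def odds_ratios(self) -> dict[str, mr.MREstimate]:
        return {m: mr.to_odds_ratio(e) for m, e in self.estimates.items()}

    def summary(self) -> pd.DataFrame:
        """One row per method: OR, 95% CI, p, plus shared diagnostics columns."""
        labels = {"ivw": "MR-IVW", "egger": "MR-Egger", "weighted_median": "MR-Weighted median"}
        rows = []
        ors = self.odds_ratios()
        for m, est in self.estimates.items():
            row = {
                "exposure": self.model.exposure,
                "method": labels.get(m, m),
                "k": est.k,
                "or": ors[m].beta,
                "or_ci_low": ors[m].ci_low,
                "or_ci_high": ors[m].ci_high,
                "log_or": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
            }
            if m == "ivw" and self.heterogeneity is not None:
                h = self.heterogeneity
                row.update(
                    {
                        "i2": h.i2,
                        "i2_ci_low": h.i2_ci_low,
                        "i2_ci_high": h.i2_ci_high,
                        "q": h.Q,
                        "q_pvalue": h.p_q,
                    }
                )
            if m == "egger":
                intercept, ci, p, flagged = het.egger_intercept_test(est)
                row.update(
                    {
                        "egger_intercept": intercept,
                        "egger_intercept_ci_low": ci[0],
                        "egger_intercept_ci_high": ci[1],
                        "egger_intercept_pvalue": p,
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        with pd.option_context("display.width", 140, "display.max_columns", 30):
            return self.summary().round(4).to_string(index=False)

    def plot(self, ax=None):
        """Scatter of outcome vs exposure effects with the fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        df = instruments_to_dataframe(self.model.instruments)
        flip = np.sign(df["beta_exp"]).replace(0, 1)
        bx, by = df["beta_exp"] * flip, df["beta_out"] * flip
        ax.errorbar(
            bx, by, yerr=1.96 * df["se_out"], xerr=1.96 * df["se_exp"],
            fmt="o", ms=3, lw=0.6, alpha=0.7, color="steelblue",
        )
        grid = np.linspace(0.0, float(bx.max()) * 1.05, 50)
        if "ivw" in self.estimates:
            ax.plot(grid, self.estimates["ivw"].beta * grid, label="IVW", color="firebrick")
        if "egger" in self.estimates:
            e = self.estimates["egger"]
            ax.plot(
                grid, e.extras["intercept"] + e.beta * grid,
                label="MR-Egger", color="darkorange", ls="--",
            )
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel(f"SNP effect on {self.model.exposure} (per SD)")
        ax.set_ylabel("SNP effect on outcome (log-odds)")
        ax.legend(frameon=False)
        return ax
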