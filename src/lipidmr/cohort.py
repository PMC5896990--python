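"""One-sample cohort stages: lipids, eligibility, event adjudication, per-SNP fits.

The cohort is an individual-level table (one row per participant) carrying
lipid measurements in mg/dL, genotype dosages in [0, 2] as ``dose_<variant>``
columns, covariates, eligibility flags and the binary incident-event status.
Clinical events are adjudicated separately from coded diagnosis/procedure/
death records. The per-SNP regressions produce the summary statistics that
feed the two-sample Mendelian randomization estimators.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .summary import SNPAssociation

# qualifying ICD-9-CM diagnosis, procedure and cause-of-death codes for
# abdominal aortic aneurysm
AAA_DIAGNOSIS_CODES = frozenset({"441.3", "441.4"})
AAA_PROCEDURE_CODES = frozenset({"38.44", "39.71"})
AAA_DEATH_CODES = frozenset({"441.3", "441.4", "I71.3", "I71.4"})

RECORD_KINDS = ("hospital_discharge", "outpatient", "procedure", "death_underlying")

#: covariate set for the observational lipid–event logistic model
OBSERVATIONAL_COVARIATES = (
    "age",
    "sex",
    "center",
    "smoking",
    "height",
    "wbc",
    "fibrinogen",
    "hypertension",
    "diabetes",
    "pad",
)

LIPID_FIELDS = ("tc", "hdl", "tg", "ldl")


class CohortError(ValueError):
    pass


class SingularDesignError(np.linalg.LinAlgError, ValueError):
    """Design matrix is rank-deficient; message names the collinear columns."""


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (perfect or quasi-separation)."""


@dataclass
class Participant:
    """Row-level view of one cohort participant."""

    pid: str
    race_white: bool = True
    has_genotype: bool = True
    lipid_med: bool = False
    fasting_hours: float = 12.0
    tc: float | None = None
    hdl: float | None = None
    tg: float | None = None
    ldl: float | None = None
    covariates: dict = field(default_factory=dict)
    dosages: dict = field(default_factory=dict)
    event: int = 0

    def __post_init__(self) -> None:
        if self.fasting_hours < 0:
            raise CohortError(f"{self.pid}: negative fasting hours")
        for vid, d in self.dosages.items():
            if not 0.0 <= d <= 2.0:
                raise CohortError(f"{self.pid}: dosage for {vid} outside [0, 2]")


@dataclass(frozen=True)
class CodedRecord:
    """One diagnosis/procedure/death code for one participant on one date."""

    pid: str
    date: _dt.date
    record_kind: str
    code_system: str
    code: str

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date):
            raise CohortError(f"{self.pid}: date must be a datetime.date")
        if not self.code:
            raise CohortError(f"{self.pid}: empty code")
        if self.record_kind not in RECORD_KINDS:
            raise CohortError(f"{self.pid}: unknown record kind {self.record_kind!r}")


@dataclass(frozen=True)
class AssociationFit:
    """Per-variant (or per-lipid) regression estimate for one term."""

    variant_id: str
    beta: float
    se: float
    pvalue: float
    n_used: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise CohortError(f"{self.variant_id}: se must be positive")


class Cohort:
    """DataFrame-backed cohort; dosage columns are ``dose_<variant_id>``."""

    def __init__(self, data: pd.DataFrame):
        if "pid" not in data.columns:
            raise CohortError("cohort table requires a 'pid' column")
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return [c[len("dose_"):] for c in self.data.columns if c.startswith("dose_")]

    @classmethod
    def from_participants(cls, participants: Iterable[Participant]) -> "Cohort":
        rows = []
        for p in participants:
            row = {
                "pid": p.pid,
                "race_white": int(p.race_white),
                "has_genotype": int(p.has_genotype),
                "lipid_med": int(p.lipid_med),
                "fasting_hours": p.fasting_hours,
                "tc": np.nan if p.tc is None else p.tc,
                "hdl": np.nan if p.hdl is None else p.hdl,
                "tg": np.nan if p.tg is None else p.tg,
                "ldl": np.nan if p.ldl is None else p.ldl,
                "event": p.event,
            }
            row.update(p.covariates)
            row.update({f"dose_{vid}": d for vid, d in p.dosages.items()})
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def to_participants(self) -> list[Participant]:
        special = {
            "pid", "race_white", "has_genotype", "lipid_med", "fasting_hours",
            "tc", "hdl", "tg", "ldl", "event",
        }
        out = []
        for row in self.data.to_dict("records"):
            covs = {
                k: v for k, v in row.items()
                if k not in special and not k.startswith("dose_")
            }
            doses = {k[len("dose_"):]: v for k, v in row.items() if k.startswith("dose_")}
            out.append(
                Participant(
                    pid=str(row["pid"]),
                    race_white=bool(row.get("race_white", 1)),
                    has_genotype=bool(row.get("has_genotype", 1)),
                    lipid_med=bool(row.get("lipid_med", 0)),
                    fasting_hours=float(row.get("fasting_hours", 12.0)),
                    tc=_none_if_nan(row.get("tc")),
                    hdl=_none_if_nan(row.get("hdl")),
                    tg=_none_if_nan(row.get("tg")),
                    ldl=_none_if_nan(row.get("ldl")),
                    covariates=covs,
                    dosages=doses,
                    event=int(row.get("event", 0)),
                )
            )
        return out

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Cohort":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _none_if_nan(v):
    if v is None:
        return None
    try:
        return None if math.isnan(v) else float(v)
    except TypeError:
        return float(v)


def _as_cohort(cohort) -> Cohort:
    if isinstance(cohort, Cohort):
        return cohort
    if isinstance(cohort, pd.DataFrame):
        return Cohort(cohort)
    return Cohort.from_participants(cohort)


# ---------------------------------------------------------------------------
# lipid derivation


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float | None:
    """LDL cholesterol (mg/dL) by the Friedewald formula, TC − HDL − TG/5.

    Returns ``None`` (undetermined) when triglycerides exceed 400 mg/dL,
    where the TG/5 approximation of VLDL cholesterol breaks down.
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise CohortError("lipid concentrations must be non-negative")
    if tg > 400.0:
        return None
    return tc - hdl - tg / 5.0


# ---------------------------------------------------------------------------
# eligibility filters

EXCLUSION_REASONS = (
    "non_white",
    "missing_genotype",
    "lipid_medication",
    "not_fasting",
    "missing_lipids",
)


def apply_exclusions(
    cohort, min_fasting_hours: float = 8.0
) -> tuple[Cohort, dict[str, int]]:
    """Apply the five eligibility filters in order; count first-cause removals.

    Filters: non-white, missing genotype data, lipid-lowering medication,
    fasting below ``min_fasting_hours``, any of the four lipid fractions
    missing. A participant removed by several criteria is counted only under
    the first one in that order, so the counts sum to the number removed.
    """
    cohort = _as_cohort(cohort)
    df = cohort.data
    fails = {
        "non_white": df["race_white"].astype(float) == 0,
        "missing_genotype": df["has_genotype"].astype(float) == 0,
        "lipid_medication": df["lipid_med"].astype(float) == 1,
        "not_fasting": df["fasting_hours"].astype(float) < min_fasting_hours,
        "missing_lipids": df[list(LIPID_FIELDS)].isna().any(axis=1),
    }
    counts: dict[str, int] = {}
    removed = pd.Series(False, index=df.index)
    for reason in EXCLUSION_REASONS:
        newly = fails[reason] & ~removed
        counts[reason] = int(newly.sum())
        removed |= fails[reason]
    return Cohort(df.loc[~removed]), counts


# ---------------------------------------------------------------------------
# event adjudication


def adjudicate_aaa(
    records: Sequence[CodedRecord],
    window: tuple[_dt.date, _dt.date] | None = None,
    review: list | None = None,
) -> dict[str, bool]:
    """Classify each participant appearing in ``records`` as AAA case or not.

    A participant is a case iff any of: one hospital-discharge diagnosis with
    code 441.3/441.4; two outpatient diagnoses with those codes at least 7
    days apart; one procedure code 38.44/39.71; one underlying-cause-of-death
    code 441.3/441.4 (ICD-9) or I71.3/I71.4 (ICD-10). Records outside
    ``window`` (inclusive) are ignored. Codes that suggest aortic disease but
    are not on the qualifying lists are ignored and appended to ``review``
    for case-by-case inspection.
    """
    status: dict[str, bool] = {}
    outpatient_dates: dict[str, set[_dt.date]] = {}
    for rec in records:
        status.setdefault(rec.pid, False)
        if window is not None and not (window[0] <= rec.date <= window[1]):
            continue
        if rec.record_kind == "hospital_discharge":
            if rec.code in AAA_DIAGNOSIS_CODES:
                status[rec.pid] = True
            else:
                _maybe_review(review, rec)
        elif rec.record_kind == "outpatient":
            if rec.code in AAA_DIAGNOSIS_CODES:
                outpatient_dates.setdefault(rec.pid, set()).add(rec.date)
            else:
                _maybe_review(review, rec)
        elif rec.record_kind == "procedure":
            if rec.code in AAA_PROCEDURE_CODES:
                status[rec.pid] = True
        elif rec.record_kind == "death_underlying":
            if rec.code in AAA_DEATH_CODES:
                status[rec.pid] = True
            else:
                _maybe_review(review, rec)
    for pid, dates in outpatient_dates.items():
        if len(dates) >= 2 and (max(dates) - min(dates)).days >= 7:
            status[pid] = True
    return status


def _maybe_review(review: list | None, rec: CodedRecord) -> None:
    if review is not None and (rec.code.startswith("441") or rec.code.startswith("I71")):
        review.append(rec)


def read_coded_records(path: str | Path) -> list[CodedRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CodedRecord(
            pid=r["pid"],
            date=_dt.date.fromisoformat(r["date"]),
            record_kind=r["record_kind"],
            code_system=r["code_system"],
            code=r["code"],
        )
        for r in df.to_dict("records")
    ]


def write_coded_records(records: Iterable[CodedRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pid": r.pid,
                "date": r.date.isoformat(),
                "record_kind": r.record_kind,
                "code_system": r.code_system,
                "code": r.code,
            }
            for r in records
        ],
        columns=["pid", "date", "record_kind", "code_system", "code"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design matrices


def _build_design(
    df: pd.DataFrame, covariate_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates; categorical columns expand to drop-first dummies."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["const"]
    for name in covariate_names:
        if name not in df.columns:
            raise CohortError(f"covariate column {name!r} not in cohort")
        col = df[name]
        if col.dtype == object or str(col.dtype) == "category" or name == "center":
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the deficiency via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])))
        bad = sorted(names[i] for i in piv[rank:])
        raise SingularDesignError(f"singular design; collinear columns: {', '.join(bad)}")


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    numeric = df[list(cols)].apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    return df.loc[keep]


# ---------------------------------------------------------------------------
# per-SNP regressions


def fit_linear_snp(
    cohort,
    variant_id: str,
    outcome_field: str,
    covariate_names: Sequence[str] = (),
    outcome_sd: float | None = None,
) -> AssociationFit:
    """OLS of ``outcome_field`` on dosage plus covariates; dosage-term estimate.

    ``outcome_sd`` divides the outcome first (per-SD scaling). Rows with any
    missing involved field are dropped. P-value from the t distribution with
    n − p degrees of freedom.
    """
    cohort = _as_cohort(cohort)
    dose_col = f"dose_{variant_id}"
    if dose_col not in cohort.data.columns:
        raise CohortError(f"no dosage column for variant {variant_id!r}")
    plain = [c for c in covariate_names]
    needed = [outcome_field, dose_col] + [c for c in plain if c != "center"]
    df = _complete_cases(cohort.data, [c for c in needed if c in cohort.data.columns])
    if "center" in plain:
        df = df.loc[df["center"].notna()]
    Xc, names = _build_design(df, plain)
    X = np.column_stack([Xc[:, :1], df[dose_col].to_numpy(dtype=float), Xc[:, 1:]])
    names = [names[0], "dosage"] + names[1:]
    n, p = X.shape
    if n < p + 2:
        raise CohortError(f"{variant_id}: too few complete cases ({n}) for {p} parameters")
    _check_rank(X, names)
    y = df[outcome_field].to_numpy(dtype=float)
    if outcome_sd is not None:
        y = y / outcome_sd
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * xtx_inv[1, 1])
    beta = float(coef[1])
    pval = max(2.0 * t_dist.sf(abs(beta) / se, df=n - p), 1e-300)
    return AssociationFit(variant_id=variant_id, beta=beta, se=se, pvalue=pval, n_used=n)


def _irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """IRLS for logistic regression with step-halving.

    Returns (coef, covariance, log-likelihood trace, converged). Covariance is
    the inverse observed information X'WX at the final iterate (observed and
    expected information coincide under the canonical logit link).
    """
    n, p = X.shape
    beta = np.zeros(p)
    # intercept warm start at the logit of the event rate
    ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
    beta[0] = math.log(ybar / (1 - ybar))

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        info = XtW @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"information matrix singular: {exc}") from exc
        # halve until the log-likelihood does not decrease
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = max(ll_new, ll)
        trace.append(loglik(beta))
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    return beta, cov, trace, converged


def fit_logistic_snp(
    cohort,
    variant_id: str,
    covariate_names: Sequence[str] = (),
    return_history: bool = False,
):
    """Logistic regression of the event on dosage plus covariates.

    Maximum likelihood via iteratively reweighted least squares; convergence
    when the largest absolute coefficient update falls below 1e-8, capped at
    50 iterations. The dosage coefficient is the log-odds per allele copy;
    SE from the observed information at the MLE. Separation (no convergence,
    or diverging linear predictor) raises :class:`SeparationError` rather
    than returning a silently unusable fit.
    """
    cohort = _as_cohort(cohort)
    dose_col = f"dose_{variant_id}"
    if dose_col not in cohort.data.columns:
        raise CohortError(f"no dosage column for variant {variant_id!r}")
    plain = list(covariate_names)
    needed = ["event", dose_col] + [c for c in plain if c != "center"]
    df = _complete_cases(cohort.data, [c for c in needed if c in cohort.data.columns])
    if "center" in plain:
        df = df.loc[df["center"].notna()]
    y = df["event"].to_numpy(dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise SeparationError(
            f"{variant_id}: only one outcome class present among complete cases"
        )
    Xc, names = _build_design(df, plain)
    X = np.column_stack([Xc[:, :1], df[dose_col].to_numpy(dtype=float), Xc[:, 1:]])
    names = [names[0], "dosage"] + names[1:]
    _check_rank(X, names)
    beta, cov, trace, converged = _irls_logistic(X, y)
    if not converged or np.max(np.abs(X @ beta)) > 1e3:
        raise SeparationError(
            f"{variant_id}: IRLS did not converge (possible separation)"
        )
    se = math.sqrt(cov[1, 1])
    b = float(beta[1])
    pval = max(2.0 * norm.sf(abs(b) / se), 1e-300)
    fit = AssociationFit(variant_id=variant_id, beta=b, se=se, pvalue=pval, n_used=len(y))
    if return_history:
        return fit, trace
    return fit


def fit_observational_lipid_model(
    cohort,
    lipid_name: str,
    unit,
    covariate_names: Sequence[str] = OBSERVATIONAL_COVARIATES,
) -> AssociationFit:
    """Traditional (confounded) logistic model: event on lipid per SD + covariates.

    For the LDL, HDL and TG models the other two of those three lipid
    fractions enter as covariates (mg/dL); the TC model excludes them, since
    TC is their linear combination. The returned coefficient is the
    observational log-odds per 1 SD of ``lipid_name`` — the β_obs input to
    the sample-overlap bias diagnostics.
    """
    cohort = _as_cohort(cohort)
    lipid = lipid_name.lower()
    if lipid not in LIPID_FIELDS:
        raise CohortError(f"unknown lipid {lipid_name!r}")
    other = [l for l in ("ldl", "hdl", "tg") if l != lipid] if lipid != "tc" else []
    covs = list(covariate_names) + other
    needed = ["event", lipid] + [c for c in covs if c != "center"]
    df = _complete_cases(cohort.data, [c for c in needed if c in cohort.data.columns])
    if "center" in covs:
        df = df.loc[df["center"].notna()]
    y = df["event"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError(f"{lipid_name}: only one outcome class present")
    Xc, names = _build_design(df, covs)
    x_lipid = df[lipid].to_numpy(dtype=float) / unit.sd
    X = np.column_stack([Xc[:, :1], x_lipid, Xc[:, 1:]])
    names = [names[0], lipid] + names[1:]
    _check_rank(X, names)
    beta, cov, _, converged = _irls_logistic(X, y)
    if not converged:
        raise SeparationError(f"{lipid_name}: IRLS did not converge")
    se = math.sqrt(cov[1, 1])
    b = float(beta[1])
    pval = max(2.0 * norm.sf(abs(b) / se), 1e-300)
    return AssociationFit(variant_id=lipid, beta=b, se=se, pvalue=pval, n_used=len(y))


def association_to_snp(
    fit: AssociationFit, template: Mapping[str, object]
) -> SNPAssociation:
    """Promote a regression fit to a summary-statistic record.

    ``template`` supplies the allele bookkeeping (effect_allele, other_allele,
    eaf) that a regression alone cannot know.
    """
    return SNPAssociation(
        variant_id=fit.variant_id,
        effect_allele=str(template["effect_allele"]),
        other_allele=str(template["other_allele"]),
        eaf=template.get("eaf"),
        beta=fit.beta,
        se=fit.se,
        pvalue=fit.pvalue,
        n=fit.n_used,
    )
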