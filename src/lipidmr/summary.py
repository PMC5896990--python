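"""Summary-statistic domain types, file I/O, instrument selection and harmonization.

GWAS summary statistics travel as flat tables: one row per variant with the
effect allele, the other allele, the effect-allele frequency, the per-allele
effect estimate and its standard error, the p-value and the sample size.
Two-sample Mendelian randomization combines an exposure table (SNP–lipid
effects, per SD of the lipid) with an outcome table (SNP–disease log-odds),
which requires selecting approximately independent genome-wide-significant
instruments and aligning the two tables to a common effect allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistic TSV files
SUMMARY_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


class SummaryDataError(ValueError):
    """Invalid summary-statistic content (row-level diagnostics in message)."""


@dataclass(frozen=True)
class SNPAssociation:
    """One variant's association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` in trait units
    (per-SD units for GWAS-consortium lipid effects, log-odds for a binary
    outcome). ``eaf`` and ``pvalue`` may be missing (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise SummaryDataError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.variant_id}: effect and other allele identical")
        if not math.isfinite(self.beta):
            raise SummaryDataError(f"{self.variant_id}: non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise SummaryDataError(f"{self.variant_id}: se must be positive, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise SummaryDataError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if self.n is not None and self.n <= 0:
            raise SummaryDataError(f"{self.variant_id}: non-positive sample size")
        if self.pvalue is not None:
            if not 0.0 < self.pvalue <= 1.0:
                raise SummaryDataError(f"{self.variant_id}: pvalue {self.pvalue} outside (0, 1]")
            # stated p must agree with the two-sided normal p from beta/se
            # within a factor of 2 (log scale; guards unit mix-ups on input)
            logp_stated = math.log(self.pvalue)
            # p-values are clamped at 1e-300 on output; clamp the Wald side too
            logp_wald = max(math.log(2.0) + norm.logsf(abs(self.beta) / self.se),
                            math.log(1e-300))
            if abs(logp_stated - logp_wald) > math.log(2.0):
                raise SummaryDataError(
                    f"{self.variant_id}: pvalue {self.pvalue:.3g} inconsistent with "
                    f"beta/se Wald p {math.exp(logp_wald):.3g} (beyond factor 2)"
                )

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variants, where strand cannot be resolved from alleles."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def wald_pvalue(self) -> float:
        return max(2.0 * norm.sf(abs(self.beta) / self.se), 1e-300)


@dataclass(frozen=True)
class UnitSpec:
    """Trait measurement scale: one standard deviation in mg/dL."""

    trait_name: str
    sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd) and self.sd > 0):
            raise SummaryDataError(f"{self.trait_name}: sd must be positive")


#: GWAS-consortium lipid standard deviations (mg/dL) used to place
#: cohort-scale effects on the per-SD scale
GLGC_LIPID_SD: Mapping[str, float] = {
    "ldl": 38.7,
    "hdl": 15.5,
    "tg": 90.7,
    "tc": 41.8,
}


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome estimates aligned to one effect allele.

    ``beta_exp`` is per effect-allele copy in per-SD exposure units;
    ``beta_out`` is the per-allele log-odds for the outcome.
    """

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se_exp) and self.se_exp > 0):
            raise SummaryDataError(f"{self.variant_id}: se_exp must be positive")
        if not (math.isfinite(self.se_out) and self.se_out > 0):
            raise SummaryDataError(f"{self.variant_id}: se_out must be positive")


class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        ids = list(variant_ids)
        if r2.shape != (len(ids), len(ids)):
            raise SummaryDataError("LD matrix dimensions do not match variant list")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise SummaryDataError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise SummaryDataError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise SummaryDataError("LD r² values must lie in [0, 1]")
        self.variant_ids = ids
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def pairwise(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(variant_ids, np.eye(len(variant_ids)))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", index_label="variant_id"
        )


# ---------------------------------------------------------------------------
# file I/O


def _parse_optional(value, row: int, name: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "NA":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SummaryDataError(f"row {row}: field {name!r} is not numeric: {value!r}")


def read_summary_stats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SNPAssociation]:
    """Read a summary-statistic TSV into validated records.

    ``column_map`` maps canonical names (``variant_id``, ``beta``, ...) to
    the file's column names; omitted entries default to the canonical name.
    Rows are validated individually and failures raise with the offending
    row index and field. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {c: c for c in SUMMARY_COLUMNS}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canonical in ("variant_id", "effect_allele", "other_allele", "beta", "se"):
        if cmap[canonical] not in df.columns:
            raise SummaryDataError(
                f"required column {cmap[canonical]!r} (for {canonical}) missing from {path}"
            )
    records: list[SNPAssociation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        beta = _parse_optional(row[cmap["beta"]], i, "beta")
        se = _parse_optional(row[cmap["se"]], i, "se")
        if beta is None or se is None:
            raise SummaryDataError(f"row {i}: beta/se must be present and numeric")
        eaf = _parse_optional(row.get(cmap["eaf"]), i, "eaf")
        pvalue = _parse_optional(row.get(cmap["pvalue"]), i, "pvalue")
        n_raw = _parse_optional(row.get(cmap["n"]), i, "n")
        try:
            records.append(
                SNPAssociation(
                    variant_id=str(row[cmap["variant_id"]]),
                    effect_allele=str(row[cmap["effect_allele"]]).upper(),
                    other_allele=str(row[cmap["other_allele"]]).upper(),
                    eaf=eaf,
                    beta=beta,
                    se=se,
                    pvalue=pvalue,
                    n=int(n_raw) if n_raw is not None else None,
                )
            )
        except SummaryDataError as exc:
            raise SummaryDataError(f"row {i}: {exc}") from exc
    return records


def write_summary_stats(records: Iterable[SNPAssociation], path: str | Path) -> None:
    """Write records as a canonical-header TSV; inverse of :func:`read_summary_stats`.

    Missing optional fields are written as ``NA``; floats use ``repr``
    precision so that a read–write round trip is exact.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "NA" if r.eaf is None else repr(float(r.eaf)),
                "beta": repr(float(r.beta)),
                "se": repr(float(r.se)),
                "pvalue": "NA" if r.pvalue is None else repr(float(r.pvalue)),
                "n": "NA" if r.n is None else str(int(r.n)),
            }
        )
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(path, sep="\t", index=False)


def summary_to_dataframe(records: Iterable[SNPAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": np.nan if r.pvalue is None else r.pvalue,
                "n": np.nan if r.n is None else r.n,
            }
            for r in records
        ],
        columns=list(SUMMARY_COLUMNS),
    )


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(
    records: Sequence[SNPAssociation],
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
) -> list[SNPAssociation]:
    """Greedy p-value-ordered LD clumping.

    Records with p-value below ``p_threshold`` are visited in order of
    ascending p-value (ties broken by variant_id); a record is kept iff its
    r² with every record already kept is ≤ ``r2_threshold``. With ``ld=None``
    variants are treated as independent (identity LD).
    """
    passing = [r for r in records if _record_pvalue(r) < p_threshold]
    if ld is not None:
        missing = [r.variant_id for r in passing if r.variant_id not in ld]
        if missing:
            raise SummaryDataError(f"variants missing from LD matrix: {', '.join(missing)}")
    passing.sort(key=lambda r: (_record_pvalue(r), r.variant_id))
    kept: list[SNPAssociation] = []
    for rec in passing:
        if ld is None or all(
            ld.pairwise(rec.variant_id, k.variant_id) <= r2_threshold for k in kept
        ):
            kept.append(rec)
    return kept


def _record_pvalue(r: SNPAssociation) -> float:
    return r.pvalue if r.pvalue is not None else r.wald_pvalue()


# ---------------------------------------------------------------------------
# harmonization


def harmonize(
    exposure: Sequence[SNPAssociation],
    outcome: Sequence[SNPAssociation],
    unit: UnitSpec | None = None,
    exposure_in_sd: bool = True,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
    dropped: list | None = None,
) -> list[HarmonizedInstrument]:
    """Align exposure and outcome estimates to the exposure's effect allele.

    The join is on ``variant_id``. Outcome records coded on the opposite
    allele have ``beta_out`` negated; records whose alleles match only after
    strand complement are complemented first. Palindromic variants (A/T or
    C/G) are dropped when either side's allele frequency is missing or lies
    inside ``palindrome_eaf_window`` — for such variants a strand flip is
    indistinguishable from an allele swap and only a clearly informative
    frequency resolves it; retained palindromes are sign-corrected when the
    two frequencies sit on opposite sides of 0.5. When ``exposure_in_sd`` is
    False the exposure estimates are divided by ``unit.sd`` to move them to
    the per-SD scale.

    Reasons for dropped variants are appended to ``dropped`` (variant_id,
    reason) when a list is supplied, and logged either way.
    """
    if not exposure_in_sd and unit is None:
        raise SummaryDataError("unit must be given when exposure is not per-SD")
    out_by_id = {r.variant_id: r for r in outcome}
    shared = [r for r in exposure if r.variant_id in out_by_id]
    if not shared:
        raise SummaryDataError("no shared variants between exposure and outcome")

    result: list[HarmonizedInstrument] = []
    for exp in shared:
        out = out_by_id[exp.variant_id]
        keep, beta_out, reason = _align_outcome(exp, out, palindrome_eaf_window)
        if not keep:
            logger.info("harmonize: dropping %s (%s)", exp.variant_id, reason)
            if dropped is not None:
                dropped.append((exp.variant_id, reason))
            continue
        beta_exp, se_exp = exp.beta, exp.se
        if not exposure_in_sd:
            beta_exp /= unit.sd
            se_exp /= unit.sd
        result.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                effect_allele=exp.effect_allele,
                beta_exp=beta_exp,
                se_exp=se_exp,
                beta_out=beta_out,
                se_out=out.se,
            )
        )
    return result


def _align_outcome(
    exp: SNPAssociation, out: SNPAssociation, window: tuple[float, float]
) -> tuple[bool, float, str]:
    """Return (keep, aligned beta_out, drop reason)."""
    lo, hi = window
    if exp.is_palindromic:
        if exp.eaf is None or out.eaf is None:
            return False, 0.0, "palindromic with missing eaf"
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return False, 0.0, "palindromic with ambiguous eaf"
        if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
            return False, 0.0, "palindromic allele mismatch"
        # allele labels carry no strand information for a palindrome: the
        # outcome's effect allele matches the exposure's iff the two
        # frequencies fall on the same side of 0.5
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        return True, out.beta if same_side else -out.beta, ""
    if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
        return True, out.beta, ""
    if (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
        return True, -out.beta, ""
    flipped_ea = _COMPLEMENT[out.effect_allele]
    flipped_oa = _COMPLEMENT[out.other_allele]
    if (flipped_ea, flipped_oa) == (exp.effect_allele, exp.other_allele):
        return True, out.beta, ""
    if (flipped_ea, flipped_oa) == (exp.other_allele, exp.effect_allele):
        return True, -out.beta, ""
    return False, 0.0, "incompatible alleles"


def instruments_to_dataframe(instruments: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": h.variant_id,
                "effect_allele": h.effect_allele,
                "beta_exp": h.beta_exp,
                "se_exp": h.se_exp,
                "beta_out": h.beta_out,
                "se_out": h.se_out,
            }
            for h in instruments
        ],
        columns=["variant_id", "effect_allele", "beta_exp", "se_exp", "beta_out", "se_out"],
    )
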