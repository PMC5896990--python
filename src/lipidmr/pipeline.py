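"""End-to-end orchestration: simulate → per-SNP associate → MR → reports.

These functions are the engine behind the command-line interface but are
written against in-memory objects so that programmatic runs (tests, Monte
Carlo studies) skip the filesystem. Every run can write a manifest (config
hash, seed, package version) sufficient to regenerate its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    SeparationError,
    apply_exclusions,
    association_to_snp,
    fit_linear_snp,
    fit_logistic_snp,
)
from .model import MRModel
from .simulate import SimulationConfig, simulate_cohort, simulate_summary_stats
from .strength import strength_report
from .summary import (
    LDMatrix,
    SNPAssociation,
    UnitSpec,
    harmonize,
    read_summary_stats,
    select_instruments,
    write_summary_stats,
)

logger = logging.getLogger(__name__)

#: named covariate sets for the outcome-association stage
COVARIATE_SETS: Mapping[str, tuple[str, ...]] = {
    "primary": ("age", "sex", "center"),
    "sensitivity": ("age", "sex", "center", "PC1", "PC2", "PC3", "PC4", "PC5"),
}

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.001


def write_manifest(path: str | Path, config: Mapping, seed: int | None) -> None:
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# simulate


def run_simulate(cfg: SimulationConfig, outdir: str | Path, mode: str = "both") -> dict:
    """Write synthetic fixtures (cohort and/or two-sample summary stats) + truth."""
    from .cohort import write_coded_records

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    truth: dict = {}
    if mode in ("cohort", "both"):
        syn = simulate_cohort(cfg)
        syn.cohort.write_tsv(outdir / "cohort.tsv")
        write_coded_records(syn.records, outdir / "coded_records.tsv")
        syn.variant_info.to_csv(outdir / "variant_info.tsv", sep="\t", index=False)
        LDMatrix.identity(list(syn.variant_info["variant_id"])).write_tsv(outdir / "ld.tsv")
        truth["cohort"] = syn.truth
        written.update(
            cohort="cohort.tsv", coded_records="coded_records.tsv",
            variant_info="variant_info.tsv", ld="ld.tsv",
        )
    if mode in ("summary", "both"):
        exp, out, t = simulate_summary_stats(cfg)
        write_summary_stats(exp, outdir / "exposure.tsv")
        write_summary_stats(out, outdir / "outcome.tsv")
        LDMatrix.identity([r.variant_id for r in exp]).write_tsv(outdir / "ld_summary.tsv")
        truth["summary"] = t
        written.update(exposure="exposure.tsv", outcome="outcome.tsv", ld_summary="ld_summary.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    write_manifest(outdir / "manifest.json", {"mode": mode, **asdict(cfg)}, cfg.seed)
    return written


# ---------------------------------------------------------------------------
# associate


def associate_cohort(
    cohort: Cohort,
    variant_info: pd.DataFrame,
    exposure_lipid: str,
    unit: UnitSpec,
    covariate_set: str | Sequence[str] = "primary",
    min_fasting_hours: float = 8.0,
) -> tuple[list[SNPAssociation], list[SNPAssociation], dict]:
    """One-sample association stages after eligibility filtering.

    Per variant: OLS of the per-SD exposure lipid on dosage + covariates, and
    logistic regression of the event on dosage + covariates. Returns exposure
    records, outcome records and a log with exclusion counts and per-variant
    failures.
    """
    covariates = (
        COVARIATE_SETS[covariate_set]
        if isinstance(covariate_set, str)
        else tuple(covariate_set)
    )
    retained, counts = apply_exclusions(cohort, min_fasting_hours=min_fasting_hours)
    if len(retained) == 0:
        raise ValueError("no participants remain after exclusions")
    exposure_records: list[SNPAssociation] = []
    outcome_records: list[SNPAssociation] = []
    failures: list[dict] = []
    templates = variant_info.set_index("variant_id").to_dict("index")
    for vid in variant_info["variant_id"]:
        template = templates[vid]
        try:
            lin = fit_linear_snp(
                retained, vid, exposure_lipid, covariates, outcome_sd=unit.sd
            )
            logi = fit_logistic_snp(retained, vid, covariates)
        except SeparationError as exc:
            logger.warning("associate: %s failed: %s", vid, exc)
            failures.append({"variant_id": vid, "error": str(exc)})
            continue
        exposure_records.append(association_to_snp(lin, template))
        outcome_records.append(association_to_snp(logi, template))
    log = {"exclusions": counts, "n_retained": len(retained), "failures": failures}
    return exposure_records, outcome_records, log


def run_associate(
    cohort_path: str | Path,
    variant_info_path: str | Path,
    out_exposure: str | Path,
    out_outcome: str | Path,
    exposure_lipid: str,
    unit_sd: float,
    covariate_set: str = "primary",
) -> dict:
    cohort = Cohort.read_tsv(cohort_path)
    variant_info = pd.read_csv(variant_info_path, sep="\t")
    unit = UnitSpec(exposure_lipid, unit_sd)
    exp, out, log = associate_cohort(
        cohort, variant_info, exposure_lipid, unit, covariate_set
    )
    write_summary_stats(exp, out_exposure)
    write_summary_stats(out, out_outcome)
    return log


# ---------------------------------------------------------------------------
# MR


def run_mr_analysis(
    exposure_records: Sequence[SNPAssociation],
    outcome_records: Sequence[SNPAssociation],
    ld: LDMatrix | None = None,
    exposure_name: str = "exposure",
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    unit: UnitSpec | None = None,
    exposure_in_sd: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Select instruments, harmonize, run all three estimators + diagnostics.

    Returns the method-per-row report (odds-ratio scale with I², Q and Egger
    intercept columns) and a stage log with instrument counts.
    """
    selected = select_instruments(exposure_records, p_threshold, ld, r2_threshold)
    dropped: list = []
    instruments = harmonize(
        selected, outcome_records, unit=unit, exposure_in_sd=exposure_in_sd, dropped=dropped
    )
    if len(instruments) < 3:
        raise ValueError(
            f"only {len(instruments)} instruments after harmonization; need ≥ 3"
        )
    results = MRModel(instruments, exposure=exposure_name).fit(
        "all", n_boot=n_boot, seed=seed
    )
    report = results.summary()
    log = {
        "n_exposure_records": len(exposure_records),
        "n_selected": len(selected),
        "n_harmonized": len(instruments),
        "dropped": dropped,
    }
    return report, log


def run_mr(
    exposure_path: str | Path,
    outcome_path: str | Path,
    out_prefix: str | Path,
    ld_path: str | Path | None = None,
    exposure_name: str = "exposure",
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    unit_sd: float | None = None,
    exposure_in_sd: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    exposure = read_summary_stats(exposure_path)
    outcome = read_summary_stats(outcome_path)
    ld = LDMatrix.read_tsv(ld_path) if ld_path else None
    unit = UnitSpec(exposure_name, unit_sd) if unit_sd else None
    report, log = run_mr_analysis(
        exposure, outcome, ld, exposure_name, p_threshold, r2_threshold,
        unit, exposure_in_sd, n_boot, seed,
    )
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(f"{prefix}_report.tsv", sep="\t", index=False)
    Path(f"{prefix}_report.json").write_text(
        json.dumps(
            {"report": report.to_dict("records"), "log": log}, indent=2, default=float
        )
    )
    write_manifest(
        f"{prefix}_manifest.json",
        {
            "exposure": str(exposure_path),
            "outcome": str(outcome_path),
            "p_threshold": p_threshold,
            "r2_threshold": r2_threshold,
            "n_boot": n_boot,
        },
        seed,
    )
    return report


# ---------------------------------------------------------------------------
# strength


def run_strength(rows: Sequence[Mapping], out_path: str | Path | None = None) -> pd.DataFrame:
    """Assemble the weak-instrument diagnostic table from per-row inputs.

    Each row mapping supplies exposure, source, r2 (or instruments), k,
    n_exposure, overlap, beta_obs, n_outcome, case_fraction.
    """
    reports = [strength_report(**row) for row in rows]
    df = pd.DataFrame([vars(r) for r in reports])
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
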