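"""Cohort stages: Friedewald LDL, exclusions, adjudication, per-SNP fits."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from lipidmr import (
    CodedRecord,
    Cohort,
    Participant,
    SeparationError,
    UnitSpec,
    adjudicate_aaa,
    apply_exclusions,
    fit_linear_snp,
    fit_logistic_snp,
    fit_observational_lipid_model,
    friedewald_ldl,
)
from lipidmr.cohort import (
    AAA_DEATH_CODES,
    AAA_DIAGNOSIS_CODES,
    AAA_PROCEDURE_CODES,
    CohortError,
    SingularDesignError,
)


class TestFriedewald:
    def test_typical_values(self):
        assert friedewald_ldl(214, 51, 128) == pytest.approx(137.4)

    def test_high_triglycerides_undetermined(self):
        assert friedewald_ldl(214, 51, 401) is None
        assert friedewald_ldl(214, 51, 400) == pytest.approx(214 - 51 - 80)

    def test_degenerate_zero(self):
        assert friedewald_ldl(51, 51, 0) == 0

    def test_negative_input_errors(self):
        with pytest.raises(CohortError):
            friedewald_ldl(-1, 50, 100)


def _participant(pid, **kw):
    base = dict(
        race_white=True, has_genotype=True, lipid_med=False, fasting_hours=12.0,
        tc=200.0, hdl=50.0, tg=120.0, ldl=126.0,
    )
    base.update(kw)
    return Participant(pid=pid, **base)


class TestExclusions:
    def test_everyone_passes(self):
        cohort = [_participant(f"P{i}") for i in range(10)]
        retained, counts = apply_exclusions(cohort)
        assert len(retained) == 10
        assert all(v == 0 for v in counts.values())

    def test_first_filter_attribution(self):
        p = _participant("P1", race_white=False, fasting_hours=2.0)
        _, counts = apply_exclusions([p, _participant("P2")])
        assert counts["non_white"] == 1
        assert counts["not_fasting"] == 0

    def test_counts_against_set_arithmetic_oracle(self, rng):
        participants = []
        flags = []
        for i in range(500):
            f = dict(
                race_white=bool(rng.random() > 0.2),
                has_genotype=bool(rng.random() > 0.15),
                lipid_med=bool(rng.random() < 0.1),
                fasting_hours=float(rng.uniform(0, 16)),
                ldl=None if rng.random() < 0.08 else 126.0,
            )
            flags.append(f)
            participants.append(_participant(f"P{i}", **f))
        retained, counts = apply_exclusions(participants, min_fasting_hours=8.0)
        # brute-force first-cause attribution over explicit per-person flags
        expected = dict.fromkeys(counts, 0)
        n_removed = 0
        for f in flags:
            reasons = [
                ("non_white", not f["race_white"]),
                ("missing_genotype", not f["has_genotype"]),
                ("lipid_medication", f["lipid_med"]),
                ("not_fasting", f["fasting_hours"] < 8.0),
                ("missing_lipids", f["ldl"] is None),
            ]
            hit = next((name for name, bad in reasons if bad), None)
            if hit:
                expected[hit] += 1
                n_removed += 1
        assert counts == expected
        assert sum(counts.values()) == 500 - len(retained) == n_removed


def _rec(pid, day, kind, code):
    return CodedRecord(pid, dt.date(2000, 1, 1) + dt.timedelta(days=day), kind,
                       "ICD10" if code.startswith("I") else "ICD9", code)


def _adjudicate_oracle(records):
    """Direct truth-table evaluation of the case definition."""
    status = {}
    for pid in {r.pid for r in records}:
        recs = [r for r in records if r.pid == pid]
        hosp = any(r.record_kind == "hospital_discharge" and r.code in AAA_DIAGNOSIS_CODES
                   for r in recs)
        proc = any(r.record_kind == "procedure" and r.code in AAA_PROCEDURE_CODES
                   for r in recs)
        death = any(r.record_kind == "death_underlying" and r.code in AAA_DEATH_CODES
                    for r in recs)
        out_dates = [r.date for r in recs
                     if r.record_kind == "outpatient" and r.code in AAA_DIAGNOSIS_CODES]
        outp = any(abs((a - b).days) >= 7 for a, b in itertools.combinations(out_dates, 2))
        status[pid] = hosp or proc or death or outp
    return status


class TestAdjudication:
    def test_single_outpatient_is_not_a_case(self):
        assert adjudicate_aaa([_rec("P1", 0, "outpatient", "441.3")]) == {"P1": False}

    @pytest.mark.parametrize("gap,case", [(6, False), (7, True)])
    def test_week_apart_boundary(self, gap, case):
        records = [_rec("P1", 0, "outpatient", "441.4"), _rec("P1", gap, "outpatient", "441.4")]
        assert adjudicate_aaa(records)["P1"] is case

    def test_each_qualifying_route(self):
        assert adjudicate_aaa([_rec("A", 0, "hospital_discharge", "441.3")])["A"]
        assert adjudicate_aaa([_rec("B", 0, "procedure", "38.44")])["B"]
        assert adjudicate_aaa([_rec("C", 0, "death_underlying", "I71.4")])["C"]
        assert not adjudicate_aaa([_rec("D", 0, "hospital_discharge", "410.1")])["D"]

    def test_order_and_duplicate_invariance(self, rng):
        records = [
            _rec("P1", 0, "outpatient", "441.3"),
            _rec("P1", 30, "outpatient", "441.3"),
            _rec("P2", 5, "hospital_discharge", "441.4"),
        ]
        base = adjudicate_aaa(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert adjudicate_aaa(shuffled) == base
        assert adjudicate_aaa(records + records) == base

    def test_date_window_filter(self):
        records = [_rec("P1", 0, "hospital_discharge", "441.3")]
        window = (dt.date(2005, 1, 1), dt.date(2011, 12, 31))
        assert adjudicate_aaa(records, window=window) == {"P1": False}

    def test_matches_brute_force_on_random_record_sets(self, rng):
        kinds = ["hospital_discharge", "outpatient", "procedure", "death_underlying"]
        codes = ["441.3", "441.4", "38.44", "39.71", "I71.3", "I71.4", "410.1", "441.9"]
        for trial in range(200):
            records = [
                _rec(f"P{rng.integers(0, 5)}", int(rng.integers(0, 30)),
                     str(rng.choice(kinds)), str(rng.choice(codes)))
                for _ in range(int(rng.integers(1, 12)))
            ]
            assert adjudicate_aaa(records) == _adjudicate_oracle(records)


def _regression_cohort(rng, n=400, slope=0.5, logistic=False):
    dose = rng.binomial(2, 0.3, n).astype(float)
    age = rng.normal(54, 6, n)
    sex = rng.binomial(1, 0.5, n).astype(float)
    y = slope * dose + 0.02 * age + 0.3 * sex + rng.normal(0, 1, n)
    df = pd.DataFrame({
        "pid": [f"P{i}" for i in range(n)],
        "dose_rs1": dose, "age": age, "sex": sex, "y": y,
        "event": rng.binomial(1, 1 / (1 + np.exp(-(-2.0 + 0.4 * dose)))),
    })
    return Cohort(df)


class TestLinearFit:
    def test_matches_closed_form_without_covariates(self, rng):
        cohort = _regression_cohort(rng)
        fit = fit_linear_snp(cohort, "rs1", "y")
        x = cohort.data["dose_rs1"].to_numpy()
        y = cohort.data["y"].to_numpy()
        xc = x - x.mean()
        beta = float(xc @ y / (xc @ xc))
        resid = y - y.mean() - beta * xc
        se = float(np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc)))
        assert fit.beta == pytest.approx(beta, rel=1e-10)
        assert fit.se == pytest.approx(se, rel=1e-10)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        cohort = _regression_cohort(rng)
        fit = fit_linear_snp(cohort, "rs1", "y", ["age", "sex"])
        X = sm.add_constant(cohort.data[["dose_rs1", "age", "sex"]].to_numpy())
        res = sm.OLS(cohort.data["y"].to_numpy(), X).fit()
        assert fit.beta == pytest.approx(res.params[1], rel=1e-9)
        assert fit.se == pytest.approx(res.bse[1], rel=1e-9)
        assert fit.pvalue == pytest.approx(res.pvalues[1], rel=1e-6)

    def test_recovers_known_slope(self, rng):
        cohort = _regression_cohort(rng, n=5000, slope=0.1)
        fit = fit_linear_snp(cohort, "rs1", "y", ["age", "sex"])
        assert abs(fit.beta - 0.1) < 3 * fit.se

    def test_duplicated_covariate_raises_naming_columns(self, rng):
        cohort = _regression_cohort(rng)
        cohort.data["age2"] = cohort.data["age"]
        with pytest.raises(SingularDesignError, match="age"):
            fit_linear_snp(cohort, "rs1", "y", ["age", "age2"])

    def test_missing_rows_dropped(self, rng):
        cohort = _regression_cohort(rng)
        cohort.data.loc[:49, "y"] = np.nan
        fit = fit_linear_snp(cohort, "rs1", "y")
        assert fit.n_used == len(cohort) - 50


class TestLogisticFit:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        cohort = _regression_cohort(rng, n=2000)
        fit = fit_logistic_snp(cohort, "rs1", ["age", "sex"])
        X = sm.add_constant(cohort.data[["dose_rs1", "age", "sex"]].to_numpy())
        res = sm.Logit(cohort.data["event"].to_numpy(), X).fit(disp=False)
        assert fit.beta == pytest.approx(res.params[1], abs=1e-6)
        assert fit.se == pytest.approx(res.bse[1], rel=1e-4)

    def test_null_dosage(self, rng):
        n = 4000
        df = pd.DataFrame({
            "pid": range(n),
            "dose_rs1": rng.binomial(2, 0.3, n).astype(float),
            "event": rng.binomial(1, 0.5, n),
        })
        fit = fit_logistic_snp(Cohort(df), "rs1")
        assert abs(fit.beta) < 3 * fit.se

    def test_recovers_simulated_log_or(self, rng):
        n = 8000
        dose = rng.binomial(2, 0.3, n).astype(float)
        p = 1 / (1 + np.exp(-(-3.4 + 0.4 * dose)))
        df = pd.DataFrame({"pid": range(n), "dose_rs1": dose, "event": rng.binomial(1, p)})
        fit = fit_logistic_snp(Cohort(df), "rs1")
        assert abs(fit.beta - 0.4) < 3 * fit.se

    def test_loglik_nondecreasing(self, rng):
        cohort = _regression_cohort(rng, n=1000)
        _, trace = fit_logistic_snp(cohort, "rs1", ["age", "sex"], return_history=True)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_all_case_subset_raises_separation(self, rng):
        cohort = _regression_cohort(rng, n=200)
        cohort.data["event"] = 1
        with pytest.raises(SeparationError):
            fit_logistic_snp(cohort, "rs1")

    def test_perfect_separation_raises(self, rng):
        n = 200
        dose = np.repeat([0.0, 2.0], n // 2)
        df = pd.DataFrame({"pid": range(n), "dose_rs1": dose, "event": (dose > 1).astype(int)})
        with pytest.raises(SeparationError):
            fit_logistic_snp(Cohort(df), "rs1")


class TestObservationalModel:
    @staticmethod
    def _cohort(rng, n=9000, beta_per_sd=0.24):
        ldl = rng.normal(136, 37, n)
        hdl = rng.normal(51, 15, n)
        tg = np.maximum(rng.normal(128, 65, n), 1.0)
        tc = ldl + hdl + tg / 5
        x = (ldl - 136) / 38.7
        p = 1 / (1 + np.exp(-(-3.2 + beta_per_sd * x)))
        df = pd.DataFrame({
            "pid": range(n), "ldl": ldl, "hdl": hdl, "tg": tg, "tc": tc,
            "age": rng.normal(54, 6, n), "sex": rng.binomial(1, 0.45, n).astype(float),
            "center": rng.choice(list("ABCD"), n), "smoking": rng.binomial(1, 0.25, n).astype(float),
            "height": rng.normal(168, 9, n), "wbc": rng.normal(6.3, 2, n),
            "fibrinogen": rng.normal(296, 60, n),
            "hypertension": rng.binomial(1, 0.25, n).astype(float),
            "diabetes": rng.binomial(1, 0.08, n).astype(float),
            "pad": rng.binomial(1, 0.02, n).astype(float),
            "event": rng.binomial(1, p),
        })
        return Cohort(df)

    def test_recovers_per_sd_log_or(self, rng):
        cohort = self._cohort(rng)
        fit = fit_observational_lipid_model(cohort, "ldl", UnitSpec("ldl", 38.7))
        assert abs(fit.beta - 0.24) < 3 * fit.se

    def test_permuted_lipid_is_null(self, rng):
        cohort = self._cohort(rng)
        cohort.data["ldl"] = rng.permutation(cohort.data["ldl"].to_numpy())
        fit = fit_observational_lipid_model(cohort, "ldl", UnitSpec("ldl", 38.7))
        assert abs(fit.beta) < 3 * fit.se

    def test_tc_model_excludes_other_lipids(self, rng):
        # TC = LDL + HDL + TG/5 exactly, so including the other fractions
        # would make the design singular; the TC model must fit cleanly, and
        # rows with missing LDL must still be usable.
        cohort = self._cohort(rng)
        cohort.data.loc[:99, "ldl"] = np.nan
        fit = fit_observational_lipid_model(cohort, "tc", UnitSpec("tc", 41.8))
        assert fit.n_used == len(cohort)

    def test_ldl_model_uses_other_lipids(self, rng):
        cohort = self._cohort(rng)
        cohort.data.loc[:99, "hdl"] = np.nan
        fit = fit_observational_lipid_model(cohort, "ldl", UnitSpec("ldl", 38.7))
        assert fit.n_used == len(cohort) - 100
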