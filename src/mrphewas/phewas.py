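"""Flat phenome-wide scan: phecode case/control assembly and logistic regression.

Diagnosis records (individual, ICD10 code) are grouped into phecodes with
control-exclusion ranges and optional sex restrictions; each phecode with
enough cases is tested by covariate-adjusted logistic regression of case
status on the genetic score, with Bonferroni control of the family-wise
error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_MIN_CASES = 200
DEFAULT_ALPHA = 0.05
DEFAULT_SUGGESTIVE_P = 1e-3


class PhecodeMap:
    """ICD10 -> phecode mapping with exclusion ranges and sex restrictions.

    Expects columns icd10, phecode, exclusion_min, exclusion_max, sex
    (sex empty, 'F' or 'M'). Phecodes are decimal strings ordered by their
    numeric value; an individual carrying any code inside a phecode's
    exclusion range is removed from that phecode's controls.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"icd10", "phecode"}
        if missing := required - set(table.columns):
            raise ValueError(f"phecode map missing columns {sorted(missing)}")
        t = table.copy()
        t["icd10"] = t["icd10"].astype(str)
        t["phecode"] = t["phecode"].astype(float)
        for col in ("exclusion_min", "exclusion_max"):
            if col not in t.columns:
                t[col] = np.nan
            t[col] = pd.to_numeric(t[col], errors="coerce")
        if "sex" not in t.columns:
            t["sex"] = ""
        t["sex"] = t["sex"].fillna("").astype(str)
        self.table = t
        self._code_to_phecode = t.groupby("icd10")["phecode"].agg(set).to_dict()

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        return cls(pd.read_csv(path))

    @property
    def phecodes(self) -> np.ndarray:
        return np.sort(self.table["phecode"].unique())

    def phecode_meta(self, phecode: float) -> dict:
        rows = self.table[self.table["phecode"] == phecode]
        return {
            "exclusion_min": float(rows["exclusion_min"].min()),
            "exclusion_max": float(rows["exclusion_max"].max()),
            "sex": next((s for s in rows["sex"] if s), ""),
        }


@dataclass
class PhenotypeAssignments:
    """Per-phecode case/control/excluded partition of the cohort."""

    ids: pd.Index
    cases: dict[float, set]
    excluded: dict[float, set]          # in exclusion range, not a case
    sex_restricted: dict[float, set]    # wrong sex for the phecode
    n_unmapped_records: int = 0

    def case_count(self, phecode: float) -> int:
        return len(self.cases[phecode])

    def labels(self, phecode: float) -> pd.Series:
        """0/1 case flags over testable individuals (excluded ones dropped)."""
        drop = self.excluded[phecode] | self.sex_restricted[phecode]
        keep = self.ids[~self.ids.isin(drop)]
        flags = pd.Series(0, index=keep, dtype=np.int8)
        flags.loc[flags.index.isin(self.cases[phecode])] = 1
        return flags


def build_phenotypes(records: pd.DataFrame, phecode_map: PhecodeMap,
                     cohort_ids: pd.Index,
                     sex: pd.Series | None = None) -> PhenotypeAssignments:
    """Assign every individual to case / control / excluded for each phecode.

    An individual is a case for a phecode if any of their ICD10 records maps
    to it, excluded from controls if any record maps into the phecode's
    exclusion range, and otherwise a control. Records for individuals outside
    ``cohort_ids`` raise; unknown ICD codes are tallied and dropped.
    """
    cohort_ids = pd.Index(cohort_ids)
    if len(records):
        bad = ~records["individual_id"].isin(cohort_ids)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} records reference unknown individuals")

    mapped = records.assign(
        phecodes=records["icd10_code"].astype(str).map(phecode_map._code_to_phecode)
    )
    n_unmapped = int(mapped["phecodes"].isna().sum())
    if n_unmapped:
        warnings.warn(f"dropped {n_unmapped} records with unmapped ICD10 codes")
    mapped = mapped.dropna(subset=["phecodes"])
    long = mapped.explode("phecodes").rename(columns={"phecodes": "phecode"})

    carriers: dict[float, set] = {
        ph: set(g["individual_id"]) for ph, g in long.groupby("phecode")
    }
    all_phecodes = phecode_map.phecodes
    cases, excluded, sex_restricted = {}, {}, {}
    for ph in all_phecodes:
        meta = phecode_map.phecode_meta(ph)
        case_set = carriers.get(ph, set())
        excl = set()
        if not np.isnan(meta["exclusion_min"]):
            lo, hi = meta["exclusion_min"], meta["exclusion_max"]
            for other, members in carriers.items():
                if other != ph and lo <= other <= hi:
                    excl |= members
        excl -= case_set
        restricted = set()
        if meta["sex"] and sex is not None:
            want = 1 if meta["sex"] == "F" else 0
            restricted = set(cohort_ids[sex.reindex(cohort_ids) != want]) - case_set
        cases[ph], excluded[ph] = case_set, excl - restricted
        sex_restricted[ph] = restricted
    return PhenotypeAssignments(cohort_ids, cases, excluded, sex_restricted,
                                n_unmapped)


def filter_min_cases(assignments: PhenotypeAssignments,
                     threshold: int = DEFAULT_MIN_CASES
                     ) -> tuple[list[float], pd.DataFrame]:
    """Keep phecodes with strictly more than ``threshold`` cases.

    Returns the kept phecode list and a table of all phecodes with counts
    and kept/dropped status.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rows = [(ph, assignments.case_count(ph)) for ph in assignments.cases]
    table = pd.DataFrame(rows, columns=["phecode", "n_cases"])
    table["kept"] = table["n_cases"] > threshold
    kept = sorted(table.loc[table["kept"], "phecode"])
    if not kept:
        warnings.warn("no phecode exceeds the minimum case count")
    return kept, table.sort_values("phecode").reset_index(drop=True)


def _design_matrix(score: pd.Series, covariates: pd.DataFrame | None,
                   categorical: tuple[str, ...] = ("centre",)) -> pd.DataFrame:
    X = pd.DataFrame({"score": score})
    if covariates is not None:
        cov = covariates.copy()
        cats = [c for c in categorical if c in cov.columns]
        if cats:
            cov = pd.get_dummies(cov, columns=cats, drop_first=True, dtype=float)
        X = X.join(cov.astype(float))
    return sm.add_constant(X, has_constant="add")


def logistic_scan(score: pd.Series, assignments: PhenotypeAssignments,
                  covariates: pd.DataFrame | None = None,
                  phecodes=None,
                  categorical: tuple[str, ...] = ("centre",)) -> pd.DataFrame:
    """Covariate-adjusted logistic regression of each phecode on the score.

    Returns one row per phecode: n_cases, n_controls, beta (log-odds per
    score unit), se, p_value and a convergence flag. Separation or
    non-convergence yields a flagged row, never an exception.
    """
    if phecodes is None:
        phecodes = sorted(assignments.cases)
    X_full = _design_matrix(score, covariates, categorical)
    rows = []
    for ph in phecodes:
        y = assignments.labels(ph)
        n_cases = int(y.sum())
        n_controls = int(len(y) - n_cases)
        beta = se = p = np.nan
        converged = False
        if n_cases > 0 and n_controls > 0:
            X = X_full.loc[y.index]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y.to_numpy(float), X.to_numpy(float)).fit(
                        disp=0, maxiter=50)
                converged = bool(fit.mle_retvals["converged"])
                if converged and np.isfinite(fit.bse[1]) and fit.bse[1] < 1e3:
                    beta, se = float(fit.params[1]), float(fit.bse[1])
                    p = float(fit.pvalues[1])
                else:
                    converged = False
            except (PerfectSeparationError, np.linalg.LinAlgError):
                converged = False
        rows.append((ph, n_cases, n_controls, beta, se, p, converged))
    return pd.DataFrame(rows, columns=["phecode", "n_cases", "n_controls",
                                       "beta", "se", "p_value", "converged"])


def bonferroni_threshold(m: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    return alpha / m


def scan_report(results: pd.DataFrame, threshold: float,
                suggestive: float = DEFAULT_SUGGESTIVE_P) -> pd.DataFrame:
    """Rank scan results and flag significant / suggestive associations.

    Adds Manhattan-ready columns: the integer phecode group and -log10 p.
    Non-converged fits are ranked last and never flagged.
    """
    if results.empty:
        raise ValueError("empty results table")
    out = results.copy()
    out["significant"] = (out["p_value"] < threshold) & out["converged"]
    out["suggestive"] = ((out["p_value"] < suggestive) & ~out["significant"]
                         & out["converged"])
    out["phecode_group"] = out["phecode"].astype(float).astype(int)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
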