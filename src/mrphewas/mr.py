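"""Mendelian-randomization estimators and effect-scale conversion.

Implements the three standard estimators for a polygenic instrument:
per-SNP Wald ratios combined by fixed-effect inverse-variance weighting
(IVW), MR-Egger weighted regression with a free pleiotropy intercept, and
two-stage estimation dividing the score->outcome coefficient by an external
first-stage score->exposure coefficient. Causal effects are reported per
unit log-exposure and rescaled to an odds ratio per SD of log-exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: SD of log-exposure used to express effects per SD (reference-panel value).
DEFAULT_EXPOSURE_SD = 0.430
#: Exact normal 97.5% quantile used for 95% confidence intervals.
Z_975 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate.

    beta is per unit log-exposure; or_per_sd = exp(beta x sd) with its 95% CI.
    egger_intercept fields are populated only for the Egger method.
    """

    method: str
    beta: float
    se: float
    p_value: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    n_snps: int | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "p_value": self.p_value, "or_per_sd": self.or_per_sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "egger_intercept": self.egger_intercept,
            "intercept_p": self.intercept_p,
        }


class MRSummary:
    """Per-SNP summary statistics for summary-level MR.

    Columns: snp_id, beta_exposure, se_exposure, beta_outcome, se_outcome.
    beta_exposure is per effect allele on the log-exposure scale;
    beta_outcome per effect allele on the outcome scale (log-odds for a
    binary outcome).
    """

    REQUIRED = ("snp_id", "beta_exposure", "se_exposure",
                "beta_outcome", "se_outcome")

    def __init__(self, table: pd.DataFrame):
        if missing := set(self.REQUIRED) - set(table.columns):
            raise ValueError(f"summary table missing columns {sorted(missing)}")
        t = table.loc[:, list(self.REQUIRED)].copy()
        if t["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in summary table")
        if (t[["se_exposure", "se_outcome"]] <= 0).to_numpy().any():
            raise ValueError("standard errors must be positive")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "MRSummary":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.table)

    def harmonized(self) -> pd.DataFrame:
        """Orient every SNP so beta_exposure > 0 (flips both betas)."""
        t = self.table.copy()
        flip = t["beta_exposure"] < 0
        t.loc[flip, ["beta_exposure", "beta_outcome"]] *= -1
        return t


def _two_sided_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def scale_to_or_per_sd(beta: float, se: float,
                       sd: float = DEFAULT_EXPOSURE_SD
                       ) -> tuple[float, float, float]:
    """Convert a per-unit-log-exposure effect to an OR per SD with 95% CI.

    or = exp(beta x sd); ci = exp((beta -/+ 1.959964 x se) x sd).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    or_per_sd = float(np.exp(beta * sd))
    ci_low = float(np.exp((beta - Z_975 * se) * sd))
    ci_high = float(np.exp((beta + Z_975 * se) * sd))
    return or_per_sd, ci_low, ci_high


def _estimate(method: str, beta: float, se: float, sd: float,
              n_snps: int | None = None, **kw) -> MREstimate:
    or_per_sd, lo, hi = scale_to_or_per_sd(beta, se, sd)
    return MREstimate(method=method, beta=beta, se=se,
                      p_value=_two_sided_p(beta / se), or_per_sd=or_per_sd,
                      ci_low=lo, ci_high=hi, n_snps=n_snps, **kw)


def wald_ratio(beta_outcome: float, beta_exposure: float,
               se_outcome: float) -> tuple[float, float]:
    """Single-SNP ratio estimate with first-order standard error."""
    if beta_exposure == 0:
        raise ValueError("beta_exposure must be non-zero")
    return beta_outcome / beta_exposure, se_outcome / abs(beta_exposure)


def ivw(summary: MRSummary, sd: float = DEFAULT_EXPOSURE_SD) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    beta = sum(bx by / sy^2) / sum(bx^2 / sy^2); se = 1/sqrt(sum(bx^2/sy^2)).
    Equivalent to zero-intercept weighted regression of by on bx with
    weights 1/sy^2; reduces to the Wald ratio for one SNP.
    """
    t = summary.table
    bx = t["beta_exposure"].to_numpy(float)
    by = t["beta_outcome"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    if np.all(bx == 0):
        raise ValueError("all beta_exposure are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    return _estimate("ivw", beta, se, sd, n_snps=len(t))


def egger(summary: MRSummary, sd: float = DEFAULT_EXPOSURE_SD) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    SNPs are first oriented so beta_exposure > 0. The intercept estimates
    average directional pleiotropy; its p-value is the pleiotropy test.
    Standard errors carry a multiplicative overdispersion factor floored at 1.
    """
    if len(summary) < 3:
        raise ValueError("Egger regression requires at least 3 SNPs")
    t = summary.harmonized()
    bx = t["beta_exposure"].to_numpy(float)
    by = t["beta_outcome"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    if np.ptp(bx) < 1e-12 * max(1.0, np.abs(bx).max()):
        raise ValueError("beta_exposure values are collinear with the "
                         "intercept; Egger slope not identifiable")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # statsmodels scales covariances by the estimated residual variance;
    # floor that factor at 1 (never shrink below the fixed-effect SE)
    adjust = np.sqrt(max(1.0, float(fit.scale)) / float(fit.scale))
    slope, slope_se = float(fit.params[1]), float(fit.bse[1]) * adjust
    inter, inter_se = float(fit.params[0]), float(fit.bse[0]) * adjust
    return _estimate("egger", slope, slope_se, sd, n_snps=len(t),
                     egger_intercept=inter, intercept_se=inter_se,
                     intercept_p=_two_sided_p(inter / inter_se))


def two_stage(score, outcome, covariates=None, *,
              first_stage_beta: float, first_stage_se: float = 0.0,
              sd: float = DEFAULT_EXPOSURE_SD,
              categorical: tuple[str, ...] = ("centre",)) -> MREstimate:
    """Two-stage estimate with an external first stage.

    Stage 2 regresses the outcome on the score (logistic when the outcome is
    binary, linear otherwise) with covariates; the causal effect is
    stage2_beta / first_stage_beta, with first-stage uncertainty propagated
    by the delta method: se^2 = se2^2/b1^2 + b2^2 se1^2 / b1^4.
    """
    if first_stage_beta == 0:
        raise ValueError("first_stage_beta must be non-zero")
    from .phewas import _design_matrix

    score = pd.Series(np.asarray(score, float)) if not isinstance(
        score, pd.Series) else score
    y = np.asarray(outcome, float)
    X = _design_matrix(score, covariates, categorical).to_numpy(float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        fit = sm.Logit(y, X).fit(disp=0)
    else:
        fit = sm.OLS(y, X).fit()
    b2, se2 = float(fit.params[1]), float(fit.bse[1])
    b1 = first_stage_beta
    beta = b2 / b1
    se = float(np.sqrt(se2**2 / b1**2 + b2**2 * first_stage_se**2 / b1**4))
    return _estimate("two_stage", beta, se, sd)


def merge_case_sources(emr_cases, sr_cases, cohort_ids=None
                       ) -> tuple[pd.Series, dict[str, int]]:
    """Union EMR-derived and self-reported case sets with provenance counts.

    Returns case flags (indexed by cohort_ids when given, else by the union
    of ids) and counts {emr_only, sr_only, both, total}; the three sources
    sum to the total.
    """
    emr, sr = set(emr_cases), set(sr_cases)
    union = emr | sr
    if cohort_ids is not None:
        ids = pd.Index(cohort_ids)
        if stray := union - set(ids):
            raise ValueError(f"{len(stray)} case ids not in cohort")
    else:
        ids = pd.Index(sorted(union))
    counts = {
        "emr_only": len(emr - sr),
        "sr_only": len(sr - emr),
        "both": len(emr & sr),
        "total": len(union),
    }
    flags = pd.Series(ids.isin(union).astype(np.int8), index=ids, name="case")
    return flags, counts


def estimates_table(estimates: list[MREstimate]) -> pd.DataFrame:
    """Stack estimates into a table matching the standard reporting layout."""
    return pd.DataFrame([e.to_row() for e in estimates])
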