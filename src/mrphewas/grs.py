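"""Weighted genetic-risk score construction and instrument QC.

Covers score building with explicit missing-dosage policies, Hardy-Weinberg
checks (chi-square and exact mid-p), score/confounder balance tests, and the
single-predictor instrument-strength F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm

from .panel import InstrumentPanel

MISSING_POLICIES = ("mean_impute", "rescale", "drop")


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    p_chi2: float
    p_exact_mid: float
    monomorphic: bool = False


@dataclass(frozen=True)
class BalanceResult:
    kind: str                 # "continuous" | "categorical"
    statistic: float          # slope (continuous) or ANOVA F (categorical)
    se: float | None
    p_value: float


def missing_dosage_policy(dosages: pd.DataFrame, panel: InstrumentPanel,
                          policy: str = "mean_impute") -> pd.DataFrame:
    """Resolve missing dosages before scoring.

    mean_impute substitutes 2 x effect-allele frequency; drop removes
    individuals with any missing dosage; rescale leaves NaNs in place (the
    score builder reweights per individual).
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {MISSING_POLICIES}")
    _check_columns(dosages, panel)
    if policy == "drop":
        return dosages.dropna()
    if policy == "rescale" or not dosages.isna().to_numpy().any():
        return dosages
    fill = dict(zip(panel.snp_ids, 2.0 * panel.freq_array))
    return dosages.fillna(fill)


def _check_columns(dosages: pd.DataFrame, panel: InstrumentPanel) -> None:
    if set(dosages.columns) != set(panel.snp_ids):
        raise ValueError("dosage columns do not match panel snp_ids")
    vals = dosages.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
            raise ValueError("dosages must lie in [0, 2]")


def weighted_score(dosages: pd.DataFrame, panel: InstrumentPanel,
                   policy: str = "mean_impute") -> tuple[pd.Series, pd.Series]:
    """score_i = sum_j weight_j x dosage_ij over the panel SNPs.

    Returns the score and per-individual completeness (fraction of non-missing
    dosages before imputation).
    """
    _check_columns(dosages, panel)
    ordered = dosages[list(panel.snp_ids)]
    completeness = ordered.notna().mean(axis=1)
    resolved = missing_dosage_policy(ordered, panel, policy)
    w = panel.weight_array
    if policy == "rescale":
        mat = np.ma.masked_invalid(resolved.to_numpy(dtype=float))
        raw = np.ma.dot(mat, w)
        observed_w = (~mat.mask) @ np.abs(w) if mat.mask is not np.ma.nomask \
            else np.full(len(resolved), np.abs(w).sum())
        if np.any(observed_w == 0):
            raise ValueError("individual with no observed dosages under rescale")
        score = np.asarray(raw) * np.abs(w).sum() / observed_w
    else:
        score = resolved.to_numpy(dtype=float) @ w
    score = pd.Series(score, index=resolved.index, name="score")
    return score, completeness.loc[resolved.index]


def hwe_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> HWEResult:
    """Hardy-Weinberg goodness of fit from genotype counts.

    Reports the 1-df chi-square test against expected counts at the sample
    allele frequency and the mid-p exact test; a monomorphic SNP gets p = 1
    by convention and is flagged.
    """
    counts = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count is zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(0.0, 1.0, 1.0, monomorphic=True)
    q = 1 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    p_mid = _hwe_exact_mid_p(int(counts[0]), int(counts[1]), int(counts[2]))
    return HWEResult(chi2, p_chi2, p_mid)


def _hwe_exact_mid_p(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Mid-p exact Hardy-Weinberg test, conditioning on the allele counts.

    The conditional law of the heterozygote count given the rare-allele
    count is evaluated over its full support (heterozygote counts share the
    rare-allele count's parity); mid-p halves the probability of outcomes
    exactly as likely as the observed one.
    """
    n = n_hom_a + n_het + n_hom_b
    n_rare = min(2 * n_hom_a + n_het, 2 * n_hom_b + n_het)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (hets * np.log(2.0) + gammaln(n + 1)
            - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    less = prob[prob < p_obs * (1 - 1e-12)].sum()
    ties = prob[np.abs(prob - p_obs) <= p_obs * 1e-12].sum()
    return float(min(1.0, less + 0.5 * ties))


def qc_report(dosages: pd.DataFrame, panel: InstrumentPanel,
              covariates: pd.DataFrame | None = None,
              categorical: tuple[str, ...] = ("sex", "centre"),
              r2: float | None = None, n_reference: int | None = None,
              policy: str = "mean_impute") -> dict:
    """Assemble the instrument QC report: per-SNP HWE, covariate balance,
    instrument strength. Returns a JSON-serializable dict."""
    report: dict = {"missing_policy": policy, "hwe": {}, "balance": {}}
    for snp, freq in zip(panel.snp_ids, panel.freq_array):
        col = dosages[snp].dropna().astype(int)
        res = hwe_test(int((col == 2).sum()), int((col == 1).sum()),
                       int((col == 0).sum()))
        report["hwe"][snp] = asdict(res) | {"effect_allele_freq_expected": freq}
    if covariates is not None:
        score, _ = weighted_score(dosages, panel, policy)
        for cov in covariates.columns:
            kind = "categorical" if cov in categorical else "continuous"
            res = confounder_balance(score, covariates[cov], kind)
            report["balance"][cov] = asdict(res)
    if r2 is not None and n_reference is not None:
        report["instrument_strength"] = {
            "r2": r2, "n": n_reference,
            "f_statistic": instrument_strength(r2, n_reference),
        }
    return report


def confounder_balance(score: pd.Series, covariate: pd.Series,
                       kind: str) -> BalanceResult:
    """Test association between the score and one potential confounder.

    Continuous covariates: univariate linear regression covariate ~ score
    (slope is in covariate units). Categorical covariates: one-way ANOVA of
    the score across levels.
    """
    df = pd.DataFrame({"score": score, "cov": covariate}).dropna()
    if kind == "continuous":
        fit = sm.OLS(df["cov"], sm.add_constant(df["score"])).fit()
        return BalanceResult("continuous", float(fit.params["score"]),
                             float(fit.bse["score"]),
                             float(fit.pvalues["score"]))
    if kind == "categorical":
        groups = [g["score"].to_numpy() for _, g in df.groupby("cov")]
        if len(groups) < 2:
            raise ValueError("categorical covariate needs >= 2 levels")
        f, p = stats.f_oneway(*groups)
        return BalanceResult("categorical", float(f), None, float(p))
    raise ValueError(f"unknown kind {kind!r}")


def instrument_strength(r2: float, n: int) -> float:
    """Single-predictor first-stage F statistic: (n - 2) r2 / (1 - r2)."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie strictly in (0,1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return (n - 2) * r2 / (1 - r2)
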