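"""Synthetic genotype/phenotype cohorts with the structure an MR-PheWAS assumes.

The generator emulates a biobank-style cohort: a small SNP panel in
Hardy-Weinberg equilibrium, a weighted score explaining a configurable share
of a log-scale exposure, binary outcomes produced by a logistic model with a
configurable causal odds ratio per SD of exposure, and hierarchical (ICD10-like)
diagnosis records derived from outcome status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .panel import InstrumentPanel, default_panel

#: SD of the log-transformed exposure in the external reference panel.
DEFAULT_EXPOSURE_SD = 0.430
#: Fraction of exposure variance explained by the instrument in the source GWAS.
DEFAULT_TARGET_R2 = 0.0284


@dataclass(frozen=True)
class OutcomeSpec:
    """One binary outcome to simulate.

    causal_or_per_sd is the odds ratio per SD of log-exposure; 1.0 simulates
    the null. icd10_codes are the leaf codes emitted for cases.
    """

    name: str
    prevalence: float
    causal_or_per_sd: float = 1.0
    icd10_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.causal_or_per_sd < 0:
            raise ValueError("causal_or_per_sd must be >= 0")


@dataclass
class SimConfig:
    """Cohort-simulation settings; reproducible given ``seed``."""

    n_individuals: int = 10_000
    panel: InstrumentPanel = field(default_factory=default_panel)
    target_r2: float = DEFAULT_TARGET_R2
    exposure_sd: float = DEFAULT_EXPOSURE_SD
    outcomes: tuple[OutcomeSpec, ...] = ()
    # per-covariate (effect on exposure, effect on outcome log-odds)
    confounder_effects: dict[str, tuple[float, float]] | None = None
    # per-SNP direct effects on outcome log-odds ("invalid instrument" switch)
    pleiotropy_effects: dict[str, float] | None = None
    n_centres: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie strictly in (0,1)")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")


@dataclass
class SyntheticCohort:
    """Container for one simulated cohort."""

    dosages: pd.DataFrame          # individuals x SNPs, values {0,1,2}
    covariates: pd.DataFrame       # age, sex, bmi, centre, east, north, pc1..pc5
    exposure: pd.Series            # log-exposure
    score: pd.Series               # weighted allele score
    first_stage_beta: float        # realized exposure-per-score-unit slope
    outcomes: pd.DataFrame         # individuals x outcome flags (0/1)
    records: pd.DataFrame          # (individual_id, icd10_code)
    config: SimConfig

    @property
    def ids(self) -> pd.Index:
        return self.dosages.index


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, freqs, seed=0, snp_ids=None) -> pd.DataFrame:
    """Draw unlinked dosages with each SNP column ~ Binomial(2, freq).

    Hardy-Weinberg equilibrium holds by construction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("freqs must be a non-empty 1-d sequence")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0,1)")
    rng = _as_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n, freqs.size))
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(freqs.size)]
    return pd.DataFrame(dosages, columns=list(snp_ids),
                        index=pd.RangeIndex(n, name="individual_id"))


def simulate_exposure(dosages, weights, target_r2: float,
                      exposure_sd: float = DEFAULT_EXPOSURE_SD,
                      seed=0) -> tuple[np.ndarray, float]:
    """Simulate a log-exposure so the weighted score explains ``target_r2``.

    Gaussian noise is added with variance solving
    var(score)/(var(score)+sigma^2) = target_r2, and the sum is rescaled
    affinely so its SD equals ``exposure_sd``.

    Returns
    -------
    exposure : ndarray
    first_stage_beta : float
        Realized OLS slope of exposure on the (unscaled) score — the first
        stage an MR two-stage analysis would use.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie strictly in (0,1)")
    if exposure_sd <= 0:
        raise ValueError("exposure_sd must be positive")
    dosage_mat = np.asarray(dosages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    score = dosage_mat @ weights
    var_score = float(np.var(score))
    if var_score == 0:
        raise ValueError("degenerate instrument: score has zero variance")
    rng = _as_rng(seed)
    sigma = np.sqrt(var_score * (1 - target_r2) / target_r2)
    raw = score + rng.normal(0.0, sigma, size=score.shape)
    scale = exposure_sd / raw.std()
    exposure = raw * scale
    centred = score - score.mean()
    beta = float(centred @ (exposure - exposure.mean()) / (centred @ centred))
    return exposure, beta


def solve_prevalence_intercept(eta: np.ndarray, prevalence: float,
                               tol: float = 1e-3) -> float:
    """Bisection for the logistic intercept giving a target marginal prevalence.

    Finds alpha in [-30, 30] such that mean(expit(alpha + eta)) matches
    ``prevalence`` within ``tol``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0,1)")

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta))) - prevalence

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("prevalence not attainable for given linear predictor")
    alpha = brentq(gap, lo, hi, xtol=1e-8)
    if abs(gap(alpha)) > tol:
        raise RuntimeError("intercept solver failed to reach tolerance")
    return float(alpha)


def simulate_binary_outcome(exposure, prevalence: float, causal_or_per_sd: float,
                            exposure_sd: float = DEFAULT_EXPOSURE_SD,
                            confounders=None, confounder_betas=None,
                            extra_eta=None, seed=0) -> np.ndarray:
    """Draw case flags from logit P = alpha + ln(OR) * exposure/SD + confounders.

    The intercept is solved numerically so the marginal case probability
    equals ``prevalence``.
    """
    if causal_or_per_sd <= 0:
        raise ValueError("causal_or_per_sd must be > 0")
    exposure = np.asarray(exposure, dtype=float)
    eta = np.log(causal_or_per_sd) * exposure / exposure_sd
    if confounders is not None and confounder_betas is not None:
        eta = eta + np.asarray(confounders, dtype=float) @ np.asarray(
            confounder_betas, dtype=float)
    if extra_eta is not None:
        eta = eta + np.asarray(extra_eta, dtype=float)
    alpha = solve_prevalence_intercept(eta, prevalence)
    rng = _as_rng(seed)
    return (rng.random(exposure.shape) < expit(alpha + eta)).astype(np.int8)


def simulate_icd_records(case_flags: pd.DataFrame,
                         outcome_codes: dict[str, tuple[str, ...]],
                         tree_edges: pd.DataFrame,
                         sibling_leakage: float = 0.0,
                         background_rate: float = 0.0,
                         background_codes=None,
                         seed=0) -> pd.DataFrame:
    """Emit (individual_id, icd10_code) diagnosis records.

    Cases emit their mapped leaf code(s); with probability ``sibling_leakage``
    a case also emits one sibling leaf of the mapped code (creating the
    tree-correlated signal a hierarchical scan exploits). Every individual
    independently emits each background code with probability
    ``background_rate``.
    """
    parent_of = dict(zip(tree_edges["child"].astype(str),
                         tree_edges["parent"].astype(str)))
    children_of: dict[str, list[str]] = {}
    for child, parent in parent_of.items():
        children_of.setdefault(parent, []).append(child)
    known = set(parent_of) | set(parent_of.values())
    for name, codes in outcome_codes.items():
        if not codes:
            raise ValueError(f"outcome {name!r} has no mapped codes")
        unknown = [c for c in codes if c not in known]
        if unknown:
            raise ValueError(f"outcome {name!r} mapped to unknown codes {unknown}")

    rng = _as_rng(seed)
    ids: list = []
    codes_out: list[str] = []
    index = case_flags.index
    for name in case_flags.columns:
        mapped = outcome_codes.get(name, ())
        carriers = index[case_flags[name].to_numpy().astype(bool)]
        for code in mapped:
            ids.extend(carriers)
            codes_out.extend([code] * len(carriers))
            siblings = [c for c in children_of.get(parent_of.get(code, ""), [])
                        if c != code and c not in children_of]  # leaf siblings
            if sibling_leakage > 0 and siblings:
                leak = carriers[rng.random(len(carriers)) < sibling_leakage]
                sib = rng.choice(siblings, size=len(leak))
                ids.extend(leak)
                codes_out.extend(sib)
    if background_rate > 0 and background_codes:
        for code in background_codes:
            if code not in known:
                raise ValueError(f"unknown background code {code!r}")
            hit = index[rng.random(len(index)) < background_rate]
            ids.extend(hit)
            codes_out.extend([code] * len(hit))
    out = pd.DataFrame({"individual_id": ids, "icd10_code": codes_out})
    return out.sort_values(["individual_id", "icd10_code"]).reset_index(drop=True)


def _simulate_covariates(n: int, n_centres: int, rng: np.random.Generator) -> pd.DataFrame:
    # marginals loosely matching a middle-aged UK cohort
    return pd.DataFrame(
        {
            "age": rng.normal(56.9, 8.0, n),
            "sex": rng.binomial(1, 0.537, n),  # 1 = female
            "bmi": rng.normal(27.4, 4.76, n),
            "centre": rng.integers(0, n_centres, n),
            "east": rng.normal(0.0, 1.0, n),
            "north": rng.normal(0.0, 1.0, n),
            **{f"pc{i}": rng.normal(0.0, 1.0, n) for i in range(1, 6)},
        },
        index=pd.RangeIndex(n, name="individual_id"),
    )


def simulate_cohort(config: SimConfig,
                    tree_edges: pd.DataFrame | None = None,
                    sibling_leakage: float = 0.0,
                    background_rate: float = 0.0,
                    background_codes=None) -> SyntheticCohort:
    """Generate a full cohort: genotypes, covariates, exposure, outcomes, records.

    By default covariates are independent of genotype, so the instrument is
    valid; ``confounder_effects`` adds covariate paths to exposure and outcome,
    and ``pleiotropy_effects`` adds direct SNP->outcome paths for testing
    pleiotropy diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    dosages = simulate_genotypes(config.n_individuals, panel.freq_array,
                                 seed=rng, snp_ids=panel.snp_ids)
    covariates = _simulate_covariates(config.n_individuals, config.n_centres, rng)

    exposure, beta1 = simulate_exposure(dosages, panel.weight_array,
                                        config.target_r2, config.exposure_sd,
                                        seed=rng)
    if config.confounder_effects:
        for cov, (eff_x, _eff_y) in config.confounder_effects.items():
            z = covariates[cov].to_numpy(dtype=float)
            exposure = exposure + eff_x * (z - z.mean()) / z.std()

    score = pd.Series(dosages.to_numpy(float) @ panel.weight_array,
                      index=dosages.index, name="score")

    outcome_flags = {}
    for spec in config.outcomes:
        extra = np.zeros(config.n_individuals)
        conf = conf_betas = None
        if config.confounder_effects:
            cols = list(config.confounder_effects)
            conf = ((covariates[cols] - covariates[cols].mean())
                    / covariates[cols].std()).to_numpy()
            conf_betas = [config.confounder_effects[c][1] for c in cols]
        if config.pleiotropy_effects:
            for snp, eff in config.pleiotropy_effects.items():
                extra += eff * dosages[snp].to_numpy(float)
        outcome_flags[spec.name] = simulate_binary_outcome(
            exposure, spec.prevalence, spec.causal_or_per_sd,
            exposure_sd=config.exposure_sd, confounders=conf,
            confounder_betas=conf_betas, extra_eta=extra, seed=rng)
    outcomes = pd.DataFrame(outcome_flags, index=dosages.index)

    if tree_edges is not None and len(config.outcomes):
        codes = {s.name: s.icd10_codes for s in config.outcomes if s.icd10_codes}
        records = simulate_icd_records(outcomes[list(codes)], codes, tree_edges,
                                       sibling_leakage=sibling_leakage,
                                       background_rate=background_rate,
                                       background_codes=background_codes,
                                       seed=rng)
    else:
        records = pd.DataFrame(columns=["individual_id", "icd10_code"])

    return SyntheticCohort(
        dosages=dosages, covariates=covariates,
        exposure=pd.Series(exposure, index=dosages.index, name="log_exposure"),
        score=score, first_stage_beta=beta1, outcomes=outcomes,
        records=records, config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write cohort tables as TSV plus a run manifest JSON; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in [("dosages", cohort.dosages),
                        ("covariates", cohort.covariates),
                        ("outcomes", cohort.outcomes)]:
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t")
        paths[name] = str(p)
    p = out / "records.tsv"
    cohort.records.to_csv(p, sep="\t", index=False)
    paths["records"] = str(p)
    p = out / "exposure.tsv"
    pd.DataFrame({"score": cohort.score,
                  "log_exposure": cohort.exposure}).to_csv(p, sep="\t")
    paths["exposure"] = str(p)
    manifest = {
        "seed": cohort.config.seed,
        "n_individuals": cohort.config.n_individuals,
        "target_r2": cohort.config.target_r2,
        "exposure_sd": cohort.config.exposure_sd,
        "first_stage_beta": cohort.first_stage_beta,
        "outcomes": [
            {"name": s.name, "prevalence": s.prevalence,
             "causal_or_per_sd": s.causal_or_per_sd}
            for s in cohort.config.outcomes
        ],
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(p)
    return paths


def write_vcf(dosages: pd.DataFrame, panel: InstrumentPanel, path) -> None:
    """Write genotypes as a minimal VCF (GT field only, dosage = effect-allele count)."""
    cols = list(dosages.columns)
    if cols != list(panel.snp_ids):
        raise ValueError("dosage columns must match panel snp_ids")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i}" for i in dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, snp in enumerate(panel.snp_ids):
            # ALT = effect allele, so the ALT count equals the dosage
            gts = "\t".join(gt_map[int(g)] for g in dosages[snp])
            fh.write(f"1\t{j + 1}\t{snp}\t{panel.other_alleles[j]}\t"
                     f"{panel.effect_alleles[j]}\t.\tPASS\t.\tGT\t{gts}\n")
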