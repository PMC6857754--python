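"""End-to-end orchestration: simulate -> score/QC -> PheWAS -> TreeWAS -> power -> MR.

Each stage writes a TSV under the run directory and the run closes with a
manifest recording the seed, thresholds, package version and SHA-256 digests
of every output, so a re-run with the same configuration is byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import InstrumentPanel, default_panel
from .simulate import (SimConfig, OutcomeSpec, simulate_cohort, write_cohort,
                       DEFAULT_EXPOSURE_SD, DEFAULT_TARGET_R2)
from .grs import weighted_score, qc_report
from .phewas import (PhecodeMap, build_phenotypes, filter_min_cases,
                     logistic_scan, bonferroni_threshold, scan_report,
                     DEFAULT_MIN_CASES, DEFAULT_ALPHA)
from .treewas import (TreePrior, build_code_tree, node_summaries,
                      tree_posterior, significant_nodes, DEFAULT_PP_THRESHOLD)
from .mr import MRSummary, ivw, egger, two_stage, estimates_table
from .power import PowerSpec, power_binary


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    n_individuals: int = 20_000
    outcomes: list[dict] = field(default_factory=lambda: [
        {"name": "outcome_a", "prevalence": 0.03, "causal_or_per_sd": 1.0,
         "icd10_codes": ["I10"]},
        {"name": "outcome_b", "prevalence": 0.05, "causal_or_per_sd": 1.0,
         "icd10_codes": ["F32.9"]},
    ])
    min_cases: int = DEFAULT_MIN_CASES
    alpha: float = DEFAULT_ALPHA
    pp_threshold: float = DEFAULT_PP_THRESHOLD
    exposure_sd: float = DEFAULT_EXPOSURE_SD
    target_r2: float = DEFAULT_TARGET_R2
    power_floor: float = 0.80
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "score", "phewas", "treewas", "power", "mr"])
    panel_path: str | None = None
    phecode_map_path: str | None = None
    tree_path: str | None = None
    evidence_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 < self.pp_threshold < 1:
            raise ValueError("pp_threshold must lie in (0,1)")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        for attr in ("panel_path", "phecode_map_path", "tree_path",
                     "evidence_path"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def _bundled(name: str) -> pd.DataFrame:
    with resources.files("mrphewas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def select_mr_outcomes(phewas_results: pd.DataFrame | None,
                       treewas_hits: list[str],
                       evidence: pd.DataFrame | None,
                       power_table: pd.DataFrame,
                       outcome_phecodes: dict[str, float] | None = None,
                       outcome_nodes: dict[str, str] | None = None,
                       power_floor: float = 0.80,
                       power_column: str = "power_or_1.2") -> pd.DataFrame:
    """Select outcomes for MR: adequate power AND (scan hit OR prior evidence).

    ``evidence`` is a table with an ``outcome`` column listing phenotypes
    flagged by prior literature (umbrella reviews / earlier MR studies).
    Returns the power table restricted to selected outcomes with a per-
    outcome rationale column.
    """
    outcome_phecodes = outcome_phecodes or {}
    outcome_nodes = outcome_nodes or {}
    evidence_set = set(evidence["outcome"]) if evidence is not None else set()
    sig_phecodes: set[float] = set()
    if phewas_results is not None and "significant" in phewas_results:
        sig_phecodes = set(
            phewas_results.loc[phewas_results["significant"], "phecode"])
    rows = []
    for entry in power_table.itertuples(index=False):
        power = getattr(entry, power_column.replace(".", "_"), None)
        if power is None:
            power = power_table.loc[power_table["outcome"] == entry.outcome,
                                    power_column].iloc[0]
        reasons = []
        if outcome_phecodes.get(entry.outcome) in sig_phecodes:
            reasons.append("phewas_significant")
        if outcome_nodes.get(entry.outcome) in set(treewas_hits):
            reasons.append("treewas_significant")
        if entry.outcome in evidence_set:
            reasons.append("prior_evidence")
        selected = bool(reasons) and power > power_floor
        rows.append({"outcome": entry.outcome, "power": float(power),
                     "selected": selected,
                     "rationale": "+".join(reasons) if reasons else "none"})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Stage outputs land in ``out_dir``; a failure in any stage propagates with
    earlier outputs left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = (InstrumentPanel.from_csv(config.panel_path)
             if config.panel_path else default_panel())
    tree_edges = (pd.read_csv(config.tree_path) if config.tree_path
                  else _bundled("toy_icd10_tree.csv"))
    phemap = (PhecodeMap.from_csv(config.phecode_map_path)
              if config.phecode_map_path
              else PhecodeMap(_bundled("toy_phecode_map.csv")))
    evidence = (pd.read_csv(config.evidence_path)
                if config.evidence_path else None)

    outputs: dict[str, Path] = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_cases": config.min_cases, "alpha": config.alpha,
            "pp_threshold": config.pp_threshold,
            "exposure_sd": config.exposure_sd, "target_r2": config.target_r2,
            "power_floor": config.power_floor,
        },
        "stages": config.stages,
    }

    specs = tuple(OutcomeSpec(name=o["name"], prevalence=o["prevalence"],
                              causal_or_per_sd=o.get("causal_or_per_sd", 1.0),
                              icd10_codes=tuple(o.get("icd10_codes", ())))
                  for o in config.outcomes)
    sim = SimConfig(n_individuals=config.n_individuals, panel=panel,
                    target_r2=config.target_r2, exposure_sd=config.exposure_sd,
                    outcomes=specs, seed=config.seed)
    cohort = simulate_cohort(sim, tree_edges=tree_edges)
    if "simulate" in config.stages:
        for name, path in write_cohort(cohort, out / "cohort").items():
            outputs[f"cohort_{name}"] = Path(path)

    score, _ = weighted_score(cohort.dosages, panel)
    if "score" in config.stages:
        p = out / "score.tsv"
        score.to_frame().to_csv(p, sep="\t")
        outputs["score"] = p
        report = qc_report(cohort.dosages, panel, cohort.covariates,
                           r2=config.target_r2, n_reference=config.n_individuals)
        p = out / "qc_report.json"
        p.write_text(json.dumps(report, indent=2, default=float))
        outputs["qc_report"] = p

    scan = None
    if "phewas" in config.stages:
        assignments = build_phenotypes(cohort.records, phemap, cohort.ids,
                                       sex=cohort.covariates["sex"])
        kept, counts = filter_min_cases(assignments, config.min_cases)
        results = logistic_scan(score, assignments, cohort.covariates,
                                phecodes=kept)
        m = max(len(results), 1)
        threshold = bonferroni_threshold(m, config.alpha)
        scan = scan_report(results, threshold) if len(results) else results
        p = out / "phewas_results.tsv"
        scan.to_csv(p, sep="\t", index=False)
        outputs["phewas_results"] = p
        manifest["phewas"] = {"m_tests": m, "bonferroni_threshold": threshold,
                              "n_phecodes_dropped": int((~counts["kept"]).sum())}

    tree_hits: list[str] = []
    if "treewas" in config.stages:
        tree = build_code_tree(tree_edges, cohort.records, cohort_ids=cohort.ids)
        summaries = node_summaries(score, tree, cohort.covariates)
        posteriors = tree_posterior(tree, summaries, TreePrior())
        tree_hits = significant_nodes(posteriors, config.pp_threshold)
        p = out / "treewas_posteriors.tsv"
        posteriors.to_csv(p, sep="\t", index=False)
        outputs["treewas_posteriors"] = p
        manifest["treewas"] = {"significant_nodes": tree_hits,
                               "max_pp": float(posteriors["pp_nonzero"].max())}

    power_tab = None
    if "power" in config.stages:
        rows = []
        for spec in specs:
            n_cases = int(cohort.outcomes[spec.name].sum())
            entry = {"outcome": spec.name, "n_total": config.n_individuals,
                     "n_cases": n_cases}
            for or_alt in (1.2, 1.1):
                entry[f"power_or_{or_alt:g}"] = power_binary(PowerSpec(
                    n_total=config.n_individuals, n_cases=max(n_cases, 1),
                    r2=config.target_r2, or_alt=or_alt, alpha=config.alpha))
            rows.append(entry)
        power_tab = pd.DataFrame(rows)
        p = out / "power_table.tsv"
        power_tab.to_csv(p, sep="\t", index=False)
        outputs["power_table"] = p

    if "mr" in config.stages and power_tab is not None:
        selection = select_mr_outcomes(
            scan, tree_hits, evidence, power_tab,
            power_floor=config.power_floor)
        p = out / "mr_selection.tsv"
        selection.to_csv(p, sep="\t", index=False)
        outputs["mr_selection"] = p
        chosen = selection.loc[selection["selected"], "outcome"]
        all_rows = []
        for name in chosen:
            ests = mr_for_outcome(cohort, score, name, panel,
                                  sd=config.exposure_sd)
            tab = estimates_table(ests)
            tab.insert(0, "outcome", name)
            all_rows.append(tab)
        mr_tab = (pd.concat(all_rows, ignore_index=True) if all_rows
                  else pd.DataFrame(columns=["outcome", "method", "beta", "se",
                                             "p_value", "or_per_sd", "ci_low",
                                             "ci_high"]))
        p = out / "mr_estimates.tsv"
        mr_tab.to_csv(p, sep="\t", index=False)
        outputs["mr_estimates"] = p

    manifest["outputs"] = {k: {"path": str(v), "sha256": _digest(v)}
                           for k, v in sorted(outputs.items())}
    manifest["config"] = asdict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def mr_for_outcome(cohort, score: pd.Series, outcome_name: str,
                   panel: InstrumentPanel, sd: float = DEFAULT_EXPOSURE_SD):
    """All three MR estimates for one simulated outcome.

    Per-SNP summary statistics are computed from the cohort (linear fit of
    exposure and logistic fit of the outcome on each dosage); the two-stage
    first stage is the cohort's realized exposure-per-score coefficient.
    """
    import statsmodels.api as sm

    y = cohort.outcomes[outcome_name].to_numpy(float)
    rows = []
    for snp in panel.snp_ids:
        g = cohort.dosages[snp].to_numpy(float)
        X = sm.add_constant(g)
        fx = sm.OLS(cohort.exposure.to_numpy(), X).fit()
        fy = sm.Logit(y, X).fit(disp=0)
        rows.append({"snp_id": snp,
                     "beta_exposure": fx.params[1], "se_exposure": fx.bse[1],
                     "beta_outcome": fy.params[1], "se_outcome": fy.bse[1]})
    summary = MRSummary(pd.DataFrame(rows))
    ests = [
        two_stage(score, y, first_stage_beta=cohort.first_stage_beta, sd=sd),
        ivw(summary, sd=sd),
        egger(summary, sd=sd),
    ]
    return ests
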