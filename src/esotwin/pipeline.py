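"""End-to-end pipeline: histology split -> imputation -> equipoise trimming
-> virtual-twin forest -> counterfactual curves -> gain/loss accounting.

A run is fully described by a :class:`PipelineConfig`; the same config and
seed reproduce the run bit for bit.  The global seed fans out to per-stage
seeds by fixed offsets so individual stages can be re-run in isolation.
All artifacts (eligibility audit, twin table, stratum tables, plots, stage
log, config snapshot) land in the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import accounting, equipoise, simulate, twins
from .cohort import AC, SCC, Cohort, read_cohort, split_by_histology, write_cohort
from .impute import impute as _impute
from .forest import ForestParams
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
_SEED_GENERATE = 0
_SEED_IMPUTE = 101
_SEED_PROPENSITY = 211
_SEED_VT_FOREST = 307


@dataclass
class PipelineConfig:
    """Serializable description of one analysis run."""

    seed: int = 0
    histology: str = AC
    # input: either a cohort CSV path or a generator preset name
    cohort_csv: str | None = None
    preset: str | None = "registry_like"  # registry_like | null | extreme_assignment
    n: int = 4000
    tau: float = 120.0
    p_lo: float = 0.1
    p_hi: float = 0.9
    propensity_ntree: int = 500
    imputation_max_iter: int = 5
    forest: dict = field(default_factory=lambda: {
        "ntree": 300, "nodesize": 15, "max_candidates": 32})
    benefit_threshold: float = accounting.DEFAULT_BENEFIT_THRESHOLD
    outdir: str | None = None

    def validate(self) -> None:
        if self.histology not in (AC, SCC):
            raise ValueError(f"histology must be {AC!r} or {SCC!r}")
        if not 0.0 <= self.p_lo < self.p_hi <= 1.0:
            raise ValueError("equipoise thresholds must satisfy 0 <= p_lo < p_hi <= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.cohort_csv is None and self.preset not in (
                "registry_like", "null", "extreme_assignment"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n <= 0:
            raise ValueError("n must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def forest_params(self) -> ForestParams:
        return ForestParams(**self.forest)


@dataclass
class RunResult:
    config: PipelineConfig
    cohort: Cohort                      # eligible, imputed analysis cohort
    eligibility: equipoise.EligibilityResult
    twin_table: twins.TwinTable
    strata_granular: list
    strata_collapsed: list
    log: dict
    ground_truth: GroundTruth | None = None

    @property
    def delta(self) -> np.ndarray:
        return self.twin_table.delta


def _load_input(config: PipelineConfig) -> tuple[Cohort, GroundTruth | None]:
    if config.cohort_csv is not None:
        return read_cohort(config.cohort_csv), None
    gen_seed = config.seed + _SEED_GENERATE
    preset = {
        "registry_like": simulate.registry_like_preset,
        "null": simulate.null_preset,
        "extreme_assignment": simulate.extreme_assignment_preset,
    }[config.preset]
    gen_cfg = preset(config.histology, n=config.n, seed=gen_seed)
    return simulate.generate(gen_cfg)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis; optionally write a report bundle."""
    config.validate()
    log: dict = {"stages": []}

    def stage(name: str, **counts) -> None:
        log["stages"].append({"stage": name, **counts})
        logger.info("%s: %s", name, counts)

    cohort_all, truth = _load_input(config)
    stage("input", n=len(cohort_all))

    ac, scc = split_by_histology(cohort_all)
    cohort = ac if config.histology == AC else scc
    if truth is not None:
        keep = cohort_all.table["histology"].to_numpy() == config.histology
        truth = GroundTruth(truth.table.loc[keep].reset_index(drop=True),
                            truth.weibull_shape)
    stage("split_by_histology", n=len(cohort))
    if len(cohort) == 0:
        raise RuntimeError(f"stage split_by_histology: no {config.histology} patients")

    cohort_imp, imp_report = _impute(
        cohort, seed=config.seed + _SEED_IMPUTE,
        max_iter=config.imputation_max_iter)
    stage("impute", n=len(cohort_imp), n_imputed=imp_report.total_imputed)

    p_hat = equipoise.fit_treatment_model(
        cohort_imp, seed=config.seed + _SEED_PROPENSITY,
        ntree=config.propensity_ntree)
    elig = equipoise.trim(p_hat, cohort_imp.treatment, config.p_lo, config.p_hi)
    eligible = cohort_imp.subset(elig.eligible)
    if truth is not None:
        truth = GroundTruth(
            truth.table.loc[elig.eligible].reset_index(drop=True),
            truth.weibull_shape)
    stage("equipoise_trim", n_eligible=elig.n_eligible, n_excluded=elig.n_excluded)

    forest, meta = twins.fit_vt_forest(
        eligible, config.forest_params(), seed=config.seed + _SEED_VT_FOREST)
    stage("fit_vt_forest", n=len(eligible), ntree=forest.ntree,
          oob_concordance=forest.oob_concordance_)

    twin_table = twins.twin_curves(forest, meta, eligible, tau=config.tau)
    stage("twin_curves", n=len(twin_table.table))

    granular = accounting.summarize_strata(
        twin_table, collapse_pn=False, threshold=config.benefit_threshold)
    collapsed = accounting.summarize_strata(
        twin_table, collapse_pn=True, threshold=config.benefit_threshold)
    stage("summarize_strata", n_strata=len(granular))

    result = RunResult(config, eligible, elig, twin_table, granular,
                       collapsed, log, truth)
    if config.outdir is not None:
        _write_bundle(result, cohort_imp, imp_report)
    return result


def _write_bundle(result: RunResult, cohort_imp: Cohort, imp_report) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result.config.to_yaml(out / "config.yaml")
        imp_report.to_json(out / "imputation_report.json")
        audit = equipoise.eligibility_by_stratum(cohort_imp, result.eligibility)
        audit.to_csv(out / "eligibility_audit.csv", index=False)
        with open(out / "eligibility_summary.json", "w") as fh:
            json.dump(result.eligibility.summary, fh, indent=2)
        result.twin_table.table.to_csv(out / "twin_table.csv", index=False)
        accounting.strata_frame(result.strata_granular).to_csv(
            out / "strata_granular.csv", index=False)
        accounting.strata_frame(result.strata_collapsed).to_csv(
            out / "strata_collapsed.csv", index=False)
        accounting.table2_style(result.strata_granular,
                                result.strata_collapsed).to_csv(
            out / "stratum_table.csv", index=False)
        accounting.plot_gain_loss(
            result.strata_collapsed, out / "gain_loss_by_pT.svg",
            title=f"{result.config.histology}: months gained/lost within 10 y")
        with open(out / "log.json", "w") as fh:
            json.dump(result.log, fh, indent=2)
    except Exception:
        # remove partial outputs so a failed run leaves no half-written bundle
        for f in out.glob("*"):
            f.unlink()
        raise


def simulate_to_dir(histology: str, n: int, seed: int, outdir,
                    preset: str = "registry_like") -> None:
    """Emit cohort CSV + ground-truth CSV + config snapshot."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fn = {
        "registry_like": simulate.registry_like_preset,
        "null": simulate.null_preset,
        "extreme_assignment": simulate.extreme_assignment_preset,
    }[preset]
    cfg = fn(histology, n=n, seed=seed)
    cohort, truth = simulate.generate(cfg)
    write_cohort(cohort, out / "cohort.csv")
    truth.table.to_csv(out / "ground_truth.csv", index=False)
    snap = asdict(cfg)
    with open(out / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(snap)), fh, sort_keys=False)


def validate_recovery(result: RunResult, tau: float | None = None,
                      min_stratum_n: int = 25,
                      sign_check_months: float = 3.0) -> dict:
    """Compare estimated deltas with closed-form ground truth.

    Reports Spearman correlation between per-patient estimated delta and
    true ITE, a stratum sign-agreement table (restricted to strata with at
    least ``min_stratum_n`` eligible patients and |true median ITE| >=
    ``sign_check_months``), and per-stratum median bias.
    """
    if result.ground_truth is None:
        raise ValueError("recovery validation requires a generator-based run")
    tau = tau if tau is not None else result.config.tau
    truth = result.ground_truth
    if len(truth.table) != len(result.twin_table.table):
        raise ValueError("ground truth and twin table lengths differ")
    true_d = simulate.true_ite(truth, tau)
    est_d = result.delta

    rho = float(spearmanr(est_d, true_d).statistic) if len(est_d) > 2 else float("nan")
    df = pd.DataFrame({
        "pT": result.twin_table.table["pT"],
        "pN": result.twin_table.table["pN"],
        "est": est_d,
        "true": true_d,
    })
    g = (df.groupby(["pT", "pN"], observed=True)
           .agg(n=("est", "size"), est_median=("est", "median"),
                true_median=("true", "median"))
           .reset_index())
    g["bias"] = g["est_median"] - g["true_median"]
    checked = g[(g["n"] >= min_stratum_n)
                & (g["true_median"].abs() >= sign_check_months)].copy()
    checked["sign_agrees"] = np.sign(checked["est_median"]) == np.sign(
        checked["true_median"])
    return {
        "spearman": rho,
        "n": len(df),
        "stratum_table": g,
        "sign_table": checked,
        "sign_agreement_rate": (
            float(checked["sign_agrees"].mean()) if len(checked) else float("nan")),
        "median_bias": float(g["bias"].median()),
        "overall_median_delta": float(np.median(est_d)),
    }
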