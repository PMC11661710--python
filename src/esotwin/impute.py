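"""Iterative random-forest imputation of missing covariates.

Missing cells are initialized with the column median (numeric) or mode
(categorical), then each incomplete covariate is repeatedly regressed on
all other covariates — plus follow-up time and event status, which are
always complete — with a random forest, and its imputed cells refreshed,
until the mean normalized change falls below tolerance or ``max_iter``
rounds have run (the missForest scheme).  Using the outcome as a predictor
keeps the imputation outcome-aware, in the spirit of imputation performed
inside survival trees during growth.

Only independent variables are imputed; outcome fields and treatment must
be complete on entry.  Observed cells are never altered.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass
class CovariateImputation:
    name: str
    n_imputed: int
    method: str  # 'forest-classifier' | 'forest-regressor' | 'mode' | 'median' | 'none'


@dataclass
class ImputationReport:
    covariates: list[CovariateImputation] = field(default_factory=list)
    iterations: int = 0
    convergence_delta: float = float("nan")

    @property
    def total_imputed(self) -> int:
        return sum(c.n_imputed for c in self.covariates)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _code_matrix(cohort: Cohort) -> tuple[np.ndarray, list]:
    """Covariates as a float matrix (categoricals as level codes, NaN for
    missing) plus the outcome/treatment predictor block."""
    specs = list(cohort.schema)
    cols = []
    for spec in specs:
        if spec.kind == "numeric":
            cols.append(cohort.table[spec.name].to_numpy(dtype=float))
        else:
            mapping = {lev: float(i) for i, lev in enumerate(spec.levels)}
            cols.append(cohort.table[spec.name].map(mapping).to_numpy(dtype=float))
    V = np.column_stack(cols)
    extra = np.column_stack([
        cohort.time,
        cohort.event.astype(float),
        cohort.treatment.astype(float),
    ])
    return np.column_stack([V, extra]), specs


def impute(cohort: Cohort, seed: int = 0, max_iter: int = 5,
           tol: float = 1e-3, n_estimators: int = 100,
           ) -> tuple[Cohort, ImputationReport]:
    """Return a fully imputed copy of the cohort and a per-covariate report.

    Deterministic given ``seed``.  A covariate missing in more than 90% of
    rows falls back to plain mode/median imputation with a warning.
    """
    M, specs = _code_matrix(cohort)
    p = len(specs)
    miss = np.isnan(M[:, :p])
    report = ImputationReport()
    if not miss.any():
        for spec in specs:
            report.covariates.append(CovariateImputation(spec.name, 0, "none"))
        return cohort.copy(), report

    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    scale = np.nanstd(M[:, :p], axis=0)
    scale[~(scale > 0)] = 1.0

    # initialize with median / mode
    methods: dict[str, str] = {}
    for j, spec in enumerate(specs):
        mj = miss[:, j]
        if not mj.any():
            methods[spec.name] = "none"
            continue
        obs = M[~mj, j]
        if spec.kind == "numeric":
            fill, fallback = float(np.median(obs)), "median"
        else:
            vals, counts = np.unique(obs, return_counts=True)
            fill, fallback = float(vals[np.argmax(counts)]), "mode"
        M[mj, j] = fill
        if mj.mean() > 0.9:
            warnings.warn(
                f"{spec.name}: >90% missing; falling back to {fallback} imputation"
            )
            methods[spec.name] = fallback
            miss[:, j] = False  # exclude from forest refinement
        else:
            methods[spec.name] = (
                "forest-regressor" if spec.kind == "numeric" else "forest-classifier"
            )

    # iterate forests over incomplete covariates, least-missing first
    targets = [j for j in range(p) if miss[:, j].any()]
    targets.sort(key=lambda j: miss[:, j].sum())
    delta = float("inf")
    it = 0
    while targets and it < max_iter and delta > tol:
        changes = []
        for j in targets:
            spec = specs[j]
            mj = miss[:, j]
            other = np.delete(np.arange(M.shape[1]), j)
            if spec.kind == "numeric":
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rng_seed + j,
                    min_samples_leaf=5, n_jobs=1)
                model.fit(M[~mj][:, other], M[~mj, j])
                new = model.predict(M[mj][:, other])
            else:
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rng_seed + j,
                    min_samples_leaf=5, n_jobs=1)
                model.fit(M[~mj][:, other], M[~mj, j].astype(int))
                new = model.predict(M[mj][:, other]).astype(float)
            changes.append(np.abs(new - M[mj, j]) / scale[j])
            M[mj, j] = new
        delta = float(np.mean(np.concatenate(changes)))
        it += 1

    report.iterations = it
    report.convergence_delta = delta
    out = cohort.table.copy()
    for j, spec in enumerate(specs):
        mj = cohort.table[spec.name].isna().to_numpy()
        n_imp = int(mj.sum())
        report.covariates.append(
            CovariateImputation(spec.name, n_imp, methods.get(spec.name, "none")))
        if n_imp == 0:
            continue
        if spec.kind == "numeric":
            out.loc[mj, spec.name] = M[mj, j]
        else:
            codes = np.clip(np.rint(M[mj, j]).astype(int), 0, len(spec.levels) - 1)
            out.loc[mj, spec.name] = np.array(spec.levels, dtype=object)[codes]
    logger.info("imputed %d cells in %d iterations (delta=%.2g)",
                report.total_imputed, it, delta)
    return Cohort(out, cohort.schema), report


def mode_impute(cohort: Cohort) -> Cohort:
    """Baseline single-pass mode/median imputation (comparison yardstick)."""
    out = cohort.table.copy()
    for spec in cohort.schema:
        col = out[spec.name]
        if not col.isna().any():
            continue
        if spec.kind == "numeric":
            out[spec.name] = col.fillna(col.median())
        else:
            out[spec.name] = col.fillna(col.mode().iloc[0])
    return Cohort(out, cohort.schema)
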