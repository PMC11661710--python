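"""Virtual-equipoise (overlap) identification and trimming.

A patient contributes fairly to a comparison of esophagectomy alone versus
esophagectomy plus adjuvant therapy only if, given their covariates, they
had a realistic chance of receiving either strategy in observed practice.
A classification forest models P(Z=1 | covariates); each patient's
probability is taken out of bag, and patients outside a configurable band
[p_lo, p_hi] — near-certainly untreated or near-certainly treated profiles —
are excluded.  The audit mirrors the registry-style sanity check: within
the low-probability group almost nobody should actually have received
adjuvant therapy, and within the high-probability group almost everybody
should have.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import Cohort, encode_design


def fit_treatment_model(cohort: Cohort, seed: int = 0, ntree: int = 500,
                        **forest_kwargs) -> np.ndarray:
    """Out-of-bag treatment probabilities from a classification forest.

    Covariates only (no treatment interactions); each patient is scored by
    the trees whose bootstrap excluded them.  Requires a fully imputed
    cohort with both arms present.
    """
    z = cohort.treatment
    if len(np.unique(z)) < 2:
        raise ValueError("both treatment arms must be present")
    X, _ = encode_design(cohort, include_treatment_interactions=False)
    if np.isnan(X).any():
        raise ValueError("treatment model requires an imputed cohort")
    model = RandomForestClassifier(
        n_estimators=ntree, oob_score=True, bootstrap=True,
        random_state=int(seed) % (2**31), min_samples_leaf=3, max_features=0.5, n_jobs=1,
        **forest_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on rows never OOB
        model.fit(X, z)
    dec = model.oob_decision_function_
    p_hat = dec[:, list(model.classes_).index(1)]
    # sklearn leaves an all-zero (or NaN) row for samples never out of bag
    never_oob = np.isnan(p_hat) | (dec.sum(axis=1) == 0)
    if never_oob.any():
        p_hat = p_hat.copy()
        p_hat[never_oob] = z.mean()
        warnings.warn(f"{never_oob.sum()} rows never out of bag; "
                      "marginal rate substituted")
    return p_hat


@dataclass
class EligibilityResult:
    """Per-patient overlap probabilities, eligibility flags and audit."""

    p_hat: np.ndarray
    eligible: np.ndarray
    p_lo: float
    p_hi: float
    summary: dict = field(default_factory=dict)

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())

    @property
    def n_excluded(self) -> int:
        return int(len(self.eligible) - self.eligible.sum())


def trim(p_hat: np.ndarray, treatment: np.ndarray, p_lo: float = 0.1,
         p_hi: float = 0.9) -> EligibilityResult:
    """Flag patients with p_lo <= p_hat <= p_hi as eligible.

    The summary reports, for the low-probability (p_hat < p_lo) and
    high-probability (p_hat > p_hi) groups, how many patients actually
    received adjuvant therapy — the observed-practice audit.
    """
    if not 0.0 <= p_lo < p_hi <= 1.0:
        raise ValueError("thresholds must satisfy 0 <= p_lo < p_hi <= 1")
    p_hat = np.asarray(p_hat, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    eligible = (p_hat >= p_lo) & (p_hat <= p_hi)
    low = p_hat < p_lo
    high = p_hat > p_hi

    def _group(mask: np.ndarray) -> dict:
        n = int(mask.sum())
        n_treated = int(treatment[mask].sum())
        return {"n": n, "n_treated": n_treated,
                "treated_rate": n_treated / n if n else float("nan")}

    summary = {
        "n": len(p_hat),
        "n_eligible": int(eligible.sum()),
        "n_excluded": int((~eligible).sum()),
        "low_probability_group": _group(low),
        "high_probability_group": _group(high),
    }
    return EligibilityResult(p_hat, eligible, p_lo, p_hi, summary)


def eligibility_by_stratum(cohort: Cohort, result: EligibilityResult
                           ) -> pd.DataFrame:
    """Stratum-level audit table: n, n eligible, observed treatment rate."""
    df = pd.DataFrame({
        "pT": cohort.table["pT"].fillna("TX"),
        "pN": cohort.table["pN"].fillna("NX"),
        "treatment": cohort.treatment,
        "eligible": result.eligible,
    })
    out = (df.groupby(["pT", "pN"], observed=True)
             .agg(n=("eligible", "size"),
                  n_eligible=("eligible", "sum"),
                  treated_rate=("treatment", "mean"))
             .reset_index())
    out["eligible_rate"] = out["n_eligible"] / out["n"]
    return out
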