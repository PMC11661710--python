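"""Restricted-mean-survival-time gain/loss accounting and stratified summaries.

The restricted mean survival time (RMST) at horizon tau is the area under
the survival step function from 0 to tau — expected months of life within
the horizon.  The per-patient difference RMST(Eso+) - RMST(Eso) is the
months of life gained (positive) or lost (negative) by adding adjuvant
therapy.  Summaries aggregate these deltas over pT x pN cells as
box-and-whisker geometry (median, quartiles, 1.5 x IQR whiskers, outliers,
box width proportional to cell size), report mean 5-year survival per arm,
and classify each cell as detriment (median < 0), insignificant benefit
(0 <= median < threshold) or meaningful benefit (median >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .cohort import PN_LEVELS, PT_LEVELS
from .estimators import SurvivalCurve

if TYPE_CHECKING:  # pragma: no cover
    from .twins import TwinTable

DETRIMENT = "detriment"
INSIGNIFICANT = "insignificant benefit"
MEANINGFUL = "meaningful benefit"

DEFAULT_BENEFIT_THRESHOLD = 4.0  # months


def rmst(curve: SurvivalCurve, tau: float) -> float:
    """Exact area under the survival step function on [0, tau].

    S = 1 on the initial segment before the first step; the last value is
    extended rightward to tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(rmst_matrix(curve.times, curve.survival[None, :], tau)[0])


def rmst_matrix(times: np.ndarray, surv: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise RMST for a matrix of step curves sharing one time grid."""
    times = np.asarray(times, dtype=float)
    surv = np.asarray(surv, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.clip(times, 0.0, tau)
    # segment [0, t_0) at S=1, then [t_k, t_{k+1}) at S_k, last extended to tau
    edges = np.concatenate(([0.0], t, [tau]))
    widths = np.diff(edges)  # len(times) + 1
    vals = np.concatenate((np.ones((len(surv), 1)), surv), axis=1)
    return vals @ widths


def survival_at(times: np.ndarray, surv: np.ndarray, t: float) -> np.ndarray:
    """Right-continuous step evaluation of curve rows at time t."""
    idx = int(np.searchsorted(np.asarray(times, dtype=float), t, side="right")) - 1
    if idx < 0:
        return np.ones(len(surv))
    return np.asarray(surv, dtype=float)[:, idx]


def gain_loss(twins: "TwinTable | list") -> np.ndarray:
    """Per-patient months gained (positive) or lost (negative).

    Accepts one TwinTable or a list of them; a list must share a common
    horizon tau.
    """
    if isinstance(twins, (list, tuple)):
        taus = {t.tau for t in twins}
        if len(taus) > 1:
            raise ValueError(f"mixed horizons {sorted(taus)}; deltas not comparable")
        return np.concatenate([t.delta for t in twins])
    return twins.delta


def classify(median_delta: float, threshold: float = DEFAULT_BENEFIT_THRESHOLD
             ) -> str:
    if median_delta < 0:
        return DETRIMENT
    if median_delta < threshold:
        return INSIGNIFICANT
    return MEANINGFUL


@dataclass
class StratumSummary:
    """Box-and-whisker geometry plus survival summary for one pT x pN cell."""

    pt: str
    pn: str
    n: int
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    surv5_eso: float  # mean 5-year survival (%) under esophagectomy alone
    surv5_eso_plus: float
    benefit_class: str = field(default="")

    def as_row(self) -> dict:
        return {
            "pT": self.pt, "pN": self.pn, "n": self.n,
            "q1": self.q1, "median": self.median, "q3": self.q3,
            "whisker_lo": self.whisker_lo, "whisker_hi": self.whisker_hi,
            "n_outliers": len(self.outliers),
            "surv5_eso_pct": self.surv5_eso,
            "surv5_eso_plus_pct": self.surv5_eso_plus,
            "class": self.benefit_class,
        }


def _box_stats(x: np.ndarray) -> tuple[float, float, float, float, float, np.ndarray]:
    # quartiles by linear interpolation of order statistics
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return q1, med, q3, float(inside.min()), float(inside.max()), outliers


def summarize_strata(twins: "TwinTable", collapse_pn: bool = False,
                     threshold: float = DEFAULT_BENEFIT_THRESHOLD
                     ) -> list[StratumSummary]:
    """Aggregate twin deltas over pT x pN cells (post-imputation labels).

    ``collapse_pn`` merges N1-N3 into a single pN+ group, matching the
    coarse summary; empty cells are simply absent from the output.
    """
    df = twins.table
    if df[["pT", "pN"]].isna().any().any():
        raise ValueError("stratum labels missing; summarize after imputation")
    pn_labels = df["pN"].to_numpy(dtype=object)
    if collapse_pn:
        pn_labels = np.where(pn_labels == "N0", "N0", "N+")
        pn_order = ("N0", "N+")
    else:
        pn_order = PN_LEVELS
    delta = twins.delta
    s5_0 = survival_at(twins.grid, twins.surv0, 60.0)
    s5_1 = survival_at(twins.grid, twins.surv1, 60.0)

    out: list[StratumSummary] = []
    pt_arr = df["pT"].to_numpy(dtype=object)
    for pt in PT_LEVELS:
        for pn in pn_order:
            mask = (pt_arr == pt) & (pn_labels == pn)
            if not mask.any():
                continue
            q1, med, q3, wlo, whi, outl = _box_stats(delta[mask])
            out.append(StratumSummary(
                pt=pt, pn=pn, n=int(mask.sum()),
                q1=q1, median=med, q3=q3,
                whisker_lo=wlo, whisker_hi=whi, outliers=outl,
                surv5_eso=100.0 * float(s5_0[mask].mean()),
                surv5_eso_plus=100.0 * float(s5_1[mask].mean()),
                benefit_class=classify(med, threshold),
            ))
    return out


def strata_frame(summaries: list[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def table2_style(granular: list[StratumSummary],
                 collapsed: list[StratumSummary]) -> pd.DataFrame:
    """Wide table: one row per pT, column blocks (RMS median, Eso %, Eso+ %)
    for pN0, pN+ and each granular pN category."""
    cells = {(s.pt, s.pn): s for s in granular}
    cells.update({(s.pt, s.pn): s for s in collapsed if s.pn == "N+"})
    rows = []
    for pt in PT_LEVELS:
        row: dict = {"pT": pt}
        for pn in ("N0", "N+", "N1", "N2", "N3"):
            s = cells.get((pt, pn))
            row[f"{pn}_rms"] = round(s.median, 1) if s else np.nan
            row[f"{pn}_eso_pct"] = round(s.surv5_eso) if s else np.nan
            row[f"{pn}_eso_plus_pct"] = round(s.surv5_eso_plus) if s else np.nan
            row[f"{pn}_class"] = s.benefit_class if s else ""
        rows.append(row)
    return pd.DataFrame(rows)


def boxplot_data(summaries: list[StratumSummary]) -> list[dict]:
    """Plot-ready box geometry; widths proportional to stratum size."""
    if not summaries:
        raise ValueError("no strata to plot")
    max_n = max(s.n for s in summaries)
    return [
        {
            "label": f"{s.pt}{s.pn}",
            "pT": s.pt, "pN": s.pn, "n": s.n,
            "width": s.n / max_n,
            "q1": s.q1, "median": s.median, "q3": s.q3,
            "whisker_lo": s.whisker_lo, "whisker_hi": s.whisker_hi,
            "outliers": np.asarray(s.outliers, dtype=float),
        }
        for s in summaries
    ]


def plot_gain_loss(summaries: list[StratumSummary], path,
                   title: str = "") -> None:
    """Figure-style box-and-whisker plot of months gained/lost per stratum."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    boxes = boxplot_data(summaries)
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(boxes)), 4.5))
    for i, b in enumerate(boxes):
        w = 0.8 * b["width"]
        ax.add_patch(plt.Rectangle((i - w / 2, b["q1"]), w, b["q3"] - b["q1"],
                                   fill=True, facecolor="#c6dbef",
                                   edgecolor="black"))
        ax.hlines(b["median"], i - w / 2, i + w / 2, color="black", lw=2)
        ax.vlines(i, b["whisker_lo"], b["q1"], color="black")
        ax.vlines(i, b["q3"], b["whisker_hi"], color="black")
        if len(b["outliers"]):
            ax.plot(np.full(len(b["outliers"]), i), b["outliers"], "k.", ms=3)
    ax.axhline(0.0, color="gray", ls="--", lw=1)
    ax.set_xticks(range(len(boxes)), [b["label"] for b in boxes], rotation=45)
    ax.set_ylabel("Months of life gained (+) or lost (−) within 10 y")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
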