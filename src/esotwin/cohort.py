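"""Cohort schema, ordinal staging encodings, and cohort-table I/O.

The analysis operates on a rectangular patient table: demographics and
comorbidity covariates, pathologic staging (pT depth of invasion, pN nodal
involvement, pM metastasis, R resection margin), a binary treatment
indicator (0 = esophagectomy alone, "Eso"; 1 = esophagectomy plus adjuvant
therapy, "Eso+"), follow-up time in months from the first management
decision, and an all-cause death indicator.

Staging categories are ordinal: Tis < T1 < T2 < T3 < T4 and
N0 < N1 < N2 < N3.  "X" categories (TX/NX) carry no rank and are flagged
missing so they can be routed to imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AC = "adenocarcinoma"
SCC = "squamous"
HISTOLOGIES = (AC, SCC)

# Ordinal level orders; rank = position in the tuple.  pTis sits below T1.
PT_LEVELS = ("Tis", "T1", "T2", "T3", "T4")
PN_LEVELS = ("N0", "N1", "N2", "N3")
PM_LEVELS = ("M0", "M1")
MARGIN_LEVELS = ("R0", "R1", "R2")

# Tokens that mean "category could not be assigned" in registry exports.
_MISSING_TOKENS = {"", "X", "TX", "NX", "MX", "RX", "NA", "NAN"}

MANDATORY_COLUMNS = ("id", "histology", "treatment", "time_months", "event")


class SchemaError(ValueError):
    """Raised when a cohort table violates the declared schema."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one model covariate.

    kind is 'numeric', 'ordinal' or 'nominal'; ordinal/nominal carry an
    ordered level tuple (rank = index for ordinals).
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    allow_missing: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "ordinal", "nominal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("ordinal", "nominal") and not self.levels:
            raise ValueError(f"{self.name}: {self.kind} covariate needs levels")


STAGING_SPECS = (
    CovariateSpec("pT", "ordinal", PT_LEVELS),
    CovariateSpec("pN", "ordinal", PN_LEVELS),
    CovariateSpec("pM", "ordinal", PM_LEVELS),
    CovariateSpec("margin", "ordinal", MARGIN_LEVELS),
)

# Default non-staging covariates: a documented stand-in for the registry's
# full demographic/comorbidity panel.
DEFAULT_EXTRA_SPECS = (
    CovariateSpec("age", "numeric"),
    CovariateSpec("sex", "nominal", ("M", "F")),
    CovariateSpec("weight_loss", "numeric"),
    CovariateSpec("comorbidity_count", "numeric"),
    CovariateSpec("location", "nominal", ("upper", "middle", "lower")),
    CovariateSpec("grade", "ordinal", ("G1", "G2", "G3")),
)

DEFAULT_SCHEMA = STAGING_SPECS + DEFAULT_EXTRA_SPECS


@dataclass
class Cohort:
    """A typed patient table plus its covariate schema.

    ``table`` holds one row per patient with the mandatory columns
    (id, histology, treatment, time_months, event) and one column per
    schema covariate.  Ordinal/nominal covariates are stored as their
    string levels with NaN for missing.
    """

    table: pd.DataFrame
    schema: tuple[CovariateSpec, ...] = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        for col in MANDATORY_COLUMNS:
            if col not in t.columns:
                raise SchemaError(f"mandatory column {col!r} missing")
        for spec in self.schema:
            if spec.name not in t.columns:
                raise SchemaError(f"declared covariate {spec.name!r} missing")
        if t["histology"].isna().any():
            raise SchemaError("histology may never be missing")
        bad = ~t["histology"].isin(HISTOLOGIES)
        if bad.any():
            raise SchemaError(
                f"unknown histology values: {sorted(t.loc[bad, 'histology'].unique())}"
            )
        for col, allowed in (("treatment", (0, 1)), ("event", (0, 1))):
            vals = t[col]
            if vals.isna().any():
                raise SchemaError(f"{col} contains missing values")
            bad_rows = ~vals.isin(allowed)
            if bad_rows.any():
                row = int(np.flatnonzero(bad_rows.to_numpy())[0])
                raise SchemaError(
                    f"{col} must be 0/1; offending value {vals.iloc[row]!r} at row {row}"
                )
        if t["time_months"].isna().any() or (t["time_months"] <= 0).any():
            bad_rows = t["time_months"].isna() | (t["time_months"] <= 0)
            row = int(np.flatnonzero(bad_rows.to_numpy())[0])
            raise SchemaError(f"time_months must be > 0; violation at row {row}")

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def time(self) -> np.ndarray:
        return self.table["time_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def treatment(self) -> np.ndarray:
        return self.table["treatment"].to_numpy(dtype=int)

    def spec(self, name: str) -> CovariateSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def ordinal_rank(self, name: str) -> np.ndarray:
        """Float ranks for an ordinal covariate, NaN where missing."""
        spec = self.spec(name)
        if spec.kind != "ordinal":
            raise ValueError(f"{name} is not ordinal")
        mapping = {lev: float(i) for i, lev in enumerate(spec.levels)}
        return self.table[name].map(mapping).to_numpy(dtype=float)

    def missing_fraction(self) -> pd.Series:
        return self.table[[s.name for s in self.schema]].isna().mean()

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.table.loc[np.asarray(mask, bool)].reset_index(drop=True),
                      self.schema)

    def copy(self) -> "Cohort":
        return Cohort(self.table.copy(), self.schema)


# ---------------------------------------------------------------------------
# I/O


def _clean_token(x: object) -> object:
    if pd.isna(x):
        return np.nan
    s = str(x).strip()
    if s.upper() in _MISSING_TOKENS:
        return np.nan
    return s


def read_cohort(path, schema: tuple[CovariateSpec, ...] = DEFAULT_SCHEMA) -> Cohort:
    """Read a cohort CSV into a typed :class:`Cohort`.

    Staging "X" strings map to missing-flagged entries; unparseable numeric
    cells become missing with a logged count.  Missing mandatory columns or
    out-of-domain treatment/event values raise :class:`SchemaError`.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty cohort file: {path}") from exc
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")

    out = pd.DataFrame({"id": raw["id"].astype(str)})
    out["histology"] = raw["histology"].map(_clean_token)
    for col in ("treatment", "time_months", "event"):
        out[col] = pd.to_numeric(raw[col], errors="coerce")

    for spec in schema:
        if spec.name not in raw.columns:
            raise SchemaError(f"declared covariate {spec.name!r} missing from {path}")
        col = raw[spec.name].map(_clean_token)
        if spec.kind == "numeric":
            parsed = pd.to_numeric(col, errors="coerce")
            n_bad = int((parsed.isna() & col.notna()).sum())
            if n_bad:
                logger.warning("%s: %d unparseable cells in %s set to missing",
                               path, n_bad, spec.name)
            out[spec.name] = parsed
        else:
            # registry exports sometimes drop the letter prefix ("3" for T3)
            aliases = {lev[1:]: lev for lev in spec.levels if len(lev) > 1}
            col = col.map(lambda v: aliases.get(v, v) if isinstance(v, str) else v)
            known = col.isin(spec.levels)
            n_bad = int((~known & col.notna()).sum())
            if n_bad:
                logger.warning("%s: %d out-of-vocabulary cells in %s set to missing",
                               path, n_bad, spec.name)
            out[spec.name] = col.where(known)
    return Cohort(out, schema)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV (missing cells as empty strings)."""
    cohort.table.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Design-matrix encoding


@dataclass(frozen=True)
class DesignMeta:
    """Column provenance for a design matrix.

    ``z_col`` is the treatment column index (or None when interactions are
    off); ``interaction_base`` maps each Z-interaction column index to the
    base covariate column it multiplies, so the treatment indicator can be
    flipped consistently for counterfactual scoring.
    """

    columns: tuple[str, ...]
    z_col: int | None = None
    interaction_base: dict[int, int] = field(default_factory=dict)

    @property
    def treatment_columns(self) -> tuple[int, ...]:
        if self.z_col is None:
            return ()
        return (self.z_col, *self.interaction_base.keys())


def encode_design(
    cohort: Cohort, include_treatment_interactions: bool = False
) -> tuple[np.ndarray, DesignMeta]:
    """Encode the cohort as a numeric matrix.

    Ordinal covariates are coded by rank, nominal covariates one-hot coded
    (first level dropped).  With ``include_treatment_interactions``, the
    treatment column Z and one Z*x column per covariate column are appended;
    this requires a fully imputed cohort.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for spec in cohort.schema:
        if spec.kind == "numeric":
            cols.append(cohort.table[spec.name].to_numpy(dtype=float))
            names.append(spec.name)
        elif spec.kind == "ordinal":
            cols.append(cohort.ordinal_rank(spec.name))
            names.append(spec.name)
        else:
            vals = cohort.table[spec.name]
            for lev in spec.levels[1:]:
                ind = (vals == lev).astype(float).to_numpy()
                ind[vals.isna().to_numpy()] = np.nan
                cols.append(ind)
                names.append(f"{spec.name}={lev}")
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))

    if not include_treatment_interactions:
        return X, DesignMeta(tuple(names))

    if np.isnan(X).any():
        bad = [names[j] for j in np.unique(np.nonzero(np.isnan(X))[1])]
        raise ValueError(
            "treatment interactions require a fully imputed cohort; "
            f"missing values remain in {bad}"
        )
    z = cohort.treatment.astype(float)
    p = X.shape[1]
    full = np.column_stack([X, z, X * z[:, None]])
    names_full = names + ["Z"] + [f"Z*{n}" for n in names]
    inter = {p + 1 + j: j for j in range(p)}
    return full, DesignMeta(tuple(names_full), z_col=p, interaction_base=inter)


def flip_treatment(X: np.ndarray, meta: DesignMeta) -> np.ndarray:
    """Counterfactual design: flip Z and recompute every Z*x column.

    Only treatment-derived columns change; all base covariate columns are
    carried over untouched.
    """
    if meta.z_col is None:
        raise ValueError("design matrix has no treatment column to flip")
    Xc = X.copy()
    z_new = 1.0 - X[:, meta.z_col]
    Xc[:, meta.z_col] = z_new
    for col, base in meta.interaction_base.items():
        Xc[:, col] = z_new * X[:, base]
    return Xc


def split_by_histology(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (adenocarcinoma, squamous) sub-cohorts."""
    is_ac = (cohort.table["histology"] == AC).to_numpy()
    return cohort.subset(is_ac), cohort.subset(~is_ac)
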