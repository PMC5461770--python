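"""Long-format longitudinal data: container, validation, covariate utilities.

A :class:`LongitudinalDataset` wraps a tidy pandas frame with one row per
subject-visit and declared column roles (subject id, age in years, continuous
response, optional binary group, optional birth cohort, time-invariant
covariates (TICs) and time-varying covariates (TVCs)).  TVC entries may be
missing (NaN); everything else must be complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "load_long_csv",
    "standardize_covariates",
    "make_cohort_dummies",
]

#: canonical column names used internally
SUBJECT, AGE, RESPONSE, GROUP, COHORT = "subject", "age", "response", "group", "cohort"


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class LongitudinalDataset:
    """Validated repeated-measures table.

    Parameters
    ----------
    frame
        Tidy frame with canonical columns ``subject``, ``age``, ``response``
        and optionally ``group`` (0/1), ``cohort``, plus TIC/TVC columns.
    tic_cols, tvc_cols
        Names of time-invariant / time-varying covariate columns.
    age_window
        Declared observation window ``(age_min, age_max)``; defaults to the
        observed range.  Ages outside a declared window are an error.
    transforms
        Per-column standardization parameters recorded by
        :func:`standardize_covariates` (for back-mapping to raw scale).
    """

    frame: pd.DataFrame
    tic_cols: tuple[str, ...] = ()
    tvc_cols: tuple[str, ...] = ()
    has_group: bool = False
    has_cohort: bool = False
    age_window: tuple[float, float] | None = None
    transforms: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        for col in (SUBJECT, AGE, RESPONSE):
            if col not in df.columns:
                raise ValidationError(f"required column {col!r} missing")
        if self.has_group and GROUP not in df.columns:
            raise ValidationError("group column declared but absent")
        if self.has_cohort and COHORT not in df.columns:
            raise ValidationError("cohort column declared but absent")
        for col in self.tic_cols + self.tvc_cols:
            if col not in df.columns:
                raise ValidationError(f"covariate column {col!r} missing")

        if len(df):
            bad = df.index[df[AGE].isna() | df[RESPONSE].isna()]
            if len(bad):
                raise ValidationError(
                    f"missing age/response on rows {list(bad[:5])}"
                    + ("..." if len(bad) > 5 else "")
                )
            lo, hi = self.age_window if self.age_window else (-np.inf, np.inf)
            out = df.loc[(df[AGE] < lo) | (df[AGE] > hi), AGE]
            if len(out):
                raise ValidationError(
                    f"{len(out)} ages outside declared window [{lo}, {hi}]"
                )
            # group / TICs must be constant within subject
            const_cols = list(self.tic_cols)
            if self.has_group:
                const_cols.append(GROUP)
                vals = set(pd.unique(df[GROUP].dropna()))
                if not vals <= {0, 1}:
                    raise ValidationError(f"group must be coded 0/1, found {sorted(vals)}")
            if self.has_cohort:
                const_cols.append(COHORT)
            for col in const_cols:
                nun = df.groupby(SUBJECT, observed=True)[col].nunique(dropna=False)
                offenders = nun.index[nun > 1].tolist()
                if offenders:
                    raise ValidationError(
                        f"column {col!r} not constant within subjects {offenders[:5]}"
                    )
        if self.age_window is None and len(df):
            object.__setattr__(
                self, "age_window", (float(df[AGE].min()), float(df[AGE].max()))
            )

    # ------------------------------------------------------------------ views
    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame[SUBJECT].nunique()

    @property
    def subjects(self) -> np.ndarray:
        return pd.unique(self.frame[SUBJECT])

    def subject_index(self) -> np.ndarray:
        """Integer codes 0..S-1 per row, in order of first appearance."""
        return pd.Categorical(
            self.frame[SUBJECT], categories=self.subjects
        ).codes.astype(np.intp)

    @property
    def ages(self) -> np.ndarray:
        return self.frame[AGE].to_numpy(float)

    @property
    def response(self) -> np.ndarray:
        return self.frame[RESPONSE].to_numpy(float)

    def group_by_subject(self) -> np.ndarray:
        """Group indicator per subject (0/1); zeros if no group column."""
        if not self.has_group:
            return np.zeros(self.n_subjects)
        g = self.frame.groupby(SUBJECT, observed=True, sort=False)[GROUP].first()
        return g.reindex(self.subjects).to_numpy(float)

    def tics_by_subject(self, cols: Sequence[str] | None = None) -> np.ndarray:
        cols = list(self.tic_cols if cols is None else cols)
        if not cols:
            return np.empty((self.n_subjects, 0))
        t = self.frame.groupby(SUBJECT, observed=True, sort=False)[cols].first()
        return t.reindex(self.subjects).to_numpy(float)

    def tvc_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-row TVC values and missingness mask (True = missing)."""
        if not self.tvc_cols:
            n = self.n_obs
            return np.empty((n, 0)), np.zeros((n, 0), bool)
        x = self.frame[list(self.tvc_cols)].to_numpy(float)
        return x, np.isnan(x)

    # ------------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        """Write the canonical long CSV (UTF-8, '.' decimal, NA for missing).

        Floats are written with 17 significant digits so the round trip is
        bit-exact."""
        self.frame.to_csv(path, index=False, na_rep="NA", float_format="%.17g")

    def with_frame(self, frame: pd.DataFrame, **changes) -> "LongitudinalDataset":
        return replace(self, frame=frame, **changes)


def load_long_csv(path, column_map: Mapping | None = None,
                  age_window: tuple[float, float] | None = None) -> LongitudinalDataset:
    """Read a long-format CSV into a validated :class:`LongitudinalDataset`.

    ``column_map`` maps roles to file columns, e.g.
    ``{"subject": "id", "age": "age_yr", "response": "bmi",
    "group": "t2dm", "cohort": "birth_year", "tics": ["sex"], "tvcs": ["ins"]}``.
    Roles absent from the map are assumed to already use canonical names.
    Unknown extra columns are preserved but ignored by the model.
    """
    cmap = dict(column_map or {})
    tics = tuple(cmap.pop("tics", ()))
    tvcs = tuple(cmap.pop("tvcs", ()))
    df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
    rename = {}
    for role in (SUBJECT, AGE, RESPONSE, GROUP, COHORT):
        src = cmap.get(role, role)
        if src in df.columns and src != role:
            rename[src] = role
        elif role in (SUBJECT, AGE, RESPONSE) and src not in df.columns:
            raise ValidationError(f"column {src!r} for role {role!r} not in {path}")
    df = df.rename(columns=rename)
    return LongitudinalDataset(
        frame=df,
        tic_cols=tics,
        tvc_cols=tvcs,
        has_group=GROUP in df.columns,
        has_cohort=COHORT in df.columns,
        age_window=age_window,
    )


def standardize_covariates(ds: LongitudinalDataset,
                           columns: Sequence[str] | None = None,
                           log: Sequence[str] = ()) -> LongitudinalDataset:
    """Return a copy with covariates scaled to mean 0, sd 1 (over non-missing).

    Columns in ``log`` are natural-log-transformed first (the usual treatment
    for right-skewed markers such as fasting insulin).  Transform parameters
    are stored in ``transforms`` for back-mapping.
    """
    cols = list(columns if columns is not None else ds.tic_cols + ds.tvc_cols)
    df = ds.frame.copy()
    transforms = dict(ds.transforms)
    for col in cols:
        x = df[col].to_numpy(float)
        if col in log:
            if np.nanmin(x) <= 0:
                raise ValidationError(f"log transform of non-positive values in {col!r}")
            x = np.log(x)
        m = np.nanmean(x)
        s = np.nanstd(x, ddof=1)
        if not np.isfinite(s) or s == 0:
            raise ValidationError(f"covariate {col!r} has zero variance")
        df[col] = (x - m) / s
        transforms[col] = {"mean": float(m), "sd": float(s), "log": col in log}
    return ds.with_frame(df, transforms=transforms)


def make_cohort_dummies(ds: LongitudinalDataset, reference_level) -> LongitudinalDataset:
    """Append k-1 birth-cohort indicator TICs (reference level coded all-zero)."""
    if not ds.has_cohort:
        raise ValidationError("dataset has no cohort column")
    levels = sorted(pd.unique(ds.frame[COHORT]), key=str)
    if reference_level not in levels:
        raise ValidationError(f"reference level {reference_level!r} absent from cohorts {levels}")
    if len(levels) < 2:
        raise ValidationError("need at least 2 cohort levels")
    df = ds.frame.copy()
    new_cols = []
    for lvl in levels:
        if lvl == reference_level:
            continue
        name = f"cohort_{lvl}"
        df[name] = (df[COHORT] == lvl).astype(float)
        new_cols.append(name)
    return ds.with_frame(df, tic_cols=ds.tic_cols + tuple(new_cols))
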