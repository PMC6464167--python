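"""Panel data model and CSV/YAML readers and writers.

A :class:`PanelDataset` couples a unit x time outcome matrix (mean annual
NDVI per management unit) with a unit x predictor table whose columns carry
social-ecological-system (SES) subsystem labels. All downstream estimation
consumes only these types.

File conventions (RFC-4180 CSV, UTF-8, "." decimal separator):

* outcomes are long format with columns ``unit,year,value`` — one row per
  unit-year;
* predictors are wide format with a ``unit`` column plus one column per
  predictor; an optional first data row whose unit field is ``subsystem``
  maps each predictor to its SES subsystem label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DegenerateInputError,
    DuplicateRecordError,
    MissingDataError,
    NonNumericDataError,
    PanelValidationError,
    UnitAlignmentError,
)

__all__ = [
    "PanelDataset",
    "StudyConfig",
    "read_panel",
    "write_panel",
    "write_importance_table",
    "read_importance_table",
]

_SUBSYSTEM_SENTINEL = "subsystem"


@dataclass(frozen=True)
class PanelDataset:
    """Aligned outcome trajectories and predictor values for a set of units.

    Parameters
    ----------
    unit_ids
        Unique unit labels; rows of ``outcomes`` and ``predictors`` follow
        this order.
    years
        Strictly increasing calendar years, length ``T >= 2``. The internal
        time index is 0-based and half-open ``[0, T)``.
    outcomes
        ``(n_units, T)`` matrix of outcome values (dimensionless index
        units, e.g. mean annual NDVI).
    predictors
        ``(n_units, N)`` matrix of temporally aggregated predictor values.
    predictor_names, subsystems, predictor_units
        Per-predictor metadata. Subsystem and unit strings are free-text
        labels, never interpreted numerically.
    """

    unit_ids: tuple[str, ...]
    years: tuple[int, ...]
    outcomes: np.ndarray
    predictors: np.ndarray
    predictor_names: tuple[str, ...]
    subsystems: tuple[str, ...] = ()
    predictor_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_ids", tuple(str(u) for u in self.unit_ids))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        outcomes = np.asarray(self.outcomes, dtype=float)
        predictors = np.asarray(self.predictors, dtype=float)
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "predictors", predictors)
        n = len(self.unit_ids)
        if len(set(self.unit_ids)) != n:
            raise PanelValidationError("unit_ids must be unique")
        if len(self.years) < 2:
            raise PanelValidationError("need at least two time points (T >= 2)")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise PanelValidationError("years must be strictly increasing")
        if outcomes.shape != (n, len(self.years)):
            raise PanelValidationError(
                f"outcomes shape {outcomes.shape} != ({n}, {len(self.years)})"
            )
        if len(self.predictor_names) < 1:
            raise PanelValidationError("need at least one predictor (N >= 1)")
        if len(set(self.predictor_names)) != len(self.predictor_names):
            raise PanelValidationError("predictor names must be unique")
        if predictors.shape != (n, len(self.predictor_names)):
            raise PanelValidationError(
                f"predictors shape {predictors.shape} != "
                f"({n}, {len(self.predictor_names)})"
            )
        if not np.isfinite(outcomes).all():
            raise MissingDataError("outcome matrix contains missing/non-finite cells")
        if not np.isfinite(predictors).all():
            raise MissingDataError(
                "predictor matrix contains missing/non-finite cells; "
                "impute before constructing the panel"
            )
        subs = tuple(self.subsystems) if self.subsystems else ("",) * predictors.shape[1]
        units = (
            tuple(self.predictor_units)
            if self.predictor_units
            else ("",) * predictors.shape[1]
        )
        if len(subs) != predictors.shape[1] or len(units) != predictors.shape[1]:
            raise PanelValidationError("predictor metadata length mismatch")
        object.__setattr__(self, "subsystems", subs)
        object.__setattr__(self, "predictor_units", units)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    def unit_index(self, unit_id: str) -> int:
        try:
            return self.unit_ids.index(unit_id)
        except ValueError:
            raise KeyError(f"unit {unit_id!r} not in panel") from None

    def outcome_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.outcomes, index=list(self.unit_ids), columns=list(self.years))

    def predictor_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.predictors, index=list(self.unit_ids), columns=list(self.predictor_names)
        )

    def reorder_units(self, unit_ids: Sequence[str]) -> "PanelDataset":
        """Return a panel with rows permuted to ``unit_ids`` (same set)."""
        if set(unit_ids) != set(self.unit_ids) or len(unit_ids) != self.n_units:
            raise UnitAlignmentError("reorder_units requires the same unit set")
        idx = [self.unit_index(u) for u in unit_ids]
        return dataclasses.replace(
            self,
            unit_ids=tuple(unit_ids),
            outcomes=self.outcomes[idx],
            predictors=self.predictors[idx],
        )


@dataclass
class StudyConfig:
    """Study-design scalars and optimizer settings for a placebo study.

    Parameters
    ----------
    n_placebo_sample
        Number of units drawn (without replacement) as placebo-treated.
    treatment_year
        Hypothetical intervention year; must lie after the last observed
        year so the entire observed series is the matching window.
    mspe_accept_threshold
        Absolute MSPE cap for plausibility. ``None`` selects the relative
        rule: accept when MSPE <= ``relative_mspe_fraction`` x variance of
        the treated trajectory.
    balance_cap
        Maximum absolute standardized predictor difference tolerated for an
        accepted fit.
    growth_cutpoints
        Percent-change breakpoints separating low / medium / high outcome
        growth (half-open bins, lower-inclusive above the first cut).
    v_normalization
        ``"sum"`` (reporting convention; weights total 1) or
        ``"euclidean"`` (unit L2 norm).
    n_multistarts
        Dirichlet-random restarts for the outer importance search, in
        addition to the equal-weights start.
    """

    n_placebo_sample: int = 30
    treatment_year: int = 2017
    mspe_accept_threshold: float | None = None
    relative_mspe_fraction: float = 0.1
    balance_cap: float = 3.0
    growth_cutpoints: tuple[float, float] = (10.0, 20.0)
    v_normalization: str = "sum"
    seed: int = 0
    n_multistarts: int = 10
    outer_maxfev_per_dim: int = 60
    outer_fatol: float = 1e-11
    outer_xatol: float = 1e-5
    inner_tol: float = 1e-10

    def __post_init__(self) -> None:
        self.growth_cutpoints = tuple(float(c) for c in self.growth_cutpoints)
        if self.n_placebo_sample < 1:
            raise PanelValidationError("n_placebo_sample must be >= 1")
        if self.mspe_accept_threshold is not None and self.mspe_accept_threshold < 0:
            raise PanelValidationError("mspe_accept_threshold must be >= 0")
        if self.relative_mspe_fraction < 0 or self.balance_cap < 0:
            raise PanelValidationError("thresholds must be >= 0")
        if any(
            b <= a
            for a, b in zip(self.growth_cutpoints, self.growth_cutpoints[1:])
        ):
            raise PanelValidationError("growth cutpoints must be strictly increasing")
        if self.v_normalization not in ("sum", "euclidean"):
            raise PanelValidationError("v_normalization must be 'sum' or 'euclidean'")
        if self.n_multistarts < 0:
            raise PanelValidationError("n_multistarts must be >= 0")

    def validate_against(self, panel: PanelDataset) -> None:
        if self.treatment_year <= max(panel.years):
            raise PanelValidationError(
                f"treatment_year {self.treatment_year} must lie after the last "
                f"observed year {max(panel.years)}"
            )
        if self.n_placebo_sample > panel.n_units:
            raise PanelValidationError(
                "placebo sample larger than the unit population"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PanelValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["growth_cutpoints"] = list(self.growth_cutpoints)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _numeric(series: pd.Series, what: str, path) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        offending = series[bad].iloc[0]
        raise NonNumericDataError(f"non-numeric {what} value {offending!r} in {path}")
    if out.isna().any():
        raise MissingDataError(f"missing {what} value in {path}")
    return out.astype(float)


def read_panel(outcome_path: str | Path, predictor_path: str | Path) -> PanelDataset:
    """Read a long-format outcome CSV and a wide-format predictor CSV.

    Units must agree between the two files; a unit present in only one file
    raises :class:`UnitAlignmentError`. Duplicate ``(unit, year)`` records
    raise :class:`DuplicateRecordError`.
    """
    out = pd.read_csv(outcome_path, dtype={"unit": str})
    required = {"unit", "year", "value"}
    if not required.issubset(out.columns):
        raise PanelValidationError(
            f"outcome file must have columns {sorted(required)}, got {list(out.columns)}"
        )
    out["year"] = _numeric(out["year"], "year", outcome_path)
    if (out["year"] % 1 != 0).any():
        raise NonNumericDataError(f"non-integer year in {outcome_path}")
    out["year"] = out["year"].astype(int)
    out["value"] = _numeric(out["value"], "outcome", outcome_path)
    dup = out.duplicated(subset=["unit", "year"])
    if dup.any():
        u, y = out.loc[dup, ["unit", "year"]].iloc[0]
        raise DuplicateRecordError(f"duplicated record ({u}, {y}) in {outcome_path}")

    pred = pd.read_csv(predictor_path, dtype={"unit": str})
    if "unit" not in pred.columns or pred.shape[1] < 2:
        raise PanelValidationError(
            f"predictor file must have a 'unit' column plus predictor columns"
        )
    subsystems: tuple[str, ...] = ()
    first = pred["unit"].iloc[0] if len(pred) else ""
    if isinstance(first, str) and first.strip().lower() == _SUBSYSTEM_SENTINEL:
        subsystems = tuple(str(v) for v in pred.iloc[0, 1:])
        pred = pred.iloc[1:].reset_index(drop=True)
    if pred["unit"].duplicated().any():
        u = pred.loc[pred["unit"].duplicated(), "unit"].iloc[0]
        raise DuplicateRecordError(f"duplicated unit {u!r} in {predictor_path}")

    out_units = set(out["unit"])
    pred_units = set(pred["unit"])
    if out_units != pred_units:
        only_out = sorted(out_units - pred_units)
        only_pred = sorted(pred_units - out_units)
        raise UnitAlignmentError(
            f"unit sets differ: only in outcomes {only_out}, only in predictors {only_pred}"
        )

    years = sorted(out["year"].unique())
    unit_ids = sorted(out_units)
    wide = out.pivot(index="unit", columns="year", values="value")
    if wide.isna().any().any():
        missing = wide.stack(future_stack=True)
        cell = missing[missing.isna()].index[0]
        raise MissingDataError(f"missing outcome for (unit, year) = {cell}")
    wide = wide.loc[unit_ids, years]

    pred = pred.set_index("unit").loc[unit_ids]
    names = tuple(pred.columns)
    for col in names:
        pred[col] = _numeric(pred[col], f"predictor '{col}'", predictor_path)
    pmat = pred.to_numpy(dtype=float)
    all_missing = ~np.isfinite(pmat)
    if all_missing.all(axis=0).any():
        raise MissingDataError("a predictor column is entirely missing")
    return PanelDataset(
        unit_ids=tuple(unit_ids),
        years=tuple(int(y) for y in years),
        outcomes=wide.to_numpy(dtype=float),
        predictors=pmat,
        predictor_names=names,
        subsystems=subsystems,
    )


def write_panel(panel: PanelDataset, outcome_path: str | Path, predictor_path: str | Path) -> None:
    """Write a panel back to the long-outcome / wide-predictor CSV pair."""
    rows = [
        {"unit": u, "year": y, "value": panel.outcomes[i, t]}
        for i, u in enumerate(panel.unit_ids)
        for t, y in enumerate(panel.years)
    ]
    pd.DataFrame(rows).to_csv(outcome_path, index=False)

    pf = panel.predictor_frame().reset_index(names="unit")
    if any(panel.subsystems):
        header = pd.DataFrame(
            [[_SUBSYSTEM_SENTINEL, *panel.subsystems]], columns=pf.columns
        )
        pf = pd.concat([header, pf], ignore_index=True)
    pf.to_csv(predictor_path, index=False)


def write_importance_table(table, path: str | Path) -> None:
    """Serialize an importance table to CSV.

    Columns: ``subsystem, predictor, mean_weight, rank, weight_2dp`` —
    full-precision weights plus a 2-decimal display column.
    """
    frame = table.to_frame()
    if len(frame) == 0:
        raise DegenerateInputError("cannot write an empty importance table")
    if not np.isfinite(frame["mean_weight"]).all():
        raise PanelValidationError("importance weights must be finite")
    out = frame[["subsystem", "predictor", "mean_weight", "rank"]].copy()
    out["weight_2dp"] = out["mean_weight"].round(2)
    out.to_csv(path, index=False, float_format="%.17g")


def read_importance_table(path: str | Path) -> pd.DataFrame:
    """Read back a serialized importance table as a DataFrame."""
    return pd.read_csv(path)
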