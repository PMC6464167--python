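"""Placebo-study importance ranking.

The four-step study loop: (1) draw a random sample of units and assign each
a hypothetical post-period treatment, every remaining unit forming its
donor pool; (2) fit a nested synthetic control per sampled unit; (3) keep
only plausible fits; (4) average the sum-normalized predictor-importance
vectors over accepted fits and rank predictors — overall and within
low / medium / high outcome-growth strata.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import RejectionReport, plausibility_filter
from .exceptions import (
    DegenerateInputError,
    NoAcceptedFitsError,
    PanelValidationError,
)
from .panel import PanelDataset, StudyConfig
from .scm import SyntheticControl, SyntheticControlResults

__all__ = [
    "ImportanceTable",
    "GrowthStratum",
    "PlaceboStudy",
    "PlaceboStudyResults",
    "assign_placebo_sample",
    "average_importance",
    "stratify_by_growth",
    "run_study",
]

_STRATUM_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ImportanceTable:
    """Averaged, normalized predictor-importance weights with ranks.

    Weights are the arithmetic mean of per-fit sum-normalized importance
    vectors, renormalized to total 1. Rows are ordered by rank: descending
    weight, ties broken alphabetically by predictor name.
    """

    predictor_names: tuple[str, ...]
    subsystems: tuple[str, ...]
    weights: np.ndarray
    stratum: str = "overall"
    n_fits: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.n_fits > 0:
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
                raise PanelValidationError(
                    "importance table weights must be >= 0 and sum to 1"
                )

    @property
    def ranks(self) -> np.ndarray:
        """Rank per predictor (1 = largest weight; ties alphabetical)."""
        order = sorted(
            range(len(self.predictor_names)),
            key=lambda i: (-self.weights[i], self.predictor_names[i]),
        )
        ranks = np.empty(len(order), dtype=int)
        for pos, i in enumerate(order, start=1):
            ranks[i] = pos
        return ranks

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "subsystem": list(self.subsystems),
                "predictor": list(self.predictor_names),
                "mean_weight": self.weights,
                "rank": self.ranks,
            }
        )
        return frame.sort_values("rank", ignore_index=True)

    def top(self, k: int = 5) -> pd.DataFrame:
        return self.to_frame().head(k)

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            f"Predictor importance ({self.stratum}; n_fits = {self.n_fits})",
            "=" * 56,
            f"{'rank':>4s}  {'weight':>7s}  predictor (subsystem)",
        ]
        for _, row in frame.iterrows():
            lines.append(
                f"{row['rank']:>4d}  {row['mean_weight']:>7.2f}  "
                f"{row['predictor']} ({row['subsystem']})"
            )
        lines.append(f"{'':>4s}  {frame['mean_weight'].sum():>7.2f}  total")
        return "\n".join(lines)


@dataclass(frozen=True)
class GrowthStratum:
    """A unit's outcome growth and its stratum assignment."""

    unit_id: str
    percent_change: float
    stratum: str


def assign_placebo_sample(panel: PanelDataset, config: StudyConfig):
    """Draw the placebo-treated sample without replacement.

    Each sampled unit is paired with its donor pool: every other unit in
    the panel. Sampling is from the sorted unit list under the configured
    seed, so the draw is independent of panel row order.
    """
    if config.n_placebo_sample > panel.n_units:
        raise PanelValidationError("sample larger than the unit population")
    rng = np.random.default_rng(config.seed)
    pool = sorted(panel.unit_ids)
    treated = list(rng.choice(pool, size=config.n_placebo_sample, replace=False))
    return [
        (t, tuple(u for u in panel.unit_ids if u != t))
        for t in treated
    ]


def average_importance(fits, stratum: str = "overall") -> ImportanceTable:
    """Average sum-normalized importance vectors over accepted fits.

    Each fit contributes equally (its vector is sum-normalized first); the
    mean is renormalized to total 1 and ranked.
    """
    fits = list(fits)
    if not fits:
        raise DegenerateInputError("average_importance needs at least one fit")
    names = fits[0].importance_sum1.predictor_names
    for fit in fits[1:]:
        if fit.importance_sum1.predictor_names != names:
            raise PanelValidationError(
                "fits disagree on the predictor set; cannot average importances"
            )
    mat = np.vstack([f.importance_sum1.v for f in fits])
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    subsystems = _subsystems_for(fits[0], names)
    return ImportanceTable(
        predictor_names=names,
        subsystems=subsystems,
        weights=mean,
        stratum=stratum,
        n_fits=len(fits),
    )


def _subsystems_for(fit, names) -> tuple[str, ...]:
    if fit.balance is None:
        return ("",) * len(names)
    lookup = dict(
        zip(fit.balance.frame["predictor"], fit.balance.frame["subsystem"])
    )
    return tuple(lookup.get(n, "") for n in names)


def percent_growth(panel: PanelDataset, unit_id: str) -> float:
    """Percent change of the outcome from the baseline (first) to the final
    observed year: ``100 * (y_T - y_0) / y_0``."""
    y = panel.outcomes[panel.unit_index(unit_id)]
    if y[0] == 0:
        raise DegenerateInputError(
            f"unit {unit_id!r} has baseline outcome 0; percent change undefined"
        )
    return float(100.0 * (y[-1] - y[0]) / y[0])


def stratify_by_growth(panel: PanelDataset, accepted_fits, config: StudyConfig):
    """Bin accepted units by outcome growth and re-average importances.

    Bins are half-open: ``(-inf, c1)`` low, ``[c1, c2)`` medium,
    ``[c2, inf)`` high, for cutpoints ``(c1, c2)``. Strata with no accepted
    units get an empty table with ``n_fits = 0``.

    Returns ``(assignments, tables)`` where ``tables`` maps stratum label
    to :class:`ImportanceTable`.
    """
    accepted_fits = list(accepted_fits)
    cuts = config.growth_cutpoints
    if len(cuts) != 2:
        raise PanelValidationError("exactly two growth cutpoints are required")
    assignments = []
    by_stratum: dict[str, list] = {label: [] for label in _STRATUM_LABELS}
    for fit in accepted_fits:
        pc = percent_growth(panel, fit.treated_id)
        # half-open bins, lower-inclusive above the first cut; values
        # within float rounding of a cutpoint count as at the cutpoint
        def _below(value, cut):
            return value < cut - 1e-9 * max(1.0, abs(cut))

        if _below(pc, cuts[0]):
            label = "low"
        elif _below(pc, cuts[1]):
            label = "medium"
        else:
            label = "high"
        assignments.append(GrowthStratum(fit.treated_id, pc, label))
        by_stratum[label].append(fit)
    tables: dict[str, ImportanceTable] = {}
    for label in _STRATUM_LABELS:
        members = by_stratum[label]
        if members:
            tables[label] = average_importance(members, stratum=label)
        else:
            names = (
                accepted_fits[0].importance_sum1.predictor_names
                if accepted_fits
                else ()
            )
            tables[label] = ImportanceTable(
                predictor_names=names,
                subsystems=_subsystems_for(accepted_fits[0], names)
                if accepted_fits
                else (),
                weights=np.zeros(len(names)),
                stratum=label,
                n_fits=0,
            )
    return assignments, tables


@dataclass
class PlaceboStudyResults:
    """Everything a placebo study produces.

    Attributes
    ----------
    fits
        All fitted units, in sample order.
    accepted
        The plausible subset.
    rejections : RejectionReport
        Rule violations for the rest.
    importance : ImportanceTable
        Overall averaged ranking.
    stratum_tables
        Per growth stratum (low / medium / high) rankings.
    """

    fits: list
    accepted: list
    rejections: RejectionReport
    importance: ImportanceTable
    growth: list
    stratum_tables: dict
    log_lines: list = field(default_factory=list)

    @property
    def acceptance_rate(self) -> float:
        return len(self.accepted) / len(self.fits)

    def log_text(self) -> str:
        return "\n".join(self.log_lines)

    def summary(self) -> str:
        lines = [
            "Placebo synthetic-control study",
            "=" * 56,
            f"fitted units     : {len(self.fits)}",
            f"accepted fits    : {len(self.accepted)} "
            f"({100 * self.acceptance_rate:.1f}%)",
            "",
            self.importance.summary(),
        ]
        for label, table in self.stratum_tables.items():
            if table.n_fits:
                lines += ["", table.summary()]
        return "\n".join(lines)


class PlaceboStudy:
    """Placebo-treatment study over a panel: the model object whose
    :meth:`fit` runs sampling, per-unit estimation, filtering, averaging
    and stratification, returning :class:`PlaceboStudyResults`."""

    def __init__(self, panel: PanelDataset, config: StudyConfig):
        config.validate_against(panel)
        self.panel = panel
        self.config = config

    def fit(self, progress: bool = False) -> PlaceboStudyResults:
        panel, config = self.panel, self.config
        sample = assign_placebo_sample(panel, config)
        log = [
            time.strftime("%Y-%m-%dT%H:%M:%S ")
            + f"study start: {len(sample)} placebo units of {panel.n_units}, "
            f"seed={config.seed}",
        ]
        fits: list[SyntheticControlResults] = []
        for treated_id, donors in sample:
            t0 = time.perf_counter()
            fit = SyntheticControl(panel, treated_id, config, donor_ids=donors).fit()
            fits.append(fit)
            log.append(
                time.strftime("%Y-%m-%dT%H:%M:%S ")
                + f"fit {treated_id}: mspe={fit.mspe:.3e} "
                f"inner_loss={fit.inner_loss:.3e} accepted={fit.accepted} "
                f"({time.perf_counter() - t0:.1f}s)"
            )
            if progress:
                print(log[-1])
        accepted, rejections = plausibility_filter(fits, config)
        log.append(
            time.strftime("%Y-%m-%dT%H:%M:%S ")
            + f"accepted {len(accepted)}/{len(fits)}"
        )
        if not accepted:
            raise NoAcceptedFitsError(
                "no fit passed the plausibility filter; relax the MSPE "
                "threshold or balance cap, or inspect the rejection report"
            )
        importance = average_importance(accepted)
        growth, stratum_tables = stratify_by_growth(panel, accepted, config)
        return PlaceboStudyResults(
            fits=fits,
            accepted=accepted,
            rejections=rejections,
            importance=importance,
            growth=growth,
            stratum_tables=stratum_tables,
            log_lines=log,
        )


def run_study(panel: PanelDataset, config: StudyConfig) -> PlaceboStudyResults:
    """Functional entry point for the full four-step study loop."""
    return PlaceboStudy(panel, config).fit()
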