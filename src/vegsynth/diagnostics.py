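"""Match-quality assessment for synthetic-control fits.

Covariate balance compares the treated unit's predictors ``B1`` with the
synthetic unit's ``B1* = B0 W*``; a well-matched fit has small absolute
standardized differences. Plausibility filtering replaces visual trajectory
inspection with two quantitative rules: an MSPE cap and a balance cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, UnitAlignmentError
from .panel import PanelDataset, StudyConfig

__all__ = [
    "BalanceTable",
    "RejectionReport",
    "covariate_balance",
    "plausibility_filter",
    "gap_frame",
]


@dataclass(frozen=True)
class BalanceTable:
    """Per-predictor covariate balance for one fit.

    Columns of :attr:`frame`: ``predictor, subsystem, treated, synthetic,
    donor_mean, donor_sd, std_diff, zero_variance``. ``synthetic`` is the
    exact w-weighted donor mean; ``std_diff`` is the absolute treated minus
    synthetic difference divided by the donor-pool standard deviation
    (the treated "group" is a single unit, so a pooled SD is unavailable).
    Zero-variance predictors are flagged and get no standardized value.
    """

    frame: pd.DataFrame

    @property
    def max_std_diff(self) -> float:
        vals = self.frame.loc[~self.frame["zero_variance"], "std_diff"]
        return float(vals.max()) if len(vals) else float("nan")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def covariate_balance(fit, panel: PanelDataset) -> BalanceTable:
    """Build the balance table B1 vs B1* = B0 W* for a fitted unit."""
    try:
        di = [panel.unit_index(d) for d in fit.donor_weights.donor_ids]
        ti = panel.unit_index(fit.treated_id)
    except KeyError as exc:
        raise UnitAlignmentError(f"fit refers to a unit missing from panel: {exc}")
    w = fit.donor_weights.w
    B0 = panel.predictors[di].T  # N x K
    b1 = panel.predictors[ti]
    synthetic = B0 @ w
    donor_mean = B0.mean(axis=1)
    donor_sd = B0.std(axis=1, ddof=1) if B0.shape[1] > 1 else np.zeros(B0.shape[0])
    zero_var = donor_sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        std_diff = np.abs(b1 - synthetic) / donor_sd
    std_diff[zero_var] = np.nan
    frame = pd.DataFrame(
        {
            "predictor": list(panel.predictor_names),
            "subsystem": list(panel.subsystems),
            "treated": b1,
            "synthetic": synthetic,
            "donor_mean": donor_mean,
            "donor_sd": donor_sd,
            "std_diff": std_diff,
            "zero_variance": zero_var,
        }
    )
    return BalanceTable(frame)


@dataclass(frozen=True)
class RejectionReport:
    """Why each rejected fit failed: one row per rejection with the rule(s)
    violated (``mspe`` and/or ``balance``)."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _fit_threshold(fit, config: StudyConfig) -> float:
    if config.mspe_accept_threshold is not None:
        return config.mspe_accept_threshold
    return config.relative_mspe_fraction * float(np.var(fit.observed_trajectory))


def plausibility_filter(fits, config: StudyConfig):
    """Split fits into accepted and rejected by the quantitative rules.

    A fit is accepted iff its MSPE is at or below the threshold (absolute,
    or the relative rule when no absolute threshold is configured) and its
    worst standardized predictor difference is at or below the balance cap.
    Raising the MSPE threshold can only grow the accepted set (monotone).

    Returns ``(accepted_fits, RejectionReport)``; an empty accepted list is
    a legal outcome.
    """
    fits = list(fits)
    if not fits:
        raise DegenerateInputError("plausibility_filter needs at least one fit")
    accepted = []
    rows = []
    for fit in fits:
        threshold = _fit_threshold(fit, config)
        max_sd = fit.balance.max_std_diff if fit.balance is not None else float("nan")
        mspe_ok = fit.mspe <= threshold
        balance_ok = np.isnan(max_sd) or max_sd <= config.balance_cap
        if mspe_ok and balance_ok:
            accepted.append(fit)
        else:
            violated = []
            if not mspe_ok:
                violated.append("mspe")
            if not balance_ok:
                violated.append("balance")
            rows.append(
                {
                    "treated_id": fit.treated_id,
                    "mspe": fit.mspe,
                    "mspe_threshold": threshold,
                    "max_std_diff": max_sd,
                    "balance_cap": config.balance_cap,
                    "violated": "+".join(violated),
                }
            )
    report = RejectionReport(
        pd.DataFrame(
            rows,
            columns=[
                "treated_id",
                "mspe",
                "mspe_threshold",
                "max_std_diff",
                "balance_cap",
                "violated",
            ],
        )
    )
    return accepted, report


def gap_frame(fits) -> pd.DataFrame:
    """Long table of per-year gaps (observed - synthetic) for a set of fits."""
    rows = []
    for fit in fits:
        for year, g in zip(fit.years, fit.gap):
            rows.append({"treated_id": fit.treated_id, "year": year, "gap": g})
    return pd.DataFrame(rows, columns=["treated_id", "year", "gap"])
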