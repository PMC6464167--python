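"""Nested synthetic-control estimation.

The synthetic control for a treated unit is the convex combination of donor
(control) units that best reproduces the treated unit's characteristics.
Two weight vectors are estimated jointly:

* **W** — per-donor weights, nonnegative and summing to one, so the
  synthetic unit never extrapolates outside the convex hull of the donors'
  predictor values. Given a diagonal predictor-importance matrix ``V``, the
  inner problem minimizes ``(B1 - B0 W)' V (B1 - B0 W)`` over the simplex,
  where ``B1`` holds the treated unit's predictors and ``B0`` the donors'.
  Diagonal nonnegative ``V`` makes this a convex quadratic program, solved
  here to a global-optimum guarantee (:mod:`vegsynth._qp`).
* **V** — predictor-importance weights, chosen so the implied synthetic
  unit has the lowest mean squared prediction error (MSPE) against the
  treated unit's observed outcome trajectory over the full matching window:
  ``V* = argmin (Y1 - Y0 W*(V))'(Y1 - Y0 W*(V))``. This outer problem is
  non-convex in ``V``; it is parametrized on the open simplex through a
  softmax map and minimized by derivative-free Nelder-Mead local search
  from Dirichlet-random multistarts plus the equal-weights point.

Because ``W*(sV) = W*(V)`` for any ``s > 0``, importances are identified
only up to scale; they are reported either sum-normalized (weights total 1,
the tabulation convention) or with unit Euclidean norm.

Predictor columns are divided by their standard deviation (treated unit and
donors jointly) before entering the inner problem, so importances are
comparable across predictors measured in different units; zero-variance
predictors carry no matching information and are dropped with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import softmax

from ._qp import solve_simplex_qp
from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    PanelValidationError,
    ZeroImportanceError,
)
from .panel import PanelDataset, StudyConfig

__all__ = [
    "DonorWeights",
    "ImportanceWeights",
    "SyntheticControl",
    "SyntheticControlResults",
    "inner_weights",
    "trajectory_mspe",
    "normalize_importance",
    "fit_synthetic_control",
    "predictor_scaling",
]


@dataclass(frozen=True)
class DonorWeights:
    """Simplex-constrained donor weights W defining a synthetic unit."""

    donor_ids: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "donor_ids", tuple(self.donor_ids))
        if len(self.donor_ids) != len(w):
            raise ValueError("donor_ids and w length mismatch")
        if np.any(w < -1e-12):
            raise ValueError("donor weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"donor weights must sum to 1 (got {w.sum()!r})")

    def as_series(self):
        import pandas as pd

        return pd.Series(self.w, index=list(self.donor_ids), name="w")


@dataclass(frozen=True)
class ImportanceWeights:
    """Nonnegative predictor-importance weights (the diagonal of V)."""

    predictor_names: tuple[str, ...]
    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        if len(self.predictor_names) != len(v):
            raise ValueError("predictor_names and v length mismatch")
        if np.any(v < 0) or not np.isfinite(v).all():
            raise ZeroImportanceError("importance weights must be finite and >= 0")
        if not np.any(v > 0):
            raise ZeroImportanceError("importance vector is all zero")

    def as_series(self):
        import pandas as pd

        return pd.Series(self.v, index=list(self.predictor_names), name="v")


def normalize_importance(raw: ImportanceWeights, mode: str = "sum") -> ImportanceWeights:
    """Rescale an importance vector to the chosen reporting gauge.

    ``mode="sum"`` makes the entries total 1 (the convention of ranked
    weight tables); ``mode="euclidean"`` gives unit L2 norm. Order and the
    zero-pattern are preserved; V is identified only up to positive scale,
    so this changes nothing substantive.
    """
    v = raw.v
    if mode == "sum":
        denom = v.sum()
    elif mode == "euclidean":
        denom = float(np.linalg.norm(v))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise ZeroImportanceError("cannot normalize an all-zero importance vector")
    return ImportanceWeights(raw.predictor_names, v / denom)


def predictor_scaling(treated: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Per-predictor standard deviation over the treated unit and donors
    jointly (population SD). Zero entries mark zero-variance predictors."""
    joint = np.column_stack([np.asarray(treated, float), np.asarray(donors, float)])
    return joint.std(axis=1)


def _scaled_problem(importance, treated_predictors, donor_predictors, scaling):
    v = np.asarray(importance.v, dtype=float)
    b1 = np.asarray(treated_predictors, dtype=float)
    B0 = np.asarray(donor_predictors, dtype=float)
    s = np.asarray(scaling, dtype=float)
    if B0.ndim != 2:
        raise ValueError("donor_predictors must be an N x K matrix")
    N, K = B0.shape
    if b1.shape != (N,) or v.shape != (N,) or s.shape != (N,):
        raise ValueError("importance / predictors / scaling dimension mismatch")
    if K < 1:
        raise DegenerateInputError("need at least one donor (K >= 1)")
    if not (np.isfinite(b1).all() and np.isfinite(B0).all()):
        raise ValueError("predictor values must be finite")
    if np.any(s <= 0) or not np.isfinite(s).all():
        raise ValueError("scaling must be strictly positive and finite")
    # gauge-fix V to sum 1: the argmin is invariant to positive rescaling
    v = v / v.sum()
    sv = np.sqrt(v)[:, None]
    A = sv * (B0 / s[:, None])
    y = np.sqrt(v) * (b1 / s)
    return A, y


_RIDGE = 1e-8


def _ridged(G: np.ndarray) -> np.ndarray:
    """Tikhonov tie-break for degenerate inner problems.

    With more donors than effective predictors the V-weighted matching
    problem has a whole face of minimizers; which one a solver returns is
    then arbitrary, and an arbitrary vertex lets the outer search overfit
    solver idiosyncrasies. A ridge of ``1e-8 x mean(diag(G))`` selects the
    minimum-norm (most dispersed) minimizer, making ``W*(V)`` unique and
    the outer objective well defined, while perturbing non-degenerate
    solutions only at the 1e-8 level.
    """
    scale = float(np.trace(G)) / max(len(G), 1)
    if scale <= 0:
        scale = 1.0
    return G + (_RIDGE * scale) * np.eye(len(G))


def inner_weights(
    importance: ImportanceWeights,
    treated_predictors: np.ndarray,
    donor_predictors: np.ndarray,
    scaling: np.ndarray,
    donor_ids: tuple[str, ...] | None = None,
    w0: np.ndarray | None = None,
    tol: float = 1e-10,
) -> tuple[DonorWeights, float]:
    """Solve the inner problem: donor weights minimizing the V-weighted
    predictor discrepancy over the simplex.

    Returns the weights together with the attained loss
    ``(B1 - B0 W)' V (B1 - B0 W)`` computed on scaled predictors.
    """
    A, y = _scaled_problem(importance, treated_predictors, donor_predictors, scaling)
    K = A.shape[1]
    G = A.T @ A
    c = A.T @ y
    w = solve_simplex_qp(_ridged(G), c, w0=w0, tol=tol)
    loss = float(max(w @ G @ w - 2.0 * c @ w + y @ y, 0.0))
    ids = tuple(donor_ids) if donor_ids is not None else tuple(f"donor_{k}" for k in range(K))
    return DonorWeights(ids, w), loss


def trajectory_mspe(
    importance: ImportanceWeights,
    treated_outcomes: np.ndarray,
    donor_outcomes: np.ndarray,
    treated_predictors: np.ndarray,
    donor_predictors: np.ndarray,
    scaling: np.ndarray,
    w0: np.ndarray | None = None,
) -> float:
    """Outcome-trajectory MSPE implied by an importance vector.

    Solves the inner problem at ``importance`` and returns the mean squared
    per-year gap between the treated trajectory ``Y1`` and the synthetic
    trajectory ``Y0 W*(V)``. Invariant to positive rescaling of the
    importance vector because the inner argmin is.
    """
    Y1 = np.asarray(treated_outcomes, dtype=float)
    Y0 = np.asarray(donor_outcomes, dtype=float)
    if Y0.ndim != 2 or Y1.ndim != 1 or Y0.shape[0] != Y1.shape[0]:
        raise ValueError("donor_outcomes must be T x K aligned with treated_outcomes")
    if Y1.shape[0] < 2:
        raise ValueError("need at least two outcome years (T >= 2)")
    dw, _ = inner_weights(
        importance, treated_predictors, donor_predictors, scaling, w0=w0
    )
    gap = Y1 - Y0 @ dw.w
    return float(gap @ gap / len(Y1))


@dataclass
class SyntheticControlResults:
    """Fitted synthetic control for one treated unit.

    Attributes
    ----------
    donor_weights : DonorWeights
        W* — the convex combination of donors defining the synthetic unit.
    importance : ImportanceWeights
        V* in the reporting normalization (``config.v_normalization``).
    importance_sum1 : ImportanceWeights
        V* sum-normalized (the gauge used internally and for averaging).
    inner_loss : float
        Predictor-space loss at the optimum, on scaled predictors.
    mspe, sspe : float
        Mean / raw-sum squared prediction error of the synthetic trajectory
        over the matching window.
    balance : diagnostics.BalanceTable
        Covariate balance B1 vs B1* = B0 W*.
    accepted : bool
        Plausibility flag (MSPE threshold and balance cap).
    """

    treated_id: str
    donor_weights: DonorWeights
    importance: ImportanceWeights
    importance_sum1: ImportanceWeights
    inner_loss: float
    mspe: float
    sspe: float
    years: tuple[int, ...]
    observed_trajectory: np.ndarray
    synthetic_trajectory: np.ndarray
    balance: "object" = None
    accepted: bool = False
    mspe_threshold: float = float("nan")
    converged: bool = True
    n_starts: int = 0
    dropped_predictors: tuple[str, ...] = ()

    @property
    def gap(self) -> np.ndarray:
        """Observed minus synthetic outcome, per year."""
        return self.observed_trajectory - self.synthetic_trajectory

    def trajectory_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "year": list(self.years),
                "observed": self.observed_trajectory,
                "synthetic": self.synthetic_trajectory,
                "gap": self.gap,
            }
        )

    def to_json(self, path: str | Path | None = None, w_floor: float = 1e-4) -> str:
        """Serialize the fit (donor weights above ``w_floor``, importances,
        losses, acceptance) to a JSON document; optionally write it."""
        keep = self.donor_weights.w > w_floor
        doc = {
            "treated_id": self.treated_id,
            "donors": {
                d: float(w)
                for d, w in zip(self.donor_weights.donor_ids, self.donor_weights.w)
                if w > w_floor
            },
            "importance": {
                p: float(v)
                for p, v in zip(self.importance.predictor_names, self.importance.v)
            },
            "inner_loss": self.inner_loss,
            "mspe": self.mspe,
            "sspe": self.sspe,
            "mspe_threshold": self.mspe_threshold,
            "accepted": bool(self.accepted),
            "converged": bool(self.converged),
            "dropped_predictors": list(self.dropped_predictors),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def summary(self) -> str:
        lines = [
            "Synthetic control fit",
            "=" * 52,
            f"treated unit     : {self.treated_id}",
            f"donors           : {len(self.donor_weights.donor_ids)}"
            f" ({int((self.donor_weights.w > 1e-4).sum())} with weight > 1e-4)",
            f"MSPE             : {self.mspe:.6g}  (threshold {self.mspe_threshold:.6g})",
            f"inner loss       : {self.inner_loss:.6g}",
            f"accepted         : {self.accepted}",
            "",
            "Top donor weights:",
        ]
        order = np.argsort(self.donor_weights.w)[::-1][:5]
        for k in order:
            if self.donor_weights.w[k] <= 1e-4:
                break
            lines.append(
                f"  {self.donor_weights.donor_ids[k]:<20s} {self.donor_weights.w[k]:.4f}"
            )
        lines.append("")
        lines.append("Predictor importances:")
        iorder = np.argsort(self.importance.v)[::-1]
        for i in iorder:
            lines.append(
                f"  {self.importance.predictor_names[i]:<28s} {self.importance.v[i]:.4f}"
            )
        return "\n".join(lines)

    def plot(self, path: str | Path | None = None):
        """Observed vs synthetic trajectory line plot (optional review aid)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.years, self.observed_trajectory, label="observed", marker="o")
        ax.plot(
            self.years, self.synthetic_trajectory, label="synthetic", linestyle="--"
        )
        ax.set_xlabel("year")
        ax.set_ylabel("outcome (NDVI)")
        ax.set_title(f"{self.treated_id}: observed vs synthetic")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class SyntheticControl:
    """Synthetic-control model for one treated unit within a panel.

    The donor pool is every other unit in the panel. ``fit()`` runs the
    nested optimization and returns :class:`SyntheticControlResults`.

    Examples
    --------
    >>> model = SyntheticControl(panel, "unit_007", config)  # doctest: +SKIP
    >>> res = model.fit()                                    # doctest: +SKIP
    >>> print(res.summary())                                 # doctest: +SKIP
    """

    def __init__(
        self,
        panel: PanelDataset,
        treated_id: str,
        config: StudyConfig | None = None,
        donor_ids: tuple[str, ...] | None = None,
    ):
        self.panel = panel
        self.treated_id = treated_id
        self.config = config if config is not None else StudyConfig(
            treatment_year=max(panel.years) + 1
        )
        ti = panel.unit_index(treated_id)  # raises KeyError if absent
        if donor_ids is None:
            donor_ids = tuple(u for u in panel.unit_ids if u != treated_id)
        else:
            donor_ids = tuple(donor_ids)
            if treated_id in donor_ids:
                raise DegenerateInputError("treated unit cannot be its own donor")
        # canonical donor order: results must not depend on panel row order
        donor_ids = tuple(sorted(donor_ids))
        if len(donor_ids) < 1:
            raise DegenerateInputError("donor pool must contain at least one unit")
        self.donor_ids = donor_ids
        self._ti = ti
        self._di = [panel.unit_index(d) for d in donor_ids]

    # ------------------------------------------------------------------
    def _prepare(self):
        panel, cfg = self.panel, self.config
        b1_full = panel.predictors[self._ti]
        B0_full = panel.predictors[self._di].T  # N x K
        scale_full = predictor_scaling(b1_full, B0_full)
        # numerically zero variance (constant column up to float rounding)
        magnitude = np.maximum(
            np.abs(np.column_stack([b1_full, B0_full])).max(axis=1), 1.0
        )
        keep = scale_full > 1e-12 * magnitude
        dropped = tuple(
            n for n, k in zip(panel.predictor_names, keep) if not k
        )
        if dropped:
            warnings.warn(
                f"dropping zero-variance predictors (no matching information): "
                f"{dropped}",
                stacklevel=3,
            )
        if not keep.any():
            raise DegenerateInputError("all predictors have zero variance")
        names = tuple(n for n, k in zip(panel.predictor_names, keep) if k)
        return (
            b1_full[keep],
            B0_full[keep],
            scale_full[keep],
            names,
            dropped,
        )

    def fit(self, seed: int | None = None) -> SyntheticControlResults:
        """Run the nested optimization and assemble the fit.

        ``seed`` overrides the multistart seed derived from the study
        config and the treated unit's identity (identity-based so results
        do not depend on unit ordering in the panel).
        """
        panel, cfg = self.panel, self.config
        if cfg.treatment_year <= max(panel.years):
            raise PanelValidationError(
                "treatment year must postdate the last observed year so the "
                "whole observed series forms the matching window"
            )
        b1, B0, scale, names, dropped = self._prepare()
        Y1 = panel.outcomes[self._ti]
        Y0 = panel.outcomes[self._di].T  # T x K
        Nk = len(names)
        T = Y1.shape[0]

        if seed is None:
            seed = _unit_seed(cfg.seed, self.treated_id)
        rng = np.random.default_rng(seed)

        warm: dict[str, np.ndarray] = {}
        Xs = B0 / scale[:, None]  # scaled donor predictors, fixed per fit
        bs = b1 / scale

        def objective(theta: np.ndarray) -> float:
            # hot path: same algebra as inner_weights without its wrapping
            v = softmax(theta - theta.max())
            sv = np.sqrt(v)
            A = sv[:, None] * Xs
            y = sv * bs
            w = solve_simplex_qp(
                _ridged(A.T @ A), A.T @ y, w0=warm.get("w"), tol=cfg.inner_tol
            )
            warm["w"] = w
            gap = Y1 - Y0 @ w
            return float(gap @ gap / T)

        # The outer objective is weakly identified wherever the donor pool
        # can reproduce the treated trajectory under many importance
        # vectors (MSPE differences then reflect the treated unit's noise,
        # not predictive structure). The search therefore anchors on a
        # regression-informed importance vector — evaluated as-is, first —
        # and local refinements started there, at equal weights, and at
        # Dirichlet-random points replace it only when they improve MSPE
        # by more than its ~sqrt(2/T) relative sampling error (a
        # one-standard-error rule); numerical ties fall to lower inner
        # loss, then lexicographically smallest importance vector.
        theta_reg = _regression_start(Xs, panel.outcomes[self._di])
        starts = [theta_reg, np.zeros(Nk)]
        for _ in range(cfg.n_multistarts):
            alpha = rng.dirichlet(np.ones(Nk))
            starts.append(np.log(alpha + 1e-12))

        # Alternative-basin acceptance margin. A single MSPE estimated
        # from T squared gaps has ~sqrt(2/T) relative sampling error; the
        # best of M restarts is selected, so the band is widened by the
        # usual sqrt(2 ln M) extreme-value factor. A basin that beats the
        # incumbent by less than this is indistinguishable from fitting
        # the treated unit's own noise and does not displace it.
        n_starts = len(starts)
        margin_rel = min(
            0.95, np.sqrt(2.0 / T) * np.sqrt(2.0 * np.log(max(n_starts, 2)))
        )

        def evaluate(theta):
            v = softmax(theta - theta.max())
            v = v / v.sum()
            imp = ImportanceWeights(names, v)
            dw, iloss = inner_weights(imp, b1, B0, scale, tol=cfg.inner_tol)
            gap = Y1 - Y0 @ dw.w
            mspe = float(gap @ gap / T)
            return v, dw, iloss, mspe

        best = None  # ((mspe, inner_loss, v_tuple), v, dw, iloss, mspe)

        def consider(candidate, privileged=False):
            nonlocal best
            v, dw, iloss, mspe = candidate
            if not np.isfinite(mspe):
                return
            if best is None:
                best = ((mspe, iloss, tuple(v)), v, dw, iloss, mspe)
                return
            b_mspe = best[0][0]
            tie = max(1e-15, 1e-9 * b_mspe)
            cut = b_mspe - tie if privileged else b_mspe * (1.0 - margin_rel) - 1e-15
            if mspe < cut:
                best = ((mspe, iloss, tuple(v)), v, dw, iloss, mspe)
            elif abs(mspe - b_mspe) <= tie:
                key = (b_mspe, iloss, tuple(v))
                if key < best[0]:
                    best = (key, v, dw, iloss, mspe)

        consider(evaluate(theta_reg))
        any_converged = False
        maxfev = max(200, cfg.outer_maxfev_per_dim * Nk)
        for idx, x0 in enumerate(starts):
            warm.pop("w", None)
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": maxfev,
                    "fatol": cfg.outer_fatol,
                    "xatol": cfg.outer_xatol,
                },
            )
            if not np.isfinite(res.fun):
                continue
            # refining the regression-informed start is the canonical
            # nested-optimization path: it stays in its basin and replaces
            # the unrefined point whenever it improves
            consider(evaluate(res.x), privileged=(idx == 0))
            any_converged = any_converged or bool(res.success)

        if best is None:
            raise ConvergenceError(
                f"outer optimizer produced no finite solution for "
                f"{self.treated_id!r} after {len(starts)} restarts"
            )
        if not any_converged:
            warnings.warn(
                f"outer optimizer hit its evaluation budget on every restart "
                f"for {self.treated_id!r}; returning best point found",
                stacklevel=2,
            )

        _, v, dw, iloss, mspe = best
        imp_sum1 = ImportanceWeights(names, v)
        imp_report = normalize_importance(imp_sum1, cfg.v_normalization)
        synthetic = Y0 @ dw.w
        sspe = mspe * T
        threshold = (
            cfg.mspe_accept_threshold
            if cfg.mspe_accept_threshold is not None
            else cfg.relative_mspe_fraction * float(np.var(Y1))
        )
        results = SyntheticControlResults(
            treated_id=self.treated_id,
            donor_weights=DonorWeights(self.donor_ids, dw.w),
            importance=imp_report,
            importance_sum1=imp_sum1,
            inner_loss=iloss,
            mspe=mspe,
            sspe=sspe,
            years=panel.years,
            observed_trajectory=Y1.copy(),
            synthetic_trajectory=synthetic,
            mspe_threshold=threshold,
            converged=any_converged,
            n_starts=len(starts),
            dropped_predictors=dropped,
        )
        from .diagnostics import covariate_balance  # deferred: avoids cycle

        results.balance = covariate_balance(results, panel)
        max_sd = results.balance.max_std_diff
        results.accepted = bool(
            mspe <= threshold and (np.isnan(max_sd) or max_sd <= cfg.balance_cap)
        )
        return results


def _regression_start(Xs_donors: np.ndarray, Y_donors: np.ndarray) -> np.ndarray:
    """Regression-informed initial importance (log scale, softmax gauge).

    Regresses the donor outcome trajectories on the scaled donor
    predictors (with intercept) and sets the initial importance of each
    predictor proportional to the squared L2 norm of its coefficient path
    — predictors that explain the outcome get large starting weight. This
    is an initialization only; the outer search refines or replaces it.
    """
    X = np.column_stack([np.ones(Xs_donors.shape[1]), Xs_donors.T])  # K x (1+N)
    coef, *_ = np.linalg.lstsq(X, Y_donors, rcond=None)  # (1+N) x T
    v0 = (coef[1:] ** 2).sum(axis=1)
    total = v0.sum()
    if not np.isfinite(total) or total <= 0:
        return np.zeros(Xs_donors.shape[0])
    v0 = v0 / total
    return np.log(v0 + 1e-12)


def _unit_seed(base_seed: int, unit_id: str) -> int:
    """Stable per-unit seed: depends on the configured seed and the unit's
    identity, not its position, so permuting panel rows changes nothing."""
    import hashlib

    h = hashlib.sha256(f"{base_seed}:{unit_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def fit_synthetic_control(
    treated_id: str, panel: PanelDataset, config: StudyConfig
) -> SyntheticControlResults:
    """Functional entry point: nested synthetic-control fit for one unit."""
    return SyntheticControl(panel, treated_id, config).fit()
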