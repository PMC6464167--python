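import warnings

import numpy as np
import pytest

import vegsynth as vs


@pytest.fixture(scope="session")
def cohort_study():
    """30-unit placebo cohort with 2 planted unmatchable units.

    Every unit is fitted once (donor pool = the other 29). The MSPE
    threshold is calibrated to the generator's noise level: 1e4 x noise
    variance sits between the matchable floor and the planted-outlier
    separation. Shared across tests because 30 nested fits dominate the
    suite's runtime.
    """
    sim = vs.SimConfig(n_units=30, seed=42)
    panel, truth = vs.generate_panel(sim)
    modified, outlier_ids = vs.generate_outlier_units(panel, k=2, seed=42)
    cfg = vs.StudyConfig(
        n_placebo_sample=30,
        treatment_year=2017,
        seed=42,
        mspe_accept_threshold=1e4 * sim.noise_sd**2,
        balance_cap=np.inf,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = vs.run_study(modified, cfg)
    return modified, outlier_ids, results


@pytest.fixture(scope="session")
def headline_study():
    """60-unit, 10-placebo study at generator defaults."""
    panel, truth = vs.generate_panel(vs.SimConfig(n_units=60, seed=11))
    cfg = vs.StudyConfig(n_placebo_sample=10, treatment_year=2017, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = vs.run_study(panel, cfg)
    return panel, truth, results


@pytest.fixture()
def tiny_panel():
    """Hand-sized panel: 6 units x 5 years x 3 predictors."""
    rng = np.random.default_rng(7)
    n, T, N = 6, 5, 3
    outcomes = 0.4 + 0.02 * rng.random((n, T)).cumsum(axis=1)
    predictors = rng.random((n, N)) * [10.0, 100.0, 1.0]
    return vs.PanelDataset(
        unit_ids=tuple(f"u{i}" for i in range(n)),
        years=tuple(range(2010, 2010 + T)),
        outcomes=outcomes,
        predictors=predictors,
        predictor_names=("households", "area", "baseline"),
        subsystems=("Actors", "Resource", "Resource"),
    )


@pytest.fixture()
def tiny_config():
    return vs.StudyConfig(n_placebo_sample=2, treatment_year=2015, seed=5)


def make_mixture_panel(seed: int, alpha: float = 0.5, n_donors: int = 5, n_pred: int = 8):
    """Panel whose first unit is an exact alpha/(1-alpha) mixture of donors
    d0 and d1 in both predictors and outcomes (zero noise).

    With more predictors than donors the mixture is the unique simplex
    solution of the matching problem, so the planted weights are the only
    way to reproduce the treated unit.
    """
    rng = np.random.default_rng(seed)
    T = 6
    donors_X = rng.random((n_donors, n_pred)) + 0.5
    donors_Y = 0.3 + 0.3 * rng.random((n_donors, T))
    mix_X = alpha * donors_X[0] + (1 - alpha) * donors_X[1]
    mix_Y = alpha * donors_Y[0] + (1 - alpha) * donors_Y[1]
    return vs.PanelDataset(
        unit_ids=("treated",) + tuple(f"d{i}" for i in range(n_donors)),
        years=tuple(range(2010, 2010 + T)),
        outcomes=np.vstack([mix_Y, donors_Y]),
        predictors=np.vstack([mix_X, donors_X]),
        predictor_names=tuple(f"p{i}" for i in range(n_pred)),
    )


def make_clone_panel(seed: int, n_donors: int = 6, n_pred: int = 8):
    """Panel whose donor pool contains an exact clone of the treated unit."""
    rng = np.random.default_rng(seed)
    T = 6
    X = rng.random((n_donors + 1, n_pred)) + 0.5
    Y = 0.3 + 0.3 * rng.random((n_donors + 1, T))
    X[1] = X[0]
    Y[1] = Y[0]
    return vs.PanelDataset(
        unit_ids=("treated", "clone") + tuple(f"d{i}" for i in range(n_donors - 1)),
        years=tuple(range(2010, 2010 + T)),
        outcomes=Y,
        predictors=X,
        predictor_names=tuple(f"p{i}" for i in range(n_pred)),
    )
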