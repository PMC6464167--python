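"""Placebo sampling, importance averaging, stratification, study loop."""

import numpy as np
import pytest

import vegsynth as vs
from vegsynth.exceptions import (
    DegenerateInputError,
    NoAcceptedFitsError,
    PanelValidationError,
)
from vegsynth.study import average_importance, percent_growth, stratify_by_growth


class TestAssignPlaceboSample:
    def test_sample_and_donor_pools(self):
        panel, _ = vs.generate_panel(vs.SimConfig(n_units=40, seed=0))
        cfg = vs.StudyConfig(n_placebo_sample=6, treatment_year=2017, seed=1)
        sample = vs.assign_placebo_sample(panel, cfg)
        assert len(sample) == 6
        treated = [t for t, _ in sample]
        assert len(set(treated)) == 6  # without replacement
        for t, donors in sample:
            assert len(donors) == 39
            assert t not in donors

    def test_every_unit_treated_when_n_equals_population(self):
        panel, _ = vs.generate_panel(vs.SimConfig(n_units=12, seed=0))
        cfg = vs.StudyConfig(n_placebo_sample=12, treatment_year=2017, seed=2)
        sample = vs.assign_placebo_sample(panel, cfg)
        assert {t for t, _ in sample} == set(panel.unit_ids)
        assert all(len(d) == 11 for _, d in sample)

    def test_deterministic_under_seed(self):
        panel, _ = vs.generate_panel(vs.SimConfig(n_units=30, seed=0))
        cfg = vs.StudyConfig(n_placebo_sample=5, treatment_year=2017, seed=3)
        assert vs.assign_placebo_sample(panel, cfg) == vs.assign_placebo_sample(
            panel, cfg
        )

    def test_oversized_sample_rejected(self):
        panel, _ = vs.generate_panel(vs.SimConfig(n_units=10, seed=0))
        cfg = vs.StudyConfig(n_placebo_sample=11, treatment_year=2017)
        with pytest.raises(PanelValidationError):
            vs.assign_placebo_sample(panel, cfg)


class _FakeFit:
    """Minimal stand-in carrying only what averaging needs."""

    def __init__(self, treated_id, names, v):
        from vegsynth.scm import ImportanceWeights

        self.treated_id = treated_id
        self.importance_sum1 = ImportanceWeights(names, np.asarray(v, float))
        self.balance = None


class TestAverageImportance:
    names = ("pa", "pb")

    def test_two_fit_arithmetic(self):
        fits = [
            _FakeFit("u1", self.names, [0.6, 0.4]),
            _FakeFit("u2", self.names, [0.2, 0.8]),
        ]
        table = average_importance(fits)
        np.testing.assert_allclose(table.weights, [0.4, 0.6])
        frame = table.to_frame().set_index("predictor")
        assert frame.loc["pb", "rank"] == 1
        assert frame.loc["pa", "rank"] == 2

    def test_idempotent_on_identical_fits(self):
        fits = [_FakeFit(f"u{i}", self.names, [0.3, 0.7]) for i in range(5)]
        table = average_importance(fits)
        np.testing.assert_allclose(table.weights, [0.3, 0.7])

    def test_weight_column_sums_to_one_at_display_precision(self):
        rng = np.random.default_rng(0)
        names = tuple(f"p{i}" for i in range(7))
        fits = [
            _FakeFit(f"u{i}", names, rng.dirichlet(np.ones(7))) for i in range(28)
        ]
        table = average_importance(fits)
        assert table.n_fits == 28
        assert round(float(table.to_frame()["mean_weight"].sum()), 2) == 1.0

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            average_importance([])
        fits = [
            _FakeFit("u1", self.names, [0.5, 0.5]),
            _FakeFit("u2", ("px", "py"), [0.5, 0.5]),
        ]
        with pytest.raises(PanelValidationError):
            average_importance(fits)


class TestStratifyByGrowth:
    def growth_panel(self):
        # units engineered to -5%, +10%, +15%, +25% growth
        years = (2001, 2002, 2003)
        outcomes = np.array(
            [
                [0.40, 0.39, 0.38],
                [0.40, 0.42, 0.44],
                [0.40, 0.43, 0.46],
                [0.40, 0.45, 0.50],
            ]
        )
        return vs.PanelDataset(
            unit_ids=("down", "ten", "fifteen", "quarter"),
            years=years,
            outcomes=outcomes,
            predictors=np.ones((4, 2)) + np.arange(4)[:, None],
            predictor_names=("pa", "pb"),
        )

    def fits_for(self, panel):
        return [
            _FakeFit(u, ("pa", "pb"), [0.5, 0.5]) for u in panel.unit_ids
        ]

    def test_boundary_conventions(self):
        panel = self.growth_panel()
        cfg = vs.StudyConfig(treatment_year=2004, growth_cutpoints=(10, 20))
        assignments, tables = stratify_by_growth(panel, self.fits_for(panel), cfg)
        by_unit = {a.unit_id: a for a in assignments}
        assert by_unit["down"].stratum == "low"
        # exactly +10% falls in the middle bin (lower-inclusive)
        assert by_unit["ten"].percent_change == pytest.approx(10.0)
        assert by_unit["ten"].stratum == "medium"
        assert by_unit["fifteen"].stratum == "medium"
        assert by_unit["quarter"].stratum == "high"

    def test_strata_partition_accepted_units(self):
        panel = self.growth_panel()
        cfg = vs.StudyConfig(treatment_year=2004)
        assignments, tables = stratify_by_growth(panel, self.fits_for(panel), cfg)
        labels = [a.unit_id for a in assignments]
        assert sorted(labels) == sorted(panel.unit_ids)
        assert sum(t.n_fits for t in tables.values()) == len(labels)

    def test_empty_stratum_reported_with_zero_fits(self):
        panel = self.growth_panel()
        cfg = vs.StudyConfig(treatment_year=2004, growth_cutpoints=(90, 95))
        _, tables = stratify_by_growth(panel, self.fits_for(panel), cfg)
        assert tables["low"].n_fits == 4
        assert tables["medium"].n_fits == 0
        assert tables["high"].n_fits == 0

    def test_zero_baseline_rejected(self):
        panel = self.growth_panel()
        outcomes = panel.outcomes.copy()
        outcomes[0, 0] = 0.0
        import dataclasses

        bad = dataclasses.replace(panel, outcomes=outcomes)
        with pytest.raises(DegenerateInputError):
            percent_growth(bad, "down")


class TestRunStudy:
    def study(self, seed=0, **cfg_kw):
        panel, truth = vs.generate_panel(
            vs.SimConfig(n_units=24, n_predictors=10, seed=seed)
        )
        cfg = vs.StudyConfig(
            n_placebo_sample=cfg_kw.pop("n_placebo_sample", 3),
            treatment_year=2017,
            seed=seed,
            **cfg_kw,
        )
        return panel, truth, cfg

    def test_tables_sum_to_one_and_log_written(self):
        panel, _, cfg = self.study(seed=1)
        res = vs.run_study(panel, cfg)
        assert abs(res.importance.weights.sum() - 1) <= 1e-6
        for table in res.stratum_tables.values():
            if table.n_fits:
                assert abs(table.weights.sum() - 1) <= 1e-6
        assert any("study start" in line for line in res.log_lines)
        assert "Placebo synthetic-control study" in res.summary()

    def test_single_placebo_table_equals_fit_importance(self):
        panel, _, cfg = self.study(seed=2, n_placebo_sample=1, balance_cap=np.inf)
        cfg.mspe_accept_threshold = np.inf
        res = vs.run_study(panel, cfg)
        assert len(res.fits) == 1
        np.testing.assert_allclose(
            res.importance.weights, res.fits[0].importance_sum1.v, atol=1e-12
        )

    def test_rerun_identical(self):
        panel, _, cfg = self.study(seed=3)
        a = vs.run_study(panel, cfg)
        b = vs.run_study(panel, cfg)
        np.testing.assert_array_equal(a.importance.weights, b.importance.weights)
        assert [f.treated_id for f in a.fits] == [f.treated_id for f in b.fits]

    def test_unit_permutation_leaves_tables_unchanged(self):
        panel, _, cfg = self.study(seed=4)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(panel.unit_ids))
        shuffled = panel.reorder_units(perm)
        a = vs.run_study(panel, cfg)
        b = vs.run_study(shuffled, cfg)
        np.testing.assert_array_equal(a.importance.weights, b.importance.weights)
        assert a.importance.predictor_names == b.importance.predictor_names

    def test_zero_accepted_raises(self):
        panel, _, cfg = self.study(seed=5)
        cfg.mspe_accept_threshold = 0.0
        with pytest.raises(NoAcceptedFitsError):
            vs.run_study(panel, cfg)
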