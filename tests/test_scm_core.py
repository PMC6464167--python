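"""Inner/outer synthetic-control optimization: oracle checks and contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vegsynth as vs
from vegsynth.exceptions import DegenerateInputError, ZeroImportanceError
from vegsynth.scm import ImportanceWeights, inner_weights, trajectory_mspe

from _gridsearch import grid_min_loss
from conftest import make_clone_panel, make_mixture_panel


def random_instance(rng, N=None, K=None):
    N = N if N is not None else int(rng.integers(1, 4))
    K = K if K is not None else int(rng.integers(1, 5))
    B0 = rng.normal(size=(N, K))
    b1 = rng.normal(size=N)
    v = rng.dirichlet(np.ones(N))
    scale = np.abs(rng.normal(1.0, 0.3, size=N)) + 0.2
    return v, b1, B0, scale


class TestInnerWeights:
    def test_exact_match_vertex(self):
        rng = np.random.default_rng(0)
        B0 = rng.random((4, 5))
        b1 = B0[:, 3].copy()
        imp = ImportanceWeights(("a", "b", "c", "d"), np.array([1.0, 2.0, 0.5, 1.0]))
        dw, loss = inner_weights(imp, b1, B0, np.ones(4))
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert dw.w[3] == pytest.approx(1.0, abs=1e-6)

    def test_single_donor_forced(self):
        imp = ImportanceWeights(("a",), np.array([1.0]))
        dw, _ = inner_weights(imp, np.array([5.0]), np.array([[1.0]]), np.ones(1))
        np.testing.assert_array_equal(dw.w, [1.0])

    def test_simplex_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v, b1, B0, scale = random_instance(rng)
            imp = ImportanceWeights(tuple(f"p{i}" for i in range(len(v))), v)
            dw, _ = inner_weights(imp, b1, B0, scale)
            assert np.all(dw.w >= 0)
            assert abs(dw.w.sum() - 1.0) <= 1e-6

    def test_loss_beats_every_vertex(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            v, b1, B0, scale = random_instance(rng)
            imp = ImportanceWeights(tuple(f"p{i}" for i in range(len(v))), v)
            _, loss = inner_weights(imp, b1, B0, scale)
            for k in range(B0.shape[1]):
                r = (b1 - B0[:, k]) / scale
                vertex = float((v / v.sum()) @ (r * r))
                assert loss <= vertex + 1e-9

    def test_matches_grid_oracle(self):
        """Attained loss agrees with exhaustive grid search (step 0.001)."""
        rng = np.random.default_rng(3)
        for _ in range(12):
            v, b1, B0, scale = random_instance(rng, K=int(rng.integers(2, 4)))
            imp = ImportanceWeights(tuple(f"p{i}" for i in range(len(v))), v)
            _, loss = inner_weights(imp, b1, B0, scale)
            oracle = grid_min_loss(v, b1, B0, scale, step=0.001)
            assert loss <= oracle + 1e-6

    def test_zero_importance_rejected(self):
        with pytest.raises(ZeroImportanceError):
            ImportanceWeights(("a", "b"), np.zeros(2))

    def test_nonfinite_predictors_rejected(self):
        imp = ImportanceWeights(("a",), np.ones(1))
        with pytest.raises(ValueError):
            inner_weights(imp, np.array([np.inf]), np.ones((1, 2)), np.ones(1))


class TestTrajectoryMspe:
    def instance(self, seed=0, N=3, K=4, T=5):
        rng = np.random.default_rng(seed)
        return dict(
            treated_outcomes=rng.random(T),
            donor_outcomes=rng.random((T, K)),
            treated_predictors=rng.normal(size=N),
            donor_predictors=rng.normal(size=(N, K)),
            scaling=np.ones(N),
        )

    def test_exact_duplicate_gives_zero(self):
        inst = self.instance()
        inst["donor_outcomes"][:, 2] = inst["treated_outcomes"]
        inst["donor_predictors"][:, 2] = inst["treated_predictors"]
        imp = ImportanceWeights(("a", "b", "c"), np.array([1.0, 1.0, 1.0]))
        assert trajectory_mspe(imp, **inst) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", [0.1, 1.0, 7.3, 10.0])
    def test_scale_invariance(self, s):
        inst = self.instance(seed=4)
        names = ("a", "b", "c")
        v = np.array([0.2, 0.5, 0.3])
        base = trajectory_mspe(ImportanceWeights(names, v), **inst)
        scaled = trajectory_mspe(ImportanceWeights(names, s * v), **inst)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_composes_inner_oracle_with_gap_formula(self):
        inst = self.instance(seed=5, N=2, K=3, T=4)
        names = ("a", "b")
        v = np.array([0.6, 0.4])
        imp = ImportanceWeights(names, v)
        mspe = trajectory_mspe(imp, **inst)
        dw, loss = inner_weights(
            imp,
            inst["treated_predictors"],
            inst["donor_predictors"],
            inst["scaling"],
        )
        oracle_loss = grid_min_loss(
            v, inst["treated_predictors"], inst["donor_predictors"], inst["scaling"]
        )
        assert loss <= oracle_loss + 1e-6
        gap = inst["treated_outcomes"] - inst["donor_outcomes"] @ dw.w
        assert mspe == pytest.approx(float(gap @ gap) / 4, abs=1e-12)


class TestNormalizeImportance:
    def test_sum_mode(self):
        out = vs.normalize_importance(
            ImportanceWeights(("a", "b", "c", "d"), np.array([2.0, 2, 2, 2])), "sum"
        )
        np.testing.assert_allclose(out.v, 0.25)

    def test_euclidean_mode_3_4_5(self):
        out = vs.normalize_importance(
            ImportanceWeights(("a", "b"), np.array([3.0, 4.0])), "euclidean"
        )
        np.testing.assert_allclose(out.v, [0.6, 0.8])

    def test_zero_vector_rejected(self):
        with pytest.raises(ZeroImportanceError):
            ImportanceWeights(("a", "b"), np.array([0.0, 0.0]))

    def test_zero_pattern_preserved(self):
        out = vs.normalize_importance(
            ImportanceWeights(("a", "b", "c"), np.array([0.0, 3.0, 1.0])), "sum"
        )
        assert out.v[0] == 0.0
        assert out.v.sum() == pytest.approx(1.0)


class TestFitSyntheticControl:
    def config(self, panel, seed=0):
        return vs.StudyConfig(
            n_placebo_sample=1, treatment_year=max(panel.years) + 1, seed=seed
        )

    def test_planted_two_donor_mixture_recovered(self):
        for seed in (0, 1, 2):
            panel = make_mixture_panel(seed)
            res = vs.fit_synthetic_control("treated", panel, self.config(panel))
            assert res.mspe <= 1e-8
            w = res.donor_weights.as_series()
            assert w["d0"] + w["d1"] >= 0.99

    def test_duplicate_donor_exactness(self):
        for seed in (0, 1, 2):
            panel = make_clone_panel(seed)
            res = vs.fit_synthetic_control("treated", panel, self.config(panel))
            assert res.mspe <= 1e-10
            assert res.donor_weights.as_series()["clone"] >= 0.999

    def test_determinism_same_seed(self):
        panel = make_mixture_panel(3)
        a = vs.fit_synthetic_control("treated", panel, self.config(panel, seed=9))
        b = vs.fit_synthetic_control("treated", panel, self.config(panel, seed=9))
        np.testing.assert_array_equal(a.donor_weights.w, b.donor_weights.w)
        np.testing.assert_array_equal(a.importance.v, b.importance.v)

    def test_synthetic_trajectory_is_convex_combination(self):
        panel = make_mixture_panel(5)
        res = vs.fit_synthetic_control("treated", panel, self.config(panel))
        di = [panel.unit_index(d) for d in res.donor_weights.donor_ids]
        Y0 = panel.outcomes[di].T
        np.testing.assert_allclose(
            res.synthetic_trajectory, Y0 @ res.donor_weights.w, atol=1e-12
        )
        lo, hi = Y0.min(axis=1), Y0.max(axis=1)
        assert np.all(res.synthetic_trajectory >= lo - 1e-9)
        assert np.all(res.synthetic_trajectory <= hi + 1e-9)

    def test_missing_treated_unit_raises(self):
        panel = make_mixture_panel(6)
        with pytest.raises(KeyError):
            vs.SyntheticControl(panel, "nope", self.config(panel))

    def test_results_serialization(self, tmp_path):
        panel = make_mixture_panel(7)
        res = vs.fit_synthetic_control("treated", panel, self.config(panel))
        text = res.to_json(tmp_path / "fit.json")
        import json

        doc = json.loads(text)
        assert doc["treated_id"] == "treated"
        assert all(w > 1e-4 for w in doc["donors"].values())
        assert res.summary().startswith("Synthetic control fit")


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_property_simplex_and_vertex_dominance(seed):
    """Any instance: weights on the simplex and loss no worse than any
    single-donor solution."""
    rng = np.random.default_rng(seed)
    v, b1, B0, scale = random_instance(rng)
    imp = ImportanceWeights(tuple(f"p{i}" for i in range(len(v))), v)
    dw, loss = inner_weights(imp, b1, B0, scale)
    assert np.all(dw.w >= 0) and abs(dw.w.sum() - 1) <= 1e-6
    vn = v / v.sum()
    for k in range(B0.shape[1]):
        r = (b1 - B0[:, k]) / scale
        assert loss <= float(vn @ (r * r)) + 1e-9
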