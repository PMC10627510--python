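"""Fit metrics, prediction, multi-start recovery on small problems, and
identifiability diagnostics."""

import numpy as np
import pytest

from rafpa import (
    FitProblem,
    ParameterLayout,
    fit_metric_absolute,
    fit_metric_chisq,
    identifiability_report,
    multistart_fit,
    predict_matrix,
    read_dose_response_csv,
)
from rafpa.fitting import submodel_layout
from rafpa.synth import make_panel, simulate_responses


@pytest.fixture(scope="module")
def small_problem():
    """3-drug noiseless panel: cheap, exactly solvable."""
    panel = make_panel(n_drugs=3, archetype_mix=["type_I", "type_I5", "type_II"],
                       seed=8)
    panel = simulate_responses(panel, noise_cv=0.0, seed=0)
    return panel, panel.to_fit_problem()


def _truth_vector(panel, layout):
    return layout.pack(
        {
            "K_A": panel.shared["K_A"],
            "K_d": [p.K_d for p in panel.ground_truth],
            "f": [p.f for p in panel.ground_truth],
            "g": [p.g for p in panel.ground_truth],
        }
    )


class TestMetrics:
    def test_zero_iff_equal(self):
        obs = np.array([[1.0, 0.5], [0.8, 0.9]])
        assert fit_metric_chisq(obs, obs) == 0.0
        assert fit_metric_absolute(obs, obs) == 0.0

    def test_forced_arithmetic(self):
        assert fit_metric_chisq(np.array([[1.1]]), np.array([[1.0]])) == pytest.approx(0.01)
        assert fit_metric_absolute(np.array([[0.9]]), np.array([[1.0]])) == pytest.approx(0.1)

    def test_constant_relative_error(self):
        obs = np.array([[0.2, 0.5], [1.0, 0.7]])
        eps = 0.03
        assert fit_metric_chisq(obs * (1 + eps), obs) == pytest.approx(eps**2)
        assert fit_metric_absolute(obs * (1 + eps), obs) == pytest.approx(eps)

    def test_shape_mismatch_and_zero_obs(self):
        with pytest.raises(ValueError):
            fit_metric_chisq(np.ones((2, 2)), np.ones((2, 3)))
        with pytest.raises(ValueError):
            fit_metric_absolute(np.ones((1, 1)), np.zeros((1, 1)))

    def test_row_permutation_invariance(self, small_problem):
        panel, prob = small_problem
        theta = _truth_vector(panel, prob.layout)
        pred = predict_matrix(theta, prob)
        perm = [2, 0, 1]
        assert fit_metric_chisq(pred, prob.Y) == pytest.approx(
            fit_metric_chisq(pred[perm], prob.Y[perm]), rel=1e-14
        )
        assert fit_metric_absolute(pred, prob.Y) == pytest.approx(
            fit_metric_absolute(pred[perm], prob.Y[perm]), rel=1e-14
        )


class TestPredictMatrix:
    def test_ground_truth_reproduces_noiseless_panel(self, small_problem):
        panel, prob = small_problem
        theta = _truth_vector(panel, prob.layout)
        np.testing.assert_allclose(predict_matrix(theta, prob), panel.noiseless,
                                   rtol=1e-12)

    def test_identical_parameters_identical_rows(self, small_problem):
        _, prob = small_problem
        layout = prob.layout
        theta = layout.pack({"K_A": 5.0, "K_d": [0.1] * 3, "f": [0.3] * 3,
                             "g": [50.0] * 3})
        pred = predict_matrix(theta, prob)
        np.testing.assert_allclose(pred[0], pred[1])
        np.testing.assert_allclose(pred[1], pred[2])

    def test_no_mechanisms_gives_monotone_rows(self, small_problem):
        _, prob = small_problem
        layout = submodel_layout(prob.layout, "NC-only")  # K_A=0, f=1 pinned
        theta = layout.pack({"K_d": [0.1] * 3, "g": [1.0] * 3})
        pred = predict_matrix(theta, prob.with_layout(layout))
        assert np.all(np.diff(pred, axis=1) <= 1e-12)

    def test_wrong_length_vector_rejected(self, small_problem):
        _, prob = small_problem
        with pytest.raises(ValueError):
            predict_matrix(np.ones(3), prob)


class TestMultistart:
    def test_start_at_optimum_converges_immediately(self, small_problem):
        panel, prob = small_problem
        res = multistart_fit(prob, n_starts=1, seed=0, inner_starts=0)
        # a single random start does not need to find the optimum, but the
        # machinery must run end-to-end and produce a valid ensemble
        assert res.n_members >= 1
        assert res.metrics[0] == res.best_metric

    def test_noiseless_recovery(self, small_problem):
        """With no noise the global optimum is the ground truth: metric ~ 0
        and the shared autoinhibition constant is recovered to ~1%."""
        panel, prob = small_problem
        res = multistart_fit(prob, n_starts=12, seed=4)
        assert res.best_metric < 1e-6
        assert res.best_params()["K_A"] == pytest.approx(
            panel.shared["K_A"], rel=0.01
        )

    def test_seeded_determinism(self, small_problem):
        _, prob = small_problem
        r1 = multistart_fit(prob, n_starts=4, seed=5)
        r2 = multistart_fit(prob, n_starts=4, seed=5)
        np.testing.assert_array_equal(r1.ensemble, r2.ensemble)
        np.testing.assert_array_equal(r1.metrics, r2.metrics)
        r3 = multistart_fit(prob, n_starts=4, seed=6)
        assert r3.best_metric != r1.best_metric or not np.array_equal(
            r3.best, r1.best
        )

    def test_ensemble_within_window(self, small_problem):
        _, prob = small_problem
        res = multistart_fit(prob, n_starts=8, seed=1)
        assert np.all(res.metrics <= 1.1 * res.best_metric + 1e-30)

    def test_result_io(self, small_problem, tmp_path):
        _, prob = small_problem
        res = multistart_fit(prob, n_starts=2, seed=3)
        res.to_json(tmp_path / "fit.json")
        res.ensemble_to_csv(tmp_path / "ens.csv", header="# h")
        res.curves_to_csv(tmp_path / "curves.csv")
        import json

        payload = json.loads((tmp_path / "fit.json").read_text())
        assert payload["best_metric"] == pytest.approx(res.best_metric)


class TestIdentifiability:
    def test_degenerate_ensemble_zero_spread(self, small_problem):
        _, prob = small_problem
        res = multistart_fit(prob, n_starts=1, seed=0, inner_starts=0)
        import dataclasses

        dup = dataclasses.replace(
            res,
            ensemble=np.vstack([res.ensemble[0], res.ensemble[0]]),
            metrics=np.array([res.best_metric] * 2),
        )
        rep = identifiability_report(dup)
        assert np.all(rep.summary["cv"] == 0.0)
        assert np.all(rep.summary["min"] == rep.summary["max"])

    def test_empty_ensemble_rejected(self, small_problem):
        _, prob = small_problem
        res = multistart_fit(prob, n_starts=1, seed=0, inner_starts=0)
        import dataclasses

        empty = dataclasses.replace(
            res, ensemble=res.ensemble[:0], metrics=res.metrics[:0]
        )
        with pytest.raises(ValueError):
            identifiability_report(empty)


class TestLayout:
    def test_submodel_pins(self):
        layout = ParameterLayout(drugs=("a", "b"))
        no_nc = submodel_layout(layout, "no-NC")
        assert "g" not in no_nc.per_drug_free
        assert no_nc.fixed["g"] == 1.0
        no_ca = submodel_layout(layout, "no-CA")
        assert "K_A" not in no_ca.global_free
        assert no_ca.fixed["K_A"] == 0.0
        assert no_ca.n_params == 2 * 3

    def test_pack_unpack_round_trip(self):
        layout = ParameterLayout(drugs=("a", "b"),
                                 global_free=("K_A", "K_dim"))
        vals = {"K_A": 3.0, "K_dim": 0.2, "K_d": [0.1, 0.5], "f": [0.2, 1.1],
                "g": [10.0, 400.0]}
        theta = layout.pack(vals)
        out = layout.unpack(theta)
        assert out["K_A"] == 3.0 and out["K_dim"] == 0.2
        np.testing.assert_allclose(out["f"], vals["f"])
        assert out["raf_total"] == pytest.approx(0.04)  # fixed default


def test_csv_round_trip(tmp_path):
    from rafpa.synth import write_panel

    panel = simulate_responses(make_panel(n_drugs=2, seed=3,
                                          archetype_mix=["type_I", "type_II"]),
                               noise_cv=0.02, seed=4)
    path = tmp_path / "panel.csv"
    write_panel(panel, path)
    prob = read_dose_response_csv(path)
    np.testing.assert_allclose(prob.Y, panel.noisy, rtol=1e-12)
    np.testing.assert_allclose(prob.dose_grids, panel.dose_grids, rtol=1e-12)
    assert prob.drugs == panel.drugs
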