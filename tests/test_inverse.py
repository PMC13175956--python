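"""Inverse optimization: prediction penalties, the relaxed inverse LP and the
cutting-plane refinement."""
import numpy as np
import pytest

import gkplan as gk
from gkplan.prediction import DosePrediction


@pytest.fixture(scope="module")
def achievable_prediction(micro_phantom, micro_kernels, generating_weights):
    """Zero-noise prediction rendered from the exact optimum under known
    generating weights."""
    pred, sol = gk.generate_prediction(
        micro_phantom, micro_kernels, generating_weights,
        isocenter_subset=None, limits=[2], noise_sd=0.0, seed=0,
    )
    return pred, sol


class TestPenalties:
    def test_exact_prescription_gives_zero_slacks(self, micro_phantom):
        tgt = micro_phantom.targets[0]
        dose = np.zeros(micro_phantom.grid.shape)
        dose[tgt.mask] = tgt.prescription_dose
        pen = gk.penalties_from_prediction(
            DosePrediction(dose=dose, provenance={}), micro_phantom, [2]
        )
        for fam in (pen.y_t, pen.y_m, pen.y_s, pen.y_g):
            assert fam[0].sum() == 0.0

    def test_zero_prediction_underdoses_everywhere(self, micro_phantom):
        tgt = micro_phantom.targets[0]
        dose = np.zeros(micro_phantom.grid.shape)
        pen = gk.penalties_from_prediction(
            DosePrediction(dose=dose, provenance={}), micro_phantom, [2]
        )
        assert np.allclose(pen.y_t[0], tgt.prescription_dose)
        assert pen.y_m[0].sum() == 0.0
        assert pen.y_s[0].sum() == 0.0

    def test_random_prediction_matches_direct_hinges(self, micro_phantom):
        rng = np.random.default_rng(4)
        dose = rng.uniform(0, 40, size=micro_phantom.grid.shape)
        pen = gk.penalties_from_prediction(
            DosePrediction(dose=dose, provenance={}), micro_phantom, [3]
        )
        tgt = micro_phantom.targets[0]
        # Brute-force voxel loop.
        d_t = tgt.prescription_dose
        expected_t = [max(d_t - dose[tuple(v)], 0.0) for v in np.argwhere(tgt.mask)]
        expected_g = [
            max(dose[tuple(v)] - tgt.dose_g, 0.0) for v in np.argwhere(tgt.shell_g)
        ]
        assert np.allclose(pen.y_t[0], expected_t)
        assert np.allclose(pen.y_g[0], expected_g)

    def test_tau_hat_from_regression_by_default(self, micro_phantom):
        dose = np.zeros(micro_phantom.grid.shape)
        pen = gk.penalties_from_prediction(
            DosePrediction(dose=dose, provenance={}), micro_phantom, [4]
        )
        tgt = micro_phantom.targets[0]
        assert pen.tau_hat[0] == pytest.approx(
            gk.bot_estimate(tgt.prescription_dose, tgt.volume_cc(micro_phantom.grid), 4)
        )

    def test_grid_mismatch_rejected(self, micro_phantom):
        with pytest.raises(ValueError):
            gk.penalties_from_prediction(
                DosePrediction(dose=np.zeros((4, 4, 4)), provenance={}),
                micro_phantom,
                [2],
            )


class TestRelaxedInverse:
    def test_weights_valid_and_duals_signed(self, micro_phantom, micro_kernels,
                                            achievable_prediction):
        pred, _ = achievable_prediction
        pen = gk.penalties_from_prediction(pred, micro_phantom, [2])
        dual = gk.solve_relaxed_inverse(pen, micro_kernels, micro_phantom, [2])
        w = dual.weights.values
        assert (w >= -1e-12).all() and w.sum() > 0
        q = dual.duals
        tol = 1e-8
        assert (q["q_t"][0] >= -tol).all()
        for key in ("q_m", "q_s", "q_g"):
            assert (q[key][0] <= tol).all()
        assert (q["q_bot"] <= tol).all()
        assert (q["q_z"] <= tol).all()
        assert q["q_h"] <= tol

    def test_dual_normalization_holds(self, micro_phantom, micro_kernels,
                                      achievable_prediction):
        pred, _ = achievable_prediction
        pen = gk.penalties_from_prediction(pred, micro_phantom, [2])
        dual = gk.solve_relaxed_inverse(pen, micro_kernels, micro_phantom, [2])
        tgt = micro_phantom.targets[0]
        q = dual.duals
        value = (
            tgt.prescription_dose * q["q_t"][0].sum()
            + 2 * tgt.prescription_dose * q["q_m"][0].sum()
            + tgt.dose_s * q["q_s"][0].sum()
            + tgt.dose_g * q["q_g"][0].sum()
            + 2 * q["q_h"]
        )
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_achievable_prediction_nonnegative_gap(self, micro_phantom, micro_kernels,
                                                   achievable_prediction):
        # With the true delivery time from provenance the prediction is
        # exactly feasible, so weak duality makes the gap finite and >= 0.
        pred, sol = achievable_prediction
        pen = gk.penalties_from_prediction(pred, micro_phantom, [2], tau_hat=sol.tau)
        dual = gk.solve_relaxed_inverse(pen, micro_kernels, micro_phantom, [2])
        assert np.isfinite(dual.gap)
        assert dual.gap >= -1e-6
        # Forward-solving the relaxation under the recovered weights can
        # only do at least as well as the prediction itself.
        assert dual.forward_objective <= dual.objective_at_prediction + 1e-6

    def test_penalty_scaling_preserves_weight_direction(self, micro_phantom,
                                                        micro_kernels,
                                                        achievable_prediction):
        pred, sol = achievable_prediction
        pen = gk.penalties_from_prediction(pred, micro_phantom, [2], tau_hat=sol.tau)
        dual1 = gk.solve_relaxed_inverse(pen, micro_kernels, micro_phantom, [2])
        doubled = gk.PredictionPenalties(
            y_t=[2 * y for y in pen.y_t],
            y_m=[2 * y for y in pen.y_m],
            y_s=[2 * y for y in pen.y_s],
            y_g=[2 * y for y in pen.y_g],
            tau_hat=2 * pen.tau_hat,
        )
        dual2 = gk.solve_relaxed_inverse(doubled, micro_kernels, micro_phantom, [2])
        # The objective is linear in the penalties, so the optimal value
        # doubles; the weight direction agrees up to LP degeneracy.
        assert dual2.objective_at_prediction == pytest.approx(
            2 * dual1.objective_at_prediction, rel=1e-4
        )
        n1 = dual1.weights.normalized().values
        n2 = dual2.weights.normalized().values
        assert np.allclose(n1, n2, atol=0.05)


@pytest.fixture(scope="module")
def inverse_setup(micro_phantom, micro_kernels, achievable_prediction):
    pred, sol = achievable_prediction
    pen = gk.penalties_from_prediction(pred, micro_phantom, [2], tau_hat=sol.tau)
    dual = gk.solve_relaxed_inverse(pen, micro_kernels, micro_phantom, [2])
    template = gk.PlanningProblem(
        phantom=micro_phantom, kernels=micro_kernels, limits=[2],
        weights=dual.weights,
    )
    return pen, dual, template


class TestCuttingPlane:

    def test_gap_history_non_increasing(self, inverse_setup):
        pen, dual, template = inverse_setup
        _, cutset = gk.cutting_plane(
            pen, template, dual.weights, max_time_s=120, forward_time_budget_s=30,
            max_iter=8,
        )
        gaps = cutset.gap_history
        assert len(gaps) >= 1
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] <= dual.gap + 1e-6

    def test_zero_budget_falls_back_to_initial_weights(self, inverse_setup):
        pen, dual, template = inverse_setup
        weights, cutset = gk.cutting_plane(
            pen, template, dual.weights, max_time_s=0.0
        )
        assert cutset.fallback
        assert np.array_equal(weights.values, dual.weights.values)

    def test_regularization_does_not_slow_convergence(self, micro_phantom,
                                                      micro_kernels,
                                                      generating_weights):
        # Across 10 seeded micro-instances the regularized variant should
        # need no more iterations than the plain variant at least half the
        # time (it is designed to cut the iteration count).
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            subset = rng.choice(micro_kernels.n_isocenters, size=2, replace=False)
            pred, sol = gk.generate_prediction(
                micro_phantom, micro_kernels, generating_weights,
                isocenter_subset=subset, noise_sd=0.0, seed=seed,
            )
            pen = gk.penalties_from_prediction(
                pred, micro_phantom, [2], tau_hat=sol.tau
            )
            dual = gk.solve_relaxed_inverse(pen, micro_kernels, micro_phantom, [2])
            template = gk.PlanningProblem(
                phantom=micro_phantom, kernels=micro_kernels, limits=[2],
                weights=dual.weights,
            )
            plain = gk.cutting_plane(
                pen, template, dual.weights, regularized=False,
                max_time_s=60, forward_time_budget_s=20, max_iter=6,
            )[1]
            reg = gk.cutting_plane(
                pen, template, dual.weights, regularized=True,
                max_time_s=60, forward_time_budget_s=20, max_iter=6,
            )[1]
            if reg.n_iterations <= plain.n_iterations:
                wins += 1
        assert wins >= 5

    def test_finite_termination_with_reason(self, inverse_setup):
        pen, dual, template = inverse_setup
        _, cutset = gk.cutting_plane(
            pen, template, dual.weights, max_time_s=120, forward_time_budget_s=30,
            max_iter=5,
        )
        assert cutset.n_iterations <= 5
        assert cutset.reason != ""


class TestPredictionGenerator:
    def test_zero_noise_equals_rendered_optimum(self, micro_phantom, micro_kernels,
                                                generating_weights):
        pred, sol = gk.generate_prediction(
            micro_phantom, micro_kernels, generating_weights,
            isocenter_subset=[0, 1], noise_sd=0.0, seed=9,
        )
        assert np.array_equal(pred.dose, micro_kernels.render_dose(sol.t))

    def test_same_seed_reproduces_noise(self, micro_phantom, micro_kernels,
                                        generating_weights):
        kwargs = dict(isocenter_subset=[0, 2], noise_sd=0.5, seed=11)
        p1, _ = gk.generate_prediction(
            micro_phantom, micro_kernels, generating_weights, **kwargs
        )
        p2, _ = gk.generate_prediction(
            micro_phantom, micro_kernels, generating_weights, **kwargs
        )
        assert np.array_equal(p1.dose, p2.dose)
        p3, _ = gk.generate_prediction(
            micro_phantom, micro_kernels, generating_weights,
            isocenter_subset=[0, 2], noise_sd=0.5, seed=12,
        )
        assert not np.array_equal(p1.dose, p3.dose)

    def test_noise_truncated_at_zero(self, micro_phantom, micro_kernels,
                                     generating_weights):
        pred, _ = gk.generate_prediction(
            micro_phantom, micro_kernels, generating_weights,
            isocenter_subset=[0], noise_sd=2.0, seed=13,
        )
        assert (pred.dose >= 0).all()
        assert np.isfinite(pred.dose).all()

    def test_provenance_records_generator(self, micro_phantom, micro_kernels,
                                          generating_weights):
        pred, _ = gk.generate_prediction(
            micro_phantom, micro_kernels, generating_weights,
            isocenter_subset=[0, 1], noise_sd=0.25, seed=3,
        )
        prov = pred.provenance
        assert prov["noise_sd"] == 0.25
        assert prov["seed"] == 3
        assert prov["isocenter_subset"] == [0, 1]
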