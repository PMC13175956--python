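"""The mixed-integer planning model, its relaxation and objective evaluation."""
import numpy as np
import pytest
from scipy.optimize import linprog

import gkplan as gk
from gkplan.kernels import CentralKernel, KernelSet
from gkplan.planning import term_values

from conftest import build_oracle_instance


def brute_force_optimum(phantom, kernels, limits, weights, big_m):
    """Independent oracle: enumerate every isocenter subset, solve the
    fixed-subset LP directly with linprog, and return the best value.

    Deliberately re-transcribes the model from scratch (dense matrices, raw
    linprog) rather than reusing the package's assembly code.
    """
    nI = kernels.n_isocenters
    nB = nI * 24
    tgt = phantom.targets[0]
    d_t, d_s, d_g = tgt.prescription_dose, tgt.dose_s, tgt.dose_g
    phi_t = kernels.rate_matrix(np.argwhere(tgt.mask))
    phi_s = kernels.rate_matrix(np.argwhere(tgt.shell_s))
    phi_g = kernels.rate_matrix(np.argwhere(tgt.shell_g))
    n_t, n_s, n_g = phi_t.shape[0], phi_s.shape[0], phi_g.shape[0]
    w = weights.values[0]
    d_cal = phantom.calibration_dose

    best = np.inf
    for bits in range(2**nI):
        z = np.array([(bits >> i) & 1 for i in range(nI)], dtype=float)
        if z.sum() > limits[0]:
            continue
        # Variables: t (nB) | u (nI) | yT | yM | yS | yG
        n_var = nB + nI + n_t + n_t + n_s + n_g
        o_u, o_yt = nB, nB + nI
        o_ym, o_ys = o_yt + n_t, o_yt + 2 * n_t
        o_yg = o_ys + n_s
        c = np.zeros(n_var)
        c[o_u : o_u + nI] = w[4] * d_t / d_cal
        c[o_yt : o_yt + n_t] = w[0] / (d_t * n_t)
        c[o_ym : o_ym + n_t] = w[1] / (2 * d_t * n_t)
        c[o_ys : o_ys + n_s] = w[2] / (d_s * n_s)
        c[o_yg : o_yg + n_g] = w[3] / (d_g * n_g)
        A_ub, b_ub = [], []
        # underdose: -phi t - yT <= -d_t
        blk = np.zeros((n_t, n_var))
        blk[:, :nB] = -phi_t
        blk[np.arange(n_t), o_yt + np.arange(n_t)] = -1.0
        A_ub.append(blk)
        b_ub.append(np.full(n_t, -d_t))
        # overdose: phi t - yM <= 2 d_t
        blk = np.zeros((n_t, n_var))
        blk[:, :nB] = phi_t
        blk[np.arange(n_t), o_ym + np.arange(n_t)] = -1.0
        A_ub.append(blk)
        b_ub.append(np.full(n_t, 2 * d_t))
        # shells
        for phi, off, n, thr in ((phi_s, o_ys, n_s, d_s), (phi_g, o_yg, n_g, d_g)):
            blk = np.zeros((n, n_var))
            blk[:, :nB] = phi
            blk[np.arange(n), off + np.arange(n)] = -1.0
            A_ub.append(blk)
            b_ub.append(np.full(n, thr))
        # sector max: sum_c t_isc - u_i <= 0
        blk = np.zeros((nI * 8, n_var))
        for i in range(nI):
            for s in range(8):
                blk[i * 8 + s, (i * 8 + s) * 3 : (i * 8 + s) * 3 + 3] = 1.0
                blk[i * 8 + s, o_u + i] = -1.0
        A_ub.append(blk)
        b_ub.append(np.zeros(nI * 8))
        # per-isocenter budget for selected isocenters: sum_sc t <= M
        blk = np.zeros((nI, n_var))
        for i in range(nI):
            blk[i, i * 24 : (i + 1) * 24] = 1.0
        A_ub.append(blk)
        b_ub.append(big_m * z)
        res = linprog(
            c,
            A_ub=np.vstack(A_ub),
            b_ub=np.concatenate(b_ub),
            bounds=[(0, None)] * n_var,
            method="highs",
        )
        assert res.status == 0
        best = min(best, res.fun)
    return best


class TestDoseOperator:
    def test_zero_times_zero_dose(self, micro_phantom, micro_kernels):
        idx = np.argwhere(micro_phantom.targets[0].mask)
        phi = gk.assemble_dose_operator(micro_kernels, idx)
        assert (phi @ np.zeros(micro_kernels.n_beams) == 0).all()
        assert (phi >= 0).all()

    def test_single_beam_scales_kernel(self, micro_phantom, micro_kernels):
        idx = np.argwhere(micro_phantom.targets[0].mask)
        phi = gk.assemble_dose_operator(micro_kernels, idx)
        t = np.zeros(micro_kernels.n_beams)
        t[5] = 2.0
        assert np.allclose(phi @ t, 2.0 * phi[:, 5], rtol=1e-12)

    def test_matches_dense_triple_loop(self, micro_phantom, micro_kernels):
        # Brute-force superposition over (isocenter, sector, collimator).
        idx = np.argwhere(micro_phantom.targets[0].mask)[:20]
        phi = gk.assemble_dose_operator(micro_kernels, idx)
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 2, size=(micro_kernels.n_isocenters, 8, 3))
        expected = np.zeros(len(idx))
        for i in range(micro_kernels.n_isocenters):
            full = gk.translate_kernel(
                micro_kernels.central,
                micro_kernels.positions_mm[i],
                micro_kernels.skull_mask,
            )
            for s in range(8):
                for c in range(3):
                    expected += t[i, s, c] * full[s, c][tuple(idx.T)]
        assert np.allclose(phi @ t.ravel(), expected, rtol=1e-9)

    def test_empty_voxel_set_rejected(self, micro_kernels):
        with pytest.raises(ValueError):
            gk.assemble_dose_operator(micro_kernels, np.empty((0, 3), dtype=int))


def _one_voxel_instance(epsilon):
    """A hand-solvable instance: one target voxel, one candidate, a single
    active beam with rate 1 Gy/min."""
    grid = gk.VoxelGrid(shape=(9, 9, 9), spacing=(2.0, 2.0, 2.0))
    center = grid.center_index
    skull = np.zeros(grid.shape, dtype=bool)
    skull[1:8, 1:8, 1:8] = True
    rates = np.zeros((8, 3) + grid.shape)
    rates[0, 0][center] = 1.0  # one beam, 1 Gy/min at the target voxel only
    central = CentralKernel(
        grid=grid, rates=rates, collimators_mm=(4.0, 8.0, 16.0),
        center_index=center, dose_rate_scale=1.0,
    )
    mask = np.zeros(grid.shape, dtype=bool)
    mask[center] = True
    shell_s = np.zeros(grid.shape, dtype=bool)
    shell_s[center[0] + 1, center[1], center[2]] = True
    shell_g = np.zeros(grid.shape, dtype=bool)
    shell_g[center[0] + 2, center[1], center[2]] = True
    target = gk.Target(
        id="T0", mask=mask, prescription_dose=18.0,
        shell_s=shell_s, shell_g=shell_g, dose_s=18.0, dose_g=9.0,
    )
    phantom = gk.Phantom(grid=grid, skull_mask=skull, targets=[target],
                         calibration_dose=18.0)
    kernels = KernelSet.from_candidates(
        central, skull, grid.voxel_to_world(np.array(center))[None, :], np.array([0])
    )
    weights = gk.ObjectiveWeights(np.array([[1.0, 0.0, 0.0, 0.0, epsilon]]))
    return gk.PlanningProblem(
        phantom=phantom, kernels=kernels, limits=[1], weights=weights, big_m=200.0
    )


class TestSolvePlanning:
    def test_time_only_weights_give_zero_plan(self, micro_phantom, micro_kernels):
        w = gk.ObjectiveWeights(np.array([[0.0, 0.0, 0.0, 0.0, 1.0]]))
        problem = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2], weights=w
        )
        sol = gk.solve_planning(problem)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sol.t, 0.0, atol=1e-9)

    def test_one_voxel_hand_solution(self):
        # Underdose vanishes at t = 18 min; the tiny time weight makes any
        # longer irradiation suboptimal, so t* = 18 and the objective is
        # epsilon * (D_T / D_cal) * 18.
        eps = 1e-4
        problem = _one_voxel_instance(eps)
        sol = gk.solve_planning(problem)
        assert sol.t.sum() == pytest.approx(18.0, rel=1e-6)
        assert sol.t[0, 0, 0] == pytest.approx(18.0, rel=1e-6)
        assert sol.objective == pytest.approx(eps * 18.0, rel=1e-6)

    def test_matches_brute_force_enumeration(self):
        phantom, kernels = build_oracle_instance(seed=101)
        w = gk.ObjectiveWeights(np.array([[0.45, 0.05, 0.25, 0.25, 0.002]]))
        problem = gk.PlanningProblem(
            phantom=phantom, kernels=kernels, limits=[2], weights=w, mip_gap=1e-6
        )
        sol = gk.solve_planning(problem)
        oracle = brute_force_optimum(phantom, kernels, [2], w, problem.big_m)
        assert sol.solver_objective == pytest.approx(oracle, rel=1e-5)

    def test_big_m_enforced_and_limits_respected(self, micro_phantom, micro_kernels,
                                                 generating_weights):
        problem = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2],
            weights=generating_weights,
        )
        sol = gk.solve_planning(problem)
        per_iso = sol.t.reshape(len(sol.z), -1).sum(axis=1)
        assert (per_iso[sol.z < 0.5] == 0).all()
        assert (per_iso <= problem.big_m + 1e-6).all()
        assert sol.z.sum() <= 2 + 1e-9

    def test_objective_monotone_in_isocenter_limit(self, micro_phantom, micro_kernels,
                                                   generating_weights):
        objectives = []
        for h in range(1, micro_kernels.n_isocenters + 1, 3):
            problem = gk.PlanningProblem(
                phantom=micro_phantom, kernels=micro_kernels, limits=[h],
                weights=generating_weights,
            )
            objectives.append(gk.solve_planning(problem).solver_objective)
        assert all(a >= b - 1e-6 for a, b in zip(objectives, objectives[1:]))

    def test_tau_recomputation_consistent(self, micro_solution, micro_problem):
        t = micro_solution.t
        expected = t.sum(axis=2).max(axis=1).sum()
        assert micro_solution.tau.sum() == pytest.approx(expected, abs=1e-9)
        # Objective recomputed from t matches the solver's value (the
        # sector-max auxiliary is tight when the time weight is positive).
        assert micro_solution.objective == pytest.approx(
            micro_solution.solver_objective, rel=1e-6
        )


class TestRelaxation:
    def test_relaxation_lower_bounds_milp(self):
        for seed in (201, 202, 203):
            phantom, kernels = build_oracle_instance(seed=seed)
            w = gk.ObjectiveWeights(np.array([[0.4, 0.05, 0.3, 0.25, 0.001]]))
            problem = gk.PlanningProblem(
                phantom=phantom, kernels=kernels, limits=[2], weights=w
            )
            relax = gk.solve_planning_relaxation(problem)
            milp = gk.solve_planning(problem)
            assert relax.solver_objective <= milp.solver_objective + 1e-6

    def test_relaxation_tight_when_limit_not_binding(self):
        phantom, kernels = build_oracle_instance(seed=204)
        w = gk.ObjectiveWeights(np.array([[0.4, 0.05, 0.3, 0.25, 0.001]]))
        problem = gk.PlanningProblem(
            phantom=phantom, kernels=kernels,
            limits=[kernels.n_isocenters], weights=w, big_m=5000.0,
        )
        relax = gk.solve_planning_relaxation(problem)
        milp = gk.solve_planning(problem)
        assert relax.solver_objective == pytest.approx(milp.solver_objective, rel=1e-5)

    def test_time_only_weights_both_zero(self, micro_phantom, micro_kernels):
        w = gk.ObjectiveWeights(np.array([[0.0, 0.0, 0.0, 0.0, 1.0]]))
        problem = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2], weights=w
        )
        assert gk.solve_planning(problem).objective == pytest.approx(0.0, abs=1e-9)
        assert gk.solve_planning_relaxation(problem).objective == pytest.approx(0.0, abs=1e-9)


class TestEvaluateObjective:
    def test_zero_times_underdose_equals_weight(self, micro_problem, generating_weights):
        total, breakdown = gk.evaluate_objective(
            np.zeros((micro_problem.n_isocenters, 8, 3)), micro_problem
        )
        assert breakdown["T0"]["underdose"] == pytest.approx(
            generating_weights.values[0, 0]
        )
        for term in ("overdose", "shell", "gradient", "bot"):
            assert breakdown["T0"][term] == 0.0
        assert total == pytest.approx(generating_weights.values[0, 0])

    def test_breakdown_sums_to_total(self, micro_solution, micro_problem):
        total, breakdown = gk.evaluate_objective(micro_solution.t, micro_problem)
        parts = sum(breakdown["T0"].values())
        assert parts == pytest.approx(total, rel=1e-12)

    def test_linear_in_weights(self, micro_phantom, micro_kernels, micro_solution,
                               generating_weights):
        doubled = gk.ObjectiveWeights(2.0 * generating_weights.values)
        p1 = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2],
            weights=generating_weights,
        )
        p2 = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2], weights=doubled
        )
        t = micro_solution.t
        assert gk.evaluate_objective(t, p2)[0] == pytest.approx(
            2.0 * gk.evaluate_objective(t, p1)[0], rel=1e-12
        )

    def test_negative_times_rejected(self, micro_problem):
        t = np.full((micro_problem.n_isocenters, 8, 3), -1.0)
        with pytest.raises(ValueError):
            gk.evaluate_objective(t, micro_problem)


class TestFixIso:
    def test_fixed_selection_respected(self, micro_phantom, micro_kernels,
                                       generating_weights):
        fixed = np.zeros(micro_kernels.n_isocenters)
        fixed[[0, 3]] = 1.0
        problem = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2],
            weights=generating_weights, mode="fix_iso", fixed_z=fixed,
        )
        sol = gk.solve_planning(problem)
        assert np.array_equal(sol.z, fixed)
        per_iso = sol.t.reshape(len(fixed), -1).sum(axis=1)
        assert (per_iso[fixed < 0.5] == 0).all()

    def test_fix_iso_never_beats_opt_iso(self, micro_phantom, micro_kernels,
                                         generating_weights):
        fixed = np.zeros(micro_kernels.n_isocenters)
        fixed[[0, 3]] = 1.0
        fix_prob = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2],
            weights=generating_weights, mode="fix_iso", fixed_z=fixed,
        )
        opt_prob = gk.PlanningProblem(
            phantom=micro_phantom, kernels=micro_kernels, limits=[2],
            weights=generating_weights,
        )
        assert (
            gk.solve_planning(opt_prob).solver_objective
            <= gk.solve_planning(fix_prob).solver_objective + 1e-6
        )
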