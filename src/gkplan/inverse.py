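"""Objective-weight estimation by inverse optimization.

Given a predicted dose, the five objective weights are estimated in two
stages. First, an inverse linear program over the dual of the planning
model's LP relaxation finds "approximate weights" minimizing the duality gap
of the prediction: the primal objective evaluated at the prediction's hinge
penalties is minimized over nonnegative weights and dual variables satisfying
the relaxation's dual feasibility, with the dual objective normalized to 1 so
that the weight scale is pinned and every admissible weight vector certifies
a unit lower bound on the achievable objective. Second, a cutting-plane
algorithm refines the weights against the integer model: it alternates
between forward-solving the planning model at the current weights (each
solution becomes a cut) and a master LP that minimizes the worst-case
sub-optimality of the prediction over all cuts. The master keeps the dual
normalization of the first stage, so the zero-cut master coincides with it
and weight vectors that trivialize the objective (all mass on a penalty
family where the prediction has no slack) remain infeasible. An optional l1
penalty (lambda = 10% of the current gap) keeps master iterates near the
incumbent, typically reducing the iteration count. On immediate infeasibility
or an exhausted time budget the pipeline falls back to the approximate
weights.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .evaluation import bot_estimate
from .kernels import N_COLLIMATORS, N_SECTORS, KernelSet
from .phantom import Phantom
from .planning import (
    ObjectiveWeights,
    PlanningProblem,
    SolverError,
    assemble_dose_operator,
    solve_planning,
    solve_planning_relaxation,
    term_values,
)


class InverseInfeasibleError(RuntimeError):
    """The inverse LP has no feasible dual; typically the instance is too
    degenerate (try more candidate isocenters or a larger isocenter limit)."""


@dataclass
class PredictionPenalties:
    """Hinge penalties of a predicted dose against the planning thresholds.

    Per target p: underdose slack on target voxels vs D_T, overdose slack vs
    2*D_T, shell slack vs D_S, gradient slack vs D_G, plus the regression
    beam-on-time estimate tau_hat (minutes).
    """

    y_t: list[np.ndarray]
    y_m: list[np.ndarray]
    y_s: list[np.ndarray]
    y_g: list[np.ndarray]
    tau_hat: np.ndarray  # (P,)

    def term_matrix(self, phantom: Phantom) -> np.ndarray:
        """Normalized penalty terms (P, 5): dot with a weight array gives the
        planning objective evaluated at the prediction."""
        P = len(phantom.targets)
        a = np.zeros((P, 5))
        for p, tgt in enumerate(phantom.targets):
            d_t = tgt.prescription_dose
            a[p, 0] = self.y_t[p].sum() / (d_t * tgt.n_t)
            a[p, 1] = self.y_m[p].sum() / (2.0 * d_t * tgt.n_t)
            a[p, 2] = self.y_s[p].sum() / (tgt.dose_s * tgt.n_s) if tgt.n_s else 0.0
            a[p, 3] = self.y_g[p].sum() / (tgt.dose_g * tgt.n_g) if tgt.n_g else 0.0
            a[p, 4] = self.tau_hat[p] * d_t / phantom.calibration_dose
        return a

    def objective_at_prediction(self, weights: ObjectiveWeights, phantom: Phantom) -> float:
        return float((weights.values * self.term_matrix(phantom)).sum())


def penalties_from_prediction(
    prediction,
    phantom: Phantom,
    limits: np.ndarray,
    tau_hat: np.ndarray | None = None,
) -> PredictionPenalties:
    """Hinge penalties of the prediction plus the beam-on-time estimate.

    ``limits`` supplies the desired isocenter count per target fed to the
    regression estimate. ``tau_hat`` overrides the regression with a known
    per-target beam-on-time (minutes) -- useful for synthetic predictions
    whose true delivery time is recorded in their provenance, isolating the
    inverse machinery from regression calibration error.
    """
    dose = np.asarray(prediction.dose if hasattr(prediction, "dose") else prediction, dtype=float)
    if dose.shape != tuple(phantom.grid.shape):
        raise ValueError(
            f"prediction grid {dose.shape} does not match phantom grid {phantom.grid.shape}"
        )
    limits = np.atleast_1d(np.asarray(limits, dtype=int))
    if tau_hat is not None:
        tau_hat = np.atleast_1d(np.asarray(tau_hat, dtype=float)).copy()
        if len(tau_hat) != len(phantom.targets):
            raise ValueError("one tau_hat per target required")
    else:
        tau_hat = np.array(
            [
                bot_estimate(t.prescription_dose, t.volume_cc(phantom.grid), int(h))
                for t, h in zip(phantom.targets, limits)
            ]
        )
    y_t, y_m, y_s, y_g = [], [], [], []
    for tgt in phantom.targets:
        d = dose[tgt.mask]
        y_t.append(np.maximum(tgt.prescription_dose - d, 0.0))
        y_m.append(np.maximum(d - 2.0 * tgt.prescription_dose, 0.0))
        y_s.append(np.maximum(dose[tgt.shell_s] - tgt.dose_s, 0.0))
        y_g.append(np.maximum(dose[tgt.shell_g] - tgt.dose_g, 0.0))
    return PredictionPenalties(y_t, y_m, y_s, y_g, tau_hat)


@dataclass
class DualSolution:
    """Approximate weights with the dual certificate they came from."""

    weights: ObjectiveWeights
    gap: float
    objective_at_prediction: float
    forward_objective: float
    duals: dict
    lp_objective: float


class _InverseMasterLP:
    """Shared LP core: formulation-(2) dual feasibility plus optional cuts.

    Variable layout: w (5P) | qT | qM | qS | qG | qBOT (nI*8) | qZ (nI) | qH
    | [alpha] | [l1 auxiliaries d (5P)].

    With no cuts and objective a.w this is the approximate-weights inverse
    LP; with cut rows w.(a - b_k) - alpha <= 0 and objective alpha (+ lambda
    * sum d) it is the cutting-plane master.
    """

    def __init__(
        self,
        kernels: KernelSet,
        phantom: Phantom,
        limits: np.ndarray,
        big_m: float,
    ):
        self.phantom = phantom
        self.kernels = kernels
        self.limits = np.atleast_1d(np.asarray(limits, dtype=int))
        self.big_m = float(big_m)
        P = len(phantom.targets)
        nI = kernels.n_isocenters
        nB = kernels.n_beams

        phi_t = [assemble_dose_operator(kernels, np.argwhere(t.mask)) for t in phantom.targets]
        phi_s = [
            kernels.rate_matrix(np.argwhere(t.shell_s)) if t.n_s else np.zeros((0, nB))
            for t in phantom.targets
        ]
        phi_g = [
            kernels.rate_matrix(np.argwhere(t.shell_g)) if t.n_g else np.zeros((0, nB))
            for t in phantom.targets
        ]
        n_t = [m.shape[0] for m in phi_t]
        n_s = [m.shape[0] for m in phi_s]
        n_g = [m.shape[0] for m in phi_g]
        self.P, self.nI, self.nB = P, nI, nB
        self.n_t, self.n_s, self.n_g = n_t, n_s, n_g

        o_qt = 5 * P
        o_qm = o_qt + sum(n_t)
        o_qs = o_qm + sum(n_t)
        o_qg = o_qs + sum(n_s)
        o_qb = o_qg + sum(n_g)
        o_qz = o_qb + nI * N_SECTORS
        o_qh = o_qz + nI
        self.offsets = dict(qt=o_qt, qm=o_qm, qs=o_qs, qg=o_qg, qb=o_qb, qz=o_qz, qh=o_qh)
        self.n_core = o_qh + 1

        tg = phantom.targets
        d_cal = phantom.calibration_dose
        rows, rhs = [], []

        # Beam feasibility rows: phi^T (qT + qM) + phi_S^T qS + phi_G^T qG
        # + qBOT_is + qZ_i <= 0, one row per beam (i, s, c).
        beam = sparse.lil_matrix((nB, self.n_core))
        for p in range(P):
            beam[:, self._sl("qt", n_t, p)] = phi_t[p].T
            beam[:, self._sl("qm", n_t, p)] = phi_t[p].T
            if n_s[p]:
                beam[:, self._sl("qs", n_s, p)] = phi_s[p].T
            if n_g[p]:
                beam[:, self._sl("qg", n_g, p)] = phi_g[p].T
        for b in range(nB):
            i = b // (N_SECTORS * N_COLLIMATORS)
            s = (b // N_COLLIMATORS) % N_SECTORS
            beam[b, o_qb + i * N_SECTORS + s] = 1.0
            beam[b, o_qz + i] = 1.0
        rows.append(beam.tocsr())
        rhs.append(np.zeros(nB))

        # Coupling qH - M qZ_i <= 0.
        coup = sparse.lil_matrix((nI, self.n_core))
        for i in range(nI):
            coup[i, o_qh] = 1.0
            coup[i, o_qz + i] = -self.big_m
        rows.append(coup.tocsr())
        rhs.append(np.zeros(nI))

        # Weight-linked dual bounds.
        def bound_rows(key, sizes, w_col, scale_fn, sign):
            """sign=+1: q - coeff*w <= 0 ; sign=-1: -q - coeff*w <= 0."""
            for p in range(P):
                m = sizes[p]
                if m == 0:
                    continue
                blk = sparse.lil_matrix((m, self.n_core))
                blk[:, self._sl(key, sizes, p)] = sign * sparse.eye(m)
                blk[:, 5 * p + w_col] = -scale_fn(p)
                rows.append(blk.tocsr())
                rhs.append(np.zeros(m))

        bound_rows("qt", n_t, 0, lambda p: 1.0 / (tg[p].prescription_dose * tg[p].n_t), 1.0)
        bound_rows("qm", n_t, 1, lambda p: 1.0 / (2.0 * tg[p].prescription_dose * tg[p].n_t), -1.0)
        bound_rows("qs", n_s, 2, lambda p: 1.0 / (tg[p].dose_s * tg[p].n_s), -1.0)
        bound_rows("qg", n_g, 3, lambda p: 1.0 / (tg[p].dose_g * tg[p].n_g), -1.0)

        # Per-isocenter BOT budget: -sum_s qBOT_is - (D_T/Dcal) w_BOT <= 0.
        bud = sparse.lil_matrix((nI, self.n_core))
        for i in range(nI):
            p = int(kernels.target_index[i])
            bud[i, o_qb + i * N_SECTORS : o_qb + (i + 1) * N_SECTORS] = -1.0
            bud[i, 5 * p + 4] = -tg[p].prescription_dose / d_cal
        rows.append(bud.tocsr())
        rhs.append(np.zeros(nI))

        self._A_ub_core = sparse.vstack(rows, format="csr")
        self._b_ub_core = np.concatenate(rhs)

        # Normalization: the dual objective equals 1.
        norm = sparse.lil_matrix((1, self.n_core))
        for p in range(P):
            norm[0, self._sl("qt", n_t, p)] = tg[p].prescription_dose
            norm[0, self._sl("qm", n_t, p)] = 2.0 * tg[p].prescription_dose
            if n_s[p]:
                norm[0, self._sl("qs", n_s, p)] = tg[p].dose_s
            if n_g[p]:
                norm[0, self._sl("qg", n_g, p)] = tg[p].dose_g
        norm[0, o_qh] = float(self.limits.sum())
        self._A_eq_core = norm.tocsr()

        self._bounds_core = (
            [(0.0, None)] * (5 * P)
            + [(0.0, None)] * sum(n_t)  # qT >= 0
            + [(None, 0.0)] * sum(n_t)  # qM <= 0
            + [(None, 0.0)] * sum(n_s)
            + [(None, 0.0)] * sum(n_g)
            + [(None, 0.0)] * (nI * N_SECTORS)
            + [(None, 0.0)] * nI
            + [(None, 0.0)]  # qH
        )

    def _sl(self, key: str, sizes: list[int], p: int) -> slice:
        start = self.offsets[key] + sum(sizes[:p])
        return slice(start, start + sizes[p])

    def solve(
        self,
        a: np.ndarray,
        cut_terms: list[np.ndarray] | None = None,
        lam: float = 0.0,
        w_ref: np.ndarray | None = None,
        time_limit_s: float | None = None,
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Solve the inverse/master LP.

        With no cuts: minimize a.w (the prediction's objective). With cuts:
        minimize alpha (+ lam * ||w - w_ref||_1) subject to
        w.(a - b_k) <= alpha for every cut. Returns (weight array (P,5),
        objective value of the LP, core solution vector).
        """
        P = self.P
        nw = 5 * P
        cuts = cut_terms or []
        with_alpha = bool(cuts)
        reg = lam > 0 and w_ref is not None
        n_var = self.n_core + (1 if with_alpha else 0) + (nw if reg else 0)
        o_alpha = self.n_core
        o_d = self.n_core + (1 if with_alpha else 0)

        def widen(mat):
            return sparse.hstack(
                [mat, sparse.csr_matrix((mat.shape[0], n_var - self.n_core))], format="csr"
            )

        A_ub = [widen(self._A_ub_core)]
        b_ub = [self._b_ub_core]
        for b_k in cuts:
            row = sparse.lil_matrix((1, n_var))
            row[0, :nw] = (a - b_k).ravel()
            row[0, o_alpha] = -1.0
            A_ub.append(row.tocsr())
            b_ub.append(np.zeros(1))
        if reg:
            w_ref_flat = np.asarray(w_ref).ravel()
            for j in range(nw):
                row = sparse.lil_matrix((1, n_var))
                row[0, j] = 1.0
                row[0, o_d + j] = -1.0
                A_ub.append(row.tocsr())
                b_ub.append(np.array([w_ref_flat[j]]))
                row = sparse.lil_matrix((1, n_var))
                row[0, j] = -1.0
                row[0, o_d + j] = -1.0
                A_ub.append(row.tocsr())
                b_ub.append(np.array([-w_ref_flat[j]]))

        c = np.zeros(n_var)
        if with_alpha:
            c[o_alpha] = 1.0
            if reg:
                c[o_d:] = lam
        else:
            c[:nw] = a.ravel()

        bounds = list(self._bounds_core)
        if with_alpha:
            # The prediction is assumed feasible, so its true sub-optimality
            # is >= 0; cuts only under-estimate it. Clamping alpha at 0 also
            # keeps the master bounded along weight directions where the
            # prediction has no slack.
            bounds.append((0.0, None))
        if reg:
            bounds += [(0.0, None)] * nw

        options = {"time_limit": time_limit_s} if time_limit_s else None
        res = linprog(
            c,
            A_ub=sparse.vstack(A_ub, format="csr"),
            b_ub=np.concatenate(b_ub),
            A_eq=widen(self._A_eq_core),
            b_eq=np.array([1.0]),
            bounds=bounds,
            method="highs",
            options=options,
        )
        if res.status != 0 or res.x is None:
            raise InverseInfeasibleError(
                f"inverse LP failed (status {res.status}: {res.message}); "
                "consider more candidate isocenters or a larger isocenter limit"
            )
        w = res.x[:nw].reshape(P, 5)
        # Report alpha itself when cuts are present (res.fun would include
        # the regularization term).
        value = float(res.x[o_alpha]) if with_alpha else float(res.fun)
        return w, value, res.x[: self.n_core]

    def extract_duals(self, x: np.ndarray) -> dict:
        o = self.offsets
        return {
            "q_t": [x[self._sl("qt", self.n_t, p)].copy() for p in range(self.P)],
            "q_m": [x[self._sl("qm", self.n_t, p)].copy() for p in range(self.P)],
            "q_s": [x[self._sl("qs", self.n_s, p)].copy() for p in range(self.P)],
            "q_g": [x[self._sl("qg", self.n_g, p)].copy() for p in range(self.P)],
            "q_bot": x[o["qb"] : o["qz"]].reshape(self.nI, N_SECTORS).copy(),
            "q_z": x[o["qz"] : o["qh"]].copy(),
            "q_h": float(x[o["qh"]]),
        }


def _default_big_m(phantom, kernels, limits) -> float:
    return PlanningProblem(
        phantom=phantom,
        kernels=kernels,
        limits=limits,
        weights=ObjectiveWeights.uniform(len(phantom.targets)),
    ).big_m


def solve_relaxed_inverse(
    penalties: PredictionPenalties,
    kernels: KernelSet,
    phantom: Phantom,
    limits: np.ndarray,
    big_m: float | None = None,
) -> DualSolution:
    """Approximate weights from the inverse of the LP relaxation.

    Minimizes the planning objective evaluated at the prediction penalties
    over nonnegative weights and dual variables satisfying the relaxation's
    dual feasibility, with the dual objective normalized to one. The reported
    gap is (objective at prediction - best achievable under the recovered
    weights) / max(best achievable, 1e-9), the best achievable value coming
    from a forward solve of the relaxation.
    """
    limits = np.atleast_1d(np.asarray(limits, dtype=int))
    if big_m is None:
        big_m = _default_big_m(phantom, kernels, limits)
    lp = _InverseMasterLP(kernels, phantom, limits, big_m)
    a = penalties.term_matrix(phantom)
    w_arr, obj_pred, x = lp.solve(a)
    w = ObjectiveWeights(w_arr)
    forward = solve_planning_relaxation(
        PlanningProblem(phantom=phantom, kernels=kernels, limits=limits, weights=w, big_m=big_m)
    )
    f_star = forward.objective
    gap = (obj_pred - f_star) / max(f_star, 1e-9)
    return DualSolution(
        weights=w,
        gap=float(gap),
        objective_at_prediction=float(obj_pred),
        forward_objective=float(f_star),
        duals=lp.extract_duals(x),
        lp_objective=float(obj_pred),
    )


# ---------------------------------------------------------------------------
# Cutting plane
# ---------------------------------------------------------------------------


@dataclass
class CutSet:
    """Audit trail of the cutting-plane run."""

    cuts: list = field(default_factory=list)  # per-iteration records
    gap_history: list = field(default_factory=list)  # incumbent relative gap
    fallback: bool = False
    reason: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.cuts)


def cutting_plane(
    penalties: PredictionPenalties,
    problem_template: PlanningProblem,
    initial_weights: ObjectiveWeights,
    regularized: bool = False,
    max_time_s: float = 3600.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    forward_time_budget_s: float = 120.0,
    master_time_budget_s: float = 60.0,
    patience: int = 2,
) -> tuple[ObjectiveWeights, CutSet]:
    """Refine approximate weights against the integer planning model.

    Each iteration forward-solves the planning model at the current weights
    (the MILP when it fits the per-iteration budget, else its LP relaxation),
    records the solution as a cut, and re-optimizes the weights with the
    master LP (dual-normalized, so the zero-cut master equals the
    approximate-weights LP). Terminates when the newest forward solution no
    longer violates the master bound, when the incumbent gap stops improving
    by ``tol`` for ``patience`` consecutive iterations, at ``max_iter``, or
    on timeout -- in which case the initial approximate weights are
    returned, flagged as the fallback.
    """
    start = time.monotonic()
    phantom = problem_template.phantom
    a = penalties.term_matrix(phantom)
    cutset = CutSet()

    def fallback(reason: str) -> tuple[ObjectiveWeights, CutSet]:
        cutset.fallback = True
        cutset.reason = reason
        return initial_weights, cutset

    if max_time_s <= 0:
        return fallback("zero time budget")
    try:
        master = _InverseMasterLP(
            problem_template.kernels, phantom, problem_template.limits, problem_template.big_m
        )
    except InverseInfeasibleError as exc:
        return fallback(f"master infeasible: {exc}")

    w = initial_weights
    cut_terms: list[np.ndarray] = []
    best_rel = np.inf
    best_abs = np.inf
    w_best = w
    alpha_prev = -np.inf
    stalled = 0

    for it in range(max_iter):
        problem = replace(
            problem_template,
            weights=w,
            mode="opt_iso",
            fixed_z=None,
            time_limit_s=forward_time_budget_s,
        )
        problem._ops = problem_template.ops  # reuse cached rate matrices
        used_relaxation = False
        try:
            sol = solve_planning(problem)
            if sol.status != "optimal":
                sol = solve_planning_relaxation(problem)
                used_relaxation = True
        except SolverError as exc:
            if it == 0:
                return fallback(f"forward model failed at initial weights: {exc}")
            cutset.reason = f"forward solver failure: {exc}"
            break
        b_k = term_values(sol.t, problem)
        f_fwd = float((w.values * b_k).sum())
        f_pred = float((w.values * a).sum())
        abs_gap = f_pred - f_fwd
        rel_gap = abs_gap / max(f_fwd, 1e-9)
        cut_terms.append(b_k)
        cutset.cuts.append(
            {
                "iteration": it,
                "weights": w.values.tolist(),
                "forward_objective": f_fwd,
                "objective_at_prediction": f_pred,
                "abs_gap": abs_gap,
                "rel_gap": rel_gap,
                "used_relaxation": used_relaxation,
            }
        )
        improved = rel_gap < best_rel - tol
        if rel_gap < best_rel:
            best_rel, best_abs, w_best = rel_gap, abs_gap, w
        cutset.gap_history.append(best_rel)

        if it >= 1 and abs_gap <= alpha_prev + tol:
            cutset.reason = "no violated cut"
            break
        stalled = 0 if improved else stalled + 1
        if it >= 1 and stalled >= patience:
            cutset.reason = "gap improvement below tolerance"
            break
        if time.monotonic() - start > max_time_s:
            return fallback("time budget exceeded")

        lam = 0.1 * max(best_abs, 0.0) if regularized else 0.0
        try:
            w_arr, alpha, _ = master.solve(
                a,
                cut_terms=cut_terms,
                lam=lam,
                w_ref=w_best.values if regularized else None,
                time_limit_s=master_time_budget_s,
            )
            w = ObjectiveWeights(w_arr)
        except (InverseInfeasibleError, ValueError) as exc:
            cutset.reason = f"master failure: {exc}"
            break
        alpha_prev = alpha
    else:
        cutset.reason = "iteration cap reached"

    return w_best, cutset
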