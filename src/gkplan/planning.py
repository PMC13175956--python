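"""Mixed-integer inverse planning: isocenter selection + beam-on-time optimization.

The model minimizes, over beam-on-times t_isc >= 0 and binary isocenter
indicators z_i, a weighted sum of five normalized penalty terms per target p:

* target underdose below the prescription D_T, weight w_Tmin, normalized by D_T*N_T;
* target overdose above 2*D_T, weight w_Tmax, normalized by 2*D_T*N_T;
* overdose above D_S on the selectivity shell, weight w_S, normalized by D_S*N_S;
* dose above D_G on the gradient shell, weight w_G, normalized by D_G*N_G;
* beam-on-time tau_p = sum_i max_s sum_c t_isc, weight w_BOT, scaled by D_T/D_cal.

Dose is linear in t through the rate kernels: f_r(t) = sum_isc phi_risc t_isc.
Constraints: at most H_p isocenters per target (sum z_i <= H_p) and the big-M
coupling sum_sc t_isc <= M z_i, aggregated per isocenter so that the model is
the exact primal of the inverse-optimization dual used for weight estimation.
Hinge terms are linearized with nonnegative slack variables, and the
per-isocenter max over sectors with one auxiliary u_i >= sum_c t_isc for
every sector. Solved with HiGHS via scipy.optimize.milp; the
LP relaxation (z in [0,1]) and a fixed-isocenter mode (z pinned to a given
selection) reuse the same matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .kernels import N_COLLIMATORS, N_SECTORS, KernelSet
from .phantom import Phantom

TERM_NAMES = ("underdose", "overdose", "shell", "gradient", "bot")


class SolverError(RuntimeError):
    """Unexpected solver failure (the model is feasible by construction at t = 0)."""


@dataclass
class ObjectiveWeights:
    """Per-target weights (w_Tmin, w_Tmax, w_S, w_G, w_BOT), all nonnegative."""

    values: np.ndarray  # (P, 5), columns ordered as TERM_NAMES

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 5:
            raise ValueError("weights need 5 columns per target")
        if (self.values < 0).any():
            raise ValueError("weights must be nonnegative")
        if not (self.values > 0).any():
            raise ValueError("at least one weight must be positive")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @classmethod
    def uniform(cls, n_targets: int = 1) -> "ObjectiveWeights":
        return cls(np.full((n_targets, 5), 0.2))

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_targets: int) -> "ObjectiveWeights":
        return cls(np.asarray(vec, dtype=float).reshape(n_targets, 5))

    def as_vector(self) -> np.ndarray:
        return self.values.ravel().copy()

    def normalized(self) -> "ObjectiveWeights":
        """Rescaled onto the simplex (all components sum to 1)."""
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize all-zero weights")
        return ObjectiveWeights(self.values / total)

    def to_dict(self) -> dict:
        return {
            "w_tmin": self.values[:, 0].tolist(),
            "w_tmax": self.values[:, 1].tolist(),
            "w_s": self.values[:, 2].tolist(),
            "w_g": self.values[:, 3].tolist(),
            "w_bot": self.values[:, 4].tolist(),
        }


def assemble_dose_operator(kernels: KernelSet, voxel_idx: np.ndarray) -> np.ndarray:
    """Rate matrix restricted to the given optimization voxels.

    Returns the (n_voxels, n_beams) matrix Phi with f = Phi @ t_flat; linear
    and nonnegative for t >= 0.
    """
    voxel_idx = np.asarray(voxel_idx, dtype=int)
    if voxel_idx.size == 0:
        raise ValueError("voxel set must be nonempty")
    return kernels.rate_matrix(voxel_idx)


@dataclass
class PlanningProblem:
    """A planning instance: phantom + kernels + limits + weights.

    ``limits`` is the maximum isocenter count H_p per target. ``big_m`` is the
    indicator bound in minutes (a value exceeding any sensible single-beam
    time); if None a default of twice the regression beam-on-time estimate,
    floored at 30 min, is used. ``mode`` is ``"opt_iso"`` (select isocenters)
    or ``"fix_iso"`` (z pinned to ``fixed_z``).
    """

    phantom: Phantom
    kernels: KernelSet
    limits: np.ndarray
    weights: ObjectiveWeights
    big_m: Optional[float] = None
    mode: str = "opt_iso"
    fixed_z: Optional[np.ndarray] = None
    mip_gap: float = 1e-4
    time_limit_s: float = 600.0

    def __post_init__(self) -> None:
        self.limits = np.atleast_1d(np.asarray(self.limits, dtype=int))
        P = len(self.phantom.targets)
        if len(self.limits) != P:
            raise ValueError("one isocenter limit per target required")
        if (self.limits < 1).any():
            raise ValueError("isocenter limits must be >= 1")
        if self.weights.n_targets != P:
            raise ValueError("one weight row per target required")
        if self.mode not in ("opt_iso", "fix_iso"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fix_iso":
            if self.fixed_z is None:
                raise ValueError("fix_iso mode requires fixed_z")
            self.fixed_z = np.asarray(self.fixed_z, dtype=float).round()
        if self.big_m is None:
            self.big_m = default_big_m(self.phantom, self.limits)
        if self.big_m <= 0:
            raise ValueError("big_m must be positive")
        self._ops: Optional[dict] = None

    # -- cached per-target geometry and rate matrices ----------------------
    @property
    def ops(self) -> dict:
        if self._ops is None:
            regions: dict[str, list] = {"t": [], "s": [], "g": []}
            for tgt in self.phantom.targets:
                for key, mask in (("t", tgt.mask), ("s", tgt.shell_s), ("g", tgt.shell_g)):
                    idx = np.argwhere(mask)
                    regions[key].append(
                        {
                            "idx": idx,
                            "phi": assemble_dose_operator(self.kernels, idx)
                            if len(idx)
                            else np.zeros((0, self.kernels.n_beams)),
                        }
                    )
            self._ops = regions
        return self._ops

    @property
    def n_isocenters(self) -> int:
        return self.kernels.n_isocenters

    @property
    def n_beams(self) -> int:
        return self.kernels.n_beams


def default_big_m(phantom: Phantom, limits: np.ndarray) -> float:
    """Instance-scaled big-M for the aggregated per-isocenter coupling.

    M bounds the summed beam-on-time over all 8 sectors x 3 collimators of
    one isocenter. A uniform 8-sector delivery of duration T contributes 8*T
    to that sum, so M is 8 sectors x twice the regression beam-on-time
    estimate for the largest target, floored at 8 x 30 minutes.
    """
    from .evaluation import bot_estimate
    from .kernels import N_SECTORS

    est = max(
        bot_estimate(t.prescription_dose, t.volume_cc(phantom.grid), int(h))
        for t, h in zip(phantom.targets, limits)
    )
    return N_SECTORS * max(30.0, 2.0 * est)


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def _build_model(problem: PlanningProblem, z_mode: str):
    """Assemble (c, LinearConstraint, Bounds, integrality, slices)."""
    phantom = problem.phantom
    P = len(phantom.targets)
    nI = problem.n_isocenters
    nB = problem.n_beams
    ops = problem.ops
    n_t = [len(r["idx"]) for r in ops["t"]]
    n_s = [len(r["idx"]) for r in ops["s"]]
    n_g = [len(r["idx"]) for r in ops["g"]]

    # Variable layout: t | u | yT | yM | yS | yG | z
    o_u = nB
    o_yt = o_u + nI
    o_ym = o_yt + sum(n_t)
    o_ys = o_ym + sum(n_t)
    o_yg = o_ys + sum(n_s)
    o_z = o_yg + sum(n_g)
    n_var = o_z + nI

    W = problem.weights.values
    d_cal = phantom.calibration_dose
    tgt_of_iso = problem.kernels.target_index

    c = np.zeros(n_var)
    for i in range(nI):
        p = tgt_of_iso[i]
        c[o_u + i] = W[p, 4] * phantom.targets[p].prescription_dose / d_cal
    # Slack costs: each hinge family normalized by its threshold and voxel count.
    pos_t, pos_m, pos_s, pos_g = o_yt, o_ym, o_ys, o_yg
    for p, tgt in enumerate(phantom.targets):
        d_t = tgt.prescription_dose
        c[pos_t : pos_t + n_t[p]] = W[p, 0] / (d_t * tgt.n_t)
        pos_t += n_t[p]
        c[pos_m : pos_m + n_t[p]] = W[p, 1] / (2.0 * d_t * tgt.n_t)
        pos_m += n_t[p]
        if n_s[p]:
            c[pos_s : pos_s + n_s[p]] = W[p, 2] / (tgt.dose_s * tgt.n_s)
            pos_s += n_s[p]
        if n_g[p]:
            c[pos_g : pos_g + n_g[p]] = W[p, 3] / (tgt.dose_g * tgt.n_g)
            pos_g += n_g[p]

    rows_A, rows_lb, rows_ub = [], [], []

    # Underdose: Phi_T t + yT >= D_T
    pos = o_yt
    for p, rec in enumerate(ops["t"]):
        m = len(rec["idx"])
        tgt = phantom.targets[p]
        A = sparse.hstack(
            [
                sparse.csr_matrix(rec["phi"]),
                sparse.csr_matrix((m, pos - nB)),
                sparse.eye(m, format="csr"),
                sparse.csr_matrix((m, n_var - pos - m)),
            ],
            format="csr",
        )
        rows_A.append(A)
        rows_lb.append(np.full(m, tgt.prescription_dose))
        rows_ub.append(np.full(m, np.inf))
        pos += m
    # Overdose: Phi_T t - yM <= 2 D_T
    pos = o_ym
    for p, rec in enumerate(ops["t"]):
        m = len(rec["idx"])
        tgt = phantom.targets[p]
        A = sparse.hstack(
            [
                sparse.csr_matrix(rec["phi"]),
                sparse.csr_matrix((m, pos - nB)),
                -sparse.eye(m, format="csr"),
                sparse.csr_matrix((m, n_var - pos - m)),
            ],
            format="csr",
        )
        rows_A.append(A)
        rows_lb.append(np.full(m, -np.inf))
        rows_ub.append(np.full(m, 2.0 * tgt.prescription_dose))
        pos += m
    # Shells: Phi t - y <= threshold
    for region, offset, thr_attr in (("s", o_ys, "dose_s"), ("g", o_yg, "dose_g")):
        pos = offset
        for p, rec in enumerate(ops[region]):
            m = len(rec["idx"])
            if m == 0:
                continue
            tgt = phantom.targets[p]
            A = sparse.hstack(
                [
                    sparse.csr_matrix(rec["phi"]),
                    sparse.csr_matrix((m, pos - nB)),
                    -sparse.eye(m, format="csr"),
                    sparse.csr_matrix((m, n_var - pos - m)),
                ],
                format="csr",
            )
            rows_A.append(A)
            rows_lb.append(np.full(m, -np.inf))
            rows_ub.append(np.full(m, getattr(tgt, thr_attr)))
            pos += m

    # u_i >= sum_c t_isc for every sector: sum_c t - u <= 0
    data, ri, ci = [], [], []
    for i in range(nI):
        for s in range(N_SECTORS):
            r = i * N_SECTORS + s
            for cc in range(N_COLLIMATORS):
                ri.append(r)
                ci.append((i * N_SECTORS + s) * N_COLLIMATORS + cc)
                data.append(1.0)
            ri.append(r)
            ci.append(o_u + i)
            data.append(-1.0)
    A_u = sparse.csr_matrix((data, (ri, ci)), shape=(nI * N_SECTORS, n_var))
    rows_A.append(A_u)
    rows_lb.append(np.full(nI * N_SECTORS, -np.inf))
    rows_ub.append(np.zeros(nI * N_SECTORS))

    # Big-M, aggregated per isocenter: sum_sc t_isc - M z_i <= 0.
    # The per-isocenter form (rather than one row per beam) is the exact
    # primal counterpart of the inverse model's single q_Z dual per isocenter.
    data, ri, ci = [], [], []
    for b in range(nB):
        i = b // (N_SECTORS * N_COLLIMATORS)
        ri.append(i)
        ci.append(b)
        data.append(1.0)
    for i in range(nI):
        ri.append(i)
        ci.append(o_z + i)
        data.append(-problem.big_m)
    A_m = sparse.csr_matrix((data, (ri, ci)), shape=(nI, n_var))
    rows_A.append(A_m)
    rows_lb.append(np.full(nI, -np.inf))
    rows_ub.append(np.zeros(nI))

    # Isocenter limits: sum_{i in p} z_i <= H_p
    data, ri, ci = [], [], []
    for p in range(P):
        for i in np.flatnonzero(tgt_of_iso == p):
            ri.append(p)
            ci.append(o_z + int(i))
            data.append(1.0)
    A_h = sparse.csr_matrix((data, (ri, ci)), shape=(P, n_var))
    rows_A.append(A_h)
    rows_lb.append(np.full(P, -np.inf))
    rows_ub.append(problem.limits.astype(float))

    A = sparse.vstack(rows_A, format="csr")
    con = LinearConstraint(A, np.concatenate(rows_lb), np.concatenate(rows_ub))

    lb = np.zeros(n_var)
    ub = np.full(n_var, np.inf)
    ub[:nB] = problem.big_m  # redundant with big-M rows but tightens the LP
    ub[o_z:] = 1.0
    integrality = np.zeros(n_var)
    if z_mode == "binary":
        integrality[o_z:] = 1
    elif z_mode == "fixed":
        lb[o_z:] = problem.fixed_z
        ub[o_z:] = problem.fixed_z
    elif z_mode != "continuous":
        raise ValueError(z_mode)

    slices = {"t": slice(0, nB), "u": slice(o_u, o_yt), "z": slice(o_z, n_var)}
    return c, con, Bounds(lb, ub), integrality, slices


@dataclass
class BeamSolution:
    """A solved plan: beam-on-times, selected isocenters, per-target times."""

    t: np.ndarray  # (nI, 8, 3) minutes
    z: np.ndarray  # (nI,) binary (fractional for the relaxation)
    tau: np.ndarray  # (P,) minutes
    objective: float  # recomputed from t (independent evaluation)
    breakdown: dict
    solver_objective: float
    status: str
    mip_gap: Optional[float]
    mode: str

    @property
    def n_selected(self) -> int:
        """Isocenters actually used (positive beam time)."""
        return int((self.t.reshape(len(self.z), -1).sum(axis=1) > 1e-9).sum())

    def to_dict(self) -> dict:
        nz = np.argwhere(self.t > 1e-12)
        return {
            "t_sparse": [
                [int(i), int(s), int(c), float(self.t[i, s, c])] for i, s, c in nz
            ],
            "shape": list(self.t.shape),
            "z": self.z.tolist(),
            "tau_min": self.tau.tolist(),
            "objective": self.objective,
            "breakdown": self.breakdown,
            "status": self.status,
            "mip_gap": self.mip_gap,
            "mode": self.mode,
        }


def recompute_tau(t: np.ndarray, kernels: KernelSet, n_targets: int) -> np.ndarray:
    """tau_p = sum over the target's isocenters of max_s sum_c t_isc."""
    per_iso = t.sum(axis=2).max(axis=1)  # (nI,)
    return np.array(
        [per_iso[kernels.candidates_of_target(p)].sum() for p in range(n_targets)]
    )


def term_values(t: np.ndarray, problem: PlanningProblem) -> np.ndarray:
    """Unweighted normalized objective terms, shape (P, 5).

    Columns follow TERM_NAMES; multiplying elementwise by the weight array and
    summing gives the objective. Linear in the weights by construction.
    """
    t = np.asarray(t, dtype=float).reshape(problem.n_isocenters, N_SECTORS, N_COLLIMATORS)
    t_flat = t.ravel()
    phantom = problem.phantom
    P = len(phantom.targets)
    tau = recompute_tau(t, problem.kernels, P)
    tv = np.zeros((P, 5))
    for p, tgt in enumerate(phantom.targets):
        d_t = tgt.prescription_dose
        f_t = problem.ops["t"][p]["phi"] @ t_flat
        tv[p, 0] = np.maximum(d_t - f_t, 0.0).sum() / (d_t * tgt.n_t)
        tv[p, 1] = np.maximum(f_t - 2.0 * d_t, 0.0).sum() / (2.0 * d_t * tgt.n_t)
        if tgt.n_s:
            f_s = problem.ops["s"][p]["phi"] @ t_flat
            tv[p, 2] = np.maximum(f_s - tgt.dose_s, 0.0).sum() / (tgt.dose_s * tgt.n_s)
        if tgt.n_g:
            f_g = problem.ops["g"][p]["phi"] @ t_flat
            tv[p, 3] = np.maximum(f_g - tgt.dose_g, 0.0).sum() / (tgt.dose_g * tgt.n_g)
        tv[p, 4] = tau[p] * d_t / phantom.calibration_dose
    return tv


def evaluate_objective(
    t: np.ndarray, problem: PlanningProblem, z: np.ndarray | None = None
) -> tuple[float, dict]:
    """Recompute the five-term objective from rendered dose by direct summation.

    Independent of the solver: hinges are evaluated voxel by voxel on
    Phi @ t. Returns (total, breakdown); breakdown carries the weighted
    contribution of each term per target.
    """
    t = np.asarray(t, dtype=float)
    if (t < -1e-9).any():
        raise ValueError("beam-on-times must be nonnegative")
    tv = term_values(t, problem)
    W = problem.weights.values
    contrib = W * tv
    breakdown = {
        tgt.id: {name: float(contrib[p, k]) for k, name in enumerate(TERM_NAMES)}
        for p, tgt in enumerate(problem.phantom.targets)
    }
    total = float(contrib.sum())
    breakdown["total"] = total
    return total, breakdown


def _solve(problem: PlanningProblem, z_mode: str) -> BeamSolution:
    c, con, bounds, integrality, slices = _build_model(problem, z_mode)
    options = {
        "mip_rel_gap": problem.mip_gap,
        "time_limit": problem.time_limit_s,
        "presolve": True,
    }
    res = milp(c, constraints=[con], bounds=bounds, integrality=integrality, options=options)
    if res.x is None:
        raise SolverError(f"planning model returned no solution (status {res.status}: {res.message})")
    x = res.x
    nI = problem.n_isocenters
    t = np.maximum(x[slices["t"]], 0.0).reshape(nI, N_SECTORS, N_COLLIMATORS)
    z = x[slices["z"]].copy()
    if z_mode in ("binary", "fixed"):
        z = (z > 0.5).astype(float)
        t[z < 0.5] = 0.0  # solver tolerance cleanup; big-M already forces this
    tau = recompute_tau(t, problem.kernels, len(problem.phantom.targets))
    total, breakdown = evaluate_objective(t, problem)
    status = {0: "optimal", 1: "limit_reached"}.get(res.status, f"status_{res.status}")
    return BeamSolution(
        t=t,
        z=z,
        tau=tau,
        objective=total,
        breakdown=breakdown,
        solver_objective=float(res.fun),
        status=status,
        mip_gap=float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else None,
        mode=problem.mode,
    )


def solve_planning(problem: PlanningProblem) -> BeamSolution:
    """Solve the mixed-integer planning model (or the fixed-z LP in fix_iso mode)."""
    return _solve(problem, "fixed" if problem.mode == "fix_iso" else "binary")


def solve_planning_relaxation(problem: PlanningProblem) -> BeamSolution:
    """Solve the LP relaxation (z in [0, 1]); its optimum lower-bounds the MILP."""
    return _solve(problem, "continuous")
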