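"""Plan-quality evaluation, time accounting, shot decomposition and the
isocenter-limit experiment harness.

Voxel-based metrics: with TV the target volume, PIV the prescription isodose
volume and TV_PIV their intersection, coverage = TV_PIV/TV, selectivity =
TV_PIV/PIV, Paddick conformity = TV_PIV^2/(TV*PIV) (= coverage x
selectivity), and gradient index = PIV_half/PIV where PIV_half is the
half-prescription isodose volume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Optional

import numpy as np
import pandas as pd

from .kernels import N_COLLIMATORS, N_SECTORS
from .phantom import Target

if TYPE_CHECKING:  # pragma: no cover
    from .planning import BeamSolution


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------


@dataclass
class QualityMetrics:
    """Voxel-based indices for one target; ``piv_empty`` flags an undefined
    gradient/selectivity (no voxel reached the prescription)."""

    target_id: str
    coverage: float
    selectivity: float
    paddick_ci: float
    gradient_index: float
    tv: int
    piv: int
    tv_piv: int
    piv_half: int
    piv_empty: bool = False


def quality_metrics(dose: np.ndarray, target: Target, prescription: float | None = None) -> QualityMetrics:
    """Compute coverage, selectivity, Paddick conformity and gradient index.

    PIV is taken over the whole dose volume. When PIV is empty the
    selectivity/gradient are undefined: they are returned as 0 and NaN with
    ``piv_empty`` set, never silently zeroed elsewhere.
    """
    if (np.asarray(dose) < 0).any():
        raise EvaluationError("dose must be nonnegative")
    d_t = float(prescription if prescription is not None else target.prescription_dose)
    tv_mask = target.mask
    tv = int(tv_mask.sum())
    if tv == 0:
        raise EvaluationError(f"target {target.id!r} is empty")
    piv_mask = dose >= d_t
    piv = int(piv_mask.sum())
    tv_piv = int((tv_mask & piv_mask).sum())
    piv_half = int((dose >= d_t / 2.0).sum())
    coverage = tv_piv / tv
    if piv == 0:
        return QualityMetrics(target.id, coverage, 0.0, 0.0, float("nan"),
                              tv, piv, tv_piv, piv_half, piv_empty=True)
    selectivity = tv_piv / piv
    paddick = tv_piv**2 / (tv * piv)
    gradient = piv_half / piv
    return QualityMetrics(target.id, coverage, selectivity, paddick, gradient,
                          tv, piv, tv_piv, piv_half)


@dataclass
class QualityReport:
    """Per-target metrics plus plan-level time accounting."""

    metrics: list[QualityMetrics]
    treatment_time_min: float
    adjusted_time_min: float
    isocenter_count: int

    @property
    def mean_conformity(self) -> float:
        return float(np.mean([m.paddick_ci for m in self.metrics]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target_id": m.target_id,
                "coverage": m.coverage,
                "selectivity": m.selectivity,
                "paddick_ci": m.paddick_ci,
                "gradient_index": m.gradient_index,
                "piv_empty": m.piv_empty,
            }
            for m in self.metrics
        ]
        rows.append(
            {
                "target_id": "__plan__",
                "coverage": np.nan,
                "selectivity": np.nan,
                "paddick_ci": self.mean_conformity,
                "gradient_index": np.nan,
                "piv_empty": False,
                "treatment_time_min": self.treatment_time_min,
                "adjusted_time_min": self.adjusted_time_min,
                "isocenter_count": self.isocenter_count,
            }
        )
        return pd.DataFrame(rows)


def treatment_time(solution: "BeamSolution", transition_delay_s: float = 8.0) -> tuple[float, float]:
    """Beam-on treatment time and the adjusted time including a per-isocenter
    transition delay (8 s by default).

    adjusted = sum_p tau_p + n_isocenters * delay/60, counting only isocenters
    that actually deliver beam time.
    """
    total = float(np.sum(solution.tau))
    n_iso = solution.n_selected
    return total, total + n_iso * transition_delay_s / 60.0


# ---------------------------------------------------------------------------
# Clinical regressions
# ---------------------------------------------------------------------------

#: Linear beam-on-time regression coefficients (prescription Gy, volume cc,
#: isocenter count, intercept), minutes.
BOT_COEFFS = (-0.3663, -9.595, 3.438, 14.94)

#: Cubic isocenter-limit predictor coefficients
#: (D_T^3, D_T^2, D_T, V, intercept).
IPRED_COEFFS = (0.0024, -0.0843, -0.0052, 0.0009, 17.354)


def bot_estimate(prescription: float, volume_cc: float, n_isocenters: int) -> float:
    """Regression estimate of the beam-on-time (minutes) needed to realize a
    dose prediction, floored at 0.1 min (the fit can go negative for large
    targets at low isocenter counts)."""
    if prescription <= 0 or volume_cc <= 0 or n_isocenters < 1:
        raise EvaluationError("prescription, volume and isocenter count must be positive")
    a, b, c, d = BOT_COEFFS
    return max(0.1, a * prescription + b * volume_cc + c * n_isocenters + d)


def predict_isocenter_limit(prescription: float, volume_cc: float) -> int:
    """Predicted maximum isocenter count from prescription and target volume
    (cubic in the prescription, rounded to the nearest integer, at least 1)."""
    if prescription <= 0 or volume_cc <= 0:
        raise EvaluationError("prescription and volume must be positive")
    a3, a2, a1, av, a0 = IPRED_COEFFS
    raw = a3 * prescription**3 + a2 * prescription**2 + a1 * prescription + av * volume_cc + a0
    return max(1, int(round(raw)))


# ---------------------------------------------------------------------------
# Shot decomposition
# ---------------------------------------------------------------------------


@dataclass
class Shot:
    """One delivery: a single isocenter, one collimator state per sector
    (aperture in mm or 'blocked'), one duration."""

    isocenter: int
    sector_states: tuple  # length 8, entries in {4.0, 8.0, 16.0, "blocked"}
    duration_min: float


@dataclass
class ShotList:
    shots: list[Shot]

    def reconstruct(self, n_isocenters: int, collimators_mm: tuple[float, ...]) -> np.ndarray:
        """Sum the shots back into a beam-on-time tensor (nI, 8, 3)."""
        t = np.zeros((n_isocenters, N_SECTORS, N_COLLIMATORS))
        cmap = {c: k for k, c in enumerate(collimators_mm)}
        for shot in self.shots:
            for s, state in enumerate(shot.sector_states):
                if state != "blocked":
                    t[shot.isocenter, s, cmap[state]] += shot.duration_min
        return t

    def to_dict(self) -> dict:
        return {
            "shots": [
                {
                    "isocenter": s.isocenter,
                    "sector_states": list(s.sector_states),
                    "duration_min": s.duration_min,
                }
                for s in self.shots
            ]
        }


def decompose_shots(
    solution: "BeamSolution",
    collimators_mm: tuple[float, ...] = (4.0, 8.0, 16.0),
    tol: float = 1e-9,
) -> ShotList:
    """Greedy exact decomposition of beam-on-times into deliverable shots.

    Per isocenter, each pass assigns every sector its largest-residual
    collimator (blocked when the sector is exhausted) and fires for the
    smallest positive assigned residual; residuals shrink until zero. The
    summed shot durations reproduce t exactly.
    """
    shots: list[Shot] = []
    t = np.asarray(solution.t, dtype=float)
    for i in range(t.shape[0]):
        residual = t[i].copy()
        while residual.max() > tol:
            states: list = []
            chosen: list[Optional[int]] = []
            for s in range(N_SECTORS):
                if residual[s].max() > tol:
                    c = int(np.argmax(residual[s]))
                    states.append(collimators_mm[c])
                    chosen.append(c)
                else:
                    states.append("blocked")
                    chosen.append(None)
            duration = min(
                residual[s, c] for s, c in enumerate(chosen) if c is not None
            )
            for s, c in enumerate(chosen):
                if c is not None:
                    residual[s, c] -= duration
            residual[residual < tol] = 0.0
            shots.append(Shot(isocenter=i, sector_states=tuple(states), duration_min=float(duration)))
    return ShotList(shots)


# ---------------------------------------------------------------------------
# Limit sweep and best-plan selection
# ---------------------------------------------------------------------------

#: Fractions of the reference isocenter count defining the standard limits.
LIMIT_FRACTIONS = {"I0": 0.6, "I1": 1.0, "I2": 1.4}


def limit_from_fraction(reference_count: int, fraction: float) -> int:
    """Percent-of-reference isocenter limit: ceil, floored at 1."""
    return max(1, math.ceil(fraction * reference_count))


def is_better_plan(
    challenger: tuple[float, float],
    incumbent: tuple[float, float],
    conformity_margin: float = 0.03,
    time_margin_min: float = 3.0,
    relative: bool = True,
) -> bool:
    """Dominance rule for (conformity, treatment time) pairs.

    The challenger wins if it improves conformity by at least the margin
    without a significant time increase (<= 3 min), or cuts time by at least
    3 min without a significant conformity loss. ``relative`` interprets the
    3% margin as a relative change (the default); set False for absolute
    points. Ties keep the incumbent.
    """
    ci_c, t_c = challenger
    ci_i, t_i = incumbent
    if relative:
        gain = ci_c >= ci_i * (1.0 + conformity_margin)
        hold = ci_c >= ci_i * (1.0 - conformity_margin)
    else:
        gain = ci_c >= ci_i + conformity_margin
        hold = ci_c >= ci_i - conformity_margin
    if gain and t_c <= t_i + time_margin_min:
        return True
    if t_c <= t_i - time_margin_min and hold:
        return True
    return False


@dataclass
class SweepResult:
    plans: dict  # limit name -> {"limit": H, "solution": ..., "report": ..., "objective": ...}
    best: Optional[str]
    failures: dict


def run_limit_sweep(
    phantom,
    kernels,
    weights_for_limit: Callable[[np.ndarray], "object"],
    reference_count: int,
    limits: dict[str, int] | None = None,
    include_ipred: bool = False,
    best_over: tuple[str, ...] = ("I0", "I1", "I2"),
    relative_rule: bool = True,
    **problem_kwargs,
) -> SweepResult:
    """Plan under several isocenter limits and pick the subjective best plan.

    ``weights_for_limit`` maps the per-target limit array H to the
    ObjectiveWeights used at that limit (a constant function reproduces the
    fixed-weight sweep; a weight-inference call reproduces the full
    pipeline). Failures at one limit are recorded and the sweep continues.
    """
    from .planning import PlanningProblem, solve_planning

    P = len(phantom.targets)
    if limits is None:
        limits = {
            name: limit_from_fraction(reference_count, frac)
            for name, frac in LIMIT_FRACTIONS.items()
        }
        if include_ipred:
            limits["Ipred"] = max(
                predict_isocenter_limit(t.prescription_dose, t.volume_cc(phantom.grid))
                for t in phantom.targets
            )
    plans: dict = {}
    failures: dict = {}
    for name, h in limits.items():
        h_arr = np.full(P, int(h))
        try:
            weights = weights_for_limit(h_arr)
            problem = PlanningProblem(
                phantom=phantom, kernels=kernels, limits=h_arr, weights=weights,
                **problem_kwargs,
            )
            sol = solve_planning(problem)
            dose = kernels.render_dose(sol.t)
            metrics = [quality_metrics(dose, tgt) for tgt in phantom.targets]
            t_time, adj_time = treatment_time(sol)
            report = QualityReport(metrics, t_time, adj_time, sol.n_selected)
            plans[name] = {
                "limit": int(h),
                "solution": sol,
                "report": report,
                "objective": sol.objective,
            }
        except Exception as exc:  # noqa: BLE001 - sweep must survive per-limit failures
            failures[name] = f"{type(exc).__name__}: {exc}"
    best = None
    for name in best_over:
        if name not in plans:
            continue
        if best is None:
            best = name
            continue
        inc = plans[best]["report"]
        cha = plans[name]["report"]
        if is_better_plan(
            (cha.mean_conformity, cha.treatment_time_min),
            (inc.mean_conformity, inc.treatment_time_min),
            relative=relative_rule,
        ):
            best = name
    return SweepResult(plans=plans, best=best, failures=failures)
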