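"""End-to-end pipeline: phantom -> candidates -> kernels -> prediction ->
weight inference -> planning -> shots -> evaluation.

Every stage writes its artifacts into the run directory, appends a structured
log line with timing and status, and is reproducible from the single global
seed (fanned out to per-stage seeds by fixed offsets). The weight stage
applies the fallback rules: when the cutting plane is infeasible at the start
or exhausts its time budget, the approximate weights from the relaxed
inverse problem are used and tagged as such.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io
from .candidates import generate_candidates, required_candidate_count
from .evaluation import (
    QualityReport,
    decompose_shots,
    limit_from_fraction,
    predict_isocenter_limit,
    quality_metrics,
    treatment_time,
)
from .inverse import (
    InverseInfeasibleError,
    cutting_plane,
    penalties_from_prediction,
    solve_relaxed_inverse,
)
from .kernels import KernelSet, make_central_kernel
from .phantom import PhantomSpec, build_phantom
from .planning import ObjectiveWeights, PlanningProblem, solve_planning
from .prediction import generate_prediction

# Fixed offsets fanning the global seed out to stages.
_SEED_OFFSETS = {"phantom": 11, "prediction": 23}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``limit_mode`` is one of ``explicit`` (use ``isocenter_limit``),
    ``percent`` (ceil of ``limit_fraction`` x ``reference_count``) or
    ``ipred`` (regression-predicted limit). ``weight_mode`` is one of
    ``approximate``, ``cutting_plane``, ``cutting_plane_regularized`` or
    ``manual``.
    """

    phantom_spec: PhantomSpec
    seed: int = 0
    candidate_method: str = "hcp"
    reference_count: int = 4
    limit_mode: str = "percent"
    limit_fraction: float = 1.0
    isocenter_limit: int = 4
    weight_mode: str = "approximate"
    manual_weights: list | None = None
    generating_weights: list | None = None
    prediction_noise_sd: float = 0.0
    dose_rate_scale: float = 2.5
    mip_gap: float = 1e-4
    solver_time_limit_s: float = 600.0
    cutting_plane_budget_s: float = 3600.0
    cutting_plane_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.limit_mode not in ("explicit", "percent", "ipred"):
            raise ValueError(f"unknown limit mode {self.limit_mode!r}")
        if self.weight_mode not in (
            "approximate",
            "cutting_plane",
            "cutting_plane_regularized",
            "manual",
        ):
            raise ValueError(f"unknown weight mode {self.weight_mode!r}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        d = io.read_yaml(path)
        spec = io.phantom_spec_from_dict(d.pop("phantom"))
        return cls(phantom_spec=spec, **d)


def _limits(config: PipelineConfig, phantom) -> np.ndarray:
    P = len(phantom.targets)
    if config.limit_mode == "explicit":
        return np.full(P, int(config.isocenter_limit))
    if config.limit_mode == "percent":
        return np.full(
            P, limit_from_fraction(config.reference_count, config.limit_fraction)
        )
    return np.array(
        [
            predict_isocenter_limit(t.prescription_dose, t.volume_cc(phantom.grid))
            for t in phantom.targets
        ]
    )


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def stage(self, name: str):
        log = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.monotonic()
                return self

            def __exit__(self, exc_type, exc, tb):
                log.records.append(
                    {
                        "stage": name,
                        "seconds": round(time.monotonic() - self.t0, 3),
                        "status": "ok" if exc_type is None else f"failed: {exc}",
                    }
                )
                log.path.write_text(
                    "\n".join(json.dumps(r) for r in log.records) + "\n"
                )
                return False

        return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> dict:
    """Execute all stages; returns a summary dict (also written to the run
    directory along with every artifact and a hashed manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "log.jsonl")
    summary: dict = {"seed": config.seed, "out_dir": str(out)}

    with log.stage("phantom"):
        spec = config.phantom_spec
        spec.seed = config.seed + _SEED_OFFSETS["phantom"]
        phantom = build_phantom(spec)
        io.save_phantom(out / "phantom", phantom)
        P = len(phantom.targets)

    with log.stage("candidates"):
        required = required_candidate_count(config.reference_count)
        cand = generate_candidates(
            phantom,
            required=required,
            reference_count=config.reference_count,
            method=config.candidate_method,
        )
        (out / "candidates.json").write_text(cand.to_json())

    with log.stage("kernels"):
        central = make_central_kernel(phantom.grid, dose_rate_scale=config.dose_rate_scale)
        pos, tgt = cand.positions_and_targets()
        kernels = KernelSet.from_candidates(central, phantom.skull_mask, pos, tgt)
        io.save_kernels(out / "kernels", kernels)

    limits = _limits(config, phantom)
    summary["limits"] = limits.tolist()

    with log.stage("prediction"):
        gen_w = (
            ObjectiveWeights(np.asarray(config.generating_weights, dtype=float))
            if config.generating_weights is not None
            else ObjectiveWeights(np.tile([0.45, 0.05, 0.25, 0.25, 0.002], (P, 1)))
        )
        prediction, gen_sol = generate_prediction(
            phantom,
            kernels,
            gen_w,
            isocenter_subset=None,
            limits=limits,
            noise_sd=config.prediction_noise_sd,
            seed=config.seed + _SEED_OFFSETS["prediction"],
        )
        io.save_volume(out / "prediction.nii.gz", prediction.dose, phantom.grid)
        io.write_json(out / "prediction_provenance.json", prediction.provenance)

    with log.stage("weights"):
        weights, weight_meta = _infer_weights(config, phantom, kernels, prediction, limits)
        io.write_json(out / "weights.json", {**weights.to_dict(), **weight_meta})
        summary["weight_mode"] = weight_meta["mode"]
        summary["weight_gap"] = weight_meta.get("gap")

    with log.stage("plan"):
        problem = PlanningProblem(
            phantom=phantom,
            kernels=kernels,
            limits=limits,
            weights=weights,
            mip_gap=config.mip_gap,
            time_limit_s=config.solver_time_limit_s,
        )
        solution = solve_planning(problem)
        io.write_json(out / "plan.json", solution.to_dict())
        summary["objective"] = solution.objective
        summary["solver_status"] = solution.status

    with log.stage("shots"):
        shots = decompose_shots(solution, kernels.central.collimators_mm)
        io.write_json(out / "shots.json", shots.to_dict())
        summary["n_shots"] = len(shots.shots)

    with log.stage("evaluate"):
        dose = kernels.render_dose(solution.t)
        io.save_volume(out / "dose.nii.gz", dose, phantom.grid)
        metrics = [quality_metrics(dose, t) for t in phantom.targets]
        t_time, adj_time = treatment_time(solution)
        report = QualityReport(metrics, t_time, adj_time, solution.n_selected)
        report.to_frame().to_csv(out / "report.csv", index=False)
        summary["coverage"] = [m.coverage for m in metrics]
        summary["paddick_ci"] = [m.paddick_ci for m in metrics]
        summary["gradient_index"] = [m.gradient_index for m in metrics]
        summary["treatment_time_min"] = t_time
        summary["adjusted_time_min"] = adj_time
        summary["isocenter_count"] = solution.n_selected

    with log.stage("manifest"):
        artifacts = sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        )
        io.write_json(
            out / "manifest.json",
            {
                "seed": config.seed,
                "stages": [r["stage"] for r in log.records],
                "artifacts": {a: io.sha256_file(out / a) for a in artifacts},
            },
        )
    io.write_json(out / "summary.json", summary)
    return summary


def _infer_weights(config, phantom, kernels, prediction, limits):
    """Weight stage with the fallback rules applied."""
    P = len(phantom.targets)
    if config.weight_mode == "manual":
        if config.manual_weights is None:
            raise ValueError("manual weight mode requires manual_weights")
        return ObjectiveWeights(np.asarray(config.manual_weights, dtype=float)), {
            "mode": "manual"
        }
    penalties = penalties_from_prediction(prediction, phantom, limits)
    approx = solve_relaxed_inverse(penalties, kernels, phantom, limits)
    if config.weight_mode == "approximate":
        return approx.weights, {"mode": "approximate", "gap": approx.gap}
    template = PlanningProblem(
        phantom=phantom,
        kernels=kernels,
        limits=limits,
        weights=approx.weights,
        mip_gap=config.mip_gap,
    )
    final, cutset = cutting_plane(
        penalties,
        template,
        approx.weights,
        regularized=(config.weight_mode == "cutting_plane_regularized"),
        max_time_s=config.cutting_plane_budget_s,
        tol=config.cutting_plane_tol,
    )
    if cutset.fallback:
        return final, {
            "mode": "approximate (fallback)",
            "gap": approx.gap,
            "fallback_reason": cutset.reason,
        }
    return final, {
        "mode": config.weight_mode,
        "gap": cutset.gap_history[-1] if cutset.gap_history else approx.gap,
        "initial_gap": approx.gap,
        "iterations": cutset.n_iterations,
        "termination": cutset.reason,
    }
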