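"""Synthetic "predicted" dose distributions with known provenance.

A real knowledge-based pipeline obtains its dose prediction from a model
trained on historical plans. Here the prediction is manufactured by solving
the planning model restricted to a chosen isocenter subset under known
generating weights, rendering the exact dose, and optionally corrupting it
with truncated Gaussian noise. Because the generating beam-on-times are
recorded, downstream weight inference can be validated against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelSet
from .phantom import Phantom
from .planning import BeamSolution, ObjectiveWeights, PlanningProblem, solve_planning


@dataclass
class DosePrediction:
    """A nonnegative, finite dose volume plus the record of how it was made."""

    dose: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.dose).all() or (self.dose < 0).any():
            raise ValueError("prediction dose must be finite and nonnegative")


def generate_prediction(
    phantom: Phantom,
    kernels: KernelSet,
    weights: ObjectiveWeights,
    isocenter_subset: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    big_m: float | None = None,
    limits: np.ndarray | None = None,
) -> tuple[DosePrediction, BeamSolution]:
    """Solve the planning model and emit the rendered dose (plus optional
    truncated zero-mean noise) as a prediction.

    With ``isocenter_subset`` given, the model is restricted to those
    isocenters (emulating a plan with manually chosen isocenters); with
    ``None``, isocenter selection itself is optimized under ``limits``,
    emulating a well-planned historical dose. Deterministic for a fixed
    seed. Returns the prediction and the generating solution.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    P = len(phantom.targets)
    if isocenter_subset is not None:
        subset = np.unique(np.asarray(isocenter_subset, dtype=int))
        if subset.size == 0:
            raise ValueError("isocenter subset must be nonempty")
        fixed_z = np.zeros(kernels.n_isocenters)
        fixed_z[subset] = 1.0
        if limits is None:
            limits = np.array(
                [max(1, int(fixed_z[kernels.candidates_of_target(p)].sum())) for p in range(P)]
            )
        problem = PlanningProblem(
            phantom=phantom,
            kernels=kernels,
            limits=limits,
            weights=weights,
            big_m=big_m,
            mode="fix_iso",
            fixed_z=fixed_z,
        )
    else:
        if limits is None:
            raise ValueError("limits required when no isocenter subset is given")
        subset = None
        problem = PlanningProblem(
            phantom=phantom,
            kernels=kernels,
            limits=np.asarray(limits, dtype=int),
            weights=weights,
            big_m=big_m,
        )
    solution = solve_planning(problem)
    dose = kernels.render_dose(solution.t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = dose + rng.normal(0.0, noise_sd, size=dose.shape)
        noisy[~kernels.skull_mask] = 0.0
        dose = np.maximum(noisy, 0.0)
    prediction = DosePrediction(
        dose=dose,
        provenance={
            "generator": "planning_model",
            "isocenter_subset": subset.tolist() if subset is not None else None,
            "weights": weights.to_dict(),
            "noise_sd": float(noise_sd),
            "seed": int(seed),
            "tau_min": solution.tau.tolist(),
            "objective": solution.objective,
        },
    )
    return prediction, solution
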