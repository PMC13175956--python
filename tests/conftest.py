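"""Shared fixtures: micro phantoms and kernel sets kept small enough that
every MILP in the suite solves in seconds."""
from __future__ import annotations

import numpy as np
import pytest

import gkplan as gk


@pytest.fixture(scope="session")
def micro_phantom() -> gk.Phantom:
    """A single 0.2 cc spherical target inside an 18 mm skull, 1.5 mm grid."""
    spec = gk.PhantomSpec(
        targets=[gk.TargetSpec(volume_cc=0.2, prescription_dose=18.0)],
        grid_shape=(32, 32, 32),
        spacing_mm=(1.5, 1.5, 1.5),
        skull_semi_axes_mm=(18.0, 18.0, 18.0),
        seed=1,
    )
    return gk.build_phantom(spec)


@pytest.fixture(scope="session")
def micro_kernels(micro_phantom: gk.Phantom) -> gk.KernelSet:
    cand = gk.generate_candidates(micro_phantom, reference_count=3)
    central = gk.make_central_kernel(micro_phantom.grid, dose_rate_scale=2.5)
    pos, tgt = cand.positions_and_targets()
    return gk.KernelSet.from_candidates(central, micro_phantom.skull_mask, pos, tgt)


@pytest.fixture(scope="session")
def generating_weights() -> gk.ObjectiveWeights:
    """Plausible clinical-style weights: hinge-dominated, small time weight."""
    return gk.ObjectiveWeights(np.array([[0.45, 0.05, 0.25, 0.25, 0.002]]))


@pytest.fixture(scope="session")
def micro_problem(micro_phantom, micro_kernels, generating_weights) -> gk.PlanningProblem:
    return gk.PlanningProblem(
        phantom=micro_phantom,
        kernels=micro_kernels,
        limits=[2],
        weights=generating_weights,
    )


@pytest.fixture(scope="session")
def micro_solution(micro_problem) -> gk.BeamSolution:
    return gk.solve_planning(micro_problem)


def build_oracle_instance(seed: int, n_candidates: int = 4):
    """A deliberately tiny planning instance for brute-force cross-checks.

    2 mm grid, ~0.1 cc target, trimmed shells, <= ``n_candidates`` candidate
    isocenters: small enough that enumerating every isocenter subset stays
    cheap.
    """
    rng = np.random.default_rng(seed)
    spec = gk.PhantomSpec(
        targets=[
            gk.TargetSpec(
                volume_cc=float(rng.uniform(0.08, 0.2)),
                prescription_dose=float(rng.choice([15.0, 18.0, 20.0])),
            )
        ],
        grid_shape=(24, 24, 24),
        spacing_mm=(2.0, 2.0, 2.0),
        skull_semi_axes_mm=(16.0, 16.0, 16.0),
        shell_s_margin_mm=2.0,
        shell_g_margin_mm=4.0,
        seed=seed,
    )
    phantom = gk.build_phantom(spec)
    cand = gk.generate_candidates(phantom, required=n_candidates)
    entry = cand.entries[0]
    entry.positions_mm = entry.positions_mm[:n_candidates]
    entry.sphere_diameters_mm = entry.sphere_diameters_mm[:n_candidates]
    central = gk.make_central_kernel(phantom.grid, dose_rate_scale=2.5)
    pos, tgt = cand.positions_and_targets()
    kernels = gk.KernelSet.from_candidates(central, phantom.skull_mask, pos, tgt)
    n_opt = sum(t.n_t + t.n_s + t.n_g for t in phantom.targets)
    assert n_opt <= 200, f"oracle instance too large ({n_opt} voxels)"
    return phantom, kernels
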