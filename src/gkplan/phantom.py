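"""Synthetic voxel phantoms: skull, targets, optimization shells, sphericity.

The phantom stands in for a contoured patient image. A skull ellipsoid bounds
the dose calculation; each target is an ellipsoidal lesion with a prescription
dose and two surrounding optimization shells: a selectivity shell (a thin ring
just outside the target, thresholded at the prescription dose) and a gradient
shell (a wider ring thresholded at half the prescription, matching the
half-isodose used by the gradient index).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid


class GeometryError(ValueError):
    """A requested phantom geometry cannot be rasterized."""


@dataclass
class Target:
    """A single lesion with its optimization shells.

    ``shell_s`` (selectivity shell) and ``shell_g`` (gradient shell) are
    disjoint boolean rings outside the target mask; ``dose_s`` and ``dose_g``
    are the dose thresholds (Gy) applied on them.
    """

    id: str
    mask: np.ndarray
    prescription_dose: float
    shell_s: np.ndarray
    shell_g: np.ndarray
    dose_s: float
    dose_g: float

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise GeometryError(f"target {self.id!r}: empty mask")
        if (self.mask & self.shell_s).any() or (self.mask & self.shell_g).any():
            raise GeometryError(f"target {self.id!r}: shells overlap the target mask")
        if (self.shell_s & self.shell_g).any():
            raise GeometryError(f"target {self.id!r}: selectivity and gradient shells overlap")
        if not (self.prescription_dose >= self.dose_s > self.dose_g > 0):
            raise GeometryError(
                f"target {self.id!r}: thresholds must satisfy D_T >= D_S > D_G > 0"
            )

    @property
    def n_t(self) -> int:
        return int(self.mask.sum())

    @property
    def n_s(self) -> int:
        return int(self.shell_s.sum())

    @property
    def n_g(self) -> int:
        return int(self.shell_g.sum())

    def volume_cc(self, grid: VoxelGrid) -> float:
        return self.n_t * grid.voxel_volume_cc

    def centroid_world(self, grid: VoxelGrid) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return grid.voxel_to_world(idx).mean(axis=0)


@dataclass
class Phantom:
    """A synthetic patient: grid, skull mask, targets and calibration dose."""

    grid: VoxelGrid
    skull_mask: np.ndarray
    targets: list[Target]
    calibration_dose: float = 18.0

    def __post_init__(self) -> None:
        for t in self.targets:
            if (t.mask & ~self.skull_mask).any():
                raise GeometryError(f"target {t.id!r} extends outside the skull")

    @property
    def thresholds(self) -> dict[str, tuple[float, float]]:
        return {t.id: (t.dose_s, t.dose_g) for t in self.targets}


@dataclass
class TargetSpec:
    """Requested geometry for one target.

    ``axis_ratios`` shapes the ellipsoid (1,1,1 is a sphere; elongating one
    axis lowers sphericity); ``center_offset_mm`` displaces it from the skull
    center.
    """

    volume_cc: float
    prescription_dose: float = 18.0
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    id: str | None = None


@dataclass
class PhantomSpec:
    """Full phantom request: grid, skull ellipsoid, targets, shell margins."""

    targets: list[TargetSpec]
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skull_semi_axes_mm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    shell_s_margin_mm: float = 2.0
    shell_g_margin_mm: float = 6.0
    shell_g_dose_fraction: float = 0.5
    calibration_dose: float = 18.0
    seed: int = 0


def _ellipsoid_mask(grid: VoxelGrid, center_mm: np.ndarray, semi_axes_mm: np.ndarray) -> np.ndarray:
    xs, ys, zs = grid.axes_coordinates()
    dx = (xs - center_mm[0]) / semi_axes_mm[0]
    dy = (ys - center_mm[1]) / semi_axes_mm[1]
    dz = (zs - center_mm[2]) / semi_axes_mm[2]
    r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    return r2 <= 1.0


def _ball_structure(grid: VoxelGrid, radius_mm: float) -> np.ndarray:
    """Spherical structuring element honoring anisotropic spacing."""
    half = [int(math.floor(radius_mm / s)) for s in grid.spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, grid.spacing)]
    r2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    return r2 <= radius_mm**2 + 1e-9


def build_shells(
    grid: VoxelGrid,
    mask: np.ndarray,
    s_margin_mm: float,
    g_margin_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Morphological optimization shells.

    selectivity ring = dilate(mask, s) \\ mask;
    gradient ring = dilate(mask, g) \\ dilate(mask, s).
    """
    if g_margin_mm <= s_margin_mm:
        raise GeometryError("gradient shell margin must exceed selectivity margin")
    dil_s = ndimage.binary_dilation(mask, structure=_ball_structure(grid, s_margin_mm))
    dil_g = ndimage.binary_dilation(mask, structure=_ball_structure(grid, g_margin_mm))
    return dil_s & ~mask, dil_g & ~dil_s


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom from its spec; deterministic for a fixed seed.

    Raises
    ------
    GeometryError
        If a target does not fit inside the skull, rasterizes to an empty
        mask, or misses its requested volume by more than 10%.
    """
    grid = VoxelGrid(shape=spec.grid_shape, spacing=spec.spacing_mm)
    center = grid.voxel_to_world(np.array(grid.center_index))
    skull = _ellipsoid_mask(grid, center, np.asarray(spec.skull_semi_axes_mm, dtype=float))
    skull_volume_cc = skull.sum() * grid.voxel_volume_cc

    targets: list[Target] = []
    for k, tspec in enumerate(spec.targets):
        if tspec.volume_cc <= 0:
            raise GeometryError(f"target {k}: requested volume must be positive")
        if tspec.volume_cc >= skull_volume_cc:
            raise GeometryError(f"target {k}: requested volume exceeds the skull volume")
        ratios = np.asarray(tspec.axis_ratios, dtype=float)
        if (ratios <= 0).any():
            raise GeometryError(f"target {k}: axis ratios must be positive")
        # (4/3) pi * (r*a)(r*b)(r*c) = V  =>  base radius r
        base_r = (3.0 * tspec.volume_cc * 1000.0 / (4.0 * math.pi * float(np.prod(ratios)))) ** (
            1.0 / 3.0
        )
        t_center = center + np.asarray(tspec.center_offset_mm, dtype=float)
        mask = _ellipsoid_mask(grid, t_center, base_r * ratios)
        if not mask.any():
            raise GeometryError(
                f"target {k}: rasterized to an empty mask (volume too small for the grid)"
            )
        if (mask & ~skull).any():
            raise GeometryError(f"target {k}: does not fit inside the skull")
        got_cc = mask.sum() * grid.voxel_volume_cc
        # Below a couple hundred voxels the lattice itself limits precision.
        if abs(got_cc - tspec.volume_cc) > 0.10 * tspec.volume_cc and mask.sum() > 200:
            raise GeometryError(
                f"target {k}: rasterized volume {got_cc:.4f} cc misses the requested "
                f"{tspec.volume_cc:.4f} cc by more than 10%"
            )
        shell_s, shell_g = build_shells(grid, mask, spec.shell_s_margin_mm, spec.shell_g_margin_mm)
        d_t = float(tspec.prescription_dose)
        targets.append(
            Target(
                id=tspec.id or f"T{k}",
                mask=mask,
                prescription_dose=d_t,
                shell_s=shell_s & skull,
                shell_g=shell_g & skull,
                dose_s=d_t,
                dose_g=spec.shell_g_dose_fraction * d_t,
            )
        )
    return Phantom(
        grid=grid, skull_mask=skull, targets=targets, calibration_dose=spec.calibration_dose
    )


# ---------------------------------------------------------------------------
# Sphericity
# ---------------------------------------------------------------------------


def discrete_surface_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Surface area by 6-connected exposed-face counting.

    Every face between a mask voxel and a non-mask (or out-of-volume) voxel
    contributes the area of that face.
    """
    if not mask.any():
        raise GeometryError("empty mask has no surface")
    area = 0.0
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    for ax, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += float(np.abs(diff).sum()) * fa
    return area


def digital_sphere(n_voxels: int, spacing: tuple[float, float, float]) -> np.ndarray:
    """The digital sphere (lattice ball) whose voxel count is closest to ``n_voxels``.

    Lattice points are ranked by distance from a voxel center; the ball is cut
    at the radius whose cumulative count is nearest the request, preferring the
    smaller ball on ties.
    """
    if n_voxels < 1:
        raise GeometryError("digital sphere needs at least one voxel")
    # Generous bounding radius for the search.
    vox_cc = float(np.prod(spacing))
    r_guess = (3.0 * n_voxels * vox_cc / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_max = r_guess + 2.0 * max(spacing)
    half = [int(math.ceil(r_max / s)) + 1 for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    flat = np.sort(d2.ravel())
    if n_voxels > flat.size:
        raise GeometryError("requested digital sphere exceeds search bound")
    # Candidate cut radii are the distinct distances; counts jump at each.
    distinct, counts = np.unique(flat, return_counts=True)
    cum = np.cumsum(counts)
    best = int(np.argmin(np.abs(cum - n_voxels)))
    return d2 <= distinct[best] + 1e-12


def compute_sphericity(target: Target | np.ndarray, grid: VoxelGrid) -> float:
    """Discrete sphericity: surface area of the equal-volume digital sphere
    divided by the surface area of the target, both by exposed-face counting.

    Equals 1 for any digital sphere by self-normalization; clipped to 1.
    """
    mask = target.mask if isinstance(target, Target) else np.asarray(target, dtype=bool)
    if not mask.any():
        raise GeometryError("cannot compute sphericity of an empty mask")
    a_target = discrete_surface_area(mask, grid.spacing)
    sphere = digital_sphere(int(mask.sum()), grid.spacing)
    a_sphere = discrete_surface_area(sphere, grid.spacing)
    return min(1.0, a_sphere / a_target)
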