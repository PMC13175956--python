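"""Synthetic dose-rate kernels and their translation to candidate isocenters.

A kernel maps beam-on-time to dose rate (Gy/min) for one (isocenter, sector,
collimator) combination. Eight sectors and three collimator apertures
(4/8/16 mm) are modelled. Each sector profile is an anisotropic Gaussian whose
full width at half maximum matches the collimator size, elongated in a
sector-specific in-plane direction so sectors are distinguishable while their
sum stays nearly isotropic. One central kernel is computed per phantom and
translated (nearest-voxel shift, no interpolation) to every candidate
location, with voxels outside the skull assigned zero dose.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .grid import VoxelGrid

N_SECTORS = 8
N_COLLIMATORS = 3
DEFAULT_COLLIMATORS_MM = (4.0, 8.0, 16.0)
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class KernelError(ValueError):
    """Kernel construction or translation failure."""


def _inplane_sigma_correction(anisotropy: float) -> float:
    """Width calibration for the 8-sector anisotropic mixture.

    The eight rotated anisotropic Gaussians sum to a non-Gaussian in-plane
    profile that is slightly wider at half maximum than a single Gaussian of
    the base sigma. Returns the factor by which the base sigma must shrink so
    the summed profile's FWHM equals the nominal collimator size.
    """
    if anisotropy == 0.0:
        return 1.0
    sx2 = (1.0 + anisotropy) ** 2
    sy2 = (1.0 - anisotropy) ** 2
    gm = 0.5 * (1.0 / sx2 + 1.0 / sy2)

    def profile(r: float) -> float:
        # Sectors at 45-degree steps: 2 aligned, 2 perpendicular, 4 diagonal.
        return (
            2.0 * math.exp(-(r**2) / (2.0 * sx2))
            + 2.0 * math.exp(-(r**2) / (2.0 * sy2))
            + 4.0 * math.exp(-(r**2) * gm / 2.0)
        )

    half = profile(0.0) / 2.0
    r_half = brentq(lambda r: profile(r) - half, 1e-6, 10.0)
    fwhm_at_unit_sigma = 2.0 * r_half
    return (1.0 / _FWHM_TO_SIGMA) / fwhm_at_unit_sigma


@dataclass
class CentralKernel:
    """Per-sector, per-collimator rate volumes centered at the skull center.

    ``rates`` has shape (8, 3, *grid.shape); ``center_index`` is the voxel the
    profiles peak at.
    """

    grid: VoxelGrid
    rates: np.ndarray
    collimators_mm: tuple[float, ...]
    center_index: tuple[int, int, int]
    dose_rate_scale: float

    def sector_sum(self, c: int) -> np.ndarray:
        """All eight sectors firing at collimator index ``c``."""
        return self.rates[:, c].sum(axis=0)


def make_central_kernel(
    grid: VoxelGrid,
    collimators_mm: tuple[float, ...] = DEFAULT_COLLIMATORS_MM,
    sector_angles: np.ndarray | None = None,
    dose_rate_scale: float = 2.5,
    anisotropy: float = 0.15,
    center_index: tuple[int, int, int] | None = None,
    tail_cutoff: float = 1e-4,
) -> CentralKernel:
    """Build the central synthetic kernel.

    Each (sector, collimator) sub-kernel is a nonnegative unimodal Gaussian
    profile with FWHM equal to the collimator size, its in-plane axes rotated
    to the sector angle and scaled by ``1 +- anisotropy``. The eight-sector
    sum at the center voxel is normalized to ``dose_rate_scale`` (Gy/min) for
    every collimator; aperture output factors are considered folded into that
    scale.
    """
    if len(collimators_mm) != N_COLLIMATORS:
        raise KernelError(f"exactly {N_COLLIMATORS} collimator sizes required")
    if sector_angles is None:
        sector_angles = np.arange(N_SECTORS) * (2.0 * math.pi / N_SECTORS)
    sector_angles = np.asarray(sector_angles, dtype=float)
    if sector_angles.shape != (N_SECTORS,):
        raise KernelError(f"exactly {N_SECTORS} sector angles required")
    if min(grid.spacing) > min(collimators_mm) / 2.0:
        raise KernelError(
            f"grid spacing {grid.spacing} too coarse for the "
            f"{min(collimators_mm)} mm collimator (need <= half the aperture)"
        )
    if dose_rate_scale <= 0:
        raise KernelError("dose rate scale must be positive")

    if center_index is None:
        center_index = grid.center_index
    center_mm = grid.voxel_to_world(np.array(center_index))
    xs, ys, zs = grid.axes_coordinates()
    x = (xs - center_mm[0])[:, None, None]
    y = (ys - center_mm[1])[None, :, None]
    z = (zs - center_mm[2])[None, None, :]

    rates = np.zeros((N_SECTORS, N_COLLIMATORS) + grid.shape)
    amp = dose_rate_scale / N_SECTORS
    correction = _inplane_sigma_correction(anisotropy)
    for ci, coll in enumerate(collimators_mm):
        sigma = coll * _FWHM_TO_SIGMA
        sigma_plane = sigma * correction
        for si, theta in enumerate(sector_angles):
            # Rotate in-plane axes to the sector direction.
            xr = math.cos(theta) * x + math.sin(theta) * y
            yr = -math.sin(theta) * x + math.cos(theta) * y
            sx = sigma_plane * (1.0 + anisotropy)
            sy = sigma_plane * (1.0 - anisotropy)
            prof = amp * np.exp(
                -0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2 + (z / sigma) ** 2)
            )
            # Truncate the far tail: tiny coefficients carry no dose but
            # destabilize the downstream linear programs.
            prof[prof < tail_cutoff * amp] = 0.0
            rates[si, ci] = prof
    return CentralKernel(
        grid=grid,
        rates=rates,
        collimators_mm=tuple(float(c) for c in collimators_mm),
        center_index=tuple(int(i) for i in center_index),
        dose_rate_scale=float(dose_rate_scale),
    )


def _shift_volume(vol: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel shift with zero fill (no wraparound)."""
    out = np.zeros_like(vol)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, off in enumerate(offset):
        n = vol.shape[ax]
        if abs(off) >= n:
            return out
        if off >= 0:
            src[ax] = slice(0, n - off)
            dst[ax] = slice(off, n)
        else:
            src[ax] = slice(-off, n)
            dst[ax] = slice(0, n + off)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def translate_kernel(
    central: CentralKernel,
    position_mm: np.ndarray,
    skull_mask: np.ndarray,
) -> np.ndarray:
    """Translate the full central kernel stack to a candidate location.

    The shift is the nearest-voxel offset from the kernel center to the
    candidate; in-skull voxels keep the shifted values exactly, voxels outside
    the skull are set to zero.

    Returns an array of shape (8, 3, *grid.shape).
    """
    grid = central.grid
    vox = grid.world_to_voxel(np.asarray(position_mm, dtype=float))
    if not grid.contains_index(vox) or not skull_mask[tuple(vox)]:
        raise KernelError(f"candidate position {position_mm} is outside the skull")
    offset = tuple(int(v) for v in (vox - np.array(central.center_index)))
    out = np.empty_like(central.rates)
    for si in range(N_SECTORS):
        for ci in range(N_COLLIMATORS):
            out[si, ci] = _shift_volume(central.rates[si, ci], offset)
    out[:, :, ~skull_mask] = 0.0
    return out


@dataclass
class KernelSet:
    """Translated kernels for all candidate isocenters of a phantom.

    Stores the central kernel plus one integer voxel offset per candidate;
    values are materialized on demand, which keeps memory at one kernel stack
    regardless of candidate count. ``target_index`` maps each candidate to the
    target it was generated for.
    """

    central: CentralKernel
    skull_mask: np.ndarray
    positions_mm: np.ndarray  # (n_iso, 3)
    offsets: np.ndarray  # (n_iso, 3) integer voxel shifts
    target_index: np.ndarray  # (n_iso,) int

    @classmethod
    def from_candidates(
        cls,
        central: CentralKernel,
        skull_mask: np.ndarray,
        positions_mm: np.ndarray,
        target_index: np.ndarray,
    ) -> "KernelSet":
        positions_mm = np.atleast_2d(np.asarray(positions_mm, dtype=float))
        grid = central.grid
        vox = grid.world_to_voxel(positions_mm)
        for p, v in zip(positions_mm, vox):
            if not grid.contains_index(v) or not skull_mask[tuple(v)]:
                raise KernelError(f"candidate position {p} is outside the skull")
        offsets = vox - np.array(central.center_index)
        return cls(
            central=central,
            skull_mask=skull_mask,
            positions_mm=positions_mm,
            offsets=offsets.astype(int),
            target_index=np.asarray(target_index, dtype=int),
        )

    @property
    def n_isocenters(self) -> int:
        return len(self.positions_mm)

    @property
    def n_beams(self) -> int:
        return self.n_isocenters * N_SECTORS * N_COLLIMATORS

    def candidates_of_target(self, p: int) -> np.ndarray:
        return np.flatnonzero(self.target_index == p)

    def rate_matrix(self, voxel_idx: np.ndarray) -> np.ndarray:
        """Rates phi at given voxels for every beam.

        Parameters
        ----------
        voxel_idx : (m, 3) integer array of voxel indices.

        Returns
        -------
        (m, n_isocenters * 8 * 3) array; beam column order is
        (isocenter, sector, collimator), C-style.
        """
        voxel_idx = np.asarray(voxel_idx, dtype=int)
        m = len(voxel_idx)
        in_skull = self.skull_mask[tuple(voxel_idx.T)]
        out = np.zeros((m, self.n_isocenters, N_SECTORS, N_COLLIMATORS))
        shape = self.central.grid.shape
        for i, off in enumerate(self.offsets):
            src = voxel_idx - off[None, :]
            ok = in_skull.copy()
            for ax in range(3):
                ok &= (src[:, ax] >= 0) & (src[:, ax] < shape[ax])
            if ok.any():
                sel = src[ok]
                vals = self.central.rates[:, :, sel[:, 0], sel[:, 1], sel[:, 2]]
                out[ok, i] = np.moveaxis(vals, -1, 0)
        return out.reshape(m, self.n_beams)

    def render_dose(self, t: np.ndarray) -> np.ndarray:
        """Full dose volume (Gy) delivered by beam-on-times ``t``.

        ``t`` has shape (n_isocenters, 8, 3) in minutes. Dose is exactly zero
        outside the skull.
        """
        t = np.asarray(t, dtype=float).reshape(self.n_isocenters, N_SECTORS, N_COLLIMATORS)
        dose = np.zeros(self.central.grid.shape)
        for i, off in enumerate(self.offsets):
            if not t[i].any():
                continue
            contrib = np.einsum("sc,scxyz->xyz", t[i], self.central.rates)
            dose += _shift_volume(contrib, tuple(off))
        dose[~self.skull_mask] = 0.0
        return dose
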