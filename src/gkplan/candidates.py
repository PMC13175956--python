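"""Candidate isocenter generation inside each target.

Two strategies are provided: an iterative hexagonal-close-packed (HCP)
lattice whose sphere diameter shrinks in 0.5 mm steps until enough in-target
centers exist, and a grassfire (distance-transform) sphere packing that
carves progressively smaller spheres out of the target. The target centroid
is always appended as an extra candidate. The required candidate count is
max(ceil(1.4 x reference count), 6).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .phantom import Target


class CandidateError(ValueError):
    """Candidate generation failure."""


def required_candidate_count(reference_isocenter_count: int) -> int:
    """Minimum candidate count: 140% of the reference plan's isocenter count
    or six, whichever is greater."""
    n = int(reference_isocenter_count)
    if n < 1:
        raise CandidateError("reference isocenter count must be at least 1")
    return max(math.ceil(1.4 * n), 6)


@dataclass
class CandidateEntry:
    """Candidates for one target.

    ``sphere_diameters_mm`` records the generating sphere diameter of each
    candidate; 0 marks the appended centroid candidate.
    """

    target_id: str
    method: str  # {"hcp", "grassfire"}
    diameter_mm: float  # final packing diameter (HCP) or largest placed (grassfire)
    positions_mm: np.ndarray  # (k, 3)
    required: int
    reference_count: int | None = None
    sphere_diameters_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sphere_diameters_mm is None:
            self.sphere_diameters_mm = np.full(len(self.positions_mm), self.diameter_mm)

    @property
    def count(self) -> int:
        return len(self.positions_mm)

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "method": self.method,
            "diameter_mm": self.diameter_mm,
            "positions_mm": np.asarray(self.positions_mm).tolist(),
            "sphere_diameters_mm": np.asarray(self.sphere_diameters_mm).tolist(),
            "required": self.required,
            "reference_count": self.reference_count,
        }


@dataclass
class CandidateSet:
    """Per-target candidate entries for a phantom."""

    entries: list[CandidateEntry]

    def positions_and_targets(self) -> tuple[np.ndarray, np.ndarray]:
        """All positions stacked, with the index of the owning target."""
        pos = np.vstack([e.positions_mm for e in self.entries])
        tgt = np.concatenate(
            [np.full(e.count, k, dtype=int) for k, e in enumerate(self.entries)]
        )
        return pos, tgt

    def to_json(self) -> str:
        return json.dumps([e.to_dict() for e in self.entries], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CandidateSet":
        entries = [
            CandidateEntry(
                target_id=d["target_id"],
                method=d["method"],
                diameter_mm=d["diameter_mm"],
                positions_mm=np.asarray(d["positions_mm"], dtype=float),
                required=d["required"],
                reference_count=d.get("reference_count"),
                sphere_diameters_mm=(
                    np.asarray(d["sphere_diameters_mm"], dtype=float)
                    if "sphere_diameters_mm" in d
                    else None
                ),
            )
            for d in json.loads(text)
        ]
        return cls(entries)


def _in_target(positions_mm: np.ndarray, target: Target, grid: VoxelGrid) -> np.ndarray:
    """Center-voxel containment test (full-sphere containment is not required)."""
    vox = grid.world_to_voxel(positions_mm)
    ok = grid.contains_index(vox)
    inside = np.zeros(len(positions_mm), dtype=bool)
    if ok.any():
        sel = vox[ok]
        inside[ok] = target.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
    return inside


def _hcp_lattice(center: np.ndarray, spacing: float, radius: float) -> np.ndarray:
    """HCP lattice points with nearest-neighbor distance ``spacing`` within
    ``radius`` of ``center``, in deterministic lexicographic basis order."""
    a1 = np.array([spacing, 0.0, 0.0])
    a2 = np.array([spacing / 2.0, spacing * math.sqrt(3.0) / 2.0, 0.0])
    a3 = np.array([spacing / 2.0, spacing * math.sqrt(3.0) / 6.0, spacing * math.sqrt(2.0 / 3.0)])
    n_max = int(math.ceil(radius / spacing)) * 2 + 2
    n = np.arange(-n_max, n_max + 1)
    n1, n2, n3 = np.meshgrid(n, n, n, indexing="ij")
    # C-order flattening keeps a deterministic lexicographic basis order.
    offsets = (
        n1.ravel()[:, None] * a1 + n2.ravel()[:, None] * a2 + n3.ravel()[:, None] * a3
    )
    keep = (offsets**2).sum(axis=1) <= radius**2
    return center + offsets[keep] if keep.any() else np.empty((0, 3))


def hcp_candidates(
    target: Target,
    grid: VoxelGrid,
    required: int,
    start_diameter_mm: float = 4.0,
    decrement_mm: float = 0.5,
    reference_count: int | None = None,
) -> CandidateEntry:
    """Iterative HCP sphere packing anchored at the target centroid.

    Sphere centers at the current packing diameter are kept when their voxel
    lies inside the target; the centroid itself is always appended. If fewer
    than ``required`` candidates result, the diameter shrinks by
    ``decrement_mm`` and packing is retried. Fails explicitly once the
    diameter would drop below one voxel spacing.
    """
    if required < 1:
        raise CandidateError("required candidate count must be at least 1")
    if not (start_diameter_mm > decrement_mm > 0):
        raise CandidateError("need start_diameter > decrement > 0")
    centroid = target.centroid_world(grid)
    idx = np.argwhere(target.mask)
    extent = np.linalg.norm(grid.voxel_to_world(idx) - centroid, axis=1).max()
    min_spacing = min(grid.spacing)

    diameter = float(start_diameter_mm)
    while True:
        pts = _hcp_lattice(centroid, diameter, extent + diameter)
        if len(pts):
            pts = pts[_in_target(pts, target, grid)]
        # Deterministic ordering by voxel index.
        if len(pts):
            order = np.lexsort(grid.world_to_voxel(pts).T[::-1])
            pts = pts[order]
        diams = np.full(len(pts), diameter)
        positions, diams = _append_centroid(pts, diams, centroid, grid)
        keep = _in_target(positions, target, grid)
        positions, diams = positions[keep], diams[keep]
        if len(positions) >= required:
            return CandidateEntry(
                target_id=target.id,
                method="hcp",
                diameter_mm=diameter,
                positions_mm=positions,
                required=required,
                reference_count=reference_count,
                sphere_diameters_mm=diams,
            )
        diameter -= decrement_mm
        if diameter < min_spacing:
            raise CandidateError(
                f"target {target.id!r}: packing diameter fell below one voxel "
                f"({min_spacing} mm) with only {len(positions)} of {required} candidates"
            )


def _append_centroid(
    pts: np.ndarray, diams: np.ndarray, centroid: np.ndarray, grid: VoxelGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Append the centroid candidate (diameter tag 0) unless a candidate
    already occupies its voxel."""
    cvox = grid.world_to_voxel(centroid)
    if len(pts):
        same = (grid.world_to_voxel(pts) == cvox).all(axis=1)
        if same.any():
            return pts, diams
        return np.vstack([pts, centroid]), np.append(diams, 0.0)
    return centroid[None, :], np.array([0.0])


def grassfire_candidates(
    target: Target,
    grid: VoxelGrid,
    required: int,
    diameters_mm: tuple[float, ...] = (4.0, 3.0, 2.0),
    reference_count: int | None = None,
) -> CandidateEntry:
    """Grassfire + sphere-packing candidates.

    Repeatedly places the largest listed sphere that fits at the deepest
    voxel of the working mask (interior distance transform), carves it out,
    and recomputes; proceeds to smaller diameters when the larger no longer
    fits. Ties at equal depth break lexicographically by voxel index, making
    the ordered candidate list deterministic.
    """
    if list(diameters_mm) != sorted(diameters_mm, reverse=True):
        raise CandidateError("diameters must be strictly decreasing")
    if required < 1:
        raise CandidateError("required candidate count must be at least 1")
    spacing = np.asarray(grid.spacing)
    working = target.mask.copy()
    placed: list[np.ndarray] = []
    placed_diams: list[float] = []
    largest_placed = 0.0
    for diam in diameters_mm:
        radius = diam / 2.0
        while working.any():
            dist = ndimage.distance_transform_edt(working, sampling=spacing)
            dmax = dist.max()
            if dmax < radius:
                break
            # np.argmax on the C-ordered array is the lexicographically
            # smallest voxel among ties.
            vox = np.unravel_index(int(np.argmax(dist)), dist.shape)
            center = grid.voxel_to_world(np.array(vox))
            placed.append(center)
            placed_diams.append(diam)
            largest_placed = max(largest_placed, diam)
            # Carve the sphere out of the working mask.
            xs, ys, zs = grid.axes_coordinates()
            d2 = (
                ((xs - center[0]) ** 2)[:, None, None]
                + ((ys - center[1]) ** 2)[None, :, None]
                + ((zs - center[2]) ** 2)[None, None, :]
            )
            working &= d2 > radius**2
    pts = np.array(placed) if placed else np.empty((0, 3))
    diams = np.array(placed_diams)
    positions, diams = _append_centroid(pts, diams, target.centroid_world(grid), grid)
    keep = _in_target(positions, target, grid)
    positions, diams = positions[keep], diams[keep]
    return CandidateEntry(
        target_id=target.id,
        method="grassfire",
        diameter_mm=largest_placed or float(diameters_mm[0]),
        positions_mm=positions,
        required=required,
        reference_count=reference_count,
        sphere_diameters_mm=diams,
    )


def generate_candidates(
    phantom,
    required: int | None = None,
    reference_count: int | None = None,
    method: str = "hcp",
    **kwargs,
) -> CandidateSet:
    """Candidates for every target of a phantom with one strategy.

    ``required`` defaults to the 140%/six rule applied to ``reference_count``.
    """
    if required is None:
        if reference_count is None:
            raise CandidateError("provide either required or reference_count")
        required = required_candidate_count(reference_count)
    gen = {"hcp": hcp_candidates, "grassfire": grassfire_candidates}.get(method)
    if gen is None:
        raise CandidateError(f"unknown candidate method {method!r}")
    entries = [
        gen(t, phantom.grid, required=required, reference_count=reference_count, **kwargs)
        for t in phantom.targets
    ]
    return CandidateSet(entries)
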