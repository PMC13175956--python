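"""File formats: NIfTI volumes, YAML configs, JSON artifacts.

Volumes (skull, masks, dose, prediction) are stored one per ``.nii.gz`` file
with the grid's spacing/origin in the affine. Kernels are cached as a single
NIfTI stack (x, y, z, sector*collimator) plus a JSON index of candidate
positions and offsets.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import VoxelGrid
from .kernels import N_COLLIMATORS, N_SECTORS, CentralKernel, KernelSet
from .phantom import Phantom, PhantomSpec, Target, TargetSpec


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_json(path: Path | str, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def read_json(path: Path | str):
    return json.loads(Path(path).read_text())


def write_yaml(path: Path | str, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: Path | str):
    return yaml.safe_load(Path(path).read_text())


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def save_volume(path: Path | str, array: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), grid.affine())
    nib.save(img, str(path))


def load_volume(path: Path | str) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    aff = img.affine
    grid = VoxelGrid(
        shape=tuple(int(n) for n in img.shape[:3]),
        spacing=tuple(float(abs(aff[k, k])) for k in range(3)),
        origin=tuple(float(aff[k, 3]) for k in range(3)),
    )
    return np.asarray(img.get_fdata()), grid


def save_mask(path: Path | str, mask: np.ndarray, grid: VoxelGrid) -> None:
    save_volume(path, mask.astype(np.uint8), grid)


def load_mask(path: Path | str) -> tuple[np.ndarray, VoxelGrid]:
    arr, grid = load_volume(path)
    return arr > 0.5, grid


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


def save_phantom(directory: Path | str, phantom: Phantom) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_mask(d / "skull.nii.gz", phantom.skull_mask, phantom.grid)
    meta = {"calibration_dose": phantom.calibration_dose, "targets": []}
    for t in phantom.targets:
        save_mask(d / f"target_{t.id}.nii.gz", t.mask, phantom.grid)
        save_mask(d / f"shell_s_{t.id}.nii.gz", t.shell_s, phantom.grid)
        save_mask(d / f"shell_g_{t.id}.nii.gz", t.shell_g, phantom.grid)
        meta["targets"].append(
            {
                "id": t.id,
                "prescription_dose": t.prescription_dose,
                "dose_s": t.dose_s,
                "dose_g": t.dose_g,
            }
        )
    write_json(d / "phantom.json", meta)


def load_phantom(directory: Path | str) -> Phantom:
    d = Path(directory)
    meta = read_json(d / "phantom.json")
    skull, grid = load_mask(d / "skull.nii.gz")
    targets = []
    for tm in meta["targets"]:
        mask, _ = load_mask(d / f"target_{tm['id']}.nii.gz")
        shell_s, _ = load_mask(d / f"shell_s_{tm['id']}.nii.gz")
        shell_g, _ = load_mask(d / f"shell_g_{tm['id']}.nii.gz")
        targets.append(
            Target(
                id=tm["id"],
                mask=mask,
                prescription_dose=tm["prescription_dose"],
                shell_s=shell_s,
                shell_g=shell_g,
                dose_s=tm["dose_s"],
                dose_g=tm["dose_g"],
            )
        )
    return Phantom(
        grid=grid, skull_mask=skull, targets=targets,
        calibration_dose=meta["calibration_dose"],
    )


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    targets = [TargetSpec(**t) for t in d.pop("targets")]
    for key in ("grid_shape", "spacing_mm", "skull_semi_axes_mm"):
        if key in d:
            d[key] = tuple(d[key])
    for t in targets:
        t.axis_ratios = tuple(t.axis_ratios)
        t.center_offset_mm = tuple(t.center_offset_mm)
    return PhantomSpec(targets=targets, **d)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def save_kernels(directory: Path | str, kernels: KernelSet) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    central = kernels.central
    stack = np.moveaxis(
        central.rates.reshape((N_SECTORS * N_COLLIMATORS,) + central.grid.shape), 0, -1
    )
    save_volume(d / "central_kernel.nii.gz", stack, central.grid)
    save_mask(d / "kernel_skull.nii.gz", kernels.skull_mask, central.grid)
    write_json(
        d / "kernels.json",
        {
            "collimators_mm": list(central.collimators_mm),
            "center_index": list(central.center_index),
            "dose_rate_scale": central.dose_rate_scale,
            "candidates": [
                {
                    "index": i,
                    "position_mm": kernels.positions_mm[i].tolist(),
                    "voxel_offset": kernels.offsets[i].tolist(),
                    "target_index": int(kernels.target_index[i]),
                }
                for i in range(kernels.n_isocenters)
            ],
        },
    )


def load_kernels(directory: Path | str) -> KernelSet:
    d = Path(directory)
    meta = read_json(d / "kernels.json")
    stack, grid = load_volume(d / "central_kernel.nii.gz")
    skull, _ = load_mask(d / "kernel_skull.nii.gz")
    rates = np.moveaxis(stack, -1, 0).reshape((N_SECTORS, N_COLLIMATORS) + grid.shape)
    central = CentralKernel(
        grid=grid,
        rates=rates,
        collimators_mm=tuple(meta["collimators_mm"]),
        center_index=tuple(meta["center_index"]),
        dose_rate_scale=meta["dose_rate_scale"],
    )
    cands = meta["candidates"]
    return KernelSet(
        central=central,
        skull_mask=skull,
        positions_mm=np.array([c["position_mm"] for c in cands]),
        offsets=np.array([c["voxel_offset"] for c in cands], dtype=int),
        target_index=np.array([c["target_index"] for c in cands], dtype=int),
    )
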