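"""NIfTI, JSON and YAML serialization helpers.

Volumes are stored with spatial axes first (slice, row, col); 4D stacks put
the acquisition axis last in the file and first in memory. Voxel sizes are
recorded in the NIfTI header in mm (1 um = 1e-3 mm).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from plaquemap.errors import InputError
from plaquemap.relaxometry import T1FitResult, T2StarFitResult
from plaquemap.synthetic import AcquisitionProtocol, Phantom, SignalStack


def _affine(voxel_size_um: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size_um):
        aff[i, i] = v * 1e-3
    return aff


def save_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_size_um: tuple[float, float, float] = (120.0, 120.0, 120.0),
    descrip: str = "",
) -> None:
    """Write a 3D volume or a 4D stack (acquisition axis first) as NIfTI."""
    arr = np.asarray(data)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, 0, -1)
    elif arr.ndim != 3:
        raise InputError("save_volume expects a 3D or 4D array")
    img = nib.Nifti1Image(arr.astype(np.float64), _affine(voxel_size_um))
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; 4D files come back with the acquisition axis first."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, -1, 0)
    zooms = img.header.get_zooms()[:3]
    voxel_um = tuple(float(z) * 1e3 for z in zooms)
    return arr, voxel_um


def save_phantom(phantom: Phantom, outdir: str | Path) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (
        ("labels", phantom.labels.astype(np.float64)),
        ("t1_true", phantom.t1_true),
        ("t2s_true", phantom.t2s_true),
        ("m0_true", phantom.m0_true),
    ):
        p = outdir / f"{name}.nii.gz"
        save_volume(vol, p, phantom.voxel_size_um, descrip=f"{name} (ms)" if "t" in name else name)
        paths[name] = str(p)
    meta = {
        "plaque_id": phantom.plaque_id,
        "class_ids": phantom.class_ids,
        "voxel_size_um": list(phantom.voxel_size_um),
    }
    mp = outdir / "phantom_meta.json"
    mp.write_text(json.dumps(meta, indent=1))
    paths["meta"] = str(mp)
    return paths


def load_phantom(outdir: str | Path) -> Phantom:
    outdir = Path(outdir)
    meta = json.loads((outdir / "phantom_meta.json").read_text())
    labels, voxel_um = load_volume(outdir / "labels.nii.gz")
    t1, _ = load_volume(outdir / "t1_true.nii.gz")
    t2s, _ = load_volume(outdir / "t2s_true.nii.gz")
    m0, _ = load_volume(outdir / "m0_true.nii.gz")
    return Phantom(
        labels=np.rint(labels).astype(np.int16),
        t1_true=t1,
        t2s_true=t2s,
        m0_true=m0,
        class_ids={k: int(v) for k, v in meta["class_ids"].items()},
        voxel_size_um=tuple(meta["voxel_size_um"]),
        plaque_id=meta["plaque_id"],
    )


def save_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(protocol), indent=1))


def load_protocol(path: str | Path) -> AcquisitionProtocol:
    p = json.loads(Path(path).read_text())
    p["flip_angles"] = tuple(p.get("flip_angles") or ())
    p["echo_times"] = tuple(p.get("echo_times") or ())
    return AcquisitionProtocol(**p)


def save_stack(
    stack: SignalStack,
    outdir: str | Path,
    name: str,
    voxel_size_um=(120.0, 120.0, 120.0),
) -> None:
    """Write ``{name}.nii.gz`` plus ``{name}_protocol.json`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(
        stack.frames, outdir / f"{name}.nii.gz", voxel_size_um,
        descrip=f"{stack.protocol.mode} stack",
    )
    save_protocol(stack.protocol, outdir / f"{name}_protocol.json")


def load_stack(outdir: str | Path, name: str, phantom_id: str = "phantom") -> SignalStack:
    outdir = Path(outdir)
    frames, _ = load_volume(outdir / f"{name}.nii.gz")
    protocol = load_protocol(outdir / f"{name}_protocol.json")
    return SignalStack(frames=frames, protocol=protocol, phantom_id=phantom_id)


def save_t1_result(res: T1FitResult, outdir: str | Path, voxel_size_um) -> None:
    outdir = Path(outdir)
    save_volume(res.t1_map, outdir / "t1_map.nii.gz", voxel_size_um, "T1 (ms)")
    save_volume(res.m0_map, outdir / "m0_map.nii.gz", voxel_size_um, "M0 (a.u.)")
    save_volume(
        res.valid_mask.astype(np.float64), outdir / "t1_valid.nii.gz", voxel_size_um, "mask"
    )


def load_t1_result(outdir: str | Path) -> T1FitResult:
    outdir = Path(outdir)
    t1, _ = load_volume(outdir / "t1_map.nii.gz")
    m0, _ = load_volume(outdir / "m0_map.nii.gz")
    valid, _ = load_volume(outdir / "t1_valid.nii.gz")
    valid = valid > 0.5
    with np.errstate(invalid="ignore"):
        slope = np.where(valid, np.exp(-1.0), np.nan)  # slope not persisted
    return T1FitResult(t1_map=t1, m0_map=m0, valid_mask=valid, slope_map=slope)


def save_t2s_result(res: T2StarFitResult, outdir: str | Path, voxel_size_um) -> None:
    outdir = Path(outdir)
    save_volume(res.t2s_map, outdir / "t2s_map.nii.gz", voxel_size_um, "T2* (ms)")
    save_volume(res.s0_map, outdir / "s0_map.nii.gz", voxel_size_um, "S0 (a.u.)")
    save_volume(
        res.valid_mask.astype(np.float64), outdir / "t2s_valid.nii.gz", voxel_size_um, "mask"
    )


def load_t2s_result(outdir: str | Path) -> T2StarFitResult:
    outdir = Path(outdir)
    t2s, _ = load_volume(outdir / "t2s_map.nii.gz")
    s0, _ = load_volume(outdir / "s0_map.nii.gz")
    valid, _ = load_volume(outdir / "t2s_valid.nii.gz")
    return T2StarFitResult(t2s_map=t2s, s0_map=s0, valid_mask=valid > 0.5)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
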