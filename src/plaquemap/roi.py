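"""ROI sampling on labeled phantoms, predictor extraction and class summaries.

An ROI is a small (4-9 voxel) 4-connected blob within one axial slice, all
of whose voxels carry one tissue label. Seven predictors are computed per
ROI from the registered T1/T2* maps: mean, sd, min and max of T1; mean and
sd of T2*; and the pixel count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from plaquemap.errors import InputError, SamplingError
from plaquemap.relaxometry import RelaxationMaps
from plaquemap.synthetic import Phantom

logger = logging.getLogger(__name__)

ROI_SIZE_MIN = 4
ROI_SIZE_MAX = 9

#: predictor order used everywhere downstream (QDA, CSV columns)
PREDICTORS = ("mean_t1", "mean_t2s", "sd_t1", "sd_t2s", "max_t1", "min_t1", "n_pixels")


def _is_4connected(voxels: Sequence[tuple[int, int, int]]) -> bool:
    vset = set(voxels)
    seen = {voxels[0]}
    stack = [voxels[0]]
    while stack:
        s, r, c = stack.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (s, r + dr, c + dc)
            if nb in vset and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(vset)


@dataclass(frozen=True)
class ROIDefinition:
    """A 4-9 voxel, single-slice, 4-connected region with one tissue label."""

    roi_id: str
    plaque_id: str
    tissue_label: str
    voxels: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.voxels)
        if not ROI_SIZE_MIN <= n <= ROI_SIZE_MAX:
            raise InputError(f"ROI {self.roi_id}: size {n} outside [4, 9]")
        if len(set(self.voxels)) != n:
            raise InputError(f"ROI {self.roi_id}: duplicate voxels")
        if len({v[0] for v in self.voxels}) != 1:
            raise InputError(f"ROI {self.roi_id}: voxels span multiple slices")
        if not _is_4connected(self.voxels):
            raise InputError(f"ROI {self.roi_id}: voxels are not 4-connected")

    @property
    def slice_plane(self) -> int:
        return self.voxels[0][0]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class ROIFeatureVector:
    """The seven QDA predictors for one ROI, with identifiers carried through."""

    roi_id: str
    plaque_id: str
    tissue_label: str
    mean_t1: float
    mean_t2s: float
    sd_t1: float
    sd_t2s: float
    max_t1: float
    min_t1: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not (self.min_t1 <= self.mean_t1 <= self.max_t1):
            raise InputError(f"ROI {self.roi_id}: min/mean/max T1 out of order")
        if self.sd_t1 < 0 or self.sd_t2s < 0:
            raise InputError(f"ROI {self.roi_id}: negative sd")
        if not ROI_SIZE_MIN <= self.n_pixels <= ROI_SIZE_MAX:
            raise InputError(f"ROI {self.roi_id}: n_pixels outside [4, 9]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PREDICTORS], dtype=float)


def _grow_blob(
    start: tuple[int, int, int],
    target: int,
    allowed: set[tuple[int, int, int]],
    rng: np.random.Generator,
) -> tuple[tuple[int, int, int], ...] | None:
    """Randomly grow a 4-connected in-slice blob; None if it gets stuck."""
    s = start[0]
    blob = [start]
    members = {start}
    frontier: list[tuple[int, int, int]] = []

    def push_neighbors(v):
        _, r, c = v
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (s, r + dr, c + dc)
            if nb in allowed and nb not in members:
                frontier.append(nb)

    push_neighbors(start)
    while len(blob) < target:
        while frontier:
            i = int(rng.integers(len(frontier)))
            cand = frontier.pop(i)
            if cand not in members:
                break
        else:
            return None
        members.add(cand)
        blob.append(cand)
        push_neighbors(cand)
    return tuple(blob)


def sample_rois(
    phantom: Phantom,
    n_per_class: Mapping[str, int],
    size_range: tuple[int, int] = (ROI_SIZE_MIN, ROI_SIZE_MAX),
    seed: int = 0,
) -> list[ROIDefinition]:
    """Sample labeled ROIs from the phantom's ground-truth label volume.

    Each ROI is a random 4-connected single-slice blob whose voxels all
    carry the requested class label; sizes are uniform over ``size_range``.
    Raises :class:`SamplingError` naming the class when a class lacks
    enough homogeneous in-slice voxels.
    """
    lo, hi = size_range
    if not (ROI_SIZE_MIN <= lo <= hi <= ROI_SIZE_MAX):
        raise InputError(f"size_range {size_range} outside [4, 9]")
    rng = np.random.default_rng(seed)
    rois: list[ROIDefinition] = []
    counter = 0
    for label, count in n_per_class.items():
        if count == 0:
            continue
        if label not in phantom.class_ids:
            raise SamplingError(f"class {label!r} is not defined in the phantom")
        cid = phantom.class_ids[label]
        coords = np.argwhere(phantom.labels == cid)
        if coords.shape[0] < lo:
            raise SamplingError(
                f"class {label!r}: only {coords.shape[0]} voxels available"
            )
        allowed = {tuple(map(int, v)) for v in coords}
        coords_list = [tuple(map(int, v)) for v in coords]
        for _ in range(count):
            target = int(rng.integers(lo, hi + 1))
            blob = None
            for _attempt in range(200):
                start = coords_list[int(rng.integers(len(coords_list)))]
                blob = _grow_blob(start, target, allowed, rng)
                if blob is not None:
                    break
            if blob is None:
                raise SamplingError(
                    f"class {label!r}: could not grow a {target}-voxel ROI "
                    f"after 200 attempts"
                )
            counter += 1
            rois.append(
                ROIDefinition(
                    roi_id=f"roi{counter:05d}",
                    plaque_id=phantom.plaque_id,
                    tissue_label=label,
                    voxels=blob,
                )
            )
    return rois


def extract_features(
    maps: RelaxationMaps,
    rois: Iterable[ROIDefinition],
    rejects: list[tuple[str, str]] | None = None,
) -> list[ROIFeatureVector]:
    """Compute the seven predictors for each ROI over its valid voxels.

    Statistics use the sample standard deviation (n-1). ROIs retaining
    fewer than 4 valid voxels are dropped with a logged warning; pass
    ``rejects`` to collect (roi_id, reason) pairs for the dropped ones.
    """
    if not maps.registered:
        raise InputError("maps must be registered on one grid")
    shape = maps.grid_shape
    t1 = maps.t1.t1_map
    t2s = maps.t2s.t2s_map
    valid = maps.t1.valid_mask & maps.t2s.valid_mask
    out: list[ROIFeatureVector] = []
    for roi in rois:
        idx = np.array(roi.voxels)
        if (idx < 0).any() or (idx >= np.array(shape)).any():
            raise InputError(f"ROI {roi.roi_id}: voxel outside the map grid")
        sel = tuple(idx.T)
        ok = valid[sel]
        n_valid = int(ok.sum())
        if n_valid < ROI_SIZE_MIN:
            reason = f"only {n_valid} valid voxels (< {ROI_SIZE_MIN})"
            logger.warning("dropping ROI %s: %s", roi.roi_id, reason)
            if rejects is not None:
                rejects.append((roi.roi_id, reason))
            continue
        v1 = t1[sel][ok]
        v2 = t2s[sel][ok]
        # summation order can push the mean one ulp past the extremes
        mean_t1 = float(np.clip(v1.mean(), v1.min(), v1.max()))
        out.append(
            ROIFeatureVector(
                roi_id=roi.roi_id,
                plaque_id=roi.plaque_id,
                tissue_label=roi.tissue_label,
                mean_t1=mean_t1,
                mean_t2s=float(v2.mean()),
                sd_t1=float(v1.std(ddof=1)),
                sd_t2s=float(v2.std(ddof=1)),
                max_t1=float(v1.max()),
                min_t1=float(v1.min()),
                n_pixels=n_valid,
            )
        )
    return out


def summarize_classes(features: Sequence[ROIFeatureVector]) -> pd.DataFrame:
    """Per-class summary of ROI-level mean T1 and mean T2*.

    One row per (class, parameter) with n_roi, min, max, mean, sample sd
    and range = max - min. A single-ROI class reports sd = 0 by convention.
    """
    if not features:
        raise InputError("summarize_classes requires a non-empty feature list")
    rows = []
    frame = features_to_frame(features)
    for label, grp in frame.groupby("tissue_label", sort=False):
        for param in ("mean_t1", "mean_t2s"):
            vals = grp[param].to_numpy()
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "tissue_label": label,
                    "parameter": param,
                    "n_roi": len(vals),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "mean": float(vals.mean()),
                    "sd": sd,
                    "range": float(vals.max()) - float(vals.min()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization: one CSV row per voxel for ROI definitions; flat CSV for
# features; JSON mirrors of both


def rois_to_frame(rois: Sequence[ROIDefinition]) -> pd.DataFrame:
    rows = [
        {
            "roi_id": r.roi_id,
            "plaque_id": r.plaque_id,
            "tissue_label": r.tissue_label,
            "slice": v[0],
            "row": v[1],
            "col": v[2],
        }
        for r in rois
        for v in r.voxels
    ]
    return pd.DataFrame(
        rows, columns=["roi_id", "plaque_id", "tissue_label", "slice", "row", "col"]
    )


def frame_to_rois(frame: pd.DataFrame) -> list[ROIDefinition]:
    required = {"roi_id", "plaque_id", "tissue_label", "slice", "row", "col"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"ROI table missing columns: {sorted(missing)}")
    rois = []
    for roi_id, grp in frame.groupby("roi_id", sort=False):
        voxels = tuple(
            (int(s), int(r), int(c))
            for s, r, c in zip(grp["slice"], grp["row"], grp["col"])
        )
        rois.append(
            ROIDefinition(
                roi_id=str(roi_id),
                plaque_id=str(grp["plaque_id"].iloc[0]),
                tissue_label=str(grp["tissue_label"].iloc[0]),
                voxels=voxels,
            )
        )
    return rois


def write_rois_csv(rois: Sequence[ROIDefinition], path: str | Path) -> None:
    rois_to_frame(rois).to_csv(path, index=False)


def read_rois_csv(path: str | Path) -> list[ROIDefinition]:
    return frame_to_rois(pd.read_csv(path))


def write_rois_json(rois: Sequence[ROIDefinition], path: str | Path) -> None:
    payload = [
        {
            "roi_id": r.roi_id,
            "plaque_id": r.plaque_id,
            "tissue_label": r.tissue_label,
            "voxels": [list(v) for v in r.voxels],
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois_json(path: str | Path) -> list[ROIDefinition]:
    payload = json.loads(Path(path).read_text())
    return [
        ROIDefinition(
            roi_id=item["roi_id"],
            plaque_id=item["plaque_id"],
            tissue_label=item["tissue_label"],
            voxels=tuple(tuple(int(x) for x in v) for v in item["voxels"]),
        )
        for item in payload
    ]


def features_to_frame(features: Sequence[ROIFeatureVector]) -> pd.DataFrame:
    cols = ["roi_id", "plaque_id", "tissue_label", *PREDICTORS]
    return pd.DataFrame(
        [{c: getattr(f, c) for c in cols} for f in features], columns=cols
    )


def frame_to_features(frame: pd.DataFrame) -> list[ROIFeatureVector]:
    required = {"roi_id", "plaque_id", "tissue_label", *PREDICTORS}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"feature table missing columns: {sorted(missing)}")
    return [
        ROIFeatureVector(
            roi_id=str(row.roi_id),
            plaque_id=str(row.plaque_id),
            tissue_label=str(row.tissue_label),
            mean_t1=float(row.mean_t1),
            mean_t2s=float(row.mean_t2s),
            sd_t1=float(row.sd_t1),
            sd_t2s=float(row.sd_t2s),
            max_t1=float(row.max_t1),
            min_t1=float(row.min_t1),
            n_pixels=int(row.n_pixels),
        )
        for row in frame.itertuples()
    ]


def write_features_csv(features: Sequence[ROIFeatureVector], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[ROIFeatureVector]:
    return frame_to_features(pd.read_csv(path))
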