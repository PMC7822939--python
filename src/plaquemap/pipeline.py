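"""End-to-end orchestration: simulate -> fit maps -> ROIs -> QDA -> report.

Every stage is pure given its inputs and a seed derived deterministically
from the master seed, so re-running a config reproduces byte-identical
CSV/JSON outputs. Stages communicate through files in one run directory:

    <out>/plaques/<plaque_id>/   phantom + stacks + fitted maps
    <out>/rois.csv, features.csv, summary.csv
    <out>/models/<scope>.json, predictions.csv, excluded.json
    <out>/report.json, report.csv, scatter.csv, manifest.json
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from plaquemap import io as pio
from plaquemap.errors import ConfigurationError, PlaquemapError
from plaquemap.qda import POOLED, Prediction, classify, fit_qda, misclassification_report
from plaquemap.relaxometry import RelaxationMaps, fit_t1_vfa, fit_t2star
from plaquemap.roi import (
    extract_features,
    frame_to_features,
    read_rois_csv,
    sample_rois,
    summarize_classes,
    write_features_csv,
    write_rois_csv,
)
from plaquemap.synthetic import (
    DEFAULT_CLASSES,
    TISSUE_CLASSES,
    AcquisitionProtocol,
    PhantomSpec,
    Region,
    TissueClassSpec,
    generate_phantom,
    simulate_acquisition,
    zero_fill,
)

logger = logging.getLogger(__name__)

_STAGE_CODES = {"phantom": 1, "vfa": 2, "multiecho": 3, "roi": 4}


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage, per-item seed from the master seed."""
    ss = np.random.SeedSequence([int(master), _STAGE_CODES[stage], int(index)])
    return int(ss.generate_state(1)[0])


def quadrant_regions(
    grid_shape: tuple[int, int, int],
    classes_present: Sequence[str],
    margin: int = 2,
) -> tuple[Region, ...]:
    """Four in-plane quadrant boxes cycling through the present classes."""
    if not classes_present:
        raise ConfigurationError("classes_present must be non-empty")
    s, r, c = grid_shape
    rm, cm = r // 2, c // 2
    spans_r = [(margin, rm - 1), (rm + 1, r - 1 - margin)]
    spans_c = [(margin, cm - 1), (cm + 1, c - 1 - margin)]
    quads = [(sr, sc) for sr in spans_r for sc in spans_c]
    regions = []
    for i, ((r0, r1), (c0, c1)) in enumerate(quads):
        label = classes_present[i % len(classes_present)]
        regions.append(
            Region(
                shape="box",
                label=label,
                center=((s - 1) / 2, (r0 + r1) / 2, (c0 + c1) / 2),
                half_size=((s - 1) / 2 + 0.25, (r1 - r0) / 2, (c1 - c0) / 2),
            )
        )
    return tuple(regions)


@dataclass
class PhantomPlan:
    plaque_id: str
    grid_shape: tuple[int, int, int] = (4, 44, 44)
    classes_present: tuple[str, ...] = TISSUE_CLASSES
    voxel_size_um: tuple[float, float, float] = (120.0, 120.0, 120.0)
    regions: tuple[Region, ...] | None = None  # explicit layout overrides quadrants

    def spec(self, seed: int) -> PhantomSpec:
        regions = self.regions or quadrant_regions(self.grid_shape, self.classes_present)
        return PhantomSpec(
            grid_shape=tuple(self.grid_shape),
            regions=tuple(regions),
            voxel_size_um=tuple(self.voxel_size_um),
            seed=seed,
            plaque_id=self.plaque_id,
        )


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a single YAML file."""

    seed: int = 0
    classes: dict[str, TissueClassSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    phantoms: list[PhantomPlan] = field(default_factory=list)
    vfa: dict = field(default_factory=dict)
    multiecho: dict = field(default_factory=dict)
    n_per_class: dict[str, int] = field(default_factory=dict)
    roi_size_range: tuple[int, int] = (4, 9)
    scope: str = "per_plaque"
    shrinkage: float = 0.1
    priors: str = "empirical"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        for plan in self.phantoms:
            for label in plan.classes_present:
                if label not in self.classes:
                    raise ConfigurationError(f"class {label!r} not defined")
        for label in self.n_per_class:
            if label not in self.classes:
                raise ConfigurationError(f"ROI plan names unknown class {label!r}")

    def vfa_protocol(self, seed: int) -> AcquisitionProtocol:
        kw = {
            "tr": 10.0,
            "flip_angles": (5.0, 10.0, 20.0, 30.0, 40.0),
            "te_fixed": 2.0,
            "noise_model": "rician",
            "noise_sigma": 0.0,
            "zero_fill_factor": 1,
        }
        kw.update(self.vfa)
        kw["flip_angles"] = tuple(kw["flip_angles"])
        return AcquisitionProtocol(mode="vfa", seed=seed, **kw)

    def multiecho_protocol(self, seed: int) -> AcquisitionProtocol:
        kw = {
            "tr": 22.0,
            "echo_times": (4.0, 8.0, 12.0, 16.0, 20.0),
            "flip_angle": 10.0,
            "noise_model": "rician",
            "noise_sigma": 0.0,
            "zero_fill_factor": 1,
        }
        kw.update(self.multiecho)
        kw["echo_times"] = tuple(kw["echo_times"])
        return AcquisitionProtocol(mode="multiecho", seed=seed, **kw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        classes = dict(DEFAULT_CLASSES)
        raw_classes = raw.get("classes", "default")
        if isinstance(raw_classes, dict):
            for name, kw in raw_classes.items():
                classes[name] = TissueClassSpec(name=name, **kw)
        phantoms = []
        for p in raw.get("phantoms", []):
            regions = None
            if "regions" in p:
                regions = tuple(
                    Region(
                        shape=r["shape"],
                        label=r["label"],
                        center=tuple(r["center"]),
                        half_size=tuple(r["half_size"]),
                    )
                    for r in p["regions"]
                )
            phantoms.append(
                PhantomPlan(
                    plaque_id=str(p["plaque_id"]),
                    grid_shape=tuple(p.get("grid_shape", (4, 44, 44))),
                    classes_present=tuple(p.get("classes_present", TISSUE_CLASSES)),
                    voxel_size_um=tuple(p.get("voxel_size_um", (120.0, 120.0, 120.0))),
                    regions=regions,
                )
            )
        protocols = raw.get("protocols", {})
        roi_raw = raw.get("roi_sampling", {})
        qda_raw = raw.get("qda", {})
        return cls(
            seed=int(raw.get("seed", 0)),
            classes=classes,
            phantoms=phantoms,
            vfa=dict(protocols.get("vfa", {})),
            multiecho=dict(protocols.get("multiecho", {})),
            n_per_class={str(k): int(v) for k, v in roi_raw.get("n_per_class", {}).items()},
            roi_size_range=tuple(roi_raw.get("size_range", (4, 9))),
            scope=str(qda_raw.get("scope", "per_plaque")),
            shrinkage=float(qda_raw.get("shrinkage", 0.1)),
            priors=str(qda_raw.get("priors", "empirical")),
            ci_level=float(qda_raw.get("ci_level", 0.95)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(pio.load_yaml(path))

    @classmethod
    def default(cls) -> "RunConfig":
        from importlib import resources

        with resources.files("plaquemap.data").joinpath("default_config.yaml").open() as fh:
            import yaml

            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        def enc(o):
            if isinstance(o, (TissueClassSpec, PhantomPlan, Region)):
                return vars(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(vars(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def _plaque_dir(outdir: Path, plaque_id: str) -> Path:
    d = outdir / "plaques" / plaque_id
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(cfg: RunConfig, outdir: str | Path) -> list[str]:
    """Generate every phantom and both signal stacks; returns written paths."""
    outdir = Path(outdir)
    written = []
    for i, plan in enumerate(cfg.phantoms):
        phantom = generate_phantom(plan.spec(derive_seed(cfg.seed, "phantom", i)), cfg.classes)
        pdir = _plaque_dir(outdir, plan.plaque_id)
        paths = pio.save_phantom(phantom, pdir)
        written.extend(paths.values())
        for mode, proto in (
            ("vfa", cfg.vfa_protocol(derive_seed(cfg.seed, "vfa", i))),
            ("multiecho", cfg.multiecho_protocol(derive_seed(cfg.seed, "multiecho", i))),
        ):
            stack = simulate_acquisition(phantom, proto)
            if proto.zero_fill_factor > 1:
                stack.frames = np.stack(
                    [zero_fill(f, proto.zero_fill_factor) for f in stack.frames]
                )
            pio.save_stack(stack, pdir, mode, plan.voxel_size_um)
            written.append(str(pdir / f"{mode}.nii.gz"))
        logger.info("simulated plaque %s (%s voxels)", plan.plaque_id, phantom.labels.size)
    return written


def _signal_floor(protocol: AcquisitionProtocol, frames: np.ndarray) -> float:
    # 3 sigma of the noise level, expressed on the signal scale
    if protocol.noise_model == "none" or protocol.noise_sigma == 0:
        return 0.0
    return 3.0 * protocol.noise_sigma * float(frames.max())


def stage_fitmaps(cfg: RunConfig, outdir: str | Path) -> list[str]:
    """Fit T1 and T2* maps for every plaque from the saved stacks."""
    outdir = Path(outdir)
    written = []
    for plan in cfg.phantoms:
        pdir = _plaque_dir(outdir, plan.plaque_id)
        vfa = pio.load_stack(pdir, "vfa", plan.plaque_id)
        me = pio.load_stack(pdir, "multiecho", plan.plaque_id)
        t1res = fit_t1_vfa(vfa, signal_floor=_signal_floor(vfa.protocol, vfa.frames))
        t2res = fit_t2star(me, signal_floor=_signal_floor(me.protocol, me.frames))
        pio.save_t1_result(t1res, pdir, plan.voxel_size_um)
        pio.save_t2s_result(t2res, pdir, plan.voxel_size_um)
        written += [str(pdir / n) for n in (
            "t1_map.nii.gz", "m0_map.nii.gz", "t1_valid.nii.gz",
            "t2s_map.nii.gz", "s0_map.nii.gz", "t2s_valid.nii.gz",
        )]
        logger.info(
            "fitted plaque %s: %d/%d T1 voxels valid, %d/%d T2*",
            plan.plaque_id,
            int(t1res.valid_mask.sum()), t1res.valid_mask.size,
            int(t2res.valid_mask.sum()), t2res.valid_mask.size,
        )
    return written


def _upsample_labels(labels: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    out = labels
    for axis in range(3):
        f, rem = divmod(target_shape[axis], out.shape[axis])
        if rem or f < 1:
            raise ConfigurationError("map grid is not an integer multiple of label grid")
        if f > 1:
            out = np.repeat(out, f, axis=axis)
    return out


def stage_roi(
    cfg: RunConfig, outdir: str | Path, rois_csv: str | Path | None = None
) -> list[str]:
    """Sample (or load) ROI definitions and extract feature vectors."""
    outdir = Path(outdir)
    all_rois = []
    all_features = []
    for i, plan in enumerate(cfg.phantoms):
        pdir = _plaque_dir(outdir, plan.plaque_id)
        phantom = pio.load_phantom(pdir)
        maps = RelaxationMaps(
            t1=pio.load_t1_result(pdir), t2s=pio.load_t2s_result(pdir), registered=True
        )
        if rois_csv is not None:
            rois = [r for r in read_rois_csv(rois_csv) if r.plaque_id == plan.plaque_id]
        else:
            if maps.grid_shape != phantom.grid_shape:
                phantom.labels = _upsample_labels(phantom.labels, maps.grid_shape)
            present = set(np.unique(phantom.labels))
            plan_counts = {
                label: n
                for label, n in cfg.n_per_class.items()
                if phantom.class_ids.get(label) in present and n > 0
            }
            rois = sample_rois(
                phantom,
                plan_counts,
                size_range=cfg.roi_size_range,
                seed=derive_seed(cfg.seed, "roi", i),
            )
            # keep roi ids unique across plaques
            rois = [
                type(r)(
                    roi_id=f"{plan.plaque_id}:{r.roi_id}",
                    plaque_id=r.plaque_id,
                    tissue_label=r.tissue_label,
                    voxels=r.voxels,
                )
                for r in rois
            ]
        rejects: list[tuple[str, str]] = []
        feats = extract_features(maps, rois, rejects=rejects)
        if rejects:
            logger.info("plaque %s: dropped %d ROIs", plan.plaque_id, len(rejects))
        all_rois.extend(rois)
        all_features.extend(feats)
    write_rois_csv(all_rois, outdir / "rois.csv")
    write_features_csv(all_features, outdir / "features.csv")
    if all_features:
        summarize_classes(all_features).to_csv(outdir / "summary.csv", index=False)
    return [str(outdir / n) for n in ("rois.csv", "features.csv", "summary.csv")]


def stage_classify(cfg: RunConfig, outdir: str | Path) -> list[str]:
    """Fit QDA per configured scope and classify by resubstitution."""
    outdir = Path(outdir)
    features = frame_to_features(pd.read_csv(outdir / "features.csv"))
    models, not_applicable = fit_qda(
        features, scope=cfg.scope, shrinkage=cfg.shrinkage, priors=cfg.priors
    )
    mdir = outdir / "models"
    mdir.mkdir(exist_ok=True)
    rows = []
    for model in models:
        model.to_json(mdir / f"{model.training_scope}.json")
        if model.training_scope == POOLED:
            scoped = features
        else:
            scoped = [f for f in features if f.plaque_id == model.training_scope]
        for p in classify(model, scoped):
            rows.append(
                {
                    "roi_id": p.roi_id,
                    "plaque_id": p.plaque_id,
                    "true_label": p.true_label,
                    "predicted_label": p.predicted_label,
                    "misclassified": int(p.misclassified),
                }
            )
    pd.DataFrame(
        rows,
        columns=["roi_id", "plaque_id", "true_label", "predicted_label", "misclassified"],
    ).to_csv(outdir / "predictions.csv", index=False)
    (outdir / "excluded.json").write_text(
        json.dumps([list(e) for e in not_applicable], indent=1)
    )
    for gid, reason in not_applicable:
        logger.info("scope %s excluded: %s", gid, reason)
    return [str(outdir / "predictions.csv"), str(outdir / "excluded.json")]


def stage_report(cfg: RunConfig, outdir: str | Path) -> list[str]:
    """Aggregate predictions into the misclassification report and exports."""
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "predictions.csv")
    excluded = [tuple(e) for e in json.loads((outdir / "excluded.json").read_text())]
    preds = [
        Prediction(
            roi_id=str(r.roi_id),
            plaque_id=str(r.plaque_id),
            true_label=str(r.true_label),
            predicted_label=str(r.predicted_label),
            discriminant_scores={},
        )
        for r in frame.itertuples()
    ]
    report = misclassification_report(preds, ci_level=cfg.ci_level, excluded_plaques=excluded)
    report.to_json(outdir / "report.json")
    pd.DataFrame(
        [
            {"plaque_id": pid, "n_roi": n, "n_misclassified": m, "rate_percent": r}
            for pid, (n, m, r) in report.per_plaque.items()
        ],
        columns=["plaque_id", "n_roi", "n_misclassified", "rate_percent"],
    ).to_csv(outdir / "report.csv", index=False)
    # scatter export: one point per ROI (mean T1 vs mean T2*), flagging misses
    feats = pd.read_csv(outdir / "features.csv")
    scatter = feats.merge(
        frame[["roi_id", "predicted_label", "misclassified"]], on="roi_id", how="left"
    )[
        [
            "roi_id", "plaque_id", "tissue_label", "mean_t1", "mean_t2s",
            "predicted_label", "misclassified",
        ]
    ]
    scatter.to_csv(outdir / "scatter.csv", index=False)
    return [str(outdir / n) for n in ("report.json", "report.csv", "scatter.csv")]


STAGES = ("simulate", "fitmaps", "roi", "classify", "report")


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write a manifest; aborts naming the stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "version": __import__("plaquemap").__version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "warnings": [],
    }
    funcs = {
        "simulate": stage_simulate,
        "fitmaps": stage_fitmaps,
        "roi": stage_roi,
        "classify": stage_classify,
        "report": stage_report,
    }
    for name in STAGES:
        try:
            manifest["stages"][name] = funcs[name](cfg, outdir)
        except Exception as exc:
            manifest["warnings"].append(f"stage {name} failed: {exc}")
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise PlaquemapError(f"stage {name!r} failed: {exc}") from exc
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
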