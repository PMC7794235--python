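"""End-to-end orchestration: phantom generation -> preprocessing ->
per-structure training -> prediction -> HU-constrained refinement ->
otic-capsule derivation -> evaluation, with a reproducible run manifest.

Ground-truth labels of test cases are read only by the evaluation stage;
prediction and refinement see just the CT volume and its side metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .metrics import aggregate, evaluate_pair
from .phantom import (
    PhantomConfig,
    PhantomSample,
    generate_dataset,
    train_test_split,
)
from .preprocess import AugmentConfig, HUWindow, standardize_side, window_rescale
from .refine import (
    DEFAULT_STRUCTURES,
    HURange,
    IslandPolicy,
    StructureSpec,
    derive_otic_capsule,
    refine_pipeline,
)
from .segnet import NetConfig, TrainConfig, binarize, build_model, predict, train
from .volgrid import GridSpec, flip_lr, isotropic_spec, resample, write_volume

log = logging.getLogger(__name__)

STAGES = ("phantoms", "preprocess", "train", "predict", "refine", "capsule", "evaluate")


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated configuration for one end-to-end run."""

    n_train: int = 12
    n_test: int = 4
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    window: HUWindow = field(default_factory=HUWindow)
    train_spacing_mm: float = 0.5  # coarse training grid
    working_spacing_mm: float = 0.25  # fine refinement grid
    structures: tuple[str, ...] = ("inner_ear",)
    derive_capsule: bool = True
    net: NetConfig = field(
        default_factory=lambda: NetConfig(depth=3, base_channels=8, patch_shape=(16, 16, 16))
    )
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            epochs=240, initial_lr=1e-3, decay_every=120, decay_factor=1.0 / 3.0, batch_size=1
        )
    )
    structure_specs: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURES))
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if len(set(self.structures)) != len(self.structures):
            raise ValidationError("structure names must be unique")
        for name in self.structures:
            if name not in self.structure_specs:
                raise ValidationError(f"no StructureSpec (HU range) configured for {name!r}")
        if self.derive_capsule and "otic_capsule" not in self.structure_specs:
            raise ValidationError("no StructureSpec configured for 'otic_capsule'")


def config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _seeded(config: PipelineConfig, **overrides) -> PipelineConfig:
    """Propagate the master seed into sub-configs."""
    phantom = dataclasses.replace(config.phantom, seed=config.seed)
    tc = config.train
    train_cfg = dataclasses.replace(
        tc, seed=config.seed, augment=dataclasses.replace(tc.augment, seed=config.seed)
    )
    return dataclasses.replace(config, phantom=phantom, train=train_cfg, **overrides)


def _preprocess_case(sample: PhantomSample, config: PipelineConfig, structure: str,
                     with_label: bool):
    label = sample.labels[structure] if with_label else None
    vol, lab, _ = standardize_side(sample.volume, label, sample.side)
    vol_w = window_rescale(vol, config.window)
    spec = isotropic_spec(vol_w.grid, config.train_spacing_mm)
    vol_c = resample(vol_w, spec, mode="continuous")
    lab_c = resample(lab, spec, mode="nearest") if lab is not None else None
    return vol, vol_c, lab_c


def run_end_to_end(config: PipelineConfig, out_dir: str | Path, write_nifti: bool = False) -> dict:
    """Execute the full pipeline; returns the summary report.

    Writes ``metrics.csv`` (one row per test case per structure),
    ``manifest.json`` (config hash, seeds, versions, stage status) and,
    optionally, per-case NIfTI predictions under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = _seeded(config)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {s: "absent" for s in STAGES},
        "case_seeds": {},
    }
    _write_manifest(out_dir, manifest)

    def stage(name):
        log.info("stage %s starting", name)
        manifest["stages"][name] = "running"
        _write_manifest(out_dir, manifest)
        return time.perf_counter()

    def done(name, t0):
        manifest["stages"][name] = "complete"
        log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        _write_manifest(out_dir, manifest)

    try:
        t0 = stage("phantoms")
        n = config.n_train + config.n_test
        samples = generate_dataset(n, config.phantom, seed=config.seed)
        train_set, test_set = train_test_split(samples, config.n_test, seed=config.seed)
        manifest["case_seeds"] = {s.case_id: s.seed for s in samples}
        manifest["test_cases"] = [s.case_id for s in test_set]
        done("phantoms", t0)

        rows = []
        models = {}
        predictions: dict[str, dict] = {s.case_id: {} for s in test_set}
        for structure in config.structures:
            spec = config.structure_specs[structure]
            t0 = stage("preprocess")
            train_data = []
            for s in train_set:
                _, vol_c, lab_c = _preprocess_case(s, config, structure, with_label=True)
                train_data.append((vol_c, lab_c))
            done("preprocess", t0)

            t0 = stage("train")
            model = build_model(config.net, seed=config.seed, structure_name=structure)
            model = train(model, train_data, config.train)
            models[structure] = model
            done("train", t0)

            for s in test_set:
                case_t0 = time.perf_counter()
                t0 = stage("predict")
                raw_vol, vol_c, _ = _preprocess_case(s, config, structure, with_label=False)
                prob = predict(model, vol_c)
                prob_native = resample(binarize(prob, config.threshold), raw_vol.grid,
                                       mode="nearest")
                done("predict", t0)

                t0 = stage("refine")
                refined = refine_pipeline(
                    prob_native, raw_vol, spec, working_spacing=config.working_spacing_mm
                )
                done("refine", t0)
                elapsed = time.perf_counter() - case_t0
                predictions[s.case_id][structure] = (refined, elapsed, raw_vol)

        if config.derive_capsule and "inner_ear" in config.structures:
            t0 = stage("capsule")
            cap_spec = config.structure_specs["otic_capsule"]
            for s in test_set:
                inner, _, raw_vol = predictions[s.case_id]["inner_ear"]
                c0 = time.perf_counter()
                capsule = derive_otic_capsule(
                    inner, raw_vol, hu_range=cap_spec.refine_range,
                    max_iterations=cap_spec.max_grow_iterations,
                )
                predictions[s.case_id]["otic_capsule"] = (
                    capsule, time.perf_counter() - c0, raw_vol
                )
            done("capsule", t0)

        t0 = stage("evaluate")
        by_structure: dict[str, list] = {}
        for s in test_set:
            for structure, (pred, elapsed, _raw) in predictions[s.case_id].items():
                ref = s.labels[structure]
                # predictions live on the standardized (right-sided) grid
                ref_cmp = flip_lr(ref) if s.side == "left" else ref
                report = evaluate_pair(pred, ref_cmp, elapsed)
                by_structure.setdefault(structure, []).append(report)
                rows.append(
                    {
                        "case_id": s.case_id,
                        "structure": structure,
                        "dsc": report.dsc,
                        "ahd_mm": report.ahd_mm,
                        "volsim_pct": report.volumetric_similarity_pct,
                        "seconds": report.seconds,
                    }
                )
                if write_nifti:
                    nifti_dir = out_dir / "predictions"
                    nifti_dir.mkdir(exist_ok=True)
                    write_volume(pred, nifti_dir / f"{s.case_id}_{structure}.nii.gz")
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")
        summary = {name: aggregate(reps) for name, reps in by_structure.items()}
        with open(out_dir / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        done("evaluate", t0)
    except Exception as exc:
        failed = [s for s, v in manifest["stages"].items() if v == "running"]
        for s_name in failed:
            manifest["stages"][s_name] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out_dir, manifest)
        (out_dir / "FAILED").write_text(manifest["error"])
        raise

    _write_manifest(out_dir, manifest)
    return {"summary": summary, "metrics_csv": str(out_dir / "metrics.csv"),
            "manifest": manifest}


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)


def version_manifest(run_dir: str | Path) -> dict:
    """Load the run manifest (config hash, seeds, versions, stage status)."""
    path = Path(run_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as f:
        return json.load(f)


# -- config file loading ----------------------------------------------------

def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; flat overrides allowed."""
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    return config_from_dict(raw, seed=seed)


def config_from_dict(raw: dict, seed: int | None = None) -> PipelineConfig:
    kw: dict = {}
    if "window" in raw:
        kw["window"] = HUWindow(lo=raw["window"].get("lo", -500.0), hi=raw["window"].get("hi", 2000.0))
    if "augment" in raw or "train" in raw:
        t = dict(raw.get("train", {}))
        a = raw.get("augment", {})
        aug = AugmentConfig(
            jitter_prob=a.get("jitter_prob", 0.1),
            jitter_magnitude=a.get("jitter_magnitude", 0.1),
            flip_prob=a.get("flip_prob", 0.5),
        )
        defaults = PipelineConfig().train
        kw["train"] = TrainConfig(
            epochs=t.get("epochs", defaults.epochs),
            initial_lr=t.get("initial_lr", defaults.initial_lr),
            decay_factor=t.get("decay_factor", defaults.decay_factor),
            decay_every=t.get("decay_every", defaults.decay_every),
            folds=t.get("folds", defaults.folds),
            batch_size=t.get("batch_size", defaults.batch_size),
            fg_crop_prob=t.get("fg_crop_prob", defaults.fg_crop_prob),
            augment=aug,
        )
    if "net" in raw:
        n = raw["net"]
        kw["net"] = NetConfig(
            depth=n.get("depth", 3),
            base_channels=n.get("base_channels", 8),
            residual_blocks=n.get("residual_blocks", False),
            patch_shape=tuple(n.get("patch_shape", (16, 16, 16))),
        )
    if "phantom" in raw:
        p = raw["phantom"]
        grid = p.get("grid", {})
        kw["phantom"] = PhantomConfig(
            grid=GridSpec(
                tuple(grid.get("shape", (64, 64, 64))),
                tuple(grid.get("spacing", (0.25, 0.25, 0.25))),
            ),
            noise_sd=p.get("noise_sd", 30.0),
        )
    if "structures" in raw:
        kw["structures"] = tuple(raw["structures"])
    if "structure_specs" in raw:
        specs = dict(DEFAULT_STRUCTURES)
        for name, s in raw["structure_specs"].items():
            policy = IslandPolicy(
                keep_largest=s.get("keep_largest", True),
                min_size=s.get("min_size"),
            )
            specs[name] = StructureSpec(
                name=name,
                refine_range=HURange(s["hu_lo"], s["hu_hi"]),
                island_policy=policy,
                max_grow_iterations=s.get("max_grow_iterations", 50),
                grow_connectivity=s.get("grow_connectivity", "faces"),
            )
        kw["structure_specs"] = specs
    for key in ("n_train", "n_test", "train_spacing_mm", "working_spacing_mm",
                "derive_capsule", "threshold", "seed"):
        if key in raw:
            kw[key] = raw[key]
    if seed is not None:
        kw["seed"] = seed
    return PipelineConfig(**kw)
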