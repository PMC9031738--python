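"""Stage-based pipeline: generate -> preprocess -> clean -> train -> eval -> report.

Each stage writes its artifacts under the output directory and drops a
``.stages/<stage>.done`` marker; a rerun with ``resume=True`` skips stages
whose markers exist and reloads their artifacts from disk.  All randomness
derives from the single ``seed`` key, so a full rerun reproduces every
manifest and metric byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .communicator import ReferenceDataset, final_sweep, run_cleanup, sweep_summary
from .datatypes import (
    CLASSES,
    CONTAMINANT_CLASSES,
    PARENCHYMAL_CLASSES,
    STATUS_DISCARDED,
    TileDataset,
)
from .errors import ConfigError, StageError
from .evaluation import confusion_and_metrics
from .manifests import read_dataset, write_manifest, write_tile_bundle
from .reporting import render_overlay, save_overlay, write_run_manifest
from .stain import normalize_tiles
from .synthetic import (
    SyntheticCohortConfig,
    cohort_to_dataset,
    generate_cohort,
    generate_expert_annotation,
    read_cohort,
    write_cohort,
)
from .training import TrainConfig, apply_split, fit, make_splits

log = logging.getLogger(__name__)

STAGES = ("generate", "preprocess", "clean", "train", "eval", "report")


def load_config(path: str | Path) -> dict:
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a YAML mapping")
    unknown = set(cfg.get("stages", [])) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    return cfg


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def pipeline_run(config: dict | str | Path, out_dir: str | Path, resume: bool = True) -> Path:
    """Execute the configured stages in order; returns the output directory.

    A stage failure raises :class:`StageError`; completed stages keep their
    markers so the run can resume.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    marker_dir = out / ".stages"
    marker_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    artifacts: dict[str, str] = {}

    def done(stage: str) -> bool:
        return resume and (marker_dir / f"{stage}.done").exists()

    def mark(stage: str) -> None:
        (marker_dir / f"{stage}.done").write_text("ok")

    for stage in stages:
        try:
            if done(stage):
                log.info("stage %s already complete; skipping", stage)
                continue
            _run_stage(stage, config, out, seed, artifacts)
            mark(stage)
        except ConfigError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return out


def _load_tiles(out: Path, name: str) -> TileDataset:
    return read_dataset(out / f"{name}.csv", out / f"{name}.npz", CLASSES)


def _save_tiles(ds: TileDataset, out: Path, name: str) -> None:
    write_manifest(ds, out / f"{name}.csv")
    write_tile_bundle(ds, out / f"{name}.npz")


def _run_stage(stage: str, config: dict, out: Path, seed: int, artifacts: dict) -> None:
    if stage == "generate":
        cc = SyntheticCohortConfig(**{**config.get("cohort", {}), "seed": seed})
        images, truth = generate_cohort(cc)
        expert = generate_expert_annotation(images, truth)
        write_cohort(out / "cohort", images, truth, expert)
    elif stage == "preprocess":
        cc = SyntheticCohortConfig(**{**config.get("cohort", {}), "seed": seed})
        images, truth = read_cohort(out / "cohort")
        raw = cohort_to_dataset(images, truth, cc.tile_size)
        ds = TileDataset(normalize_tiles(raw.tiles), classes=raw.classes)
        plan = make_splits(ds, seed=seed)
        apply_split(ds, plan)
        _save_tiles(ds, out, "tiles")
    elif stage == "clean":
        ds = _load_tiles(out, "tiles")
        clean_cfg = dict(config.get("clean", {}))
        cycles = int(clean_cfg.pop("cycles", 3))
        threshold = float(clean_cfg.pop("threshold", 0.55))
        k = int(clean_cfg.pop("k", 20))
        tc = _train_config(config, seed)
        reference = ReferenceDataset(
            [t for t in ds.tiles if t.label in CONTAMINANT_CLASSES]
        )
        paren = TileDataset(
            [t for t in ds.tiles if t.label in PARENCHYMAL_CLASSES], classes=ds.classes
        )
        result = run_cleanup(paren, reference, cycles, tc, k=k, seed=seed)
        swept = final_sweep(result.models, ds, threshold=threshold)
        swept.split = dict(ds.split)
        _save_tiles(swept, out, "cleaned")
        logs = {cls: st.discard_log for cls, st in result.states.items()}
        (out / "discard_log.json").write_text(
            json.dumps(_round_floats({"per_class": logs, "sweep": sweep_summary(swept)}),
                       indent=2, sort_keys=True)
        )
    elif stage == "train":
        swept = _load_tiles(out, "cleaned")
        tc = _train_config(config, seed)
        train = [t for t in swept.of_split("train") if t.status != STATUS_DISCARDED]
        val = [t for t in swept.of_split("val") if t.status != STATUS_DISCARDED]
        model, log_df = fit(train, val, tc)
        np.savez(
            out / "model.npz",
            classes=np.array(model.classes),
            feat_mean=model.feat_mean,
            feat_sd=model.feat_sd,
            input_size=model.input_size,
            backbone=model.backbone.name,
            **model.params,
        )
        log_df.to_csv(out / "training_log.csv", index=False)
    elif stage == "eval":
        swept = _load_tiles(out, "cleaned")
        model = _load_model(out)
        test = swept.of_split("test")
        y_true = [t.true_class or t.label for t in test]
        _, y_pred = model.predict(test)
        rep = confusion_and_metrics(y_true, y_pred, CLASSES)
        payload = {
            "confusion": rep.confusion.tolist(),
            "classes": list(rep.classes),
            "accuracy": rep.accuracy,
            "macro": rep.macro,
            "weighted": rep.weighted,
            "per_class": rep.per_class.round(10).to_dict(),
        }
        (out / "metrics.json").write_text(
            json.dumps(_round_floats(payload), indent=2, sort_keys=True)
        )
    elif stage == "report":
        swept = _load_tiles(out, "cleaned")
        images, _ = read_cohort(out / "cohort")
        odir = out / "overlays"
        odir.mkdir(exist_ok=True)
        by_image = swept.by_image()
        written = []
        for im in images[: int(config.get("report", {}).get("max_overlays", 6))]:
            ov = render_overlay(im, by_image.get(im.image_id, []))
            path = odir / f"{im.image_id}.png"
            save_overlay(ov, path)
            written.append(str(path.relative_to(out)))
        entries = {
            "seed": seed,
            "config": _round_floats(config),
            "artifacts": sorted(
                str(p.relative_to(out))
                for p in out.rglob("*")
                if p.is_file() and ".stages" not in p.parts
            ),
        }
        write_run_manifest(out / "run_manifest.json", entries)
    else:
        raise ConfigError(f"unknown stage {stage!r}")


def _train_config(config: dict, seed: int) -> TrainConfig:
    d = dict(config.get("train", {}))
    d.setdefault("lr", 3e-3)
    d.setdefault("batch_size", 64)
    d.setdefault("max_epochs", 40)
    d["seed"] = seed
    return TrainConfig(**d)


def _load_model(out: Path):
    from .models import TileClassifier, get_backbone

    data = np.load(out / "model.npz", allow_pickle=False)
    params = {k: data[k] for k in data.files if k[0] in ("W", "b") and k[1:].isdigit()}
    return TileClassifier(
        backbone=get_backbone(str(data["backbone"])),
        classes=tuple(data["classes"].tolist()),
        params=params,
        feat_mean=data["feat_mean"],
        feat_sd=data["feat_sd"],
        input_size=int(data["input_size"]),
    )
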