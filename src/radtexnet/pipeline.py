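"""End-to-end pipeline: phantoms/volumes -> texture -> selection -> ablation -> explanations.

A :class:`RunConfig` bundles every stage's parameters, resolves all defaults
up front, and is serialized (with a hash) alongside every output so a run is
reproducible from its artifact directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import CTVolume, PreprocessSpec, load_volume, preprocess_volume, minmax_normalize, save_volume
from .haralick import TextureSpec, texture_maps, FEATURE_NAMES
from .feature_selection import cohort_table, rank_features
from .networks import EnsembleConfig
from .training import TrainSpec, desk_scale_train_spec, run_ablation, ABLATION_VARIANTS
from .synthetic import PhantomSpec, default_class_specs, make_cohort
from . import explain as explain_mod


@dataclass
class SynthSpec:
    """Synthetic-cohort stage parameters."""

    n_per_class: int = 5
    shape: Tuple[int, int, int] = (32, 32, 16)
    effect: str = "easy"


@dataclass
class RunConfig:
    """Union of all stage specs plus paths and the master seed."""

    seed: int = 0
    out_dir: str = "run_output"
    data_dir: Optional[str] = None  # NIfTI directory with labels.csv; None => synth
    synth: SynthSpec = field(default_factory=SynthSpec)
    preprocess: Optional[PreprocessSpec] = None  # None skips resampling for synth data
    texture: TextureSpec = field(default_factory=lambda: TextureSpec(gray_levels=8))
    select_patch_edge: int = 8
    select_trees: int = 100
    select_folds: int = 5
    run_selection: bool = True
    ensemble: EnsembleConfig = field(default_factory=lambda: EnsembleConfig(
        input_shape=(32, 32, 16), cnn_filters=(8, 16, 32), cnn_feature_dim=64,
        vit_patch_edge=8, vit_depth=2, vit_dim=64, vit_heads=4))
    train: TrainSpec = field(default_factory=lambda: desk_scale_train_spec())
    cv_folds: int = 3
    variants: Tuple[str, ...] = tuple(ABLATION_VARIANTS)

    def validate(self) -> None:
        if self.data_dir is None and self.synth is None:
            raise ValueError("config must set either data_dir or synth")
        if self.data_dir is not None and not os.path.isdir(self.data_dir):
            raise ValueError(f"data_dir {self.data_dir!r} does not exist")
        unknown = set(self.variants) - set(ABLATION_VARIANTS)
        if unknown:
            raise ValueError(f"unknown ablation variants {sorted(unknown)}")

    def resolved(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return convert(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(handle, record: dict) -> None:
    handle.write(json.dumps(record) + "\n")
    handle.flush()


def run_pipeline(config: RunConfig) -> str:
    """Execute every stage, writing artifacts and a JSON-lines run log.

    Returns the artifact directory.  Rerunning with the same config and seed
    reproduces the metrics JSON bit for bit.
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    resolved = config.resolved()
    resolved["config_hash"] = config.config_hash()
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)

    log = open(os.path.join(out, "run_log.jsonl"), "w")
    _log(log, {"event": "start", "config_hash": resolved["config_hash"]})

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _log(log, {"event": "stage_failed", "stage": name, "error": str(exc)})
                    raise StageError(name, exc) from exc
                _log(log, {"event": "stage_done", "stage": name,
                           "seconds": round(time.time() - self.t0, 3)})
                return False

        return _Ctx()

    with stage("data"):
        if config.data_dir is None:
            pos, neg = default_class_specs(config.synth.shape, config.synth.effect)
            volumes, masks, manifest = make_cohort(
                config.synth.n_per_class, pos, neg, seed=config.seed)
            manifest.to_csv(os.path.join(out, "manifest.csv"), index=False)
        else:
            volumes, masks, manifest = _load_labeled_dir(config.data_dir)
        labels = np.array([v.label for v in volumes], dtype=int)

    with stage("preprocess"):
        if config.preprocess is not None:
            volumes = [preprocess_volume(v, config.preprocess) for v in volumes]
        lo, hi = (config.preprocess.window if config.preprocess is not None
                  else (-1000.0, 400.0))
        clipped = [CTVolume(np.clip(v.voxels, lo, hi), v.spacing, v.label) for v in volumes]

    with stage("texture"):
        tspec = config.texture
        if tspec.quant_range is None:
            tspec = dataclasses.replace(tspec, quant_range=(lo, hi))
        map_sets = [texture_maps(v, tspec) for v in clipped]

    with stage("selection"):
        if config.run_selection:
            table = cohort_table(map_sets, labels, config.select_patch_edge)
            report = rank_features(table, n_trees=config.select_trees,
                                   k=config.select_folds, seed=config.seed)
            selected = report.selected_map
            with open(os.path.join(out, "selection_report.json"), "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        else:
            selected = "HaralickCorrelation"
        _log(log, {"event": "selected_map", "name": selected})

    with stage("ablation"):
        ct = np.stack([minmax_normalize(v.voxels) for v in clipped])
        rad = np.stack([minmax_normalize(ms.maps[selected]) for ms in map_sets])
        results = run_ablation(ct, rad, labels, config.ensemble, config.train,
                               k=config.cv_folds, seed=config.seed,
                               variants=config.variants)
        metrics = {name: res.to_dict() for name, res in results.items()}
        with open(os.path.join(out, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        _write_roc_points(results, os.path.join(out, "roc_points.csv"))
        _write_loss_curves(results, os.path.join(out, "loss_curves.png"))

    with stage("explain"):
        _write_explanations(results, ct, rad, clipped, config, out)

    _log(log, {"event": "done"})
    log.close()
    return out


def _load_labeled_dir(data_dir: str):
    import pandas as pd

    labels_csv = os.path.join(data_dir, "labels.csv")
    if not os.path.isfile(labels_csv):
        raise ValueError(f"{data_dir!r} must contain labels.csv with columns file,label")
    table = pd.read_csv(labels_csv)
    volumes, masks = [], []
    for _, row in table.iterrows():
        vol = load_volume(os.path.join(data_dir, row["file"]), "nifti")
        vol.label = int(row["label"])
        volumes.append(vol)
        masks.append(np.zeros(vol.shape, dtype=bool))
    return volumes, masks, table


def _write_roc_points(results, path: str) -> None:
    import pandas as pd
    from sklearn.metrics import roc_curve

    frames = []
    for name, res in results.items():
        fpr, tpr, thr = roc_curve(res.pooled_labels, res.pooled_scores)
        frames.append(pd.DataFrame({"variant": name, "fpr": fpr, "tpr": tpr,
                                    "threshold": thr}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _write_loss_curves(results, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, res in results.items():
        hist = res.histories[0]  # one fold, as in the usual convergence plot
        ax.plot(hist.train_loss, label=f"{name} train")
        ax.plot(hist.val_loss, linestyle="--", label=f"{name} val")
    ax.set_xlabel("epoch")
    ax.set_ylabel("BCE loss")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _write_explanations(results, ct, rad, volumes, config: RunConfig, out: str) -> None:
    from .training import variant_inputs, ABLATION_VARIANTS
    from .networks import EnsembleModel
    import dataclasses as dc
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    name = "radct_cnnvit" if "radct_cnnvit" in results else next(iter(results))
    v = ABLATION_VARIANTS[name]
    cfg = dc.replace(config.ensemble, input_channels=len(v["channels"]), fusion=v["fusion"])
    X = variant_inputs(ct, rad, v["channels"])
    from .training import train_model
    model, _ = train_model(X, np.array([vv.label for vv in volumes]), cfg, config.train)

    x0 = X[0]
    mid = volumes[0].shape[2] // 2
    panels = []
    if model.cnn is not None:
        amap = explain_mod.hirescam(model, x0, class_index=1)
        panels.append(("hirescam", explain_mod.overlay(amap, volumes[0], mid)))
    if model.vit is not None:
        rmap = explain_mod.rollout_from_model(model, x0)
        panels.append(("rollout", explain_mod.overlay(rmap, volumes[0], mid)))
    fig, axes = plt.subplots(1, max(1, len(panels)), figsize=(4 * len(panels), 4))
    axes = np.atleast_1d(axes)
    for ax, (title, img) in zip(axes, panels):
        ax.imshow(np.transpose(img, (1, 0, 2)), origin="lower")
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(os.path.join(out, "explanations.png"), dpi=100)
    plt.close(fig)
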