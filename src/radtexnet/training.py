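"""Training loop, augmentation, cross-validation harness and metric suite.

Training minimizes binary cross-entropy with AdamW.  The cross-validation
harness assigns stratified volume-level folds, trains a fresh model per
fold, and evaluates on the held-out fold; the combined AUC is computed from
the out-of-fold scores pooled across folds (one ROC), alongside per-fold
confusion-matrix metrics.  The five ablation variants differ only in input
channels (CT, radiomics texture map, or both) and fusion mode (CNN, ViT or
both branches) and are run from one configuration sweep on shared folds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .networks import EnsembleConfig, EnsembleModel
from .nn import AdamW, bce_loss

#: channels/fusion for the five ablation variants; "ct" and "rad" name the
#: CT intensity channel and the radiomics texture-map channel respectively
ABLATION_VARIANTS: Dict[str, Dict] = {
    "ct_vit": {"channels": ("ct",), "fusion": "vit_only"},
    "ct_cnn": {"channels": ("ct",), "fusion": "cnn_only"},
    "ct_cnnvit": {"channels": ("ct",), "fusion": "concat"},
    "rad_cnnvit": {"channels": ("rad",), "fusion": "concat"},
    "radct_cnnvit": {"channels": ("ct", "rad"), "fusion": "concat"},
}


@dataclass
class AugmentSpec:
    """Probabilities and ranges for random flip / noise / affine."""

    flip_prob: float = 0.5
    flip_axes: Tuple[int, ...] = (0, 1, 2)
    noise_prob: float = 0.5
    noise_sd_range: Tuple[float, float] = (0.0, 0.05)  # on normalized intensities
    affine_prob: float = 0.5
    rotation_deg: float = 10.0
    scale_range: Tuple[float, float] = (0.9, 1.1)


@dataclass
class TrainSpec:
    """Loss/optimizer recipe; defaults are the full-scale training settings."""

    learning_rate: float = 1e-5
    epochs: int = 50
    batch_size: int = 2
    weight_decay: float = 0.01
    val_fraction: float = 0.2
    augment: bool = True
    augment_spec: AugmentSpec = field(default_factory=AugmentSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def desk_scale_train_spec(seed: int = 0, epochs: int = 12) -> TrainSpec:
    """Reduced-scale recipe for 32 x 32 x 16 phantoms (see docs/methods.md)."""
    return TrainSpec(learning_rate=1e-3, epochs=epochs, batch_size=8,
                     augment=False, seed=seed)


@dataclass
class ConfusionMatrix:
    """Binary counts; positive class = pulmonary sarcoidosis (label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def normalized_rates(self) -> np.ndarray:
        """Row-normalized per-class rates [[TPR, FNR], [FPR, TNR]]."""
        pos = max(self.tp + self.fn, 1)
        neg = max(self.tn + self.fp, 1)
        return np.array([[self.tp / pos, self.fn / pos],
                         [self.fp / neg, self.tn / neg]])


def confusion_from_scores(scores: np.ndarray, labels: np.ndarray,
                          threshold: float = 0.5) -> ConfusionMatrix:
    pred = np.asarray(scores) >= threshold
    y = np.asarray(labels).astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)), tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)), fn=int(np.sum(~pred & y)),
    )


def compute_metrics(cm: ConfusionMatrix) -> Dict[str, float]:
    """Sensitivity, specificity, precision, accuracy and F1 from counts.

    Metrics with a zero denominator are reported as NaN ("undefined");
    an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix has no observations")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    f1 = ratio(2 * prec * sens, prec + sens) if np.isfinite(prec) and np.isfinite(sens) else float("nan")
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "f1": f1}


def pooled_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC of one ROC over pooled scores."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# augmentation


def augment(x: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Random flip / noise / affine on a multichannel volume (C, D, H, W).

    Each transform fires independently with its probability; the spatial
    transforms (flip, affine) use one shared map for all channels so the CT
    and texture channels stay co-registered.
    """
    out = np.asarray(x, dtype=np.float64).copy()
    if spec.flip_prob > 0:
        for axis in spec.flip_axes:
            if rng.random() < spec.flip_prob:
                out = np.flip(out, axis=axis + 1)
    if spec.affine_prob > 0 and rng.random() < spec.affine_prob:
        matrix, offset = _random_affine(out.shape[1:], spec, rng)
        out = np.stack([
            ndimage.affine_transform(ch, matrix, offset=offset, order=1, mode="nearest")
            for ch in out
        ])
    if spec.noise_prob > 0 and rng.random() < spec.noise_prob:
        sd = rng.uniform(*spec.noise_sd_range)
        out = out + rng.standard_normal(out.shape) * sd
    return out


def _random_affine(shape, spec: AugmentSpec, rng: np.random.Generator):
    """In-plane rotation + isotropic scale about the volume center."""
    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    scale = rng.uniform(*spec.scale_range)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) / scale
    center = (np.asarray(shape) - 1) / 2.0
    offset = center - rot @ center
    return rot, offset


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingHistory:
    train_loss: List[float]
    val_loss: List[float]


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Indices (train, val) with at least one validation volume per class."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def train_model(X: np.ndarray, y: np.ndarray, cfg: EnsembleConfig,
                spec: TrainSpec) -> Tuple[EnsembleModel, TrainingHistory]:
    """Fit the ensemble on labeled multichannel volumes (N, C, D, H, W).

    A stratified validation split is carved from the data to record per-epoch
    training and validation BCE.  Deterministic for a fixed ``spec.seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.unique(y).size < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 volumes per class")
    rng = np.random.default_rng(spec.seed)
    tr, va = _stratified_split(y, spec.val_fraction, rng)
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    model = EnsembleModel(cfg, seed=int(rng.integers(2**31 - 1)))
    opt = AdamW(model.parameters(), lr=spec.learning_rate,
                weight_decay=spec.weight_decay)
    history = TrainingHistory(train_loss=[], val_loss=[])
    n = len(ytr)
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb = Xtr[idx]
            if spec.augment:
                xb = np.stack([augment(v, spec.augment_spec, rng) for v in xb])
            logits = model.logits(xb, train=True)
            loss, dlogits = bce_loss(logits, ytr[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        val_logits = model.logits(Xva, train=False)
        history.val_loss.append(bce_loss(val_logits, yva)[0])
    return model, history


# ---------------------------------------------------------------------------
# cross-validation and the ablation harness


@dataclass
class FoldResults:
    """Per-fold confusion/metrics plus pooled out-of-fold scores and AUC."""

    fold_confusions: List[ConfusionMatrix]
    fold_metrics: List[Dict[str, float]]
    fold_auc: List[float]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_confusion: ConfusionMatrix
    pooled_metrics: Dict[str, float]
    combined_auc: float
    histories: List[TrainingHistory]

    def metric_summary(self) -> Dict[str, Tuple[float, float]]:
        """Cross-fold mean +/- sd for each metric."""
        out = {}
        for key in self.fold_metrics[0]:
            vals = np.array([m[key] for m in self.fold_metrics])
            out[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out

    def to_dict(self) -> dict:
        return {
            "fold_metrics": self.fold_metrics,
            "fold_auc": self.fold_auc,
            "metric_summary": {k: {"mean": m, "sd": s}
                               for k, (m, s) in self.metric_summary().items()},
            "pooled_metrics": self.pooled_metrics,
            "pooled_confusion": asdict(self.pooled_confusion),
            "normalized_confusion": self.pooled_confusion.normalized_rates().tolist(),
            "combined_auc": self.combined_auc,
        }


def cross_validate(X: np.ndarray, y: np.ndarray, cfg: EnsembleConfig,
                   spec: TrainSpec, k: int = 5, seed: int = 0) -> FoldResults:
    """Stratified volume-level k-fold cross-validation.

    Every volume appears in exactly one validation fold; a fresh model is
    trained per fold and the combined AUC is computed from the pooled
    out-of-fold scores (single ROC).  Confusion matrices use a decision
    threshold of 0.5.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    if min(np.sum(y == 0), np.sum(y == 1)) < k:
        raise ValueError(f"need at least {k} volumes per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    confusions, metrics, aucs, histories = [], [], [], []
    pooled_scores = np.empty(len(y))
    for fold, (tr, te) in enumerate(skf.split(X[:, :1, 0, 0, 0], y)):
        fold_spec = replace(spec, seed=spec.seed + fold)
        model, hist = train_model(X[tr], y[tr], cfg, fold_spec)
        scores = model.forward(X[te], train=False)
        pooled_scores[te] = scores
        cm = confusion_from_scores(scores, y[te])
        confusions.append(cm)
        metrics.append(compute_metrics(cm))
        aucs.append(float(roc_auc_score(y[te], scores)) if np.unique(y[te]).size > 1 else float("nan"))
        histories.append(hist)

    pooled_cm = confusion_from_scores(pooled_scores, y)
    return FoldResults(
        fold_confusions=confusions,
        fold_metrics=metrics,
        fold_auc=aucs,
        pooled_scores=pooled_scores,
        pooled_labels=np.asarray(y, dtype=int),
        pooled_confusion=pooled_cm,
        pooled_metrics=compute_metrics(pooled_cm),
        combined_auc=pooled_auc(pooled_scores, y),
        histories=histories,
    )


def variant_inputs(ct: np.ndarray, rad: np.ndarray, channels: Sequence[str]) -> np.ndarray:
    """Assemble (N, C, D, H, W) inputs from normalized CT and texture stacks."""
    chans = {"ct": ct, "rad": rad}
    return np.stack([chans[c] for c in channels], axis=1)


def run_ablation(ct: np.ndarray, rad: np.ndarray, y: np.ndarray,
                 base_cfg: EnsembleConfig, spec: TrainSpec, k: int = 5,
                 seed: int = 0,
                 variants: Optional[Sequence[str]] = None) -> Dict[str, FoldResults]:
    """Run the five-variant ablation on shared folds and shared seeds.

    ``ct`` and ``rad`` are (N, D, H, W) stacks of the normalized CT channel
    and the selected radiomics texture-map channel.
    """
    variants = list(variants) if variants is not None else list(ABLATION_VARIANTS)
    results: Dict[str, FoldResults] = {}
    for name in variants:
        v = ABLATION_VARIANTS[name]
        cfg = replace(base_cfg, input_channels=len(v["channels"]), fusion=v["fusion"])
        X = variant_inputs(ct, rad, v["channels"])
        results[name] = cross_validate(X, y, cfg, spec, k=k, seed=seed)
    return results
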