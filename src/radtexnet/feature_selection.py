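"""Patch statistics and random-forest Gini-importance map selection.

Each texture-map volume is divided into non-overlapping cubic patches; the
mean and standard deviation of each of the 8 texture maps over a patch give
a 16-element feature vector, and every patch inherits its volume's label.
A random forest (100 trees) is fit per cross-validation fold and the mean
decrease in Gini impurity, averaged over trees and folds, ranks the 16
columns; the texture map whose mean + std column importances sum highest is
selected as the network's radiomics input channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold

from .haralick import FEATURE_NAMES, TextureMapSet

FEATURE_COLUMNS: Tuple[str, ...] = tuple(
    f"{stat}_{name}" for name in FEATURE_NAMES for stat in ("mean", "std")
)


@dataclass
class ImportanceReport:
    """Cross-fold Gini importances for the 16 patch features and the winner."""

    importance_mean: Dict[str, float]
    importance_sd: Dict[str, float]
    map_scores: Dict[str, float]
    selected_map: str
    per_fold: np.ndarray  # (k, 16)

    def to_dict(self) -> dict:
        return {
            "importance_mean": self.importance_mean,
            "importance_sd": self.importance_sd,
            "map_scores": self.map_scores,
            "selected_map": self.selected_map,
        }


def patchify(maps: TextureMapSet, patch_edge: int, volume_id: int = 0,
             label: Optional[int] = None) -> pd.DataFrame:
    """Per-patch mean/std rows for one volume's texture maps.

    Trailing voxels that do not fill a whole patch are discarded.  Returns a
    DataFrame with columns volume_id, (pi, pj, pk), the 16 feature columns
    in (mean, std) x feature-name order, and the inherited label.
    """
    shape = maps.shape
    e = int(patch_edge)
    if e < 1 or any(s < e for s in shape):
        raise ValueError(f"patch edge {e} does not fit volume {shape}")
    grid = tuple(s // e for s in shape)
    stack = maps.stacked()  # (8, X, Y, Z)
    trimmed = stack[:, : grid[0] * e, : grid[1] * e, : grid[2] * e]
    # reshape into (8, gi, e, gj, e, gk, e) and reduce over patch voxels
    blocks = trimmed.reshape(8, grid[0], e, grid[1], e, grid[2], e)
    blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(8, *grid, e**3)
    means = blocks.mean(axis=-1)
    stds = blocks.std(axis=-1)

    rows = []
    for pi in range(grid[0]):
        for pj in range(grid[1]):
            for pk in range(grid[2]):
                row = {"volume_id": volume_id, "pi": pi, "pj": pj, "pk": pk}
                for f, name in enumerate(FEATURE_NAMES):
                    row[f"mean_{name}"] = means[f, pi, pj, pk]
                    row[f"std_{name}"] = stds[f, pi, pj, pk]
                row["label"] = label
                rows.append(row)
    return pd.DataFrame(rows)


def rank_features(table: pd.DataFrame, n_trees: int = 100, k: int = 5,
                  seed: int = 0, by_volume: bool = True) -> ImportanceReport:
    """Rank the 16 patch features by cross-validated mean decrease in Gini.

    Folds are split at volume level (patches of one volume never straddle a
    fold boundary) unless ``by_volume`` is False.  Per fold, a random forest
    with ``n_trees`` trees is fit on the training patches and its per-tree
    averaged Gini importances recorded; the report carries cross-fold
    mean +/- sd and the selected map (argmax of mean-column + std-column
    importance per texture map).
    """
    cols = list(FEATURE_COLUMNS)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature columns {missing}")
    y_all = table["label"].to_numpy()
    classes = np.unique(y_all)
    if classes.size < 2:
        raise ValueError("both labels must be present in the table")
    X_all = table[cols].to_numpy(dtype=np.float64)

    rng = np.random.default_rng(seed)
    per_fold = []
    if by_volume:
        vols = table["volume_id"].to_numpy()
        uniq = np.unique(vols)
        vol_labels = np.array(
            [y_all[vols == v][0] for v in uniq]
        )
        if min(np.bincount(vol_labels.astype(int))) < k:
            raise ValueError(f"need >= {k} volumes per class for {k}-fold split")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = (
            (np.isin(vols, uniq[tr]), np.isin(vols, uniq[te]))
            for tr, te in splitter.split(uniq.reshape(-1, 1), vol_labels)
        )
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = (
            (np.isin(np.arange(len(y_all)), tr), np.isin(np.arange(len(y_all)), te))
            for tr, te in splitter.split(X_all, y_all)
        )

    for tr_mask, _te_mask in fold_iter:
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X_all[tr_mask], y_all[tr_mask])
        per_fold.append(rf.feature_importances_)
    per_fold = np.asarray(per_fold)

    mean = per_fold.mean(axis=0)
    sd = per_fold.std(axis=0)
    importance_mean = dict(zip(cols, mean.tolist()))
    importance_sd = dict(zip(cols, sd.tolist()))
    map_scores = {
        name: importance_mean[f"mean_{name}"] + importance_mean[f"std_{name}"]
        for name in FEATURE_NAMES
    }
    selected = max(map_scores, key=map_scores.get)
    return ImportanceReport(
        importance_mean=importance_mean,
        importance_sd=importance_sd,
        map_scores=map_scores,
        selected_map=selected,
        per_fold=per_fold,
    )


def cohort_table(map_sets: Sequence[TextureMapSet], labels: Sequence[int],
                 patch_edge: int) -> pd.DataFrame:
    """Concatenate patch tables across a labeled cohort of texture-map sets."""
    frames = [
        patchify(ms, patch_edge, volume_id=i, label=int(lab))
        for i, (ms, lab) in enumerate(zip(map_sets, labels))
    ]
    return pd.concat(frames, ignore_index=True)
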