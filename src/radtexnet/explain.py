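"""HiResCAM saliency for the CNN branch and Attention Rollout for the ViT.

HiResCAM backpropagates the raw class score s_m to a chosen convolution
block's feature map A and forms the element-wise product summed over the
feature channels, sum_f (ds_m/dA (.) A)_f — no channel-averaged weights, so
the map is faithful to where the gradient actually lands.  Attention Rollout
multiplies identity-augmented (and, by default, row-renormalized) attention
matrices layer by layer and reads the classification-token row over the
patch tokens.  Both maps are upsampled trilinearly to the input volume shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .networks import EnsembleModel
from .preprocess import CTVolume, minmax_normalize


@dataclass
class AttentionMap:
    """A saliency volume co-registered with the input."""

    values: np.ndarray  # raw signed values, input-volume shape
    source: str  # "hirescam" or "rollout"
    class_index: int = 1

    def display(self) -> np.ndarray:
        """Min-max normalized values in [0, 1] for rendering."""
        return minmax_normalize(self.values)


def _upsample(a: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, a.shape)]
    out = ndimage.zoom(a, factors, order=1, mode="nearest", grid_mode=True)
    slices = tuple(slice(0, t) for t in shape)
    out = out[slices]
    pads = [(0, t - s) for s, t in zip(out.shape, shape)]
    if any(p[1] for p in pads):
        out = np.pad(out, pads, mode="edge")
    return out


def hirescam(model: EnsembleModel, x: np.ndarray, class_index: int = 1,
             block_index: int = -1) -> AttentionMap:
    """Gradient-weighted feature-map saliency of the CNN branch.

    The raw score of class ``class_index`` (the logit for class 1, its
    negation for class 0) is backpropagated to the output feature map A of
    the chosen convolution block (default: last).  The saliency is
    sum over channels of (ds/dA * A), upsampled to the input shape.  Raw
    signed values are retained; use :meth:`AttentionMap.display` for the
    min-max normalized version.
    """
    if model.cnn is None:
        raise ValueError("model has no CNN branch to explain")
    xb = x[None] if x.ndim == 4 else x
    logits = model.logits(xb, train=False)
    sign = 1.0 if class_index == 1 else -1.0
    dlogits = np.full(logits.shape, sign)
    model.zero_grad()
    model.backward(dlogits)

    n_blocks = len(model.cnn.blocks)
    idx = block_index % n_blocks
    A = model.cnn.block_outputs[idx]  # (B, F, d, h, w)
    dA = model.cnn.block_grads[idx]
    if A.ndim != 5 or A.shape[2] * A.shape[3] * A.shape[4] <= 0:
        raise ValueError("chosen layer has no spatial extent")
    amap = np.sum(dA * A, axis=1)[0]  # sum over feature channels F
    values = _upsample(amap, xb.shape[2:])
    return AttentionMap(values=values, source="hirescam", class_index=class_index)


def attention_rollout(attentions: Sequence[np.ndarray],
                      grid: Optional[Tuple[int, int, int]] = None,
                      volume_shape: Optional[Tuple[int, int, int]] = None,
                      normalize: bool = True) -> AttentionMap:
    """Recursive (A + I) product across layers, read out at the class token.

    ``attentions`` are per-layer head-averaged square row-stochastic
    matrices (heads are averaged here if 3D/4D tensors are passed).  With
    ``normalize`` (default) every (A + I) is row-renormalized so the rollout
    stays row-stochastic, following the original rollout formulation; with
    ``normalize=False`` the raw product is used exactly as the recursion is
    usually printed.  If ``grid`` is given the class-token row over patch
    tokens is reshaped to the 3D patch grid (and upsampled to
    ``volume_shape`` when provided); otherwise the full rollout matrix is
    returned in ``values``.
    """
    mats = [np.asarray(A, dtype=np.float64) for A in attentions]
    if not mats:
        raise ValueError("need at least one attention matrix")
    cleaned = []
    for A in mats:
        if A.ndim == 4:  # (B, heads, T, T) -> first sample, head average
            A = A[0].mean(axis=0)
        elif A.ndim == 3:  # (heads, T, T)
            A = A.mean(axis=0)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"attention matrices must be square, got {A.shape}")
        cleaned.append(A)
    sizes = {A.shape for A in cleaned}
    if len(sizes) != 1:
        raise ValueError(f"attention matrices must share one size, got {sizes}")

    T = cleaned[0].shape[0]
    eye = np.eye(T)
    rollout = None
    for A in cleaned:
        M = A + eye
        if normalize:
            M = M / M.sum(axis=1, keepdims=True)
        rollout = M if rollout is None else M @ rollout

    if grid is None:
        return AttentionMap(values=rollout, source="rollout")
    saliency = rollout[0, 1:]  # class-token row over patch tokens
    vol = saliency.reshape(grid)
    if volume_shape is not None:
        vol = _upsample(vol, volume_shape)
    return AttentionMap(values=vol, source="rollout")


def rollout_from_model(model: EnsembleModel, x: np.ndarray,
                       normalize: bool = True) -> AttentionMap:
    """Run the ViT branch and roll its retained attentions out to a volume."""
    if model.vit is None:
        raise ValueError("model has no ViT branch to explain")
    xb = x[None] if x.ndim == 4 else x
    model.vit.forward(xb, train=False)
    return attention_rollout(model.vit.attentions(), grid=model.vit.grid,
                             volume_shape=xb.shape[2:], normalize=normalize)


def overlay(amap: AttentionMap, v: CTVolume, slice_index: int,
            alpha: float = 0.5, cmap: str = "jet") -> np.ndarray:
    """Blend one axial CT slice with the color-mapped saliency slice.

    Returns an RGB array in [0, 1].  ``alpha`` 0 shows the CT slice only,
    1 the pure colormapped saliency.
    """
    import matplotlib

    if amap.values.shape != v.shape:
        raise ValueError(f"map shape {amap.values.shape} != volume shape {v.shape}")
    if not 0 <= slice_index < v.shape[2]:
        raise IndexError(f"slice {slice_index} out of range for depth {v.shape[2]}")
    ct_slice = minmax_normalize(np.asarray(v.voxels[:, :, slice_index], dtype=np.float64))
    gray = np.repeat(ct_slice[:, :, None], 3, axis=2)
    sal = amap.display()[:, :, slice_index]
    colored = np.asarray(matplotlib.colormaps[cmap](sal))[:, :, :3]
    return (1.0 - alpha) * gray + alpha * colored
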