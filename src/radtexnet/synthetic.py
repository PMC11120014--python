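"""Labeled 3D phantoms with controllable gray-level co-occurrence structure.

Two phantom families stand in for the two clinical classes:

* ``diffuse_texture`` — spatially correlated Gaussian random fields
  (white noise smoothed at a controllable correlation length) riding on a
  lung-window background.  Smoothing raises the co-occurrence correlation
  of neighboring voxels, mimicking the diffuse textural character of
  granulomatous lung disease.  This is the positive class (label 1).
* ``focal_nodule`` — an uncorrelated noisy background plus one or more
  hyperintense spherical inclusions, a crude surrogate for focal lung
  malignancy.  This is the negative class (label 0).

Anatomical realism is explicitly not a goal; what the generator controls is
the statistical contrast (texture correlation length, amplitude, noise,
nodule contrast) and bit-exact reproducibility from a seed.  Per-volume
texture amplitudes are jittered so that amplitude-sensitive texture
statistics vary within class while correlation-sensitive ones separate the
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import CTVolume

PHANTOM_KINDS = ("diffuse_texture", "focal_nodule")


@dataclass
class PhantomSpec:
    """Generator parameters for one phantom volume (HU units throughout)."""

    shape: Tuple[int, int, int] = (32, 32, 16)
    kind: str = "diffuse_texture"
    texture_correlation_length: float = 1.2  # Gaussian smoothing sigma, voxels
    texture_amplitude: float = 150.0  # sd of the correlated field
    amplitude_jitter: Tuple[float, float] = (0.7, 1.3)  # per-volume multiplier
    background: float = -800.0
    noise_sd: float = 25.0  # additive white noise
    nodule_count: int = 2
    nodule_radius: float = 3.0
    nodule_contrast: float = 500.0
    window: Tuple[float, float] = (-1000.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(d) for d in self.shape)
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"kind must be one of {PHANTOM_KINDS}")
        if any(d < 3 for d in self.shape):
            raise ValueError(f"shape must cover at least a 3^3 window, got {self.shape}")
        if self.nodule_contrast <= 0:
            raise ValueError("nodule_contrast must be positive")


def make_phantom(spec: PhantomSpec) -> Tuple[CTVolume, np.ndarray]:
    """One phantom volume plus its nodule voxel mask (all-False for diffuse).

    The same seed always yields bit-identical output.  Intensities are
    clipped to the lung window so phantoms live in the same HU range that
    preprocessing would produce.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    amp = spec.texture_amplitude * rng.uniform(*spec.amplitude_jitter)
    mask = np.zeros(shape, dtype=bool)

    if spec.kind == "diffuse_texture":
        field = rng.standard_normal(shape)
        if spec.texture_correlation_length > 0:
            field = ndimage.gaussian_filter(field, spec.texture_correlation_length, mode="reflect")
        sd = field.std()
        if sd > 0:
            field = field / sd
        vox = spec.background + amp * field + rng.standard_normal(shape) * spec.noise_sd
        label = 1
    else:
        vox = spec.background + rng.standard_normal(shape) * spec.noise_sd
        r = spec.nodule_radius
        if spec.nodule_count > 0:
            if any(d < 2 * r + 1 for d in shape):
                raise ValueError(f"nodule radius {r} cannot fit shape {shape}")
            grids = np.meshgrid(*[np.arange(d) for d in shape], indexing="ij")
            for _ in range(spec.nodule_count):
                center = [rng.uniform(r, d - 1 - r) for d in shape]
                d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
                profile = np.exp(-d2 / (2.0 * (r / 1.5) ** 2))
                vox = vox + spec.nodule_contrast * profile
                mask |= d2 <= r * r
        label = 0

    vox = np.clip(vox, *spec.window)
    return CTVolume(voxels=vox, spacing=(1.0, 1.0, 1.0), label=label), mask


def default_class_specs(shape: Tuple[int, int, int] = (32, 32, 16),
                        effect: str = "easy") -> Tuple[PhantomSpec, PhantomSpec]:
    """Study-condition specs for the two classes.

    ``easy`` is the well-separated regime used by the end-to-end harness;
    ``hard`` shrinks the textural and focal contrast for ablation-ordering
    experiments.
    """
    if effect == "easy":
        pos = PhantomSpec(shape=shape, kind="diffuse_texture")
        neg = PhantomSpec(shape=shape, kind="focal_nodule")
    elif effect == "hard":
        pos = PhantomSpec(shape=shape, kind="diffuse_texture",
                          texture_correlation_length=0.8, texture_amplitude=80.0,
                          noise_sd=40.0)
        neg = PhantomSpec(shape=shape, kind="focal_nodule", noise_sd=40.0,
                          nodule_contrast=200.0, nodule_count=1)
    else:
        raise ValueError(f"unknown effect regime {effect!r}")
    return pos, neg


def correlation_contrast_specs(shape: Tuple[int, int, int] = (32, 32, 16),
                               length_pos: float = 1.2, length_neg: float = 0.3,
                               ) -> Tuple[PhantomSpec, PhantomSpec]:
    """Two diffuse-texture specs differing only in co-occurrence correlation.

    Matched amplitude/noise with a wide per-volume amplitude jitter make the
    co-occurrence correlation (not raw contrast) the discriminating factor:
    amplitude-sensitive statistics (energy, entropy, inertia) then vary as
    much within class as between classes while the correlation coefficient,
    being amplitude-invariant, separates cleanly.  Used by the
    feature-selection study.
    """
    jitter = (0.45, 1.55)
    pos = PhantomSpec(shape=shape, kind="diffuse_texture",
                      texture_correlation_length=length_pos,
                      amplitude_jitter=jitter)
    neg = PhantomSpec(shape=shape, kind="diffuse_texture",
                      texture_correlation_length=length_neg,
                      amplitude_jitter=jitter)
    # the negative class of this study is still labeled 0 downstream
    return pos, neg


def make_cohort(n_per_class: int, spec_pos: PhantomSpec, spec_neg: PhantomSpec,
                seed: int = 0) -> Tuple[List[CTVolume], List[np.ndarray], pd.DataFrame]:
    """A balanced labeled cohort with per-volume seeds derived from ``seed``.

    Returns (volumes, nodule masks, manifest).  The manifest records id,
    label, kind and per-volume seed so any member can be regenerated.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    volumes: List[CTVolume] = []
    masks: List[np.ndarray] = []
    records = []
    for i in range(2 * n_per_class):
        base = spec_pos if i < n_per_class else spec_neg
        label = 1 if i < n_per_class else 0
        sub = int(rng.integers(2**31 - 1))
        spec_i = replace(base, seed=sub)
        vol, mask = make_phantom(spec_i)
        vol.label = label  # correlation-contrast cohorts relabel the neg class
        volumes.append(vol)
        masks.append(mask)
        records.append({"id": i, "label": label, "kind": base.kind, "seed": sub})
    manifest = pd.DataFrame(records)
    return volumes, masks, manifest
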