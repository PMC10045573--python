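"""Synthetic low-contrast liver phantoms and labeled feature sets.

The generator emulates the regime of contrast-enhanced abdominal CT with
small, low-contrast hepatic lesions: a large smooth "liver" blob covering
20-50% of the frame over a darker background, containing small hypodense
ellipsoidal "tumours" whose mean intensity sits only ``contrast`` units
below the liver mean — deliberately close to it, since in the clinical data
this mimics, lesion and parenchyma attenuation are nearly identical. A
smooth multiplicative bias field and additive Gaussian noise complete the
image. All randomness flows from one seeded stream.

``generate_classification_set`` turns phantoms into a labeled HOG-feature
matrix: positives are tumour-containing crops resized to the canonical
128x64 window, negatives are tumour-free liver crops.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .elm import LabeledSet
from .exceptions import DomainError
from .hogfeat import hog_descriptor
from .imaging import BinaryMask, IntensityImage
from .interactions import BoundingBox

__all__ = ["PhantomSpec", "generate_phantom", "generate_classification_set", "two_gaussian_set", "EASY_SPEC"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic regime.

    Defaults: 256x256 frame, up to 3 hypodense tumours of radius 5-12 px,
    contrast 20 intensity units below a liver mean of 100 over background 40,
    noise sigma 5, multiplicative bias amplitude 0.05.
    """

    shape: Tuple[int, ...] = (256, 256)
    n_tumours: int = 3
    tumour_radius_range: Tuple[float, float] = (5.0, 12.0)
    contrast: float = 20.0
    noise_sigma: float = 5.0
    bias_amplitude: float = 0.05
    background_mean: float = 40.0
    liver_mean: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.tumour_radius_range[0] < 1:
            raise DomainError("tumour radii must be >= 1 pixel")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if self.n_tumours < 0:
            raise DomainError("n_tumours must be >= 0")
        if len(self.shape) not in (2, 3):
            raise DomainError("phantom must be 2D or 3D")


EASY_SPEC = PhantomSpec(contrast=40.0, noise_sigma=2.0)
"""High-contrast low-noise regime used for classifier calibration."""


def _smooth_noise(shape, rng, sigma_frac=0.08) -> np.ndarray:
    field = rng.standard_normal(shape)
    sigma = [max(1.0, sigma_frac * s) for s in shape]
    field = ndimage.gaussian_filter(field, sigma=sigma)
    field -= field.mean()
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def _liver_blob(shape, rng) -> np.ndarray:
    """Smooth random blob covering 20-50% of the frame (largest component,
    holes filled); retried with fresh noise if the fraction lands outside."""
    for _ in range(50):
        field = _smooth_noise(shape, rng)
        target = rng.uniform(0.28, 0.42)
        thresh = np.quantile(field, 1.0 - target)
        blob = field > thresh
        lab, nlab = ndimage.label(blob)
        if nlab == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        blob = lab == (1 + int(np.argmax(sizes)))
        blob = ndimage.binary_fill_holes(blob)
        frac = blob.mean()
        if 0.2 <= frac <= 0.5:
            return blob
    raise DomainError("could not generate a liver blob in the 20-50% area range")


def _ellipsoid_mask(shape, center, radii, angle, ndim) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = np.stack([g - c for g, c in zip(grids, center)])
    if ndim == 2:
        c, s = np.cos(angle), np.sin(angle)
        u = c * coords[0] - s * coords[1]
        v = s * coords[0] + c * coords[1]
        rot = np.stack([u, v])
    else:  # axis-aligned ellipsoids in 3D keep the generator simple
        rot = coords
    q = sum((rot[k] / radii[k]) ** 2 for k in range(ndim))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> Tuple[IntensityImage, BinaryMask, BinaryMask]:
    """Generate one phantom: (image, liver mask, tumour mask).

    Tumours are pairwise-disjoint ellipsoids fully inside the liver; if the
    requested count cannot be placed within bounded retries an error names
    the number placed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    ndim = len(shape)
    liver = _liver_blob(shape, rng)

    tumours = np.zeros(shape, dtype=bool)
    struct = ndimage.generate_binary_structure(ndim, 1)
    placed = 0
    for _ in range(spec.n_tumours):
        ok = False
        for _attempt in range(200):
            radii = rng.uniform(*spec.tumour_radius_range, size=ndim)
            margin = int(np.ceil(radii.max())) + 1
            interior = ndimage.binary_erosion(liver, structure=struct, iterations=margin)
            cand = np.argwhere(interior)
            if cand.size == 0:
                continue
            center = cand[rng.integers(len(cand))].astype(float)
            angle = rng.uniform(0, np.pi)
            ell = _ellipsoid_mask(shape, center, radii, angle, ndim)
            if not ell.any():
                continue
            if not (ell <= liver).all():
                continue
            # keep tumours separated by at least one pixel
            if (ndimage.binary_dilation(ell, structure=struct) & tumours).any():
                continue
            tumours |= ell
            ok = True
            break
        if ok:
            placed += 1
        else:
            raise DomainError(
                f"could only place {placed} of {spec.n_tumours} requested tumours"
            )

    image = np.full(shape, spec.background_mean, dtype=np.float64)
    image[liver] = spec.liver_mean
    image[tumours] = spec.liver_mean - spec.contrast
    if spec.bias_amplitude > 0:
        bias = _smooth_noise(shape, rng) * spec.bias_amplitude
        image = image * (1.0 + bias)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    return (
        IntensityImage(image),
        BinaryMask(liver.astype(np.uint8)),
        BinaryMask(tumours.astype(np.uint8)),
    )


def _component_bbox(mask: np.ndarray, expand: int, shape) -> BoundingBox:
    pts = np.argwhere(mask)
    lows = np.maximum(pts.min(axis=0) - expand, 0)
    highs = np.minimum(pts.max(axis=0) + expand, np.array(shape) - 1)
    return BoundingBox(tuple(int(v) for v in lows), tuple(int(v) for v in highs))


def _crop_to_window(values: np.ndarray, window=(128, 64)) -> np.ndarray:
    return resize(values, window, order=1, anti_aliasing=False, preserve_range=True)


def generate_classification_set(
    n_pos: int,
    n_neg: int,
    spec: Optional[PhantomSpec] = None,
    seed: int = 0,
    expand: int = 5,
    window: Tuple[int, int] = (128, 64),
    **hog_kwargs,
) -> LabeledSet:
    """Labeled HOG features: tumour crops (label 1) vs tumour-free liver
    crops (label 0), each resized to the canonical window.

    Descriptor entries are scaled to per-block vote *fractions* (counts /
    256) so classifier inputs are bounded in [0, 1].
    """
    if n_pos < 1 or n_neg < 1:
        raise DomainError("need at least one sample per class")
    spec = spec if spec is not None else PhantomSpec()
    if len(spec.shape) != 2:
        raise DomainError("classification sets are built from 2D phantoms")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    pos_left, neg_left = n_pos, n_neg
    struct = ndimage.generate_binary_structure(2, 1)
    while pos_left > 0 or neg_left > 0:
        sub = replace(
            spec,
            seed=int(rng.integers(2**31 - 1)),
            n_tumours=max(1, spec.n_tumours) if pos_left > 0 else 0,
        )
        img, liver, tumours = generate_phantom(sub)
        lab, nlab = ndimage.label(tumours.values, structure=struct)
        for k in range(1, nlab + 1):
            if pos_left <= 0:
                break
            box = _component_bbox(lab == k, expand, img.shape)
            rows.append(
                hog_descriptor(
                    _crop_to_window(img.values[box.slices], window), **hog_kwargs
                ).feature_vector
                / 256.0
            )
            labels.append(1)
            pos_left -= 1
        if neg_left > 0:
            # tumour-free boxes inside the liver, sized like tumour crops
            for _attempt in range(100):
                if neg_left <= 0:
                    break
                size = int(rng.uniform(2 * spec.tumour_radius_range[0], 2 * spec.tumour_radius_range[1]) + 2 * expand)
                h, w = img.shape
                if size >= min(h, w):
                    size = min(h, w) // 2
                r0 = int(rng.integers(0, h - size))
                c0 = int(rng.integers(0, w - size))
                region_liver = liver.values[r0 : r0 + size, c0 : c0 + size]
                region_tum = tumours.values[r0 : r0 + size, c0 : c0 + size]
                if region_liver.mean() < 0.9 or region_tum.any():
                    continue
                rows.append(
                    hog_descriptor(
                        _crop_to_window(img.values[r0 : r0 + size, c0 : c0 + size], window),
                        **hog_kwargs,
                    ).feature_vector
                    / 256.0
                )
                labels.append(0)
                neg_left -= 1
    X = np.vstack(rows)
    T = np.array(labels, dtype=np.float64)[:, None]
    return LabeledSet(X=X, T=T)


def two_gaussian_set(n_features: int = 4, n_samples: int = 200, separation: float = 3.0, seed: int = 0) -> LabeledSet:
    """Two-class isotropic Gaussian blobs whose means are ``separation``
    standard deviations apart; binary {0, 1} targets, balanced classes."""
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    mu = np.zeros(n_features)
    mu[0] = separation
    x0 = rng.standard_normal((n_samples - half, n_features))
    x1 = rng.standard_normal((half, n_features)) + mu
    X = np.vstack([x0, x1])
    T = np.concatenate([np.zeros(n_samples - half), np.ones(half)])[:, None]
    perm = rng.permutation(n_samples)
    return LabeledSet(X=X[perm], T=T[perm])
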