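"""Initial-segmentation stage: a pluggable (image, cue map) -> probability-pair contract.

The pipeline's initial phase feeds the normalized crop and its EGD cue map to
a segmenter that returns per-pixel foreground/background probabilities. The
contract is deliberately model-agnostic so that any learned predictor can be
registered; the shipped implementation is a deterministic, non-learned
baseline that combines the cue map with an intensity-similarity term fitted
to the pixels under the clicks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .exceptions import DomainError, ShapeError
from .geodesic import CueMap
from .imaging import IntensityImage

__all__ = ["ProbabilityPair", "Segmenter", "BaselineSegmenter", "baseline_predict", "SEGMENTERS", "get_segmenter"]


@dataclass
class ProbabilityPair:
    """Foreground/background probability maps summing to 1 per pixel."""

    Pf: np.ndarray
    Pb: np.ndarray

    def __post_init__(self):
        self.Pf = np.asarray(self.Pf, dtype=np.float64)
        self.Pb = np.asarray(self.Pb, dtype=np.float64)
        if self.Pf.shape != self.Pb.shape:
            raise ShapeError("Pf and Pb must share a shape")
        for name, p in (("Pf", self.Pf), ("Pb", self.Pb)):
            if p.min() < -1e-12 or p.max() > 1 + 1e-12:
                raise DomainError(f"{name} values must lie in [0, 1]")
        if not np.allclose(self.Pf + self.Pb, 1.0, atol=1e-9):
            raise DomainError("Pf + Pb must equal 1 elementwise")

    @property
    def shape(self):
        return self.Pf.shape


@runtime_checkable
class Segmenter(Protocol):
    def predict(self, img: IntensityImage, cue: CueMap) -> ProbabilityPair: ...


def baseline_predict(
    img: IntensityImage,
    cue: CueMap,
    smooth_sigma: float = 2.0,
    mix_weight: float = 0.5,
) -> ProbabilityPair:
    """Deterministic non-learned baseline.

    Pf = clip(mix_weight * cue + (1 - mix_weight) * similarity, 0, 1), where
    similarity = exp(-(I - mu)^2 / (2 s^2)) with mu, s the mean/std of the
    intensities at cue >= 0.99 pixels (the clicked neighborhood), smoothed by
    a Gaussian of ``smooth_sigma`` pixels (sigma=0 disables smoothing). With
    no cue >= 0.99 pixel the baseline falls back to Pf = cue.
    """
    if img.values.shape != cue.values.shape:
        raise ShapeError(
            f"image shape {img.values.shape} does not match cue shape {cue.values.shape}"
        )
    c = cue.values
    seedlike = c >= 0.99
    if not seedlike.any():
        pf = np.clip(c, 0.0, 1.0)
        return ProbabilityPair(pf, 1.0 - pf)
    vals = img.values[seedlike]
    mu = float(vals.mean())
    s = float(vals.std())
    if s <= 0:  # constant clicked intensities: fall back to a small scale
        s = max(1e-3, 1e-3 * (img.values.max() - img.values.min()))
    similarity = np.exp(-((img.values - mu) ** 2) / (2.0 * s * s))
    if smooth_sigma > 0:
        similarity = ndimage.gaussian_filter(similarity, sigma=smooth_sigma)
    pf = np.clip(mix_weight * c + (1.0 - mix_weight) * similarity, 0.0, 1.0)
    return ProbabilityPair(pf, 1.0 - pf)


@dataclass(frozen=True)
class BaselineSegmenter:
    """Registered baseline implementation of the segmenter contract."""

    smooth_sigma: float = 2.0
    mix_weight: float = 0.5

    def predict(self, img: IntensityImage, cue: CueMap) -> ProbabilityPair:
        return baseline_predict(img, cue, self.smooth_sigma, self.mix_weight)


SEGMENTERS: Dict[str, Callable[..., Segmenter]] = {"baseline": BaselineSegmenter}


def get_segmenter(name: str, **kwargs) -> Segmenter:
    try:
        factory = SEGMENTERS[name]
    except KeyError:
        raise DomainError(f"unknown segmenter {name!r}; registered: {sorted(SEGMENTERS)}") from None
    return factory(**kwargs)
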