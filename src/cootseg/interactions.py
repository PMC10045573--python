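"""Click simulation and bounding-box geometry.

At training/evaluation time, user clicks are emulated from a ground-truth
mask as *inner margin points*: points picked on the object's inner boundary —
one near each axis-aligned extreme so the object is fully enclosed, plus a
few random boundary points for shape context — then shifted a little towards
the interior, mimicking slightly inaccurate clicks placed just inside the
edge. A relaxed bounding box of these points (expanded by a few pixels)
defines the crop the rest of the pipeline works in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import DomainError
from .imaging import BinaryMask, IntensityImage

__all__ = [
    "ClickSet",
    "BoundingBox",
    "simulate_inner_margin_points",
    "relaxed_bbox",
    "crop",
    "crop_mask",
    "paste_back",
]

Coord = Tuple[int, ...]


@dataclass
class ClickSet:
    """Ordered foreground/background click coordinates (0-based, row-major)."""

    fg: List[Coord] = field(default_factory=list)
    bg: List[Coord] = field(default_factory=list)

    def __post_init__(self):
        self.fg = [tuple(int(v) for v in c) for c in self.fg]
        self.bg = [tuple(int(v) for v in c) for c in self.bg]
        if set(self.fg) & set(self.bg):
            raise DomainError("a pixel cannot be both a foreground and a background click")

    def check_in_bounds(self, shape: Sequence[int]) -> None:
        for c in self.fg + self.bg:
            if len(c) != len(shape) or any(v < 0 or v >= s for v, s in zip(c, shape)):
                raise DomainError(f"click {c} outside image bounds {tuple(shape)}")

    def merged(self, other: "ClickSet") -> "ClickSet":
        """Cumulative click set; duplicates are dropped, order preserved."""
        fg = list(dict.fromkeys(self.fg + other.fg))
        bg = list(dict.fromkeys(self.bg + other.bg))
        return ClickSet(fg=fg, bg=bg)

    def to_json(self) -> str:
        return json.dumps({"fg": [list(c) for c in self.fg], "bg": [list(c) for c in self.bg]})

    @classmethod
    def from_json(cls, text: str) -> "ClickSet":
        d = json.loads(text)
        return cls(fg=[tuple(c) for c in d.get("fg", [])], bg=[tuple(c) for c in d.get("bg", [])])


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis inclusive [low, high] integer bounds."""

    lows: Tuple[int, ...]
    highs: Tuple[int, ...]

    def __post_init__(self):
        if len(self.lows) != len(self.highs):
            raise DomainError("lows/highs length mismatch")
        if any(l > h for l, h in zip(self.lows, self.highs)):
            raise DomainError(f"bounding box has low > high: {self.lows} / {self.highs}")

    @property
    def ndim(self) -> int:
        return len(self.lows)

    @property
    def slices(self) -> Tuple[slice, ...]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lows, self.highs))

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(h - l + 1 for l, h in zip(self.lows, self.highs))

    def contains_point(self, c: Coord) -> bool:
        return all(l <= v <= h for v, l, h in zip(c, self.lows, self.highs))

    def shift_into(self, c: Coord) -> Coord:
        """Translate a full-frame coordinate into crop coordinates."""
        return tuple(int(v - l) for v, l in zip(c, self.lows))


def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 4-adjacent (2D) / 6-adjacent (3D) to background."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask.astype(bool) & ~eroded


def _shift_inward(point: np.ndarray, mask: np.ndarray, centroid: np.ndarray, dist: int) -> Coord:
    """Walk up to ``dist`` unit steps from a boundary point towards the centroid,
    stopping early if the next step would exit the mask."""
    pos = point.astype(np.int64).copy()
    direction = centroid - point
    norm = np.linalg.norm(direction)
    if norm == 0:
        return tuple(int(v) for v in pos)
    step_f = direction / norm
    acc = np.zeros_like(step_f)
    for _ in range(dist):
        acc = acc + step_f
        step = np.round(acc).astype(np.int64)
        nxt = pos + step
        acc = acc - step
        if np.array_equal(nxt, pos):
            continue
        if np.any(nxt < 0) or np.any(nxt >= np.array(mask.shape)) or not mask[tuple(nxt)]:
            break
        pos = nxt
    return tuple(int(v) for v in pos)


def simulate_inner_margin_points(
    mask: BinaryMask,
    n_extra: int = 5,
    inward_shift_range: Tuple[int, int] = (1, 3),
    seed: int = 0,
) -> ClickSet:
    """Emulate user clicks enclosing an object, from its ground-truth mask.

    Two stages: (1) pick one boundary point at each of the 2*ndim axis-aligned
    extremes (ties broken by lowest lexicographic coordinate) plus ``n_extra``
    random boundary points; (2) shift every point towards the object centroid
    by an integer distance drawn uniformly from ``inward_shift_range``,
    stopping at the mask edge. Returns foreground clicks only.
    """
    m = mask.values.astype(bool)
    if not m.any():
        raise DomainError("mask has no foreground pixels")
    boundary = _inner_boundary(m)
    if not boundary.any():
        # degenerate: e.g. full-frame mask has no background-adjacent pixels
        boundary = m
    bpts = np.argwhere(boundary)  # sorted lexicographically by argwhere
    # independent streams so extra-point selection does not perturb the
    # extremes' inward shifts (adding extras may only grow the click hull)
    sel_rng, shift_rng = (
        np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(2)
    )
    centroid = np.argwhere(m).mean(axis=0)

    chosen: List[int] = []
    for ax in range(m.ndim):
        for extreme in (np.argmin, np.argmax):
            vals = bpts[:, ax]
            target = vals[extreme(vals)]
            # lowest lexicographic row among those attaining the extreme
            idx = int(np.flatnonzero(vals == target)[0])
            chosen.append(idx)
    chosen_set = set(chosen)
    remaining = [i for i in range(len(bpts)) if i not in chosen_set]
    if n_extra > 0 and remaining:
        extra = sel_rng.choice(len(remaining), size=min(n_extra, len(remaining)), replace=False)
        chosen.extend(remaining[i] for i in sorted(int(e) for e in extra))

    lo, hi = inward_shift_range
    points: List[Coord] = []
    for idx in chosen:  # extremes first: their shifts are independent of n_extra
        dist = int(shift_rng.integers(lo, hi + 1))
        points.append(_shift_inward(bpts[idx], m, centroid, dist))
    return ClickSet(fg=list(dict.fromkeys(points)), bg=[])


def relaxed_bbox(points: ClickSet, expand: int, image_shape: Sequence[int]) -> BoundingBox:
    """Coordinate-wise min/max box of the foreground clicks, expanded by
    ``expand`` pixels per side and clipped to the image bounds."""
    if not points.fg:
        raise DomainError("cannot build a bounding box from an empty click set")
    arr = np.array(points.fg)
    lows = np.maximum(arr.min(axis=0) - expand, 0)
    highs = np.minimum(arr.max(axis=0) + expand, np.array(image_shape) - 1)
    return BoundingBox(tuple(int(v) for v in lows), tuple(int(v) for v in highs))


def crop(img: IntensityImage, box: BoundingBox) -> IntensityImage:
    """Extract the boxed sub-image (values copied; box records the offset)."""
    _check_box(box, img.shape)
    return IntensityImage(img.values[box.slices].copy(), spacing=img.spacing)


def crop_mask(mask: BinaryMask, box: BoundingBox) -> BinaryMask:
    _check_box(box, mask.shape)
    return BinaryMask(mask.values[box.slices].copy())


def paste_back(full_shape: Sequence[int], box: BoundingBox, values: np.ndarray, fill=0):
    """Place crop-sized ``values`` back into a full-frame array of ``full_shape``."""
    if tuple(values.shape) != box.shape:
        raise DomainError(f"values shape {values.shape} does not match box shape {box.shape}")
    out = np.full(tuple(full_shape), fill, dtype=values.dtype)
    out[box.slices] = values
    return out


def _check_box(box: BoundingBox, shape: Sequence[int]) -> None:
    if box.ndim != len(shape):
        raise DomainError("box/image dimensionality mismatch")
    if any(l < 0 or h >= s for l, h, s in zip(box.lows, box.highs, shape)):
        raise DomainError(f"box {box} outside image of shape {tuple(shape)}")
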