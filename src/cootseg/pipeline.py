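"""End-to-end orchestration: initial phase, refinement rounds, classification.

Phase 1: foreground margin clicks imply a relaxed bounding box; the crop is
min-max normalized to [0, 1], the EGD cue map is computed from the clicks,
and the registered segmenter turns (crop, cue) into probabilities that are
thresholded at 0.5 and pasted back into the full frame.

Phase 2 (repeatable): each round adds refinement clicks; cue maps Ef/Eb and
the locality weight alpha are recomputed from the *cumulative* refinement
click set, fused against the ORIGINAL initial probabilities, and the fused
probabilities are re-cut by the graph-cut CRF with the clicks as hard
constraints.

Classification: the bounding-box crop is resized to the canonical 128x64
window, selective-bin HOG features are extracted, and the (COA-)ELM
predicts the binary tumour label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .elm import ELMModel, elm_predict
from .exceptions import DomainError, StateError
from .geodesic import egd_cue_map
from .hogfeat import hog_descriptor
from .imaging import BinaryMask, IntensityImage, NormalizationSpec, normalize
from .interactions import BoundingBox, ClickSet, crop, crop_mask, paste_back, relaxed_bbox, simulate_inner_margin_points
from .metrics import dice
from .phantom import PhantomSpec, generate_phantom
from .refine import CrfParams, crf_energy, fuse, graph_cut_refine, refinement_cue_maps
from .segmenter import ProbabilityPair, get_segmenter

__all__ = [
    "RunConfig",
    "Round",
    "Session",
    "run_initial",
    "run_refine",
    "run_classify",
    "oracle_clicks",
    "initial_suite",
    "refinement_trajectories",
]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs with their defaults; every stage reads from here."""

    segmenter: str = "baseline"
    smooth_sigma: float = 2.0
    mix_weight: float = 0.5
    connectivity: int = 8
    expand: int = 5
    normalization: NormalizationSpec = NormalizationSpec(0.0, 1.0)
    crf: CrfParams = CrfParams()
    window: Tuple[int, int] = (128, 64)
    high_bins: int = 9
    low_bins: int = 4
    seed: int = 0


@dataclass
class Round:
    mask: BinaryMask  # full-frame labeling after this round
    energy: float
    clicks_added: ClickSet


@dataclass
class Session:
    """State of one interactive segmentation: crop geometry, the original
    probability pair, and the per-round refined masks/energies."""

    image: IntensityImage
    box: BoundingBox
    crop_raw: IntensityImage
    crop_norm: IntensityImage
    initial_clicks: ClickSet
    P: ProbabilityPair
    initial_mask: BinaryMask
    refinement_clicks: ClickSet = field(default_factory=ClickSet)
    rounds: List[Round] = field(default_factory=list)

    @property
    def current_mask(self) -> BinaryMask:
        return self.rounds[-1].mask if self.rounds else self.initial_mask


def run_initial(img: IntensityImage, clicks: ClickSet, config: RunConfig = RunConfig()) -> Session:
    """Phase 1: crop, cue, segment, threshold at 0.5, paste back."""
    if not clicks.fg:
        raise DomainError("the initial phase requires at least one foreground click")
    clicks.check_in_bounds(img.shape)
    box = relaxed_bbox(clicks, config.expand, img.shape)
    sub = crop(img, box)
    sub_norm = normalize(sub, config.normalization)
    seeds = [box.shift_into(c) for c in clicks.fg]
    cue = egd_cue_map(sub_norm.values, seeds, connectivity=config.connectivity)
    seg = get_segmenter(config.segmenter, smooth_sigma=config.smooth_sigma, mix_weight=config.mix_weight)
    P = seg.predict(sub_norm, cue)
    crop_mask_arr = (P.Pf >= 0.5).astype(np.uint8)
    full = paste_back(img.shape, box, crop_mask_arr)
    return Session(
        image=img,
        box=box,
        crop_raw=sub,
        crop_norm=sub_norm,
        initial_clicks=clicks,
        P=P,
        initial_mask=BinaryMask(full),
    )


def run_refine(session: Session, new_clicks: ClickSet, config: RunConfig = RunConfig()) -> Session:
    """One refinement round over the cumulative refinement click set."""
    new_clicks.check_in_bounds(session.image.shape)
    for c in new_clicks.fg + new_clicks.bg:
        if not session.box.contains_point(c):
            raise DomainError(f"refinement click {c} falls outside the session crop {session.box}")
    session.refinement_clicks = session.refinement_clicks.merged(new_clicks)
    local = ClickSet(
        fg=[session.box.shift_into(c) for c in session.refinement_clicks.fg],
        bg=[session.box.shift_into(c) for c in session.refinement_clicks.bg],
    )
    # cue maps on native intensity units: alpha = e^-D must stay local to the
    # clicks, and native-scale neighbor differences give distances >> 1
    maps = refinement_cue_maps(session.crop_raw, local, connectivity=config.connectivity)
    R = fuse(session.P, maps)
    refined = graph_cut_refine(R, session.crop_raw, local, config.crf)
    energy = crf_energy(refined, R, session.crop_raw, local, config.crf)
    full = paste_back(session.image.shape, session.box, refined.values)
    session.rounds.append(Round(mask=BinaryMask(full), energy=energy, clicks_added=new_clicks))
    return session


def run_classify(session: Session, model: ELMModel, config: RunConfig = RunConfig()) -> int:
    """Resize the session crop to the canonical window, extract HOG, predict."""
    if model.beta is None:
        raise StateError("classifier has no output weights; train it first")
    win = resize(
        session.crop_raw.values, config.window, order=1, anti_aliasing=False, preserve_range=True
    )
    # same vote-fraction scaling as the training features
    feats = (
        hog_descriptor(win, high_bins=config.high_bins, low_bins=config.low_bins).feature_vector
        / 256.0
    )
    return int(elm_predict(model, feats[None, :])[0])


def oracle_clicks(session: Session, gt: BinaryMask, seed: int = 0) -> ClickSet:
    """Simulated corrective click: an interior point of the largest
    mis-segmented component (FN components get a foreground click, FP a
    background one)."""
    gt.check_congruent(session.image)
    cur = session.current_mask.values.astype(bool)
    truth = gt.values.astype(bool)
    inside = np.zeros_like(truth)
    inside[session.box.slices] = True
    fn = truth & ~cur & inside
    fp = cur & ~truth & inside
    already = set(session.refinement_clicks.fg + session.refinement_clicks.bg)
    best = None  # (size, kind, coord)
    for err, kind in ((fn, "fg"), (fp, "bg")):
        lab, nlab = ndimage.label(err)
        for k in range(1, nlab + 1):
            comp = lab == k
            size = int(comp.sum())
            # deepest interior point of the component is a robust click spot
            dist = ndimage.distance_transform_edt(comp)
            order = np.argsort(dist.ravel())[::-1]
            coord = None
            for flat in order[: min(32, size)]:
                c = tuple(int(v) for v in np.unravel_index(flat, comp.shape))
                if comp[c] and c not in already:
                    coord = c
                    break
            if coord is None:
                continue
            if best is None or size > best[0]:
                best = (size, kind, coord)
    if best is None:
        return ClickSet()
    _, kind, coord = best
    return ClickSet(fg=[coord] if kind == "fg" else [], bg=[coord] if kind == "bg" else [])


# ---------------------------------------------------------------------------
# Seeded evaluation suites (shared by tests and the acceptance script)
# ---------------------------------------------------------------------------

def _suite_spec(seed: int, contrast: Optional[float] = None) -> PhantomSpec:
    spec = PhantomSpec(n_tumours=1, seed=seed)
    if contrast is not None:
        spec = replace(spec, contrast=contrast)
    return spec


def initial_suite(
    n_phantoms: int = 20,
    seed: int = 0,
    config: RunConfig = RunConfig(),
    contrast: Optional[float] = None,
) -> List[float]:
    """Initial-phase Dice scores over seeded single-tumour phantoms."""
    scores = []
    for k in range(n_phantoms):
        spec = _suite_spec(seed + k, contrast)
        img, _liver, tumours = generate_phantom(spec)
        clicks = simulate_inner_margin_points(tumours, seed=seed + k)
        session = run_initial(img, clicks, config)
        scores.append(dice(tumours, session.initial_mask))
    return scores


def classification_calibration(seed: int = 0, n_pos: int = 60, n_neg: int = 60):
    """Classifier calibration in the high-contrast regime: COA-ELM vs plain
    ELM test accuracy on a held-out 30% split of phantom-derived features.

    Returns ``(coa_accuracy, plain_accuracy, n_test)``. Settings: L=200
    hidden units, ridge 1.0, COA budget 15 coots x 10 iterations.
    """
    from .coa import CoaParams
    from .elm import LabeledSet, coa_elm_train, elm_predict, elm_train
    from .phantom import EASY_SPEC, generate_classification_set

    data = generate_classification_set(n_pos, n_neg, spec=EASY_SPEC, seed=seed)
    rng = np.random.default_rng(seed)
    n = data.X.shape[0]
    idx = rng.permutation(n)
    n_test = int(0.3 * n)
    test, train = idx[:n_test], idx[n_test:]
    tr = LabeledSet(data.X[train], data.T[train])
    y = data.labels
    coa = coa_elm_train(
        tr, L=200, ridge=1.0, coa_params=CoaParams(n_coots=15, iter_max=10, seed=seed), seed=seed
    )
    plain = elm_train(tr, L=200, ridge=1.0, seed=seed)
    coa_acc = float(np.mean(elm_predict(coa, data.X[test]) == y[test]))
    plain_acc = float(np.mean(elm_predict(plain, data.X[test]) == y[test]))
    return coa_acc, plain_acc, n_test


def refinement_trajectories(
    n_phantoms: int = 20,
    n_rounds: int = 3,
    seed: int = 0,
    config: RunConfig = RunConfig(),
) -> List[List[float]]:
    """Dice per round (index 0 = initial) under oracle corrective clicks."""
    trajs = []
    for k in range(n_phantoms):
        spec = _suite_spec(seed + k)
        img, _liver, tumours = generate_phantom(spec)
        clicks = simulate_inner_margin_points(tumours, seed=seed + k)
        session = run_initial(img, clicks, config)
        traj = [dice(tumours, session.initial_mask)]
        for r in range(n_rounds):
            extra = oracle_clicks(session, tumours, seed=seed + 31 * r)
            session = run_refine(session, extra, config)
            traj.append(dice(tumours, session.current_mask))
        trajs.append(traj)
    return trajs
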