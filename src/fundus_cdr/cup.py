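"""Optic cup segmentation: four-loop thresholding cascade with automatic
error detection and circular Hough approximation.

Each loop multilevel-thresholds the (optionally contrast-enhanced) disc ROI,
keeps the brightest surviving spot, heals vessel-induced gaps, and fits a
circle by Hough voting. A loop's result is rejected — triggering the next
loop — when the fitted cup is implausibly small (area at or below a floor
that is 3000 px in the 2376-px-wide reference frame, scaled by relative image
area) or touches the disc boundary. Loop order is fixed: thresholds
(3, 2, 4, 3) with contrast enhancement on for the first two loops only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.draw import disk as draw_disk
from skimage.measure import label as cc_label
from skimage.morphology import closing, dilation, disk, erosion
from skimage.transform import hough_circle

from .core import LabelImage, ValidationError
from .t2fuzzy import DeParams, apply_thresholds, de_optimize, histogram

#: the cascade: (loop index, number of thresholds k, contrast enhancement)
CUP_LOOPS: tuple[tuple[int, int, bool], ...] = ((1, 3, True), (2, 2, True), (3, 4, False), (4, 3, False))


@dataclass(frozen=True)
class CupConfig:
    """Cascade tuning. ``area_floor`` is quoted for ``reference_width``-wide
    frames and scaled by relative image area unless ``scale_area_floor`` is
    off (the unscaled mode reproduces the literal constant)."""

    min_spot: int = 50
    area_floor: float = 3000.0
    scale_area_floor: bool = True
    reference_width: int = 2376
    closing_radius: int = 3
    bridge_radius: int = 6
    enhance_percentiles: tuple[float, float] = (1.0, 99.0)
    hough_radius_rel: tuple[float, float] = (0.15, 0.6)
    fou_width: float = 10.0
    de_population: int = 30
    de_generations: int = 100
    seed: int = 0
    area_test_after_hough: bool = False


@dataclass
class CupResult:
    """Cascade outcome; on success the mask is the Hough circle's filled
    interior (ROI frame) and ``loop_used`` records which loop accepted."""

    success: bool
    loop_used: int | None = None
    mask: np.ndarray | None = None
    area: int = 0
    centroid: tuple[float, float] | None = None
    circle: tuple[float, float, float] | None = None  # (row, col, radius)
    loops_log: list = field(default_factory=list)


def scaled_area_floor(cfg: CupConfig, image_width: int) -> float:
    if not cfg.scale_area_floor:
        return cfg.area_floor
    return cfg.area_floor * (image_width / cfg.reference_width) ** 2


def enhance_contrast(gray: np.ndarray, percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Linear stretch of the ROI to full 8-bit range between the given percentiles."""
    lo, hi = np.percentile(gray, percentiles)
    if hi <= lo:
        return gray.copy()
    out = (gray.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def brightest_region(labels: LabelImage, min_spot: int = 50, center: tuple[float, float] | None = None) -> np.ndarray:
    """Largest component of the top intensity class, after discarding bright
    spots smaller than ``min_spot`` pixels (strictly less-than, so a spot of
    exactly ``min_spot`` survives). Ties go to the component closest to
    ``center`` (ROI center by default). Empty mask when nothing survives."""
    top = labels.grid == labels.k
    cc = cc_label(top, connectivity=2)
    n = cc.max()
    if n == 0:
        return np.zeros_like(top, dtype=bool)
    if center is None:
        center = ((top.shape[0] - 1) / 2, (top.shape[1] - 1) / 2)
    sizes = np.bincount(cc.ravel())
    best, best_key = None, None
    for lab in range(1, n + 1):
        if sizes[lab] < min_spot:
            continue
        rows, cols = np.nonzero(cc == lab)
        dist = np.hypot(rows.mean() - center[0], cols.mean() - center[1])
        key = (-sizes[lab], dist)  # largest area, tie -> closest to center
        if best_key is None or key < best_key:
            best, best_key = lab, key
    if best is None:
        return np.zeros_like(top, dtype=bool)
    return cc == best


def refine_cup(mask: np.ndarray, vessels: np.ndarray, closing_radius: int = 3, bridge_radius: int = 6) -> np.ndarray:
    """Heal vessel-induced gaps in the bright spot.

    Vessel pixels are brought back only where they fall inside the spot's
    internal gaps — the region added by a morphological closing of the spot
    with a ``bridge_radius`` disk. That bridges parts of the cup that a
    crossing vessel split apart, without following the vessel track outward
    and dragging the candidate beyond the cup. A final closing with
    ``closing_radius`` seals residual pinholes, interior holes are filled,
    and the largest component is returned as the single cup candidate.
    Empty input gives empty output; the output always contains the input's
    largest component, so its area never shrinks below a single-component
    input's.
    """
    mask = np.asarray(mask, dtype=bool)
    vessels = np.asarray(vessels, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    joined = mask
    if bridge_radius > 0:
        gaps = closing(mask, disk(bridge_radius)) & ~mask
        joined = mask | (vessels & gaps)
    if closing_radius > 0:
        joined = closing(joined, disk(closing_radius))
    joined = binary_fill_holes(joined)
    cc2 = cc_label(joined, connectivity=2)
    sizes = np.bincount(cc2.ravel())
    sizes[0] = 0
    return cc2 == sizes.argmax()


def hough_circle_fit(mask: np.ndarray, r_min: int, r_max: int) -> tuple[float, float, float]:
    """Accumulator-maximal circle over the mask's boundary pixels.

    Radii are swept in ``[r_min, r_max]``; returns ``(row, col, radius)``.
    Downstream area/centroid/extent computations use the circle's filled
    interior in place of the raw mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot fit a circle to an empty mask")
    boundary = mask & ~erosion(mask, disk(1))
    r_min = max(1, int(r_min))
    r_max = max(r_min, int(r_max))
    radii = np.arange(r_min, r_max + 1)
    accum = hough_circle(boundary, radii)
    # hough_circle normalizes by circumference; rescale to absolute vote
    # counts so a short dense arc cannot outvote the true (larger) circle
    votes = accum * radii[:, None, None]
    ri, rowi, coli = np.unravel_index(int(np.argmax(votes)), votes.shape)
    return float(rowi), float(coli), float(radii[ri])


def filled_circle(circle: tuple[float, float, float], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((circle[0], circle[1]), circle[2] + 0.5, shape=shape)
    out[rr, cc] = True
    return out


def touches_disc_boundary(cup: np.ndarray, disc: np.ndarray) -> bool:
    """True when any cup pixel is 8-adjacent to a non-disc pixel (or outside)."""
    outside = ~np.asarray(disc, dtype=bool)
    near_outside = dilation(outside, disk(1))
    return bool(np.any(cup & near_outside))


def _run_loop(
    loop: int,
    k: int,
    enhance: bool,
    roi_gray: np.ndarray,
    vessels: np.ndarray,
    disc: np.ndarray,
    cfg: CupConfig,
) -> tuple[np.ndarray | None, tuple[float, float, float] | None, np.ndarray | None]:
    """One cascade loop: threshold, brightest spot, gap healing, Hough fit.

    Returns ``(fitted_cup, circle, candidate)`` — the circle's filled
    interior, its parameters and the pre-fit candidate mask — or a triple of
    ``None`` when the loop produces no candidate. Separated from the cascade
    driver so the loop-order contract can be exercised with scripted
    candidates.
    """
    img = enhance_contrast(roi_gray, cfg.enhance_percentiles) if enhance else roi_gray
    hist = histogram(img)
    if np.count_nonzero(hist) <= k:
        return None, None, None
    de = DeParams(population=cfg.de_population, generations=cfg.de_generations, seed=cfg.seed + loop)
    ts = de_optimize(hist, k, de, cfg.fou_width)
    labels = apply_thresholds(img, ts)
    spot = brightest_region(labels, cfg.min_spot)
    cand = refine_cup(spot, vessels, cfg.closing_radius, cfg.bridge_radius)
    if not cand.any():
        return None, None, None
    disc_r_eq = np.sqrt(max(disc.sum(), 1) / np.pi)
    r_min = int(round(cfg.hough_radius_rel[0] * disc_r_eq))
    r_max = int(round(cfg.hough_radius_rel[1] * disc_r_eq))
    circle = hough_circle_fit(cand, r_min, r_max)
    return filled_circle(circle, roi_gray.shape), circle, cand


def segment_cup(
    roi_gray: np.ndarray,
    disc: np.ndarray,
    vessels: np.ndarray,
    cfg: CupConfig = CupConfig(),
    image_width: int | None = None,
) -> CupResult:
    """Run the four-loop cascade inside the disc ROI.

    ``roi_gray``, ``disc`` and ``vessels`` share the ROI frame; ``disc`` must
    be a successful disc segmentation. ``image_width`` (full frame) sets the
    area-floor scaling; defaults to the reference frame width. Loops run
    strictly in order and the first loop that clears the area floor without
    touching the disc boundary wins; exhausting all four is the failure
    state. By default the two error conditions are checked on the pre-fit
    candidate mask (``area_test_after_hough=False``): a loop whose threshold
    slices into the disc interior grows a candidate that reaches the disc rim
    (typically along a vessel) and is rejected there, which is what lets the
    cascade fall through to a loop that isolates the cup; checking the fitted
    circle instead would mask such failures, since the bounded Hough radius
    keeps any circle clear of the rim.
    """
    roi_gray = np.asarray(roi_gray)
    if image_width is None:
        image_width = cfg.reference_width
    floor = scaled_area_floor(cfg, image_width)
    log = []
    for loop, k, enh in CUP_LOOPS:
        cup, circle, cand = _run_loop(loop, k, enh, roi_gray, vessels, disc, cfg)
        if cup is None:
            log.append({"loop": loop, "k": k, "enhance": enh, "area": 0, "touching": None, "accepted": False})
            continue
        tested = cup if cfg.area_test_after_hough else cand
        area = int(tested.sum())
        touching = touches_disc_boundary(tested, disc)
        accepted = area > floor and not touching
        log.append({"loop": loop, "k": k, "enhance": enh, "area": area, "touching": touching, "accepted": accepted})
        if accepted:
            rows, cols = np.nonzero(cup)
            return CupResult(
                success=True,
                loop_used=loop,
                mask=cup,
                area=int(cup.sum()),
                centroid=(float(rows.mean()), float(cols.mean())),
                circle=circle,
                loops_log=log,
            )
    return CupResult(success=False, loops_log=log)
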