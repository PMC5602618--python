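"""End-to-end segmentation of a single fundus image.

Ties the stages together: vessel extraction and inpainting, disc
localization and level-set segmentation (path chosen by image quality),
the four-loop cup cascade inside the disc ROI, and the six-parameter record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FundusImage, RegionParams
from .cup import CupConfig, CupResult, segment_cup
from .disc import DiscResult, LevelSetParams, segment_disc
from .metrics import region_params
from .t2fuzzy import DeParams
from .vessels import VesselParams, extract_vessels, inpaint, scaled_radius


@dataclass
class SegmentationRecord:
    """Everything the pipeline produced for one image."""

    status: str  # "ok" | "not_localized" | "cup_failed"
    disc: DiscResult
    cup: CupResult | None = None
    params: RegionParams | None = None
    cup_mask_full: np.ndarray | None = None


def segment_image(image: FundusImage, config: dict | None = None) -> SegmentationRecord:
    """Run the full disc + cup pipeline on one image.

    ``config`` follows the layout of :data:`fundus_cdr.config.DEFAULTS`;
    omitted blocks fall back to defaults. The record's ``params`` carries the
    six parameters only when both stages succeed.
    """
    from .config import DEFAULTS, merge_config

    cfg = merge_config(DEFAULTS, config or {})
    seed = int(cfg["seed"])

    vradius = scaled_radius(image.width, cfg["vessel"]["radius"]) if cfg["vessel"]["scale_with_width"] else cfg["vessel"]["radius"]
    vp = VesselParams(
        radius=vradius,
        threshold_rule=cfg["vessel"]["threshold_rule"],
        fixed_threshold=cfg["vessel"]["fixed_threshold"],
        prefilter_sigma=cfg["vessel"]["prefilter_sigma"],
        inpaint_iterations=cfg["vessel"]["inpaint_iterations"],
    )
    vessels = extract_vessels(image, vp)
    inpainted = inpaint(image, vessels, iterations=vp.inpaint_iterations)

    ls = LevelSetParams(**cfg["level_set"])
    de = DeParams(seed=seed, **cfg["de"])
    disc = segment_disc(
        image,
        vessel_params=vp,
        ls_params=ls,
        k=cfg["localize"]["k"],
        seed=seed,
        roi_fraction=cfg["localize"]["roi_fraction"],
        min_component_frac=cfg["localize"]["min_component_frac"],
        fou_width=cfg["fou_width"],
        de_params=de,
        vessels=vessels,
        inpainted=inpainted,
    )
    if not disc.localized:
        return SegmentationRecord(status="not_localized", disc=disc)

    roi = disc.roi
    roi_gray = roi.extract(inpainted.green)
    disc_roi = roi.extract(disc.mask)
    vessels_roi = roi.extract(vessels)
    ccfg = CupConfig(seed=seed, fou_width=cfg["fou_width"], **cfg["cup"])
    cup = segment_cup(roi_gray, disc_roi, vessels_roi, ccfg, image_width=image.width)
    if not cup.success:
        return SegmentationRecord(status="cup_failed", disc=disc, cup=cup)

    cup_full = roi.embed(cup.mask, (image.height, image.width))
    params = region_params(disc.mask, cup_full)
    return SegmentationRecord(status="ok", disc=disc, cup=cup, params=params, cup_mask_full=cup_full)
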