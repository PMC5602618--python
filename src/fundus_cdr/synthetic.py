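"""Synthetic fundus phantoms and simulated grader markings.

The phantom emulates what the segmentation pipeline actually relies on in a
fundus photograph of the optic nerve head: a bright elliptical optic disc
containing a brighter elliptical cup, dark curvilinear vessels crossing both,
background vignetting, optical blur and sensor noise. Ground-truth masks and
the derived six-parameter record make every downstream stage testable without
clinical images.

The grader simulator perturbs a ground-truth record into per-ophthalmologist
markings with controllable jitter, and injects gross outliers whose identity
is returned in a ledger so detection sensitivity/specificity can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, binary_dilation
from skimage.draw import ellipse, disk

from .core import FundusImage, MarkingTable, RegionParams, ValidationError
from .metrics import region_params

#: native frame sizes (rows, cols) of the three clinical camera families the
#: generator mimics, plus a small profile for fast tests
PROFILE_SHAPES = {
    "messidor": (1488, 2240),
    "binrushed": (1584, 2376),
    "magrabi": (1936, 2743),
    "small": (512, 512),
}

#: image-quality routing per profile (nonmydriatic frames take the double level-set path)
PROFILE_QUALITY = {
    "messidor": "high_quality",
    "binrushed": "low_quality",
    "magrabi": "high_quality",
    "small": "high_quality",
}

PARAM_IDS = ("disc_area", "disc_centroid", "cup_area", "cup_centroid", "hcdr", "vcdr")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and photometry of one synthetic optic-nerve-head image.

    ``disc_axes`` are (vertical, horizontal) semi-axes in pixels; the cup is a
    concentric ellipse with semi-axes ``(cdr_v, cdr_h) * disc_axes``.
    Brightness values are 8-bit gray levels.
    """

    shape: tuple[int, int] = (512, 512)
    disc_center: tuple[int, int] | None = None  # defaults to the image center
    disc_axes: tuple[float, float] = (52.0, 48.0)
    cdr_h: float = 0.5
    cdr_v: float = 0.5
    disc_brightness: int = 150
    cup_brightness: int = 200
    background_level: int = 60
    vignette_strength: float = 0.25
    n_vessels: int = 4
    vessel_width: int = 3
    noise_sigma: float = 8.0
    blur_sigma: float = 1.5
    seed: int = 0
    profile: str = "small"

    def __post_init__(self):
        if not (0 < self.cdr_h < 1 and 0 < self.cdr_v < 1):
            raise ValidationError("cup axes must be strictly inside the disc (0 < cdr < 1)")
        if not (self.cup_brightness > self.disc_brightness > self.background_level):
            raise ValidationError("need cup brighter than disc brighter than background")

    def center(self) -> tuple[int, int]:
        if self.disc_center is not None:
            return self.disc_center
        return (self.shape[0] // 2, self.shape[1] // 2)


@dataclass(frozen=True)
class GraderSimSpec:
    """Noise model for simulated manual markings.

    Areas get multiplicative log-normal jitter (keeps them positive and scale
    proportional); centroid coordinates and CDRs get additive Gaussian jitter.
    With probability ``outlier_rate`` per (image, grader, parameter) the
    perturbation is replaced by an inflated one of magnitude
    ``outlier_scale * jitter * (1 + |z|)`` with random sign — a genuine
    blunder, bounded away from zero so that injected outliers are actually
    aberrant markings.
    """

    n_graders: int = 6
    area_jitter_cv: float = 0.05
    centroid_jitter_sd: float = 2.0
    cdr_jitter_sd: float = 0.03
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.outlier_rate <= 1:
            raise ValidationError("outlier_rate must be in [0, 1]")
        if self.outlier_rate > 0 and self.outlier_scale <= 1:
            raise ValidationError("outlier_scale must exceed 1")


def profile_spec(profile: str, seed: int = 0, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` scaled to one of the built-in dataset profiles."""
    shape = PROFILE_SHAPES[profile]
    scale = shape[1] / 512.0  # geometry scales with frame width
    base = PhantomSpec(
        shape=shape,
        disc_axes=(52.0 * scale, 48.0 * scale),
        vessel_width=max(3, int(round(3 * scale))),
        blur_sigma=1.5 * scale,
        seed=seed,
        profile=profile,
    )
    return replace(base, **overrides)


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(center[0], center[1], axes[0], axes[1], shape=shape)
    mask[rr, cc] = True
    return mask


def _vessel_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Dark curvilinear occluders: random walks with smooth heading changes,
    seeded at the disc center and drawn at the stated width."""
    h, w = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    radius = max(1, spec.vessel_width / 2)
    n_steps = int(0.7 * max(h, w))
    for _ in range(spec.n_vessels):
        r, c = map(float, spec.center())
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            heading += rng.normal(0, 0.12)
            r += np.sin(heading)
            c += np.cos(heading)
            if not (0 <= r < h and 0 <= c < w):
                break
            rr, cc = disk((r, c), radius, shape=spec.shape)
            mask[rr, cc] = True
    return mask


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(image, disc_mask, cup_mask, vessel_mask, truth)`` where
    ``truth`` is the :class:`RegionParams` record computed from the noiseless
    masks. Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    center = spec.center()
    cup_axes = (spec.cdr_v * spec.disc_axes[0], spec.cdr_h * spec.disc_axes[1])

    disc_mask = _ellipse_mask(spec.shape, center, spec.disc_axes)
    cup_mask = _ellipse_mask(spec.shape, center, cup_axes)
    if not disc_mask[binary_dilation(cup_mask)].all():
        raise ValidationError("cup is not strictly inside the disc")

    # background with radial vignetting toward the frame corners
    rr, cc = np.mgrid[0:h, 0:w]
    radial = np.hypot((rr - h / 2) / (h / 2), (cc - w / 2) / (w / 2)) / np.sqrt(2)
    img = spec.background_level * (1.0 - spec.vignette_strength * radial**2)
    img[disc_mask] = spec.disc_brightness
    img[cup_mask] = spec.cup_brightness

    vessel_mask = _vessel_mask(spec, rng)
    img[vessel_mask] = max(spec.background_level - 40, 5)

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    image = FundusImage(np.stack([img] * 3, axis=-1), profile=PROFILE_QUALITY[spec.profile])
    truth = region_params(disc_mask, cup_mask)
    return image, disc_mask, cup_mask, vessel_mask, truth


def simulate_markings(truth: dict[str, RegionParams], spec: GraderSimSpec):
    """Simulate per-grader markings for each ground-truth record.

    Returns ``(table, ledger)``: the :class:`MarkingTable` over graders
    "1".."n_graders" and a DataFrame ledger with one row per injected outlier
    (columns image_id, grader_id, param).
    """
    if not truth:
        raise ValidationError("truth table is empty")
    rng = np.random.default_rng(spec.seed)
    graders = [str(g + 1) for g in range(spec.n_graders)]
    rows, ledger = [], []

    for image_id in sorted(truth):
        t = truth[image_id]
        for g in graders:
            is_out = {p: bool(rng.random() < spec.outlier_rate) for p in PARAM_IDS}

            def _noise(sd, outlier):
                z = rng.normal()
                if not outlier:
                    return sd * z
                return np.sign(rng.random() - 0.5) * spec.outlier_scale * sd * (1 + abs(z))

            disc_area = t.disc_area * np.exp(_noise(spec.area_jitter_cv, is_out["disc_area"]))
            cup_area = t.cup_area * np.exp(_noise(spec.area_jitter_cv, is_out["cup_area"]))
            disc_cen = tuple(v + _noise(spec.centroid_jitter_sd, is_out["disc_centroid"]) for v in t.disc_centroid)
            cup_cen = tuple(v + _noise(spec.centroid_jitter_sd, is_out["cup_centroid"]) for v in t.cup_centroid)
            h = None if t.hcdr is None else float(np.clip(t.hcdr + _noise(spec.cdr_jitter_sd, is_out["hcdr"]), 0.01, 1.5))
            v = None if t.vcdr is None else float(np.clip(t.vcdr + _noise(spec.cdr_jitter_sd, is_out["vcdr"]), 0.01, 1.5))

            params = RegionParams(
                disc_area=float(disc_area),
                disc_centroid=disc_cen,
                cup_area=float(cup_area),
                cup_centroid=cup_cen,
                hcdr=h,
                vcdr=v,
            )
            rows.append(params.as_row(image_id, g))
            for p, flag in is_out.items():
                if flag:
                    ledger.append({"image_id": image_id, "grader_id": g, "param": p})

    table = MarkingTable(pd.DataFrame(rows))
    ledger_df = pd.DataFrame(ledger, columns=["image_id", "grader_id", "param"])
    return table, ledger_df


def random_truth_table(n_images: int, seed: int = 0, shape: tuple[int, int] = (512, 512)) -> dict[str, RegionParams]:
    """Analytic ground-truth records for ``n_images`` plausible optic nerve heads.

    Samples disc/cup ellipse geometry in the given frame and derives the six
    parameters in closed form (area = pi*a*b, CDR = cup/disc axis ratio)
    without rendering pixels — cheap enough for large evaluation-protocol
    simulations.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    out = {}
    for i in range(n_images):
        a = rng.uniform(0.08, 0.12) * w  # vertical semi-axis
        b = a * rng.uniform(0.85, 1.05)
        cdr_v = rng.uniform(0.3, 0.8)
        cdr_h = np.clip(cdr_v + rng.normal(0, 0.05), 0.2, 0.9)
        cen = (h / 2 + rng.uniform(-0.05, 0.05) * h, w / 2 + rng.uniform(-0.05, 0.05) * w)
        out[f"img{i:03d}"] = RegionParams(
            disc_area=float(np.pi * a * b),
            disc_centroid=cen,
            cup_area=float(np.pi * a * b * cdr_v * cdr_h),
            cup_centroid=cen,
            hcdr=float(cdr_h),
            vcdr=float(cdr_v),
        )
    return out


def truth_table(specs: list[PhantomSpec]) -> dict[str, RegionParams]:
    """Ground-truth records for a list of phantom specs, keyed img000, img001, ..."""
    out = {}
    for i, spec in enumerate(specs):
        *_, truth = generate_phantom(spec)
        out[f"img{i:03d}"] = truth
    return out
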