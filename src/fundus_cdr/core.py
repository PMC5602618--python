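"""Domain types, coordinate conventions and readers/writers shared by the pipeline.

Conventions used everywhere in this package:

* raster coordinates are 0-based ``(row, col)``, row-major;
* regions of interest are half-open windows (``row0 <= r < row0 + n_rows``);
* areas are pixel counts of a boolean mask; centroids are arithmetic means of
  member-pixel coordinates (float).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger("fundus_cdr")

PROFILES = ("high_quality", "low_quality")

#: manual grader identifiers; the automated pipeline contributes rows as "algorithm"
MANUAL_GRADERS = ("1", "2", "3", "4", "5", "6")
ALGORITHM_ID = "algorithm"

MARKING_COLUMNS = [
    "image_id",
    "grader_id",
    "disc_area",
    "disc_centroid_row",
    "disc_centroid_col",
    "cup_area",
    "cup_centroid_row",
    "cup_centroid_col",
    "hcdr",
    "vcdr",
]


class InputError(ValueError):
    """Unreadable or malformed external input."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass
class FundusImage:
    """An 8-bit RGB retinal fundus photograph.

    ``profile`` encodes acquisition quality: ``low_quality`` (nonmydriatic
    camera class) routes disc segmentation through the double level-set path.
    The profile is always set explicitly, never inferred from pixel content.
    """

    pixels: np.ndarray
    profile: str = "high_quality"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected (H, W, 3) raster, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValidationError("fundus images must be at least 64x64 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.profile not in PROFILES:
            raise ValidationError(f"profile must be one of {PROFILES}, got {self.profile!r}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def green(self) -> np.ndarray:
        """The G channel, the highest-contrast channel for retinal structures."""
        return self.pixels[:, :, 1]


@dataclass(frozen=True)
class RoiWindow:
    """Half-open axis-aligned window fully contained in its parent image."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("ROI extent must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError("ROI offsets must be non-negative")

    @classmethod
    def centered(cls, center: tuple[float, float], side: int, shape: tuple[int, int]) -> "RoiWindow":
        """Square window of ``side`` pixels about ``center``, clipped to ``shape``."""
        h, w = shape
        side_r = min(side, h)
        side_c = min(side, w)
        r0 = int(round(center[0] - side_r / 2))
        c0 = int(round(center[1] - side_c / 2))
        r0 = min(max(r0, 0), h - side_r)
        c0 = min(max(c0, 0), w - side_c)
        return cls(r0, c0, side_r, side_c)

    def check_inside(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.n_rows > shape[0] or self.col0 + self.n_cols > shape[1]:
            raise ValidationError(f"ROI {self} exceeds image shape {shape}")

    def extract(self, raster: np.ndarray) -> np.ndarray:
        self.check_inside(raster.shape[:2])
        return raster[self.row0 : self.row0 + self.n_rows, self.col0 : self.col0 + self.n_cols]

    def embed(self, patch: np.ndarray, shape: tuple[int, int], fill=0) -> np.ndarray:
        """Place ``patch`` back into a full-frame raster of ``shape``."""
        out = np.full(shape, fill, dtype=patch.dtype)
        out[self.row0 : self.row0 + self.n_rows, self.col0 : self.col0 + self.n_cols] = patch
        return out

    def contains_point(self, point: tuple[float, float]) -> bool:
        r, c = point
        return (self.row0 <= r < self.row0 + self.n_rows) and (self.col0 <= c < self.col0 + self.n_cols)


@dataclass
class LabelImage:
    """Multilevel threshold classes: labels 0..k, 0 darkest, k brightest."""

    grid: np.ndarray
    k: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.min() < 0 or grid.max() > self.k:
            raise ValidationError("labels must lie in [0, k]")
        self.grid = grid.astype(np.int16)

    @property
    def n_classes(self) -> int:
        return self.k + 1


@dataclass
class RegionParams:
    """The six per-image parameters the screening protocol compares across graders."""

    disc_area: float
    disc_centroid: tuple[float, float]
    cup_area: float
    cup_centroid: tuple[float, float]
    hcdr: float | None
    vcdr: float | None

    def __post_init__(self) -> None:
        if self.disc_area < 0 or self.cup_area < 0:
            raise ValidationError("areas must be non-negative")

    def as_row(self, image_id: str, grader_id: str) -> dict:
        return {
            "image_id": image_id,
            "grader_id": grader_id,
            "disc_area": self.disc_area,
            "disc_centroid_row": self.disc_centroid[0],
            "disc_centroid_col": self.disc_centroid[1],
            "cup_area": self.cup_area,
            "cup_centroid_row": self.cup_centroid[0],
            "cup_centroid_col": self.cup_centroid[1],
            "hcdr": self.hcdr if self.hcdr is not None else np.nan,
            "vcdr": self.vcdr if self.vcdr is not None else np.nan,
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "RegionParams":
        def _ratio(x):
            return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)

        return cls(
            disc_area=float(row["disc_area"]),
            disc_centroid=(float(row["disc_centroid_row"]), float(row["disc_centroid_col"])),
            cup_area=float(row["cup_area"]),
            cup_centroid=(float(row["cup_centroid_row"]), float(row["cup_centroid_col"])),
            hcdr=_ratio(row["hcdr"]),
            vcdr=_ratio(row["vcdr"]),
        )


class MarkingTable:
    """Per (image, grader) table of :class:`RegionParams` records.

    Thin wrapper around a pandas DataFrame with a fixed column order; grader
    ids are strings ("1".."6" for the ophthalmologists, "algorithm" for the
    automated pipeline).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in MARKING_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"marking table missing columns: {missing}")
        frame["image_id"] = frame["image_id"].astype(str)
        frame["grader_id"] = frame["grader_id"].astype(str)
        dup = frame.duplicated(subset=["image_id", "grader_id"])
        if dup.any():
            key = frame.loc[dup.idxmax(), ["image_id", "grader_id"]].tolist()
            raise ValidationError(f"duplicate marking for (image_id, grader_id)=({key[0]}, {key[1]})")
        if (frame["disc_area"] < 0).any() or (frame["cup_area"] < 0).any():
            bad = frame.loc[(frame["disc_area"] < 0) | (frame["cup_area"] < 0), "image_id"].iloc[0]
            raise ValidationError(f"negative area for image {bad}")
        self.frame = frame[MARKING_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Mapping[tuple[str, str], RegionParams]) -> "MarkingTable":
        rows = [params.as_row(img, grader) for (img, grader), params in records.items()]
        return cls(pd.DataFrame(rows, columns=MARKING_COLUMNS))

    def images(self) -> list[str]:
        return sorted(self.frame["image_id"].unique())

    def graders(self) -> list[str]:
        ids = set(self.frame["grader_id"])
        manual = sorted(g for g in ids if g != ALGORITHM_ID)
        return manual + ([ALGORITHM_ID] if ALGORITHM_ID in ids else [])

    def get(self, image_id: str, grader_id: str) -> RegionParams:
        sel = self.frame[(self.frame["image_id"] == str(image_id)) & (self.frame["grader_id"] == str(grader_id))]
        if sel.empty:
            raise KeyError((image_id, grader_id))
        return RegionParams.from_row(sel.iloc[0])

    def with_rows(self, rows: Iterable[dict]) -> "MarkingTable":
        return MarkingTable(pd.concat([self.frame, pd.DataFrame(list(rows))], ignore_index=True))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkingTable):
            return NotImplemented
        a = self.frame.sort_values(["image_id", "grader_id"]).reset_index(drop=True)
        b = other.frame.sort_values(["image_id", "grader_id"]).reset_index(drop=True)
        if not a[["image_id", "grader_id"]].equals(b[["image_id", "grader_id"]]):
            return False
        return bool(np.allclose(a[MARKING_COLUMNS[2:]].astype(float), b[MARKING_COLUMNS[2:]].astype(float), equal_nan=True))


def read_image(path: str | Path, profile: str = "high_quality") -> FundusImage:
    """Read a PNG/TIFF/JPEG raster as an 8-bit RGB fundus image.

    16-bit inputs are rescaled to 0-255 by integer division of the full range
    (``value // 257``); single-channel images are replicated across the three
    channels with a logged warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # unreadable or not a raster
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint16 or (arr.dtype.kind in "iu" and arr.dtype.itemsize > 1):
        arr = (arr.astype(np.uint32) // 257).astype(np.uint8)
    if arr.ndim == 2:
        logger.warning("single-channel image %s replicated to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return FundusImage(arr.astype(np.uint8), profile=profile)


def write_image(path: str | Path, image: FundusImage | np.ndarray) -> None:
    arr = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def read_markings(path: str | Path) -> MarkingTable:
    """Read a marking table from CSV (one-line header) or its JSON mirror."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            with open(path) as fh:
                frame = pd.DataFrame(json.load(fh))
        else:
            frame = pd.read_csv(path)
    except ValidationError:
        raise
    except Exception as exc:
        raise InputError(f"cannot read marking table {path}: {exc}") from exc
    return MarkingTable(frame)


def write_markings(path: str | Path, table: MarkingTable) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(table.frame.to_dict(orient="records"), fh, indent=1)
    else:
        table.frame.to_csv(path, index=False)
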