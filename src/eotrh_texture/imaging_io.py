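"""Image, mask and table I/O plus masked-ROI patch extraction.

Radiographs are single-channel 8- or 16-bit PNG or TIFF rasters.  Per-tooth
segmentations are integer label images (one raster, one label per tooth) with
a JSON sidecar mapping each label to a Triadan tooth code; grades live in a
CSV keyed by ``(subject_id, tooth_id)``.  All coordinates are 0-based,
row-major ``(row, col)`` and bounding boxes are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import EmptyROIError, FormatError, MissingGradeError

#: Triadan codes of the six maxillary incisors (right 101-103, left 201-203).
MAXILLARY_INCISORS = (101, 102, 103, 201, 202, 203)

#: Valid EOTRH grades: 0 normal, 1 mild, 2 moderate, 3 severe.
GRADES = (0, 1, 2, 3)

#: Minimum foreground pixels for a usable (non-excluded) ROI.
MIN_ROI_PIXELS = 16

FEATURE_TABLE_COLUMNS = [
    "subject_id",
    "tooth_id",
    "grade",
    "filter",
    "family",
    "feature",
    "value",
]


@dataclass
class GrayImage:
    """2D grayscale raster with its on-disk bit depth.

    Pixels are held as float64 in memory (filters produce real values); the
    bit depth records the integer range the image had, or will have, on disk.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise FormatError(f"image too small: {self.pixels.shape} (need >= 3x3)")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth} (need 8 or 16)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ToothROI:
    """Binary tooth mask with its Triadan id, EOTRH grade and exclusion flag."""

    mask: np.ndarray
    tooth_id: int
    grade: int
    excluded: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tooth_id not in MAXILLARY_INCISORS:
            raise FormatError(
                f"tooth_id {self.tooth_id} is not a maxillary incisor Triadan code"
            )
        if self.grade not in GRADES:
            raise FormatError(f"grade {self.grade} outside 0-3")
        if not self.excluded and int(self.mask.sum()) < MIN_ROI_PIXELS:
            raise EmptyROIError(
                f"mask for tooth {self.tooth_id} has {int(self.mask.sum())} "
                f"foreground pixels (< {MIN_ROI_PIXELS}) and is not excluded"
            )


@dataclass
class GradeTable:
    """Per-tooth grade records: (subject_id, tooth_id) -> grade, excluded."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"subject_id", "tooth_id", "grade", "excluded"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"grade table missing columns: {sorted(missing)}")
        df = df.astype(
            {"subject_id": str, "tooth_id": int, "grade": int, "excluded": bool}
        )
        if df.duplicated(["subject_id", "tooth_id"]).any():
            raise FormatError("duplicate (subject_id, tooth_id) in grade table")
        if not df["grade"].isin(GRADES).all():
            raise FormatError("grade table contains grades outside 0-3")
        self.records = df.reset_index(drop=True)

    def lookup(self, subject_id: str, tooth_id: int) -> tuple[int, bool]:
        sel = self.records[
            (self.records["subject_id"] == str(subject_id))
            & (self.records["tooth_id"] == int(tooth_id))
        ]
        if sel.empty:
            raise MissingGradeError(
                f"no grade record for subject {subject_id!r}, tooth {tooth_id}"
            )
        row = sel.iloc[0]
        return int(row["grade"]), bool(row["excluded"])

    @classmethod
    def read_csv(cls, path: str | Path) -> "GradeTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    arr = np.array(Image.open(path))
    return arr


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a single-channel 8/16-bit PNG or TIFF as a :class:`GrayImage`.

    Pixel values are preserved bit-exactly (stored as float64).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"{path.name}: unsupported pixel type {arr.dtype} (need uint8 or uint16)"
        )
    return GrayImage(pixels=arr, bit_depth=depth)


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write a GrayImage at its declared bit depth (values must be in range)."""
    path = Path(path)
    lo, hi = 0, 2**image.bit_depth - 1
    px = image.pixels
    if px.min() < lo or px.max() > hi:
        raise FormatError(
            f"pixel values outside {image.bit_depth}-bit range [{lo}, {hi}]"
        )
    if not np.allclose(px, np.round(px)):
        raise FormatError("pixel values must be integral to write at a bit depth")
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = px.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_label_image(path: str | Path) -> np.ndarray:
    """Read an integer label raster (0 = background, k = tooth k)."""
    path = Path(path)
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: label image must be single channel")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path.name}: label image must be integer-typed")
    return arr.astype(np.int32)


def read_mask_set(
    path: str | Path,
    grade_table: GradeTable,
    subject_id: str,
    label_map: dict[int, int] | str | Path | None = None,
) -> list[ToothROI]:
    """Read a label image into one :class:`ToothROI` per nonzero label.

    ``label_map`` maps label value -> Triadan code; it may be a dict or a path
    to a JSON sidecar ``{"1": 103, ...}``.  When omitted, a sidecar named
    ``<image>.labels.json`` next to the label image is used.  Grades and
    exclusion flags are joined from ``grade_table``.
    """
    path = Path(path)
    labels = read_label_image(path)
    if label_map is None:
        label_map = path.with_suffix(path.suffix + ".labels.json")
    if not isinstance(label_map, dict):
        sidecar = Path(label_map)
        if not sidecar.exists():
            raise FormatError(f"label map sidecar not found: {sidecar}")
        with open(sidecar) as fh:
            label_map = {int(k): int(v) for k, v in json.load(fh).items()}
    rois = []
    for lab in sorted(np.unique(labels)):
        if lab == 0:
            continue
        if int(lab) not in label_map:
            raise FormatError(f"label {int(lab)} present with no Triadan mapping")
        tooth_id = int(label_map[int(lab)])
        grade, excluded = grade_table.lookup(subject_id, tooth_id)
        rois.append(
            ToothROI(
                mask=labels == lab,
                tooth_id=tooth_id,
                grade=grade,
                excluded=excluded,
                subject_id=str(subject_id),
            )
        )
    return rois


def extract_roi_patch(
    image: GrayImage, roi: ToothROI, pad: int = 8
) -> tuple[GrayImage, np.ndarray]:
    """Cut the mask's tight bounding box, expanded by ``pad`` and clipped at
    the image border, returning (patch, patch_mask).

    Pixel values are never altered; the patch simply windows the image so
    that neighbourhood filters see real surrounding tissue where available.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if roi.excluded:
        raise ValueError(f"tooth {roi.tooth_id} is excluded from analysis")
    if roi.mask.shape != image.shape:
        raise FormatError(
            f"mask shape {roi.mask.shape} != image shape {image.shape}"
        )
    rows, cols = np.nonzero(roi.mask)
    if rows.size == 0:
        raise EmptyROIError(f"tooth {roi.tooth_id}: empty mask")
    r0 = max(int(rows.min()) - pad, 0)
    r1 = min(int(rows.max()) + 1 + pad, image.height)
    c0 = max(int(cols.min()) - pad, 0)
    c1 = min(int(cols.max()) + 1 + pad, image.width)
    patch = GrayImage(image.pixels[r0:r1, c0:c1].copy(), bit_depth=image.bit_depth)
    patch_mask = roi.mask[r0:r1, c0:c1].copy()
    return patch, patch_mask


def write_feature_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format feature table as CSV with a stable row order.

    Rows are sorted by all key columns; values round-trip at 12 significant
    digits; NaN is serialized as the literal ``nan``.
    """
    df = pd.DataFrame(records)
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"feature table missing columns: {sorted(missing)}")
    df = df[FEATURE_TABLE_COLUMNS].copy()
    keys = [c for c in FEATURE_TABLE_COLUMNS if c != "value"]
    df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.12g", na_rep="nan")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, na_values=["nan"], keep_default_na=True)
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"feature table missing columns: {sorted(missing)}")
    return df.astype({"subject_id": str, "tooth_id": int, "grade": int})
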