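"""Synthetic EOTRH cohort generator.

The study's radiographs are not publicly deposited, so this module renders a
stand-in cohort of per-tooth grayscale patches whose texture heterogeneity
increases monotonically with EOTRH grade.  Each tooth is a bright, elongated
silhouette (a smooth crown-to-apex intensity ramp) on a darker background.
Disease grade g adds, on top of that shared base model:

* ``mottle_count_per_grade[g]`` dark Gaussian blobs of contrast
  ``mottle_contrast_per_grade[g]`` inside the mask — the radiolucent
  mottling of resorption;
* one bright apical disc of radius ``bulb_radius_per_grade[g]`` — the
  radiopaque bulb of hypercementosis;
* i.i.d. Gaussian pixel noise of standard deviation ``noise_sd``.

A small subject-level brightness intercept mimics exposure variation between
radiographs.  Because grade effects are additive motifs on one base model,
trend *direction* (not just group difference) is built into the cohort.
Default cohort bookkeeping matches the study population: 80 subjects with 6
maxillary incisors each, 8 teeth excluded for fractures, and 472 graded
teeth split 105/195/111/61 across grades 0-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .imaging_io import (
    MAXILLARY_INCISORS,
    GradeTable,
    GrayImage,
    write_gray_image,
)

DEFAULT_GRADE_COUNTS = (105, 195, 111, 61)


@dataclass
class CohortConfig:
    """Cohort structure and grade effect sizes.

    Effect-size sequences are indexed by grade and must be non-negative and
    non-decreasing, so that texture heterogeneity grows with disease grade.
    """

    n_subjects: int = 80
    teeth_per_subject: int = 6
    grade_counts: tuple[int, int, int, int] = DEFAULT_GRADE_COUNTS
    n_excluded: int = 8
    patch_size: tuple[int, int] = (96, 64)  # (rows, cols)
    rng_seed: int = 0
    mottle_count_per_grade: tuple[int, ...] = (0, 6, 12, 20)
    mottle_contrast_per_grade: tuple[float, ...] = (0.0, 25.0, 40.0, 60.0)
    bulb_radius_per_grade: tuple[float, ...] = (0.0, 4.0, 7.0, 10.0)
    noise_sd: float = 3.0
    subject_brightness_sd: float = 4.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        total = self.n_subjects * self.teeth_per_subject
        if sum(self.grade_counts) + self.n_excluded != total:
            raise ConfigError(
                f"grade_counts {self.grade_counts} + n_excluded {self.n_excluded} "
                f"!= {self.n_subjects} subjects x {self.teeth_per_subject} teeth = {total}"
            )
        if len(self.grade_counts) != 4:
            raise ConfigError("grade_counts must have one entry per grade 0-3")
        for name in (
            "mottle_count_per_grade",
            "mottle_contrast_per_grade",
            "bulb_radius_per_grade",
        ):
            seq = getattr(self, name)
            if len(seq) != 4:
                raise ConfigError(f"{name} must have one entry per grade 0-3")
            if any(v < 0 for v in seq) or any(
                seq[i] > seq[i + 1] for i in range(3)
            ):
                raise ConfigError(f"{name} must be non-negative and non-decreasing")
        if self.noise_sd < 0 or self.subject_brightness_sd < 0:
            raise ConfigError("noise_sd and subject_brightness_sd must be >= 0")
        if self.patch_size[0] < 16 or self.patch_size[1] < 16:
            raise ConfigError("patch_size must be at least 16x16")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A cohort carrying no grade information (noise and exposure only)."""
        defaults = dict(
            mottle_count_per_grade=(0, 0, 0, 0),
            mottle_contrast_per_grade=(0.0, 0.0, 0.0, 0.0),
            bulb_radius_per_grade=(0.0, 0.0, 0.0, 0.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticTooth:
    """One rendered tooth patch with its mask, grade and draw parameters."""

    patch: GrayImage
    mask: np.ndarray
    grade: int
    tooth_id: int
    subject_id: str
    excluded: bool = False
    params: dict = field(default_factory=dict)


def _tooth_silhouette(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Elongated elliptical mask with small random axis jitter."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    ay = h * (0.40 + 0.03 * rng.uniform(-1, 1))
    ax = w * (0.30 + 0.03 * rng.uniform(-1, 1))
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def render_tooth(
    grade: int,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_intercept: float = 0.0,
    tooth_id: int = 101,
    subject_id: str = "S000",
    excluded: bool = False,
) -> SyntheticTooth:
    """Render one tooth patch for the given grade (see module docstring)."""
    if grade not in (0, 1, 2, 3):
        raise ConfigError(f"grade {grade} outside 0-3")
    h, w = config.patch_size
    mask = _tooth_silhouette((h, w), rng)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)

    background = 60.0
    img = np.full((h, w), background)
    # crown (top) to apex (bottom) brightness ramp inside the tooth
    ramp = 140.0 + 50.0 * rr / (h - 1)
    img[mask] = ramp[mask] + subject_intercept

    params: dict = {"subject_intercept": subject_intercept, "mottles": []}

    n_mottles = config.mottle_count_per_grade[grade]
    contrast = config.mottle_contrast_per_grade[grade]
    if n_mottles > 0 and contrast > 0:
        mrows, mcols = np.nonzero(mask)
        idx = rng.integers(0, mrows.size, size=n_mottles)
        for k in range(n_mottles):
            r0, c0 = float(mrows[idx[k]]), float(mcols[idx[k]])
            sigma = rng.uniform(1.5, 3.0)
            blob = contrast * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
            )
            img -= np.where(mask, blob, 0.0)
            params["mottles"].append({"row": r0, "col": c0, "sigma": sigma})

    bulb_radius = config.bulb_radius_per_grade[grade]
    if bulb_radius > 0:
        # apical bright disc near the bottom of the silhouette
        apex_row = float(np.nonzero(mask.any(axis=1))[0].max())
        r0 = apex_row - bulb_radius - 2.0
        c0 = w / 2.0 + rng.uniform(-2, 2)
        dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
        disc = 45.0 / (1.0 + np.exp(2.0 * (dist - bulb_radius)))  # soft-edged disc
        img += np.where(mask, disc, 0.0)
        params["bulb"] = {"row": r0, "col": c0, "radius": bulb_radius}

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=(h, w))

    img = np.clip(np.round(img), 0, 2**config.bit_depth - 1)
    patch = GrayImage(img, bit_depth=config.bit_depth)
    return SyntheticTooth(
        patch=patch,
        mask=mask,
        grade=grade,
        tooth_id=tooth_id,
        subject_id=subject_id,
        excluded=excluded,
        params=params,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticTooth], GradeTable]:
    """Generate the full cohort: one patch+mask per tooth plus a grade table.

    Deterministic given ``config.rng_seed``.  Exactly ``grade_counts[g]``
    non-excluded teeth carry grade g; excluded teeth (fracture stand-ins)
    are rendered too but flagged, and are skipped by downstream analysis.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_total = config.n_subjects * config.teeth_per_subject
    slots = []
    for g, count in enumerate(config.grade_counts):
        slots += [(g, False)] * count
    excluded_grades = rng.integers(0, 4, size=config.n_excluded)
    slots += [(int(g), True) for g in excluded_grades]
    order = rng.permutation(n_total)
    slots = [slots[k] for k in order]

    teeth: list[SyntheticTooth] = []
    records = []
    k = 0
    for s in range(config.n_subjects):
        subject_id = f"S{s:03d}"
        intercept = rng.normal(0.0, config.subject_brightness_sd)
        for tooth_id in MAXILLARY_INCISORS:
            grade, excluded = slots[k]
            k += 1
            tooth = render_tooth(
                grade,
                config,
                rng,
                subject_intercept=intercept,
                tooth_id=tooth_id,
                subject_id=subject_id,
                excluded=excluded,
            )
            teeth.append(tooth)
            records.append(
                {
                    "subject_id": subject_id,
                    "tooth_id": tooth_id,
                    "grade": grade,
                    "excluded": excluded,
                }
            )
    return teeth, GradeTable(pd.DataFrame(records))


def write_cohort(
    teeth: list[SyntheticTooth], grade_table: GradeTable, out_dir: str | Path
) -> Path:
    """Write PNG patches, label masks (+ JSON sidecars) and the grades CSV.

    The layout is exactly what :mod:`eotrh_texture.imaging_io` reads back:
    ``images/<subject>_<tooth>.png``, ``masks/<subject>_<tooth>.png`` with
    ``masks/<subject>_<tooth>.png.labels.json``, and ``grades.csv``.
    """
    import json

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for tooth in teeth:
        stem = f"{tooth.subject_id}_{tooth.tooth_id}"
        write_gray_image(tooth.patch, out_dir / "images" / f"{stem}.png")
        mask_img = GrayImage(tooth.mask.astype(np.uint8), bit_depth=8)
        write_gray_image(mask_img, out_dir / "masks" / f"{stem}.png")
        with open(out_dir / "masks" / f"{stem}.png.labels.json", "w") as fh:
            json.dump({"1": tooth.tooth_id}, fh)
    grade_table.write_csv(out_dir / "grades.csv")
    return out_dir
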