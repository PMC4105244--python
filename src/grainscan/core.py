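"""Shared domain types for the grain-scanning pipeline.

The pipeline operates on flatbed-scanner images of seeds scattered on a
dark background.  All physical sizes are configured in millimetres and
converted to pixels through the scanner resolution (dots per inch), with
25.4 mm to the inch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

MM_PER_INCH = 25.4

#: Fixed qualitative palette used for label overlays, cycled by label id.
OVERLAY_PALETTE = np.array(
    [
        (230, 25, 75),
        (60, 180, 75),
        (255, 225, 25),
        (0, 130, 200),
        (245, 130, 48),
        (145, 30, 180),
        (70, 240, 240),
        (240, 50, 230),
        (210, 245, 60),
        (250, 190, 190),
        (0, 128, 128),
        (170, 110, 40),
    ],
    dtype=np.uint8,
)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def mm_to_px(mm: float, dpi: float) -> int:
    """Convert a length in millimetres to whole pixels at ``dpi``.

    Rounded to the nearest integer with a floor of one pixel, so that
    derived structuring sizes are always usable.
    """
    if dpi <= 0:
        raise ValidationError(f"dpi must be positive, got {dpi}")
    return max(1, int(round(mm * dpi / MM_PER_INCH)))


def px_to_mm(px: float, dpi: float) -> float:
    if dpi <= 0:
        raise ValidationError(f"dpi must be positive, got {dpi}")
    return px * MM_PER_INCH / dpi


@dataclass
class RasterImage:
    """An H×W×3 unsigned-integer raster with resolution metadata.

    ``pixels`` is uint8 or uint16; greyscale sources are promoted to three
    identical channels on read.  ``dpi`` may be ``None`` when neither the
    file nor the configuration supplied a resolution; operations that need
    a physical scale then refuse to run rather than guess.
    """

    pixels: np.ndarray
    dpi: Optional[float] = None
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected H×W×3 pixels, got shape {px.shape}")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ValidationError("zero-area image")
        if px.dtype not in (np.uint8, np.uint16):
            raise ValidationError(f"expected uint8/uint16 pixels, got {px.dtype}")
        if self.dpi is not None and self.dpi <= 0:
            raise ValidationError(f"dpi must be positive, got {self.dpi}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMap:
    """H×W non-negative integer image; 0 is background, 1..n are objects.

    Labels are always consecutive: the set of values is exactly
    {0} ∪ {1..n_objects}.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"labels must be 2-D, got shape {lab.shape}")
        if lab.size and lab.min() < 0:
            raise ValidationError("negative labels")
        self.labels = lab.astype(np.int32, copy=False)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def validate_consecutive(self) -> None:
        present = np.unique(self.labels)
        expected = np.arange(self.n_objects + 1)
        nonzero = present[present > 0]
        if not np.array_equal(nonzero, expected[1:]):
            raise ValidationError("labels are not consecutive from 1")


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Remap nonzero labels onto 1..n preserving ascending label order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


@dataclass
class PipelineConfig:
    """User-facing parameters of the segmentation and measurement pipeline.

    Parameters
    ----------
    min_grain_width_mm, min_grain_length_mm:
        Smallest grain the run should keep.  They parameterise the
        preprocessing attribute filters (crease fill at 0.3× width, debris
        removal at 0.7× width and 0.7× length) and the final area filter
        (0.5 × width × length).
    dpi:
        Scanner resolution; overrides any file metadata when set.
    gaussian_sigma_px:
        Pre-smoothing strength in pixels.
    dt_sigma_px:
        Smoothing of the distance transform before seed extraction when
        splitting touching grains.
    dt_min_depth_px:
        Minimum trough depth (in distance units, i.e. pixels) separating
        two seeds; shallower maxima — discretisation ripples along the
        distance ridge of an elongated grain — are merged before seeding.
        Default (``None``): 10 % of the minimum grain width in pixels,
        at least 1 px; genuine necks between touching grains are an order
        of magnitude deeper.
    elongation_threshold:
        Axis ratio above which a bright structure is treated as a scratch
        and thinned away.  The default (12) keeps even strongly elongated
        seeds (Brachypodium length/width ≈ 6–8) while removing scratches,
        which are tens of times longer than wide.
    crease_enabled / crease_tau:
        Toggle crease detection and the grey-level contrast needed to call
        a crease present.
    """

    min_grain_width_mm: float = 2.0
    min_grain_length_mm: float = 4.0
    dpi: float = 300.0
    gaussian_sigma_px: float = 1.0
    dt_sigma_px: float = 2.0
    dt_min_depth_px: Optional[float] = None
    elongation_threshold: float = 12.0
    crease_enabled: bool = False
    crease_tau: float = 15.0
    crease_mean_k: int = 9
    calibration_stem: Optional[str] = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (self.min_grain_length_mm >= self.min_grain_width_mm > 0):
            raise ValidationError(
                "require min_grain_length_mm >= min_grain_width_mm > 0, got "
                f"width={self.min_grain_width_mm}, length={self.min_grain_length_mm}"
            )
        if self.dpi is not None and self.dpi <= 0:
            raise ValidationError("dpi must be positive")
        if self.gaussian_sigma_px < 0 or self.dt_sigma_px < 0:
            raise ValidationError("sigma must be non-negative")
        if self.elongation_threshold <= 1:
            raise ValidationError("elongation_threshold must exceed 1")
        if self.crease_mean_k < 3 or self.crease_mean_k % 2 == 0:
            raise ValidationError("crease_mean_k must be an odd integer >= 3")

    # Derived pixel sizes -------------------------------------------------
    @property
    def min_width_px(self) -> int:
        return mm_to_px(self.min_grain_width_mm, self.dpi)

    @property
    def min_length_px(self) -> int:
        return mm_to_px(self.min_grain_length_mm, self.dpi)

    @property
    def min_area_px(self) -> float:
        return 0.5 * self.min_width_px * self.min_length_px

    @property
    def seed_min_depth_px(self) -> float:
        if self.dt_min_depth_px is not None:
            return self.dt_min_depth_px
        return max(1.0, 0.1 * self.min_width_px)

    # Serialisation -------------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or simple ``key=value`` lines."""
        text = Path(path).read_text()
        first = next((ln for ln in text.splitlines() if ln.strip()), "")
        if "=" in first and ":" not in first.partition("=")[0]:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = yaml.safe_load(val.strip())
        else:
            data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class GrainRecord:
    """Per-grain measurements, sizes in millimetres, colours in 0..255."""

    grain_id: int
    area_mm2: float = np.nan
    perimeter_mm: float = np.nan
    majellipse_mm: float = np.nan
    minellipse_mm: float = np.nan
    centroid_px: tuple[float, float] = (np.nan, np.nan)
    orientation_rad: float = np.nan
    mean_R: Optional[float] = None
    mean_G: Optional[float] = None
    mean_B: Optional[float] = None
    L: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    crease_detected: Optional[bool] = None
    L_noncrease: Optional[float] = None
    a_noncrease: Optional[float] = None
    b_noncrease: Optional[float] = None
    L_crease: Optional[float] = None
    a_crease: Optional[float] = None
    b_crease: Optional[float] = None


#: Fixed column order of the results CSV.
RESULTS_COLUMNS = [
    "grain_id",
    "area_mm2",
    "perimeter_mm",
    "majellipse_mm",
    "minellipse_mm",
    "mean_R",
    "mean_G",
    "mean_B",
    "L",
    "a",
    "b",
    "crease_detected",
    "L_noncrease",
    "a_noncrease",
    "b_noncrease",
    "L_crease",
    "a_crease",
    "b_crease",
]
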