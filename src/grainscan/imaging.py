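"""Raster and tabular I/O: input scans, label TIFFs, overlays, results CSV.

File conventions: labelled grain/crease images are written as 16-bit
single-channel TIFFs named ``<stem>.grainLbl.tif`` / ``<stem>.creaseLbl.tif``;
overlay renderings as ``<stem>.grainOvr.jpg`` / ``<stem>.creaseOvr.jpg``;
per-grain measurements as ``Results/<stem>.csv``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .core import (
    OVERLAY_PALETTE,
    RESULTS_COLUMNS,
    GrainRecord,
    LabelMap,
    RasterImage,
    ValidationError,
)

LABEL_SUFFIXES = ("grainLbl", "creaseLbl")
OVERLAY_SUFFIXES = ("grainOvr", "creaseOvr")


def _dpi_from_tiff(path: Path) -> Optional[float]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        xres = tags.get("XResolution")
        unit = tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value if isinstance(xres.value, tuple) else (xres.value, 1)
        if den == 0 or num == 0:
            return None
        res = num / den
        unit_val = getattr(unit.value, "value", unit.value) if unit is not None else 2
        if unit_val == 3:  # centimetres
            res *= 2.54
        elif unit_val != 2:  # unit "none": cannot interpret as dpi
            return None
        return float(res)


def read_image(path: str | Path, dpi: Optional[float] = None) -> RasterImage:
    """Read a TIFF/PNG/JPEG scan as a 3-channel raster.

    Greyscale files are promoted to three identical channels; an alpha
    channel, if present, is dropped.  The resolution is taken from the file
    metadata unless ``dpi`` is given, which always wins.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    suffix = path.suffix.lower()
    meta_dpi: Optional[float] = None
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        meta_dpi = _dpi_from_tiff(path)
    else:
        with Image.open(path) as im:
            info_dpi = im.info.get("dpi")
            if info_dpi and info_dpi[0]:
                meta_dpi = float(info_dpi[0])
            pixels = np.asarray(im)
    pixels = np.atleast_2d(np.squeeze(pixels))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] >= 3:
        pixels = pixels[:, :, :3]
    else:
        raise IOError(f"cannot interpret image of shape {pixels.shape}: {path}")
    if pixels.dtype == np.uint16:
        dtype = np.uint16
    else:
        dtype = np.uint8
    return RasterImage(
        pixels=pixels.astype(dtype, copy=False),
        dpi=dpi if dpi is not None else meta_dpi,
        source_path=str(path),
    )


def write_label_image(labels: LabelMap, stem: str | Path, suffix: str) -> Path:
    """Write a label map as ``<stem>.<suffix>.tif`` (16-bit, lossless)."""
    if suffix not in LABEL_SUFFIXES:
        raise ValidationError(f"suffix must be one of {LABEL_SUFFIXES}, got {suffix!r}")
    if labels.n_objects > 65535:
        raise ValidationError("more than 65535 objects cannot be stored in 16 bits")
    out = Path(f"{stem}.{suffix}.tif")
    out.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out, labels.labels.astype(np.uint16))
    return out


def read_label_image(path: str | Path) -> LabelMap:
    return LabelMap(tifffile.imread(path).astype(np.int32))


def overlay_array(image: RasterImage, labels: LabelMap, alpha: float = 0.6) -> np.ndarray:
    """Blend each labelled object with a palette colour cycled by label id."""
    if image.shape != labels.shape:
        raise ValidationError(
            f"image {image.shape} and labels {labels.shape} shapes differ"
        )
    base = image.pixels
    if base.dtype == np.uint16:
        base = (base // 257).astype(np.uint8)
    out = base.astype(np.float64)
    lab = labels.labels
    fg = lab > 0
    if fg.any():
        colours = OVERLAY_PALETTE[(lab[fg] - 1) % len(OVERLAY_PALETTE)]
        out[fg] = (1 - alpha) * out[fg] + alpha * colours
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def write_overlay(
    image: RasterImage, labels: LabelMap, stem: str | Path, suffix: str
) -> Path:
    """Write a JPEG overlay ``<stem>.<suffix>.jpg``; pure w.r.t. the input."""
    if suffix not in OVERLAY_SUFFIXES:
        raise ValidationError(
            f"suffix must be one of {OVERLAY_SUFFIXES}, got {suffix!r}"
        )
    rendered = overlay_array(image, labels)
    out = Path(f"{stem}.{suffix}.jpg")
    out.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rendered).save(out, format="JPEG", quality=90)
    return out


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return ""
        return f"{value:.4f}"
    return str(value)


def results_frame(records: Iterable[GrainRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({col: getattr(rec, col) for col in RESULTS_COLUMNS})
    frame = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    return frame


def write_results_csv(
    records: Iterable[GrainRecord], out_dir: str | Path, stem: str
) -> Path:
    """Write per-grain measurements to ``<out_dir>/Results/<stem>.csv``.

    Floats are serialised with four decimal places; unset optional columns
    are left empty.
    """
    results_dir = Path(out_dir) / "Results"
    results_dir.mkdir(parents=True, exist_ok=True)
    out = results_dir / f"{stem}.csv"
    records = list(records)
    lines = [",".join(RESULTS_COLUMNS)]
    for rec in records:
        lines.append(",".join(_fmt(getattr(rec, col)) for col in RESULTS_COLUMNS))
    out.write_text("\n".join(lines) + "\n")
    return out
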