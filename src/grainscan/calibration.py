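"""RGB → CIELAB colour calibration from a scanned colour-checker card.

A 24-swatch ColorChecker card scanned under the same settings as the
seeds anchors the scanner's device RGB to device-independent CIELAB: the
card is located in the scan, per-swatch mean RGB values are extracted,
and a single affine map (3×3 matrix plus offset) is fitted by linear
least squares against the card's published CIELAB reference values.  The
fitted map is serialised as two floating-point TIFFs with the suffixes
``*RGB2Labmat.tif`` (matrix) and ``*RGB2Laboff.tif`` (offset), and later
applied to per-grain mean RGB values.

An affine map commutes with averaging, so applying it to a grain's mean
RGB equals averaging per-pixel Lab under the same model; this matches the
swatch-mean convention the regression itself uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .core import RasterImage, ValidationError

MAT_SUFFIX = "RGB2Labmat.tif"
OFF_SUFFIX = "RGB2Laboff.tif"

#: Published CIELAB (D50, 2° observer) reference values for the classic
#: 24-patch ColorChecker, in card order (rows top→bottom, left→right).
COLORCHECKER_LAB = np.array(
    [
        [37.986, 13.555, 14.059],   # dark skin
        [65.711, 18.130, 17.810],   # light skin
        [49.927, -4.880, -21.925],  # blue sky
        [43.139, -13.095, 21.905],  # foliage
        [55.112, 8.844, -25.399],   # blue flower
        [70.719, -33.397, -0.199],  # bluish green
        [62.661, 36.067, 57.096],   # orange
        [40.020, 10.410, -45.964],  # purplish blue
        [51.124, 48.239, 16.248],   # moderate red
        [30.325, 22.976, -21.587],  # purple
        [72.532, -23.709, 57.255],  # yellow green
        [71.941, 19.363, 67.857],   # orange yellow
        [28.778, 14.179, -50.297],  # blue
        [55.261, -38.342, 31.370],  # green
        [42.101, 53.378, 28.190],   # red
        [81.733, 4.039, 79.819],    # yellow
        [51.935, 49.986, -14.574],  # magenta
        [51.038, -28.631, -28.638], # cyan
        [96.539, -0.425, 1.186],    # white
        [81.257, -0.638, -0.335],   # neutral 8
        [66.766, -0.734, -0.504],   # neutral 6.5
        [50.867, -0.153, -0.270],   # neutral 5
        [35.656, -0.421, -1.231],   # neutral 3.5
        [20.461, -0.079, -0.973],   # black
    ]
)

#: Nominal sRGB renderings of the same 24 patches; used only by the
#: synthetic card generator to construct a plausible true scanner map.
COLORCHECKER_SRGB = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
        [133, 128, 177], [103, 189, 170], [214, 126, 44], [80, 91, 166],
        [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
        [187, 86, 149], [8, 133, 161], [243, 243, 242], [200, 200, 200],
        [160, 160, 160], [122, 122, 121], [85, 85, 85], [52, 52, 52],
    ],
    dtype=np.float64,
)


@dataclass
class CardLayout:
    """Row-major grid layout of the colour card (default 4×6)."""

    rows: int = 4
    cols: int = 6

    @property
    def n_swatches(self) -> int:
        return self.rows * self.cols


@dataclass
class SwatchSet:
    """Measured swatch means aligned row-for-row with reference Lab."""

    mean_rgb: np.ndarray
    reference_lab: np.ndarray

    def __post_init__(self) -> None:
        self.mean_rgb = np.atleast_2d(np.asarray(self.mean_rgb, dtype=np.float64))
        self.reference_lab = np.atleast_2d(
            np.asarray(self.reference_lab, dtype=np.float64)
        )
        if self.mean_rgb.shape != self.reference_lab.shape or self.mean_rgb.shape[1] != 3:
            raise ValidationError(
                "mean_rgb and reference_lab must both be n×3 and aligned"
            )

    @property
    def n_swatches(self) -> int:
        return self.mean_rgb.shape[0]


@dataclass
class ColourTransform:
    """Affine RGB→Lab map: ``Lab = RGB @ matrix.T + offset``."""

    matrix: np.ndarray
    offset: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.matrix)) or not np.all(np.isfinite(self.offset)):
            raise ValidationError("non-finite transform")

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        return apply_transform(self, rgb)


def load_reference_csv(path: str | Path, expected_n: int | None = None) -> np.ndarray:
    """Read a user-supplied swatch reference table (swatch_id, L, a, b)."""
    import pandas as pd

    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    try:
        lab = frame[[cols["l"], cols["a"], cols["b"]]].to_numpy(dtype=np.float64)
    except KeyError as exc:
        raise ValidationError(f"reference CSV lacks column {exc}") from exc
    if expected_n is not None and lab.shape[0] != expected_n:
        raise ValidationError(
            f"reference CSV has {lab.shape[0]} swatches, expected {expected_n}"
        )
    return lab


# ---------------------------------------------------------------------------
# Swatch extraction


def _grid_assign(centroids: np.ndarray, rows: int, cols: int):
    """Assign swatch centroids to (row, col) grid positions.

    The grid axes are estimated from the centroid cloud (PCA gives the
    card rotation, tolerant to a few degrees); positions are then binned
    along each rotated axis.  Returns an index array ordering the
    centroids row-major, or raises if the grid is inconsistent.
    """
    centred = centroids - centroids.mean(axis=0)
    # principal axis of a row-major card is the column (long) direction
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    long_axis = vt[0]
    angle = np.arctan2(long_axis[0], long_axis[1])  # rotation w.r.t. horizontal
    if angle > np.pi / 2:
        angle -= np.pi
    if angle < -np.pi / 2:
        angle += np.pi
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])  # rotate (row, col) coords back
    aligned = centred @ rot.T
    order_r = np.argsort(aligned[:, 0], kind="stable")
    row_idx = np.empty(len(centroids), dtype=int)
    row_idx[order_r] = np.repeat(np.arange(rows), cols)
    col_idx = np.empty(len(centroids), dtype=int)
    for r in range(rows):
        members = np.flatnonzero(row_idx == r)
        if members.size != cols:
            raise ValidationError("grid fit failure: uneven swatch rows")
        members = members[np.argsort(aligned[members, 1], kind="stable")]
        col_idx[members] = np.arange(cols)
    return np.lexsort((col_idx, row_idx))


def extract_swatches(
    card_image: RasterImage,
    layout: CardLayout | None = None,
    reference_lab: np.ndarray | None = None,
) -> SwatchSet:
    """Locate the card's swatches and measure their mean RGB.

    The card is assumed to fill most of the scan with swatches brighter
    than the dark card mask/border.  Swatch cells are the n largest
    components above an Otsu threshold; each mean is taken over the
    central 50 % of the cell (border-safe).  Tolerates small rotations
    (≈5°).
    """
    from scipy import ndimage as ndi
    from skimage.filters import threshold_otsu

    layout = layout or CardLayout()
    if reference_lab is None:
        if layout.n_swatches != COLORCHECKER_LAB.shape[0]:
            raise ValidationError(
                "non-default layout requires an explicit reference table"
            )
        reference_lab = COLORCHECKER_LAB
    reference_lab = np.asarray(reference_lab, dtype=np.float64)
    if reference_lab.shape != (layout.n_swatches, 3):
        raise ValidationError(
            f"reference table shape {reference_lab.shape} does not match "
            f"{layout.rows}×{layout.cols} layout"
        )

    px = card_image.pixels.astype(np.float64)
    gray = px.mean(axis=2)
    # the darkest patch can sit below the Otsu split of a card scan, so
    # walk the threshold down towards the background level until the
    # expected number of similar-sized swatch cells appears
    bg = float(np.median(gray))
    t_otsu = float(threshold_otsu(gray))
    lab = keep = None
    for frac in (1.0, 0.5, 0.25, 0.1):
        t = bg + frac * (t_otsu - bg)
        if t <= bg:
            continue
        cand_lab, n = ndi.label(gray > t)
        if n < layout.n_swatches:
            continue
        areas = np.bincount(cand_lab.ravel())
        areas[0] = 0
        cand_keep = np.argsort(areas)[::-1][: layout.n_swatches]
        if areas[cand_keep].min() >= 0.3 * np.median(areas[cand_keep]):
            lab, keep = cand_lab, cand_keep
            break
    if lab is None:
        raise ValidationError(
            f"card not found: no threshold yields {layout.n_swatches} "
            "similar-sized swatch regions"
        )

    centroids = np.array(ndi.center_of_mass(lab > 0, lab, keep))
    order = _grid_assign(centroids, layout.rows, layout.cols)
    means = np.zeros((layout.n_swatches, 3))
    for out_pos, cand in enumerate(keep[order]):
        rr, cc = np.nonzero(lab == cand)
        r0, r1 = rr.min(), rr.max()
        c0, c1 = cc.min(), cc.max()
        hr = (r1 - r0 + 1) / 4.0
        hc = (c1 - c0 + 1) / 4.0
        inner = (
            (rr >= r0 + hr) & (rr <= r1 - hr) & (cc >= c0 + hc) & (cc <= c1 - hc)
        )
        if not inner.any():
            inner = slice(None)
        means[out_pos] = px[rr[inner], cc[inner]].mean(axis=0)
    return SwatchSet(mean_rgb=means, reference_lab=reference_lab)


# ---------------------------------------------------------------------------
# Regression and application


def fit_transform(swatches: SwatchSet) -> ColourTransform:
    """Least-squares affine fit of reference Lab on measured swatch RGB.

    Solves ``Lab ≈ RGB·Mᵀ + o`` jointly over the three Lab channels;
    ``residual_rms`` is the mean Euclidean Lab distance (ΔE*ab against
    the training swatches).
    """
    rgb = swatches.mean_rgb
    lab = swatches.reference_lab
    n = rgb.shape[0]
    if n < 4:
        raise ValidationError(f"need at least 4 swatches for the regression, got {n}")
    design = np.hstack([rgb, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValidationError("degenerate swatch colours: design matrix rank-deficient")
    coef, *_ = np.linalg.lstsq(design, lab, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    fitted = rgb @ matrix.T + offset
    residual_rms = float(np.mean(np.linalg.norm(fitted - lab, axis=1)))
    return ColourTransform(matrix=matrix, offset=offset, residual_rms=residual_rms)


def apply_transform(t: ColourTransform, mean_rgb: np.ndarray) -> np.ndarray:
    """Map n×3 (or length-3) mean RGB rows to Lab: ``RGB·Mᵀ + o``."""
    rgb = np.asarray(mean_rgb, dtype=np.float64)
    squeeze = rgb.ndim == 1
    rgb = np.atleast_2d(rgb)
    lab = rgb @ t.matrix.T + t.offset
    return lab[0] if squeeze else lab


def delta_e(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """Per-row Euclidean ΔE*ab between two n×3 Lab arrays."""
    return np.linalg.norm(np.atleast_2d(lab1) - np.atleast_2d(lab2), axis=1)


# ---------------------------------------------------------------------------
# Serialisation


def save_transform(t: ColourTransform, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>RGB2Labmat.tif`` (3×3) and ``<stem>RGB2Laboff.tif`` (3×1)."""
    mat_path = Path(f"{stem}{MAT_SUFFIX}")
    off_path = Path(f"{stem}{OFF_SUFFIX}")
    mat_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        mat_path,
        t.matrix.astype(np.float64),
        description=f"residual_rms={t.residual_rms!r}",
    )
    tifffile.imwrite(off_path, t.offset.reshape(3, 1).astype(np.float64))
    return mat_path, off_path


def load_transform(stem: str | Path) -> ColourTransform:
    """Load a transform written by :func:`save_transform` (bit-exact)."""
    residual = 0.0
    with tifffile.TiffFile(f"{stem}{MAT_SUFFIX}") as tf:
        matrix = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is not None and str(desc.value).startswith("residual_rms="):
            residual = float(str(desc.value).partition("=")[2])
    offset = tifffile.imread(f"{stem}{OFF_SUFFIX}")
    return ColourTransform(
        matrix=matrix, offset=np.asarray(offset).reshape(3), residual_rms=residual
    )
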