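"""Grain segmentation: grayscale, preprocessing, thresholding, splitting.

The chain that turns a colour scan into a label map of individual grains:

1. grayscale = mean of the red and green channels (these carry the most
   seed/background contrast on a flatbed scanner; blue is ignored);
2. preprocessing by Gaussian smoothing followed by contour-preserving
   attribute filters — a width-attribute closing (0.3 × minimum grain
   width) fills the dark crease, an elongation thinning removes bright
   scratches, and width/length openings (0.7 × minima) remove debris;
3. a single global threshold chosen from the low-gradient stratum of the
   bivariate (grey level, gradient) histogram, so edge pixels do not
   smear the grey histogram used for the between-class-variance split;
4. touching grains are split by flooding from the regional maxima of the
   smoothed Euclidean distance transform (troughs become cuts);
5. fragments below 0.5 × min width × min length pixels are dropped and
   survivors relabelled consecutively.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from . import attributes
from .core import LabelMap, PipelineConfig, RasterImage, ValidationError, relabel_consecutive


def to_grayscale(image: RasterImage) -> np.ndarray:
    """Grayscale as the per-pixel mean of the red and green channels."""
    px = image.pixels.astype(np.float64)
    return (px[:, :, 0] + px[:, :, 1]) / 2.0


def preprocess(gray: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Simplify the grayscale image prior to thresholding.

    Order: Gaussian smoothing; width-attribute closing at
    0.3 × min grain width (fills the crease); elongation thinning
    (removes scratches); width opening at 0.7 × min width (thin debris);
    length opening at 0.7 × min length (thick debris).  The attribute
    stages operate on an 8-bit quantisation of the smoothed image and are
    contour-preserving.
    """
    if min(gray.shape) < 1:
        raise ValidationError("empty image")
    sigma = config.gaussian_sigma_px
    if sigma > 0:
        if 2 * int(4 * sigma) + 1 > 2 * max(gray.shape):
            raise ValidationError("smoothing kernel larger than image")
        smoothed = ndi.gaussian_filter(gray, sigma=sigma, mode="nearest")
    else:
        smoothed = gray
    work = np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)

    close_w = max(1, int(round(0.3 * config.min_width_px)))
    open_w = max(1, int(round(0.7 * config.min_width_px)))
    open_l = max(1, int(round(0.7 * config.min_length_px)))

    work = attributes.width_closing(work, close_w)
    work = attributes.elongation_thinning(work, config.elongation_threshold)
    work = attributes.width_opening(work, open_w)
    work = attributes.length_opening(work, open_l)
    return work.astype(np.float64)


def _between_class_split(sample: np.ndarray, bins: int = 256) -> float:
    """Between-class-variance-maximising split of a sample's histogram.

    When the variance curve has a flat maximal plateau — typical for a
    cleanly bimodal histogram with an empty gap between the modes — the
    threshold is taken at the middle of the plateau, not its lower edge,
    so the cut sits midway between the modes.
    """
    hist, edges = np.histogram(sample, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist.astype(np.float64) / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sb = sb[:-1]
    sb[~np.isfinite(sb)] = -np.inf
    peak = sb.max()
    plateau = np.flatnonzero(sb >= peak - 1e-9 * max(abs(peak), 1.0))
    k = plateau[(plateau.size - 1) // 2]
    return float(centers[k])


def global_threshold(gray: np.ndarray, min_contrast: float = 20.0) -> float:
    """Global threshold from the bivariate grey/gradient histogram.

    Pixels with gradient magnitude at or below the median gradient (the
    low-gradient stratum: interiors of background and objects, not their
    borders) enter a between-class-variance split.  Foreground is
    ``gray > t``.

    When the two classes the split produces are separated by less than
    ``min_contrast`` grey levels the image is treated as background only
    (an empty scan is just noise; any split of it is spurious) and the
    returned threshold sits at the image maximum.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if np.ptp(gray) == 0:
        raise ValidationError("no contrast: constant image")
    grad = sobel(gray)
    low_grad = grad <= np.median(grad)
    sample = gray[low_grad]
    if np.ptp(sample) == 0:
        # degenerate stratum (e.g. a noiseless two-level image whose flat
        # zones all have zero gradient on one side); fall back to all pixels
        sample = gray.ravel()
    t = _between_class_split(sample)
    above = gray > t
    if not above.any() or gray[above].mean() - gray[~above].mean() < min_contrast:
        return float(gray.max())
    return t


def split_touching(mask: np.ndarray, config: PipelineConfig) -> LabelMap:
    """Partition the foreground mask into grains.

    Seeds are the regional maxima (one per plateau) of the Gaussian-
    smoothed Euclidean distance transform; each foreground pixel is
    assigned by watershed flooding of the negated distance map.  The union
    of the parts equals the input mask exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LabelMap(np.zeros(mask.shape, dtype=np.int32))
    dist = ndi.distance_transform_edt(mask)
    if config.dt_sigma_px > 0:
        dist = ndi.gaussian_filter(dist, sigma=config.dt_sigma_px, mode="nearest")
    h = config.seed_min_depth_px
    if h > 0:
        # merge maxima separated by troughs shallower than the minimum
        # depth (discretisation ripple along a grain's distance ridge, or
        # the duplicated top pixels of a symmetric grain): regional maxima
        # of the h-reconstruction form one connected plateau per peak
        rec = reconstruction(dist - h, dist, method="dilation")
        peaks = local_maxima(rec, connectivity=2) & mask
    else:
        peaks = local_maxima(dist, connectivity=2) & mask
    markers, n_seeds = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    if n_seeds == 0:  # pathological: no interior maxima; keep components whole
        markers, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    labels = watershed(-dist, markers=markers, mask=mask, connectivity=2)
    return LabelMap(relabel_consecutive(labels))


def filter_small(labels: LabelMap, config: PipelineConfig) -> LabelMap:
    """Drop objects below 0.5 × min width × min length pixels; relabel 1..n."""
    lab = labels.labels
    n = labels.n_objects
    if n == 0:
        return labels
    areas = np.bincount(lab.ravel(), minlength=n + 1)
    small = np.flatnonzero(areas < config.min_area_px)
    small = small[small > 0]
    if small.size:
        lab = lab.copy()
        lab[np.isin(lab, small)] = 0
    return LabelMap(relabel_consecutive(lab))


def segment(image: RasterImage, config: PipelineConfig) -> LabelMap:
    """Full segmentation: grayscale → preprocess → threshold → split → filter."""
    gray = to_grayscale(image)
    simplified = preprocess(gray, config)
    t = global_threshold(simplified)
    mask = simplified > t
    labels = split_touching(mask, config)
    return filter_small(labels, config)
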