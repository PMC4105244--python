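"""Crease detection and crease-aware colour partitioning.

A wheat grain lying crease-up shows a dark longitudinal groove that can
bias colour means.  For each segmented grain the crease is traced as the
minimum-cost path running end-to-end along the grain's long axis, after
mean filtering preferentially along that axis to suppress intensity
variation unrelated to the crease:

1. every grain pixel is replaced by the mean of up to ``k`` samples taken
   along the major-axis direction (clipped to the grain);
2. the grain is resampled (nearest neighbour) into an axis-aligned frame
   and a dynamic-programming shortest path is run column-by-column, the
   path moving at most one row sideways per column;
3. a crease is declared present when the grain's mean intensity exceeds
   the path's mean intensity by more than the contrast threshold τ; the
   crease region is the dark valley (below grain mean − τ/2) contiguous
   with the path.

Colour is then reported in three modes: the whole seed (GS), whole seeds
where no crease was detected (GSncd), and the non-crease area of seeds
with a detected crease (GSwc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .calibration import ColourTransform, apply_transform
from .core import GrainRecord, LabelMap, RasterImage, PipelineConfig, ValidationError


@dataclass
class CreaseResult:
    """Outcome of crease tracing for one grain (pixel coords are native)."""

    grain_id: int
    crease_detected: bool
    path_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    path_cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    crease_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    crease_cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    contrast: float = 0.0


def _axis_vectors(orientation_rad: float) -> tuple[np.ndarray, np.ndarray]:
    # direction of the major axis in (row, col) coordinates; orientation is
    # the ccw angle between the row axis and the major axis
    e_long = np.array([np.cos(orientation_rad), np.sin(orientation_rad)])
    e_perp = np.array([-np.sin(orientation_rad), np.cos(orientation_rad)])
    return e_long, e_perp


def directional_mean_filter(
    gray: np.ndarray,
    grain_mask: np.ndarray,
    orientation_rad: float,
    k: int = 9,
) -> np.ndarray:
    """Mean filter along the grain's major axis, clipped to the grain.

    Each grain pixel becomes the mean of the nearest-neighbour samples at
    offsets −(k−1)/2 … +(k−1)/2 pixels along the axis direction that fall
    inside the grain; pixels outside the grain are untouched.
    """
    if k < 3 or k % 2 == 0:
        raise ValidationError("k must be an odd integer >= 3")
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(grain_mask, dtype=bool)
    e_long, _ = _axis_vectors(orientation_rad)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return gray.copy()
    offsets = np.arange(k) - k // 2
    sample_r = np.rint(rr[None, :] + offsets[:, None] * e_long[0]).astype(np.int64)
    sample_c = np.rint(cc[None, :] + offsets[:, None] * e_long[1]).astype(np.int64)
    inside = (
        (sample_r >= 0)
        & (sample_r < gray.shape[0])
        & (sample_c >= 0)
        & (sample_c < gray.shape[1])
    )
    sr = np.clip(sample_r, 0, gray.shape[0] - 1)
    sc = np.clip(sample_c, 0, gray.shape[1] - 1)
    valid = inside & mask[sr, sc]
    vals = np.where(valid, gray[sr, sc], 0.0)
    counts = valid.sum(axis=0)
    counts = np.maximum(counts, 1)
    out = gray.copy()
    out[rr, cc] = vals.sum(axis=0) / counts
    return out


def _axis_align(values: np.ndarray, mask: np.ndarray, orientation_rad: float):
    """Nearest-neighbour resampling into a frame with the major axis
    horizontal; returns aligned values/mask plus source-index maps."""
    e_long, e_perp = _axis_vectors(orientation_rad)
    rr, cc = np.nonzero(mask)
    coords = np.stack([rr, cc], axis=1).astype(np.float64)
    p_long = coords @ e_long
    p_perp = coords @ e_perp
    l0, l1 = p_long.min(), p_long.max()
    q0, q1 = p_perp.min(), p_perp.max()
    width = int(np.ceil(l1 - l0)) + 1
    height = int(np.ceil(q1 - q0)) + 1
    jj, ii = np.meshgrid(np.arange(width), np.arange(height))
    native = (
        (l0 + jj)[..., None] * e_long[None, None, :]
        + (q0 + ii)[..., None] * e_perp[None, None, :]
    )
    src_r = np.rint(native[..., 0]).astype(np.int64)
    src_c = np.rint(native[..., 1]).astype(np.int64)
    inside = (
        (src_r >= 0)
        & (src_r < mask.shape[0])
        & (src_c >= 0)
        & (src_c < mask.shape[1])
    )
    src_r_c = np.clip(src_r, 0, mask.shape[0] - 1)
    src_c_c = np.clip(src_c, 0, mask.shape[1] - 1)
    a_mask = inside & mask[src_r_c, src_c_c]
    a_vals = np.where(a_mask, values[src_r_c, src_c_c], 0.0)
    return a_vals, a_mask, src_r_c, src_c_c


def _min_cost_path(cost: np.ndarray, valid: np.ndarray):
    """Column-wise DP shortest path with lateral steps in {−1, 0, +1}.

    Returns per-column row indices, or ``None`` when no end-to-end path
    exists inside ``valid``.
    """
    h, w = cost.shape
    INF = np.inf
    acc = np.full((h, w), INF)
    back = np.zeros((h, w), dtype=np.int64)
    acc[:, 0] = np.where(valid[:, 0], cost[:, 0], INF)
    for j in range(1, w):
        prev = acc[:, j - 1]
        stay = prev
        up = np.concatenate([[INF], prev[:-1]])  # from row-1
        down = np.concatenate([prev[1:], [INF]])  # from row+1
        choices = np.stack([up, stay, down])  # order fixes ties: prefer upper
        best = np.argmin(choices, axis=0)
        best_cost = choices[best, np.arange(h)]
        acc[:, j] = np.where(valid[:, j], best_cost + cost[:, j], INF)
        back[:, j] = best - 1  # offset of predecessor row
    if not np.isfinite(acc[:, -1]).any():
        return None
    rows = np.empty(w, dtype=np.int64)
    rows[-1] = int(np.argmin(acc[:, -1]))
    for j in range(w - 1, 0, -1):
        rows[j - 1] = rows[j] + back[rows[j], j]
    if not np.isfinite(acc[rows[0], 0]):
        return None
    return rows


def find_crease_path(
    filtered: np.ndarray,
    grain_mask: np.ndarray,
    orientation_rad: float,
    grain_id: int = 0,
    tau: float = 15.0,
) -> CreaseResult:
    """Trace the minimum-intensity path along the grain's long axis.

    ``filtered`` should be the axially mean-filtered grayscale.  A crease
    is declared when the grain mean exceeds the path mean by more than
    ``tau`` grey levels; the crease mask collects the dark valley pixels
    contiguous with the path.
    """
    mask = np.asarray(grain_mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0 or np.ptp(rr) < 2 or np.ptp(cc) < 2:
        return CreaseResult(grain_id=grain_id, crease_detected=False)
    # keep the path off the grain boundary: the anti-aliased / shaded rim
    # is dark for reasons unrelated to the crease
    interior = ndi.binary_erosion(mask, structure=np.ones((5, 5)))
    if not interior.any():
        return CreaseResult(grain_id=grain_id, crease_detected=False)
    a_vals, a_mask, src_r, src_c = _axis_align(filtered, interior, orientation_rad)
    col_ok = a_mask.any(axis=0)
    j0, j1 = np.flatnonzero(col_ok)[[0, -1]]
    sub_vals = a_vals[:, j0 : j1 + 1]
    sub_mask = a_mask[:, j0 : j1 + 1]
    if sub_mask.shape[1] < 3 or sub_mask.shape[0] < 3:
        return CreaseResult(grain_id=grain_id, crease_detected=False)
    rows = _min_cost_path(sub_vals, sub_mask)
    if rows is None:
        return CreaseResult(grain_id=grain_id, crease_detected=False)
    cols = np.arange(j0, j1 + 1)
    path_mean = float(sub_vals[rows, cols - j0].mean())
    grain_mean = float(filtered[interior].mean())
    contrast = grain_mean - path_mean
    detected = contrast > tau

    path_r = src_r[rows, cols]
    path_c = src_c[rows, cols]
    result = CreaseResult(
        grain_id=grain_id,
        crease_detected=bool(detected),
        path_rows=path_r,
        path_cols=path_c,
        contrast=contrast,
    )
    if not detected:
        return result
    valley = a_mask & (a_vals < grain_mean - tau / 2.0)
    lab, _ = ndi.label(valley, structure=np.ones((3, 3), dtype=int))
    on_path = np.unique(lab[rows, cols - j0])
    on_path = on_path[on_path > 0]
    crease_aligned = np.isin(lab, on_path)
    cr = src_r[crease_aligned]
    cc_ = src_c[crease_aligned]
    # de-duplicate native pixels hit by multiple aligned samples
    flat = np.unique(cr * mask.shape[1] + cc_)
    result.crease_rows = flat // mask.shape[1]
    result.crease_cols = flat % mask.shape[1]
    return result


def detect_creases(
    gray: np.ndarray,
    labels: LabelMap,
    records: list[GrainRecord],
    config: PipelineConfig,
) -> list[CreaseResult]:
    """Run the axial mean filter and crease tracing on every grain."""
    results: list[CreaseResult] = []
    lab = labels.labels
    slices = ndi.find_objects(lab)
    for rec in records:
        sl = slices[rec.grain_id - 1]
        if sl is None:
            results.append(CreaseResult(grain_id=rec.grain_id, crease_detected=False))
            continue
        pad_sl = tuple(
            slice(max(0, s.start - 2), min(dim, s.stop + 2))
            for s, dim in zip(sl, lab.shape)
        )
        sub_gray = gray[pad_sl]
        sub_mask = lab[pad_sl] == rec.grain_id
        filtered = directional_mean_filter(
            sub_gray, sub_mask, rec.orientation_rad, k=config.crease_mean_k
        )
        res = find_crease_path(
            filtered,
            sub_mask,
            rec.orientation_rad,
            grain_id=rec.grain_id,
            tau=config.crease_tau,
        )
        off_r, off_c = pad_sl[0].start, pad_sl[1].start
        res.path_rows = res.path_rows + off_r
        res.path_cols = res.path_cols + off_c
        res.crease_rows = res.crease_rows + off_r
        res.crease_cols = res.crease_cols + off_c
        results.append(res)
    return results


def crease_label_map(labels: LabelMap, creases: list[CreaseResult]) -> LabelMap:
    """Label map of detected crease regions (grain ids preserved)."""
    out = np.zeros(labels.shape, dtype=np.int32)
    for res in creases:
        if res.crease_detected and res.crease_rows.size:
            out[res.crease_rows, res.crease_cols] = res.grain_id
    # crease ids follow grain ids; re-pack to consecutive for the LabelMap
    from .core import relabel_consecutive

    return LabelMap(relabel_consecutive(out))


def partition_colour(
    image: RasterImage,
    labels: LabelMap,
    creases: list[CreaseResult] | None,
    records: list[GrainRecord],
    transform: ColourTransform | None = None,
) -> list[GrainRecord]:
    """Fill per-grain colour columns, split by crease where detected.

    The whole-seed mean (GS) is always reported.  For grains with a
    detected crease the crease / non-crease means are also computed; the
    channel sums are integers, so the whole-seed mean is exactly the
    area-weighted combination of the two parts.  When ``transform`` is
    given, CIELAB values are appended (applied to mean RGB).
    """
    if labels.shape != image.shape:
        raise ValidationError("labels and image shapes differ")
    px = image.pixels
    lab_img = labels.labels
    crease_by_id = {c.grain_id: c for c in creases} if creases is not None else {}
    for rec in records:
        gmask = lab_img == rec.grain_id
        n_grain = int(gmask.sum())
        if n_grain == 0:
            continue
        res = crease_by_id.get(rec.grain_id)
        if res is not None and res.crease_detected and res.crease_rows.size:
            cmask = np.zeros_like(gmask)
            cmask[res.crease_rows, res.crease_cols] = True
            cmask &= gmask
            nmask = gmask & ~cmask
            c_sum = px[cmask].astype(np.int64).sum(axis=0)
            n_sum = px[nmask].astype(np.int64).sum(axis=0)
            n_c, n_n = int(cmask.sum()), int(nmask.sum())
            total = c_sum + n_sum  # exact: integer sums over a disjoint partition
            rec.mean_R, rec.mean_G, rec.mean_B = (float(s) / n_grain for s in total)
            rec.crease_detected = True
            if transform is not None and n_n and n_c:
                non_rgb = n_sum / n_n
                cre_rgb = c_sum / n_c
                rec.L_noncrease, rec.a_noncrease, rec.b_noncrease = apply_transform(
                    transform, non_rgb
                )
                rec.L_crease, rec.a_crease, rec.b_crease = apply_transform(
                    transform, cre_rgb
                )
        else:
            total = px[gmask].astype(np.int64).sum(axis=0)
            rec.mean_R, rec.mean_G, rec.mean_B = (float(s) / n_grain for s in total)
            if creases is not None:
                rec.crease_detected = False
        if transform is not None:
            rec.L, rec.a, rec.b = apply_transform(
                transform, np.array([rec.mean_R, rec.mean_G, rec.mean_B])
            )
    return records


def colour_mode_means(
    image: RasterImage, labels: LabelMap, creases: list[CreaseResult]
) -> dict[str, np.ndarray | None]:
    """Per-scan mean RGB under the three colour-reporting modes.

    ``GS``: mean over whole-seed means of all grains.  ``GSncd``: grains
    where no crease was detected.  ``GSwc``: non-crease area of grains
    with a detected crease.  A mode with no qualifying grain maps to
    ``None``.
    """
    px = image.pixels
    lab_img = labels.labels
    gs, ncd, wc = [], [], []
    for res in creases:
        gmask = lab_img == res.grain_id
        if not gmask.any():
            continue
        whole = px[gmask].astype(np.float64).mean(axis=0)
        gs.append(whole)
        if res.crease_detected and res.crease_rows.size:
            cmask = np.zeros_like(gmask)
            cmask[res.crease_rows, res.crease_cols] = True
            nmask = gmask & ~cmask
            if nmask.any():
                wc.append(px[nmask].astype(np.float64).mean(axis=0))
        else:
            ncd.append(whole)

    def avg(rows):
        return np.mean(rows, axis=0) if rows else None

    return {"GS": avg(gs), "GSncd": avg(ncd), "GSwc": avg(wc)}
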