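"""Ground-truthed synthetic scenes: grain fields and colour-checker cards.

The generators emulate the scanning setup the pipeline targets — seeds
scattered on a dark background, scanned at a known dpi, plus a 24-swatch
colour card scanned under the same settings — with pixel-exact ground
truth (labels, per-grain physical dimensions and colours, crease masks,
the true RGB→Lab map).  Everything is driven by a seeded generator, so a
given (spec, seed) always renders bit-identical output.

Grains are rendered as ellipses with an optional dark axial crease
stripe, anti-aliased by 4×4 supersampling, with additive Gaussian pixel
noise.  Truth labels mark pixels with supersampled coverage ≥ 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import COLORCHECKER_LAB, COLORCHECKER_SRGB, CardLayout, ColourTransform
from .core import LabelMap, RasterImage, ValidationError

SUPERSAMPLE = 4


@dataclass
class GrainFieldSpec:
    """Parameters of a rendered grain field.

    Lengths/widths are grain axis diameters in mm (mean, sd of a clipped
    normal).  ``crease_fraction`` of grains carry a dark axial stripe of
    the given depth (grey levels subtracted from the body colour) and
    width; ``touching_fraction`` of grains are placed as touching pairs
    with a small (~2 px) overlap so the splitting stage has work to do.
    """

    n_grains: int = 50
    length_mm: tuple[float, float] = (6.71, 0.45)
    width_mm: tuple[float, float] = (3.41, 0.22)
    body_rgb: tuple[float, float, float] = (172.0, 126.0, 78.0)
    body_rgb_sd: float = 8.0
    background_rgb: tuple[float, float, float] = (14.0, 13.0, 15.0)
    noise_sd: float = 3.0
    crease_fraction: float = 0.0
    crease_depth: float = 60.0
    crease_width_mm: float = 0.45
    touching_fraction: float = 0.0
    dpi: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grains <= 0:
            raise ValidationError("n_grains must be positive")
        if min(self.length_mm[0], self.width_mm[0]) <= 0:
            raise ValidationError("grain dimensions must be positive")
        if self.length_mm[0] < self.width_mm[0]:
            raise ValidationError("mean length must be >= mean width")
        for frac in (self.crease_fraction, self.touching_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must be in [0, 1]")


def wheat_spec(**overrides) -> GrainFieldSpec:
    """Wheat-like preset: mean area ≈ 18 mm², length ≈ 6.7, width ≈ 3.4 mm."""
    return replace(GrainFieldSpec(), **overrides)


def brachypodium_spec(**overrides) -> GrainFieldSpec:
    """Elongated-seed preset: mean length 8.71 mm, width 1.47 mm."""
    base = GrainFieldSpec(
        length_mm=(8.71, 0.4),
        width_mm=(1.47, 0.09),
        body_rgb=(150.0, 118.0, 82.0),
    )
    return replace(base, **overrides)


@dataclass
class GrainTruth:
    """Ground truth accompanying a rendered grain field."""

    labels: LabelMap
    crease_labels: LabelMap
    table: pd.DataFrame  # per-grain true parameters


def _render_grain(
    canvas: np.ndarray,
    cover_accum: np.ndarray,
    label_img: np.ndarray,
    crease_img: np.ndarray,
    gid: int,
    center: tuple[float, float],
    a_px: float,
    b_px: float,
    phi: float,
    body: np.ndarray,
    crease_rgb: np.ndarray | None,
    crease_halfwidth_px: float,
) -> None:
    h, w = canvas.shape[:2]
    cr, cc = center
    reach = a_px + 2
    r0, r1 = max(0, int(cr - reach)), min(h, int(cr + reach) + 1)
    c0, c1 = max(0, int(cc - reach)), min(w, int(cc + reach) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    sub = (np.arange(SUPERSAMPLE) + 0.5) / SUPERSAMPLE - 0.5
    rows = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel()
    dr = rows[:, None] - cr
    dc = cols[None, :] - cc
    u = dr * np.cos(phi) + dc * np.sin(phi)
    v = -dr * np.sin(phi) + dc * np.cos(phi)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    shape = (r1 - r0, SUPERSAMPLE, c1 - c0, SUPERSAMPLE)
    cover = inside.reshape(shape).mean(axis=(1, 3))
    if crease_rgb is not None:
        stripe = inside & (np.abs(v) <= crease_halfwidth_px) & (np.abs(u) <= 0.85 * a_px)
        cover_stripe = stripe.reshape(shape).mean(axis=(1, 3))
    else:
        cover_stripe = np.zeros_like(cover)
    cover_body = cover - cover_stripe
    region = canvas[r0:r1, c0:c1]
    region *= (1.0 - cover)[..., None]
    region += cover_body[..., None] * body[None, None, :]
    if crease_rgb is not None:
        region += cover_stripe[..., None] * crease_rgb[None, None, :]
    # label ownership: majority coverage wins; earlier grain keeps ties
    owned = (cover >= 0.5) & (cover > cover_accum[r0:r1, c0:c1])
    label_img[r0:r1, c0:c1][owned] = gid
    cover_accum[r0:r1, c0:c1] = np.maximum(cover_accum[r0:r1, c0:c1], cover)
    if crease_rgb is not None:
        crease_img[r0:r1, c0:c1][(cover_stripe >= 0.5) & owned] = gid


def render_grain_field(spec: GrainFieldSpec) -> tuple[RasterImage, GrainTruth]:
    """Render a grain field with pixel-exact ground truth.

    Grains (or touching pairs) are laid out on a shuffled, jittered grid
    whose cells are sized to the largest grain, which guarantees feasible
    packing; an infeasible spec (grain larger than its cell at the
    requested count) raises instead of looping forever.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_grains
    lengths = np.clip(
        rng.normal(spec.length_mm[0], spec.length_mm[1], n),
        0.4 * spec.length_mm[0],
        1.8 * spec.length_mm[0],
    )
    widths = np.clip(
        rng.normal(spec.width_mm[0], spec.width_mm[1], n),
        0.4 * spec.width_mm[0],
        1.6 * spec.width_mm[0],
    )
    widths = np.minimum(widths, lengths)
    phis = rng.uniform(-np.pi / 2, np.pi / 2, n)
    bodies = np.clip(
        np.asarray(spec.body_rgb)[None, :] + rng.normal(0, spec.body_rgb_sd, (n, 3)),
        0,
        255,
    )
    has_crease = rng.random(n) < spec.crease_fraction

    len_px = lengths * spec.dpi / 25.4
    wid_px = widths * spec.dpi / 25.4
    max_len = float(len_px.max())

    n_pairs = int(round(spec.touching_fraction * n / 2.0))
    pair_first = list(range(0, 2 * n_pairs, 2))
    singles = list(range(2 * n_pairs, n))
    n_cells = n_pairs + len(singles)
    cell = int(np.ceil(1.45 * max_len))
    if cell < 4:
        raise ValidationError("grains too small for the pixel grid")
    grid = int(np.ceil(np.sqrt(n_cells)))
    margin = cell // 2
    side = grid * cell + 2 * margin
    canvas = np.ones((side, side, 3)) * np.asarray(spec.background_rgb)
    cover_accum = np.zeros((side, side))
    label_img = np.zeros((side, side), dtype=np.int32)
    crease_img = np.zeros((side, side), dtype=np.int32)

    cells = [(r, c) for r in range(grid) for c in range(grid)]
    rng.shuffle(cells)
    cells = cells[:n_cells]
    crease_hw_px = max(0.6, spec.crease_width_mm / 2.0 * spec.dpi / 25.4)

    placements: list[tuple[int, float, float]] = []  # gid, center r, c
    jitter = max(1.0, 0.08 * cell)
    for k, gid_idx in enumerate(pair_first + singles):
        gr, gc = cells[k]
        cr = margin + (gr + 0.5) * cell + rng.uniform(-jitter, jitter)
        cc = margin + (gc + 0.5) * cell + rng.uniform(-jitter, jitter)
        if k < n_pairs:
            i, j = gid_idx, gid_idx + 1
            phi = phis[i]
            phis[j] = phi  # touching pairs share orientation
            sep = (wid_px[i] + wid_px[j]) / 2.0 - 2.0  # ~2 px overlap
            off = np.array([-np.sin(phi), np.cos(phi)]) * sep / 2.0
            placements.append((i, cr - off[0], cc - off[1]))
            placements.append((j, cr + off[0], cc + off[1]))
        else:
            placements.append((gid_idx, cr, cc))

    order = sorted(placements, key=lambda t: t[0])
    centers = np.zeros((n, 2))
    for idx, cr, cc in order:
        centers[idx] = (cr, cc)
        crease_rgb = None
        if has_crease[idx]:
            crease_rgb = np.clip(bodies[idx] - spec.crease_depth, 0, 255)
        _render_grain(
            canvas,
            cover_accum,
            label_img,
            crease_img,
            idx + 1,
            (cr, cc),
            len_px[idx] / 2.0,
            wid_px[idx] / 2.0,
            phis[idx],
            bodies[idx],
            crease_rgb,
            crease_hw_px,
        )

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0, spec.noise_sd, canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    table = pd.DataFrame(
        {
            "grain_id": np.arange(1, n + 1),
            "center_row": centers[:, 0],
            "center_col": centers[:, 1],
            "length_mm": lengths,
            "width_mm": widths,
            "orientation_rad": phis,
            "area_mm2": np.pi * (lengths / 2) * (widths / 2),
            "body_R": bodies[:, 0],
            "body_G": bodies[:, 1],
            "body_B": bodies[:, 2],
            "has_crease": has_crease,
        }
    )
    truth = GrainTruth(
        labels=LabelMap(label_img),
        crease_labels=LabelMap(crease_img.astype(np.int32)),
        table=table,
    )
    return RasterImage(pixels=pixels, dpi=spec.dpi, source_path="<synthetic>"), truth


# ---------------------------------------------------------------------------
# Colour card


def default_true_transform() -> ColourTransform:
    """A plausible scanner RGB→Lab affine map.

    Constructed once by regressing the published card Lab values on the
    card's nominal sRGB renderings; used as the generator's ground truth.
    """
    rgb = COLORCHECKER_SRGB
    lab = COLORCHECKER_LAB
    design = np.hstack([rgb, np.ones((rgb.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, lab, rcond=None)
    return ColourTransform(matrix=coef[:3].T, offset=coef[3], residual_rms=0.0)


def render_colour_card(
    reference_lab: np.ndarray | None = None,
    transform: ColourTransform | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rotation_deg: float = 0.0,
    layout: CardLayout | None = None,
    swatch_px: int = 48,
    gap_px: int = 14,
    pixel_noise_sd: float = 0.0,
) -> tuple[RasterImage, dict]:
    """Render a colour-checker card whose swatch RGBs invert a true map.

    Swatch RGB = inverse-affine image of the reference Lab values under
    ``transform``, plus per-swatch Gaussian noise of sd ``noise_sd``.
    Returns the card image and a truth dict with the true transform, the
    exact (float, post-noise) swatch RGBs and the rotation applied.
    """
    layout = layout or CardLayout()
    if reference_lab is None:
        reference_lab = COLORCHECKER_LAB
    reference_lab = np.asarray(reference_lab, dtype=np.float64)
    if reference_lab.shape[0] != layout.n_swatches:
        raise ValidationError("reference table does not match layout")
    transform = transform or default_true_transform()
    rng = np.random.default_rng(seed)
    inv = np.linalg.inv(transform.matrix)
    rgb_exact = (reference_lab - transform.offset) @ inv.T
    rgb_noisy = rgb_exact + rng.normal(0, noise_sd, rgb_exact.shape)
    if rgb_noisy.min() < 0 or rgb_noisy.max() > 255:
        raise ValidationError(
            "rendering map pushes swatch RGB outside [0, 255]; choose another map"
        )

    pitch = swatch_px + gap_px
    card_h = layout.rows * pitch + gap_px
    card_w = layout.cols * pitch + gap_px
    pad = int(0.12 * max(card_h, card_w)) + int(abs(rotation_deg)) * 4
    h, w = card_h + 2 * pad, card_w + 2 * pad
    bg = 8.0
    img = np.full((h, w, 3), bg)
    theta = np.deg2rad(rotation_deg)
    cr0, cc0 = h / 2.0, w / 2.0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr = rr - cr0
    dc = cc - cc0
    # derotate pixel coords into the card frame
    r_card = dr * np.cos(theta) + dc * np.sin(theta) + card_h / 2.0
    c_card = -dr * np.sin(theta) + dc * np.cos(theta) + card_w / 2.0
    row_idx = np.floor((r_card - gap_px) / pitch).astype(int)
    col_idx = np.floor((c_card - gap_px) / pitch).astype(int)
    in_row_cell = (r_card - gap_px) - row_idx * pitch < swatch_px
    in_col_cell = (c_card - gap_px) - col_idx * pitch < swatch_px
    valid = (
        (row_idx >= 0)
        & (row_idx < layout.rows)
        & (col_idx >= 0)
        & (col_idx < layout.cols)
        & in_row_cell
        & in_col_cell
    )
    sw = row_idx * layout.cols + col_idx
    sw = np.where(valid, sw, 0)
    img[valid] = rgb_noisy[sw[valid]]
    if pixel_noise_sd > 0:
        img = img + rng.normal(0, pixel_noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {
        "transform": transform,
        "swatch_rgb": rgb_noisy,
        "reference_lab": reference_lab,
        "rotation_deg": rotation_deg,
    }
    return RasterImage(pixels=pixels, dpi=300.0, source_path="<synthetic card>"), truth
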