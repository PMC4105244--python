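"""Ground-truth benchmarks of the pipeline on synthetic scenes.

Shared by the test suite and the reproduction script: each benchmark
renders known scenes, runs the pipeline and scores it against the
generator's truth (count recall/precision, size errors against analytic
ellipse dimensions, crease sensitivity/specificity, colour-mode
agreement).
"""

from __future__ import annotations

import numpy as np

from .calibration import SwatchSet, fit_transform
from .core import LabelMap, PipelineConfig
from .crease import colour_mode_means
from .morphometry import measure_size
from .pipeline import analyse_image
from .segmentation import segment
from .synthetic import render_colour_card, render_grain_field, wheat_spec

#: Grain counts of the 20-scene segmentation benchmark, spanning small
#: scenes up to the full scan scale (the mean seeds-per-scan of the wheat
#: material the tool was built for is 654).
SEGMENTATION_SCENE_SIZES = (
    50, 55, 60, 65, 70, 75, 80, 85, 90, 95,
    100, 105, 110, 115, 120, 130, 150, 200, 300, 654,
)


def match_counts(pred: LabelMap, truth: LabelMap) -> tuple[int, int, int]:
    """Majority-overlap one-to-one matching: (matched, n_pred, n_true)."""
    pl = pred.labels
    tl = truth.labels
    n_true = truth.n_objects
    n_pred = pred.n_objects
    matched = 0
    used: set[int] = set()
    for tid in range(1, n_true + 1):
        m = tl == tid
        overlap = np.bincount(pl[m], minlength=n_pred + 1)
        overlap[0] = 0
        if overlap.sum() == 0:
            continue
        best = int(overlap.argmax())
        if best not in used and overlap[best] > 0.5 * m.sum():
            used.add(best)
            matched += 1
    return matched, n_pred, n_true


def segmentation_benchmark(
    seed: int = 1,
    scene_sizes: tuple[int, ...] = SEGMENTATION_SCENE_SIZES,
    touching_fraction: float = 0.15,
    crease_fraction: float = 0.3,
) -> dict:
    """Grain-count recall/precision over ground-truthed wheat scenes."""
    config = PipelineConfig()
    matched = n_pred = n_true = 0
    per_scene = []
    for i, n in enumerate(scene_sizes):
        spec = wheat_spec(
            n_grains=n,
            seed=seed + i,
            touching_fraction=touching_fraction,
            crease_fraction=crease_fraction,
        )
        image, truth = render_grain_field(spec)
        labels = segment(image, config)
        m, p, t = match_counts(labels, truth.labels)
        matched += m
        n_pred += p
        n_true += t
        per_scene.append({"n_true": t, "n_pred": p, "matched": m})
    return {
        "recall": matched / n_true,
        "precision": matched / n_pred,
        "n_scenes": len(scene_sizes),
        "n_grains_total": n_true,
        "per_scene": per_scene,
    }


def size_accuracy_benchmark(seed: int = 1, n_grains: int = 40) -> dict:
    """Per-grain size errors against analytic ellipse truth, plus the
    shift in mm measurements when the same scene is rendered at 2× dpi."""
    errors: dict[str, list[float]] = {"area": [], "major": [], "minor": []}
    recs_by_dpi = {}
    for dpi in (300.0, 600.0):
        spec = wheat_spec(
            n_grains=n_grains, seed=seed, noise_sd=0.0, dpi=dpi,
            crease_fraction=0.0, touching_fraction=0.0,
        )
        image, truth = render_grain_field(spec)
        labels = segment(image, PipelineConfig(dpi=dpi))
        records = measure_size(labels, dpi)
        tl = truth.labels.labels
        by_truth = {}
        for rec in records:
            r, c = (int(round(v)) for v in rec.centroid_px)
            tid = int(tl[r, c])
            if tid > 0:
                by_truth[tid] = rec
        recs_by_dpi[dpi] = by_truth
        if dpi == 300.0:
            for tid, rec in by_truth.items():
                row = truth.table.iloc[tid - 1]
                errors["area"].append(abs(rec.area_mm2 - row.area_mm2) / row.area_mm2)
                errors["major"].append(
                    abs(rec.majellipse_mm - row.length_mm) / row.length_mm
                )
                errors["minor"].append(
                    abs(rec.minellipse_mm - row.width_mm) / row.width_mm
                )
    dpi_shift = []
    for tid, lo in recs_by_dpi[300.0].items():
        hi = recs_by_dpi[600.0].get(tid)
        if hi is None:
            continue
        for attr in ("area_mm2", "majellipse_mm", "minellipse_mm"):
            a, b = getattr(lo, attr), getattr(hi, attr)
            dpi_shift.append(abs(a - b) / a)
    return {
        "max_area_rel_err": float(np.max(errors["area"])),
        "max_major_rel_err": float(np.max(errors["major"])),
        "max_minor_rel_err": float(np.max(errors["minor"])),
        "max_dpi_doubling_shift": float(np.max(dpi_shift)),
        "n_grains": len(errors["area"]),
    }


def calibration_benchmark(seed: int = 1) -> dict:
    """Affine-map recovery error and residual growth with swatch noise."""
    _, truth = render_colour_card(noise_sd=0.0, seed=seed)
    fitted = fit_transform(SwatchSet(truth["swatch_rgb"], truth["reference_lab"]))
    true = truth["transform"]
    recovery = max(
        float(np.abs(fitted.matrix - true.matrix).max()),
        float(np.abs(fitted.offset - true.offset).max()),
    )
    residuals = []
    for sd in (0.0, 0.5, 1.0, 2.0):
        _, t = render_colour_card(noise_sd=sd, seed=seed + 1)
        f = fit_transform(SwatchSet(t["swatch_rgb"], t["reference_lab"]))
        residuals.append(float(f.residual_rms))
    return {
        "recovery_max_abs_err": recovery,
        "residuals_by_noise": residuals,
        "monotone": all(a < b for a, b in zip(residuals, residuals[1:])),
        "n_swatches": truth["swatch_rgb"].shape[0],
    }


def crease_benchmark(
    seed: int = 1, n_grains: int = 200, depth: float = 40.0
) -> dict:
    """Crease sensitivity (creased grains) and false-positive rate
    (crease-free grains) at the given crease depth."""
    config = PipelineConfig(crease_enabled=True)
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    half = n_grains // 2
    for offs, crease_fraction in ((0, 1.0), (1, 0.0)):
        spec = wheat_spec(
            n_grains=half,
            seed=seed + offs,
            crease_fraction=crease_fraction,
            crease_depth=depth,
            noise_sd=3.0,
        )
        image, truth = render_grain_field(spec)
        result = analyse_image(image, config)
        tl = truth.labels.labels
        for rec, cres in zip(result.records, result.creases):
            r, c = (int(round(v)) for v in rec.centroid_px)
            tid = int(tl[r, c])
            if tid == 0:
                continue
            truly = bool(truth.table.has_crease[tid - 1])
            if truly and cres.crease_detected:
                counts["tp"] += 1
            elif truly:
                counts["fn"] += 1
            elif cres.crease_detected:
                counts["fp"] += 1
            else:
                counts["tn"] += 1
    sens = counts["tp"] / max(1, counts["tp"] + counts["fn"])
    fpr = counts["fp"] / max(1, counts["fp"] + counts["tn"])
    return {"sensitivity": sens, "false_positive_rate": fpr, **counts}


def colour_mode_benchmark(
    seed: int = 1, n_scenes: int = 10, n_grains: int = 150
) -> dict:
    """Agreement of the GS / GSncd / GSwc colour-reporting modes.

    Scenes play the role of seed samples: each has many grains (a scan of
    the target material averages hundreds) and its own body colour,
    spread over ±30 grey levels — the scale on which wheat samples of
    different pigmentation genotypes differ.  Returned is the minimum
    Pearson correlation between per-scene mode means over channels and
    mode pairs.
    """
    rng = np.random.default_rng(seed)
    per_mode: dict[str, list[np.ndarray]] = {"GS": [], "GSncd": [], "GSwc": []}
    config = PipelineConfig(crease_enabled=True)
    for i in range(n_scenes):
        shift = rng.uniform(-30, 30, 3)
        body = tuple(np.clip(np.array([172.0, 126.0, 78.0]) + shift, 30, 225))
        spec = wheat_spec(
            n_grains=n_grains,
            seed=seed + 100 + i,
            crease_fraction=0.5,
            crease_depth=40.0,
            noise_sd=3.0,
            body_rgb=body,
        )
        image, _ = render_grain_field(spec)
        result = analyse_image(image, config)
        modes = colour_mode_means(image, result.labels, result.creases)
        if any(v is None for v in modes.values()):
            continue
        for k, v in modes.items():
            per_mode[k].append(v)
    arrays = {k: np.array(v) for k, v in per_mode.items()}
    corrs = []
    pairs = (("GS", "GSncd"), ("GS", "GSwc"), ("GSncd", "GSwc"))
    for a, b in pairs:
        for ch in range(3):
            corrs.append(float(np.corrcoef(arrays[a][:, ch], arrays[b][:, ch])[0, 1]))
    return {
        "min_correlation": min(corrs),
        "n_scenes": len(arrays["GS"]),
        "correlations": corrs,
    }
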