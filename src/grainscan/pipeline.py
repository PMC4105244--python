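"""End-to-end analysis of one scan: segment, measure, colour, outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .calibration import ColourTransform
from .core import GrainRecord, LabelMap, PipelineConfig, RasterImage, ValidationError
from .crease import CreaseResult, crease_label_map, detect_creases, partition_colour
from .imaging import write_label_image, write_overlay, write_results_csv
from .morphometry import measure_size
from .segmentation import segment, to_grayscale


@dataclass
class ScanResult:
    """Everything the pipeline produced for one input image."""

    image: RasterImage
    labels: LabelMap
    records: list[GrainRecord]
    creases: Optional[list[CreaseResult]] = None
    output_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def n_grains(self) -> int:
        return self.labels.n_objects


def analyse_image(
    image: RasterImage,
    config: PipelineConfig,
    transform: ColourTransform | None = None,
) -> ScanResult:
    """Segment and measure a scan in memory (no files written)."""
    dpi = config.dpi if config.dpi is not None else image.dpi
    if dpi is None or dpi <= 0:
        raise ValidationError(
            "no resolution available: set dpi in the config or use a file "
            "with resolution metadata"
        )
    labels = segment(image, config)
    records = measure_size(labels, dpi) if labels.n_objects else []
    creases = None
    if config.crease_enabled and records:
        gray = to_grayscale(image)
        creases = detect_creases(gray, labels, records, config)
    partition_colour(image, labels, creases, records, transform)
    return ScanResult(image=image, labels=labels, records=records, creases=creases)


def write_outputs(result: ScanResult, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write the CSV, label TIFFs and overlay JPEGs for one scan."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["csv"] = write_results_csv(result.records, out_dir, stem)
    base = out_dir / stem
    paths["grainLbl"] = write_label_image(result.labels, base, "grainLbl")
    paths["grainOvr"] = write_overlay(result.image, result.labels, base, "grainOvr")
    if result.creases is not None:
        crease_labels = crease_label_map(result.labels, result.creases)
        paths["creaseLbl"] = write_label_image(crease_labels, base, "creaseLbl")
        paths["creaseOvr"] = write_overlay(result.image, crease_labels, base, "creaseOvr")
    result.output_paths = paths
    return paths
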