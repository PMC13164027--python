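"""End-to-end per-image scoring: config, reports, batch driver.

One call takes an RGB tile plus a mask source (file, built-in fallback
segmenter, or external adapter), runs postprocessing, per-nucleus
classification and Allred scoring, and emits three artifacts per image: a
per-nucleus CSV, a four-color overlay PNG and a JSON report.  The batch
driver accepts a manifest of images (or a counts-only table, which routes
straight to the scoring rules) and writes one summary CSV whose columns
mirror the reference scoring table: Total, Strong, Moderate, Weak,
Negative, P, I, Allred.

All floats in reports use fixed formatting (mu to 4 decimals, percentages
to 2), so re-running a configuration yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .classification import (
    ClassThresholds,
    NucleusRecord,
    StainClass,
    classify_image,
    render_class_overlay,
)
from .errors import ConfigError, FormatError
from .scoring import AllredResult, CountTable, allred, score_counts_frame
from .segmentation import (
    InstanceMask,
    fallback_segment,
    load_instance_mask,
    postprocess_instances,
    run_external_segmenter,
)
from .stains import StainModel

__all__ = ["RunConfig", "ImageReport", "score_image", "score_batch", "load_rgb"]

logger = logging.getLogger("dabquant")


class StainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vectors: list[list[float]] | None = None
    background_intensity: float = 255.0
    od_reference: float = 1.0

    def build(self) -> StainModel:
        kwargs = {}
        if self.vectors is not None:
            kwargs["vectors"] = np.asarray(self.vectors, dtype=float)
        return StainModel(
            background_intensity=self.background_intensity,
            od_reference=self.od_reference,
            **kwargs,
        )


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    source: Literal["file", "fallback", "external"] = "fallback"
    min_area: int = Field(default=20, ge=1)
    fill_holes: bool = True
    merge_fragments: bool = True
    min_seed_distance: int = Field(default=7, ge=1)


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tau1: float = 0.89
    tau2: float = 0.94
    tau3: float = 0.975

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdConfig":
        if not (0 < self.tau1 < self.tau2 < self.tau3 < 1):
            raise ValueError("thresholds must satisfy 0 < tau1 < tau2 < tau3 < 1")
        return self

    def build(self) -> ClassThresholds:
        return ClassThresholds(self.tau1, self.tau2, self.tau3)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    stains: StainConfig = Field(default_factory=StainConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    output_dir: str = "dabquant_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(data)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc


@dataclass(frozen=True)
class ImageReport:
    """Per-image result: nucleus records, counts, Allred scores, provenance."""

    image_id: str
    records: tuple[NucleusRecord, ...]
    counts: CountTable
    result: AllredResult | None  # None when no nuclei were found
    thresholds: tuple[float, float, float]
    status: str = "ok"  # "ok" | "undefined"

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "status": self.status,
            "thresholds": {
                "tau1": self.thresholds[0],
                "tau2": self.thresholds[1],
                "tau3": self.thresholds[2],
            },
            "counts": asdict(self.counts),
            "n_nuclei": self.counts.total,
            "result": None
            if self.result is None
            else {
                "positive_pct": round(self.result.positive_pct, 2),
                "P": self.result.P,
                "I": self.result.I,
                "allred": self.result.total,
                "recommendation": self.result.recommendation,
            },
            "records": [
                {
                    "id": r.id,
                    "area_px": r.area,
                    "mu": round(r.mu, 4),
                    "class": r.class_label.value,
                }
                for r in self.records
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ImageReport":
        with open(path) as fh:
            d = json.load(fh)
        records = tuple(
            NucleusRecord(
                id=r["id"],
                area=r["area_px"],
                mu=r["mu"],
                class_label=StainClass(r["class"]),
            )
            for r in d["records"]
        )
        counts = CountTable(**d["counts"])
        result = None
        if d["result"] is not None:
            result = AllredResult(
                positive_pct=d["result"]["positive_pct"],
                P=d["result"]["P"],
                I=d["result"]["I"],
                total=d["result"]["allred"],
                recommendation=d["result"]["recommendation"],
            )
        thr = d["thresholds"]
        return cls(
            image_id=d["image_id"],
            records=records,
            counts=counts,
            result=result,
            thresholds=(thr["tau1"], thr["tau2"], thr["tau3"]),
            status=d["status"],
        )


def load_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB tile from PNG/TIFF."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return np.asarray(arr, dtype=np.uint8)


def _records_frame(records: tuple[NucleusRecord, ...]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "area_px": [r.area for r in records],
            "mu": [f"{r.mu:.4f}" for r in records],
            "class": [r.class_label.value for r in records],
        }
    )


def _resolve_mask(
    rgb: np.ndarray,
    mask_source: str | Path | InstanceMask | None,
    config: RunConfig,
    model: StainModel,
) -> InstanceMask:
    seg = config.segmentation
    if isinstance(mask_source, InstanceMask):
        mask = mask_source
    elif mask_source is not None:
        mask = load_instance_mask(mask_source)
    elif seg.source == "fallback":
        return fallback_segment(
            rgb, model, min_area=seg.min_area, min_seed_distance=seg.min_seed_distance
        )
    elif seg.source == "external":
        return run_external_segmenter(rgb, min_area=seg.min_area)
    else:
        raise ConfigError("segmentation.source is 'file' but no mask was given")
    return postprocess_instances(
        mask,
        min_area=seg.min_area,
        fill_holes=seg.fill_holes,
        merge_fragments=seg.merge_fragments,
    )


def score_image(
    rgb: str | Path | np.ndarray,
    mask_source: str | Path | InstanceMask | None = None,
    config: RunConfig | None = None,
    image_id: str | None = None,
    output_dir: str | Path | None = None,
) -> ImageReport:
    """Segment (or load), classify and Allred-score one tile.

    When ``output_dir`` is given, writes ``<id>_nuclei.csv``,
    ``<id>_overlay.png`` and ``<id>_report.json`` into it.  An image with
    zero nuclei after postprocessing yields a report with zero counts,
    ``result=None`` and status ``"undefined"`` (scoring an empty ROI has no
    clinical meaning).
    """
    if config is None:
        config = RunConfig()
    if isinstance(rgb, (str, Path)):
        image_id = image_id or Path(rgb).stem
        rgb = load_rgb(rgb)
    image_id = image_id or "image"
    model = config.stains.build()
    thresholds = config.thresholds.build()

    mask = _resolve_mask(rgb, mask_source, config, model)
    records, counts = classify_image(rgb, mask, model, thresholds)
    logger.info("%s: %d nuclei, counts=%s", image_id, counts.total, counts)

    if counts.total == 0:
        result = None
        status = "undefined"
        logger.warning("%s: no nuclei detected; Allred score undefined", image_id)
    else:
        result = allred(counts)
        status = "ok"

    report = ImageReport(
        image_id=image_id,
        records=tuple(records),
        counts=counts,
        result=result,
        thresholds=thresholds.as_tuple(),
        status=status,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _records_frame(report.records).to_csv(out / f"{image_id}_nuclei.csv", index=False)
        import imageio.v3 as iio

        iio.imwrite(out / f"{image_id}_overlay.png", render_class_overlay(mask, list(records)))
        report.to_json(out / f"{image_id}_report.json")
    return report


_SUMMARY_COLUMNS = [
    "image", "Total", "Strong", "Moderate", "Weak", "Negative",
    "positive_pct", "P", "I", "Allred", "recommendation", "status",
]


def _summary_row(image_id: str, report: ImageReport) -> dict:
    c = report.counts
    r = report.result
    return {
        "image": image_id,
        "Total": c.total,
        "Strong": c.strong,
        "Moderate": c.moderate,
        "Weak": c.weak,
        "Negative": c.negative,
        "positive_pct": "" if r is None else f"{r.positive_pct:.2f}",
        "P": "" if r is None else r.P,
        "I": "" if r is None else r.I,
        "Allred": "" if r is None else r.total,
        "recommendation": "" if r is None else r.recommendation,
        "status": report.status,
    }


def score_batch(
    manifest: str | Path | pd.DataFrame,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score every row of a manifest; failures are isolated per row.

    Two manifest layouts are accepted:

    * image manifest — columns ``image`` (path) and optionally ``mask``;
    * counts manifest — columns ``strong``, ``moderate``, ``weak``,
      ``negative`` (and optionally ``image`` for labels), routed directly
      through the scoring rules.

    Returns (and optionally writes as ``summary.csv``) one summary row per
    input row with the reference column layout.
    """
    if config is None:
        config = RunConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise FormatError("manifest is empty")

    rows: list[dict] = []
    if {"strong", "moderate", "weak", "negative"} <= set(manifest.columns):
        scored = score_counts_frame(manifest)
        for idx, r in scored.iterrows():
            c = CountTable(int(r.strong), int(r.moderate), int(r.weak), int(r.negative))
            rows.append(
                {
                    "image": r["image"] if "image" in scored.columns else f"row{idx + 1}",
                    "Total": c.total,
                    "Strong": c.strong,
                    "Moderate": c.moderate,
                    "Weak": c.weak,
                    "Negative": c.negative,
                    "positive_pct": f"{r.positive_pct:.2f}",
                    "P": r.P,
                    "I": r.I,
                    "Allred": r.allred,
                    "recommendation": r.recommendation,
                    "status": "ok",
                }
            )
    elif "image" in manifest.columns:
        for idx, r in manifest.iterrows():
            image_id = Path(str(r.image)).stem
            try:
                report = score_image(
                    str(r.image),
                    mask_source=str(r["mask"]) if "mask" in manifest.columns and pd.notna(r.get("mask")) else None,
                    config=config,
                    image_id=image_id,
                    output_dir=output_dir,
                )
                rows.append(_summary_row(image_id, report))
            except Exception as exc:  # isolate per-row failures
                logger.error("%s: %s", image_id, exc)
                rows.append(
                    {col: "" for col in _SUMMARY_COLUMNS}
                    | {"image": image_id, "status": f"error: {exc}"}
                )
    else:
        raise FormatError(
            "manifest must have an 'image' column or the four count columns "
            "strong/moderate/weak/negative"
        )

    summary = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
    return summary
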