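"""Reading and writing the pipeline's file formats.

COCO JSON annotation/detection files, the sample-metadata CSV (with the
deposited dataset's column names ``legume_fruit_pod_mass_g`` and
``processed_mixture_mass_g``), and flat CSV trait/result tables. Also the
bridge from per-image box records to per-sample object counts, including the
prediction post-processing (confidence floor, then per-class NMS) and the
SS/2 accounting rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .boxes import BoundingBox, ImageAnnotationSet, canonical_label
from .detection import filter_and_nms
from .traits import SeedObjectCounts

SAMPLE_TABLE_COLUMNS = (
    "sample_id",
    "variety",
    "processing_method",
    "nominal_mass_g",
    "legume_fruit_pod_mass_g",
    "processed_mixture_mass_g",
    "replicate",
)

PROCESSING_METHODS = ("belt_thresher", "impact_dehuller")


@dataclass(frozen=True)
class SampleRecord:
    """One processed pod sample in the factorial design."""

    sample_id: str
    variety: str
    processing_method: str
    nominal_mass_g: int
    pod_mass_g: float
    mixture_mass_g: float
    replicate: int

    def __post_init__(self) -> None:
        if self.processing_method not in PROCESSING_METHODS:
            raise ValueError(
                f"processing_method must be one of {PROCESSING_METHODS}, "
                f"got {self.processing_method!r}"
            )
        if not self.pod_mass_g > 0:
            raise ValueError(f"pod_mass_g must be > 0, got {self.pod_mass_g}")
        if not 0 <= self.mixture_mass_g <= self.pod_mass_g:
            raise ValueError(
                f"mixture_mass_g must lie in [0, pod_mass_g], got "
                f"{self.mixture_mass_g} with pod_mass_g={self.pod_mass_g}"
            )


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------

def read_coco(path: str | Path) -> list[ImageAnnotationSet]:
    """Read a COCO-format annotation or detection file.

    COCO ``[x, y, width, height]`` records are converted to corner form;
    detection files carry their per-box ``score``. Category names must map
    onto {IP, WS, SS} (full names or short labels, case-insensitive).
    Out-of-canvas boxes are clipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = json.load(fh)
    for section in ("images", "annotations", "categories"):
        if section not in doc:
            raise ValueError(f"{path}: COCO file missing {section!r} section")

    cat_map = {c["id"]: canonical_label(c["name"]) for c in doc["categories"]}
    images: dict[object, ImageAnnotationSet] = {}
    for im in doc["images"]:
        iid = im["id"]
        if iid in images:
            raise ValueError(f"{path}: duplicate image id {iid!r}")
        images[iid] = ImageAnnotationSet(
            image_id=str(iid),
            width=float(im["width"]),
            height=float(im["height"]),
            sample_id=im.get("sample_id"),
        )

    for idx, ann in enumerate(doc["annotations"]):
        try:
            label = cat_map[ann["category_id"]]
        except KeyError:
            raise ValueError(
                f"{path}: annotation {idx} has unknown category_id "
                f"{ann['category_id']!r}"
            ) from None
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(
                f"{path}: annotation {idx} has non-positive width/height {ann['bbox']}"
            )
        if ann["image_id"] not in images:
            raise ValueError(f"{path}: annotation {idx} references unknown image")
        box = BoundingBox.from_coco([x, y, w, h], label, ann.get("score"))
        images[ann["image_id"]].boxes.append(box)

    return [im.clipped() for im in images.values()]


def write_coco(images: list[ImageAnnotationSet], path: str | Path) -> None:
    """Write annotation sets as a COCO JSON file (scores included if present)."""
    categories = [
        {"id": 1, "name": "intact_pod"},
        {"id": 2, "name": "whole_seed"},
        {"id": 3, "name": "split_seed"},
    ]
    cat_ids = {"IP": 1, "WS": 2, "SS": 3}
    doc: dict = {"images": [], "annotations": [], "categories": categories}
    ann_id = 1
    for im in images:
        entry = {"id": im.image_id, "width": im.width, "height": im.height}
        if im.sample_id is not None:
            entry["sample_id"] = im.sample_id
        doc["images"].append(entry)
        for b in im.boxes:
            ann = {
                "id": ann_id,
                "image_id": im.image_id,
                "category_id": cat_ids[b.class_label],
                "bbox": b.to_coco(),
                "area": b.area,
                "iscrowd": 0,
            }
            if b.confidence is not None:
                ann["score"] = b.confidence
            doc["annotations"].append(ann)
            ann_id += 1
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Sample metadata CSV
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> tuple[list[SampleRecord], dict]:
    """Read the sample metadata CSV.

    Returns the records and a design-completeness report: which
    variety x method x mass cells are present and with how many replicates.
    ``report["status"]`` is "empty", "complete" (every cell has the modal
    replicate count) or "incomplete".
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records: list[SampleRecord] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        for col in ("legume_fruit_pod_mass_g", "processed_mixture_mass_g"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {i}: non-numeric value {row[col]!r} in column {col!r}"
                ) from None
        key = (row["variety"], row["processing_method"], int(row["nominal_mass_g"]),
               int(row["replicate"]))
        if key in seen:
            raise ValueError(f"{path}: row {i}: duplicate design key {key}")
        seen.add(key)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                variety=str(row["variety"]),
                processing_method=str(row["processing_method"]),
                nominal_mass_g=int(row["nominal_mass_g"]),
                pod_mass_g=float(row["legume_fruit_pod_mass_g"]),
                mixture_mass_g=float(row["processed_mixture_mass_g"]),
                replicate=int(row["replicate"]),
            )
        )

    if not records:
        return records, {"status": "empty", "cells": {}}
    cells: dict[tuple, int] = {}
    for r in records:
        cell = (r.variety, r.processing_method, r.nominal_mass_g)
        cells[cell] = cells.get(cell, 0) + 1
    counts = set(cells.values())
    n_expected = (
        len({r.variety for r in records})
        * len({r.processing_method for r in records})
        * len({r.nominal_mass_g for r in records})
    )
    status = "complete" if len(counts) == 1 and len(cells) == n_expected else "incomplete"
    return records, {"status": status, "cells": cells}


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "variety": [r.variety for r in records],
            "processing_method": [r.processing_method for r in records],
            "nominal_mass_g": [r.nominal_mass_g for r in records],
            "legume_fruit_pod_mass_g": [r.pod_mass_g for r in records],
            "processed_mixture_mass_g": [r.mixture_mass_g for r in records],
            "replicate": [r.replicate for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Boxes -> counts
# ---------------------------------------------------------------------------

def counts_from_image(
    annotations: ImageAnnotationSet,
    is_prediction: bool = False,
    confidence_floor: float = 0.1,
    nms_iou: float = 0.5,
) -> SeedObjectCounts:
    """Count seed objects in one image.

    Predictions are first post-processed: boxes scoring below
    ``confidence_floor`` are dropped, then greedy per-class NMS at
    ``nms_iou`` removes duplicate detections. Raw per-class counts are
    recorded and the split-seed count enters the effective total as
    ``n_SS_raw / 2`` (each SS detection is assumed to be one of two halves
    of a single seed); the halved value stays fractional.
    """
    boxes = annotations.boxes
    if is_prediction:
        lacking = [i for i, b in enumerate(boxes) if b.confidence is None]
        if lacking:
            raise ValueError(
                f"image {annotations.image_id}: is_prediction=True but box(es) "
                f"{lacking} lack a confidence score"
            )
        boxes = filter_and_nms(boxes, confidence_floor, nms_iou)
    n = {"IP": 0, "WS": 0, "SS": 0}
    for b in boxes:
        n[b.class_label] += 1
    return SeedObjectCounts(n_ip=n["IP"], n_ws=n["WS"], n_ss_raw=n["SS"])
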