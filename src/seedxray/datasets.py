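"""On-disk layouts: image I/O, the crop store and the dataset manifest.

A *dataset* directory holds annotated radiographs::

    dataset/
      classes.txt            ordered class catalog
      manifest.csv           one row per image (relative paths, box counts)
      images/<id>.png        8-bit grayscale radiographs
      annotations/voc/<id>.xml
      annotations/yolo/<id>.txt

A *crop store* directory holds extracted (possibly augmented) seeds::

    crops/
      crops.csv              crop_id, label, provenance, history
      patches/<crop_id>.png
      masks/<crop_id>.png    0/255 binary masks
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annot_io import (AnnotatedRadiograph, Box, ClassCatalog, read_voc,
                       write_voc, write_yolo)
from .decompose import SeedCrop
from .errors import ConfigurationError

__all__ = [
    "read_image",
    "write_image",
    "save_crop_store",
    "load_crop_store",
    "save_dataset",
    "load_dataset",
    "dataset_class_counts",
]


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as a 2D uint8 array (converted to 8-bit gray)."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2D uint8 array as 8-bit grayscale PNG/TIFF (by extension)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ConfigurationError(f"expected uint8 image, got {arr.dtype}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(str(path))


# ---------------------------------------------------------------------------
# crop store
# ---------------------------------------------------------------------------

def save_crop_store(crops: list[SeedCrop], directory: str | os.PathLike) -> Path:
    """Persist crops as PNG patch/mask pairs plus a metadata table."""
    directory = Path(directory)
    (directory / "patches").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, crop in enumerate(crops):
        crop_id = f"crop_{i:06d}"
        write_image(crop.patch, directory / "patches" / f"{crop_id}.png")
        write_image(crop.mask.astype(np.uint8) * 255,
                    directory / "masks" / f"{crop_id}.png")
        box = crop.source_box
        rows.append({
            "crop_id": crop_id,
            "label": crop.label,
            "source_id": crop.source_id,
            "box_x_min": box.x_min if box else -1,
            "box_y_min": box.y_min if box else -1,
            "box_x_max": box.x_max if box else -1,
            "box_y_max": box.y_max if box else -1,
            "history": json.dumps(crop.history),
        })
    pd.DataFrame(rows).to_csv(directory / "crops.csv", index=False)
    return directory


def load_crop_store(directory: str | os.PathLike) -> list[SeedCrop]:
    directory = Path(directory)
    table = pd.read_csv(directory / "crops.csv")
    crops: list[SeedCrop] = []
    for row in table.itertuples(index=False):
        patch = read_image(directory / "patches" / f"{row.crop_id}.png")
        mask = read_image(directory / "masks" / f"{row.crop_id}.png") > 127
        box = None
        if row.box_x_min >= 0:
            box = Box(int(row.box_x_min), int(row.box_y_min),
                      int(row.box_x_max), int(row.box_y_max), str(row.label))
        crops.append(SeedCrop(
            patch=patch, mask=mask, label=str(row.label),
            source_id=str(row.source_id), source_box=box,
            history=json.loads(row.history),
        ))
    return crops


# ---------------------------------------------------------------------------
# dataset directory
# ---------------------------------------------------------------------------

def save_dataset(records: list[AnnotatedRadiograph], catalog: ClassCatalog,
                 directory: str | os.PathLike) -> pd.DataFrame:
    """Write images + VOC + YOLO + classes + manifest for a list of records."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "annotations" / "voc").mkdir(parents=True, exist_ok=True)
    (directory / "annotations" / "yolo").mkdir(parents=True, exist_ok=True)
    catalog.write(directory / "classes.txt")

    rows = []
    for rec in records:
        if rec.image is None:
            raise ConfigurationError(f"record {rec.source_id!r} has no pixels")
        img_rel = f"images/{rec.source_id}.png"
        voc_rel = f"annotations/voc/{rec.source_id}.xml"
        yolo_rel = f"annotations/yolo/{rec.source_id}.txt"
        write_image(rec.image, directory / img_rel)
        write_voc(rec, directory / voc_rel, filename=f"{rec.source_id}.png")
        write_yolo(rec, catalog, directory / yolo_rel)
        row = {
            "image_id": rec.source_id,
            "image_path": img_rel,
            "voc_path": voc_rel,
            "yolo_path": yolo_rel,
            "width": rec.width,
            "height": rec.height,
            "n_boxes": len(rec.boxes),
        }
        for name in catalog:
            row[f"n_{name}"] = sum(1 for b in rec.boxes if b.label == name)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_dataset(directory: str | os.PathLike,
                 with_images: bool = True
                 ) -> tuple[list[AnnotatedRadiograph], ClassCatalog, pd.DataFrame]:
    """Load a dataset directory back into records (+ catalog + manifest)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    catalog = ClassCatalog.read(directory / "classes.txt")
    records = []
    for row in manifest.itertuples(index=False):
        rec = read_voc(directory / row.voc_path)
        rec.source_id = str(row.image_id)
        if with_images:
            rec.image = read_image(directory / row.image_path)
        records.append(rec)
    return records, catalog, manifest


def dataset_class_counts(manifest: pd.DataFrame) -> dict[str, int]:
    """Total per-class box counts from a manifest's ``n_<class>`` columns."""
    return {
        col[2:]: int(manifest[col].sum())
        for col in manifest.columns
        if col.startswith("n_") and col != "n_boxes"
    }
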