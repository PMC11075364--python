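"""Detection-annotation I/O: PASCAL VOC XML and YOLO text dialects.

Internal boxes are 0-based and half-open, ``[x_min, x_max) x [y_min, y_max)``,
so ``width = x_max - x_min`` with no +1 bookkeeping.  On disk, VOC XML uses the
common 1-based *inclusive* dialect (``xmin = x_min + 1``, ``xmax = x_max``) and
YOLO lines carry a 0-based class index plus center/size normalized to [0, 1].

Class indices for YOLO always come from an explicit ordered
:class:`ClassCatalog`, persisted as a ``classes.txt`` file next to the
annotations, never from label sort order.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from lxml import etree

from .errors import AnnotationError, BoxValidationError, CatalogError

__all__ = [
    "Box",
    "AnnotatedRadiograph",
    "ClassCatalog",
    "read_voc",
    "write_voc",
    "box_to_yolo",
    "read_yolo",
    "write_yolo",
]


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned bounding box, 0-based half-open, with a class label."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    label: str

    def __post_init__(self) -> None:
        for name in ("x_min", "y_min", "x_max", "y_max"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise BoxValidationError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.x_min < 0 or self.y_min < 0:
            raise BoxValidationError(f"negative origin in {self.as_tuple()}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise BoxValidationError(
                f"degenerate box {self.as_tuple()}: width/height must be >= 1"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    def within(self, width: int, height: int) -> bool:
        return self.x_max <= width and self.y_max <= height


@dataclass
class AnnotatedRadiograph:
    """One grayscale radiograph (or a reference to it) plus its boxes.

    ``image`` may be ``None`` when only annotations were loaded; ``width`` and
    ``height`` always describe the declared image size.  ``acquisition`` is
    free-form metadata (tube voltage kV, exposure s, magnification,
    resolution) carried along but never interpreted.
    """

    width: int
    height: int
    boxes: list[Box]
    source_id: str
    image: np.ndarray | None = None
    acquisition: dict | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise BoxValidationError(
                f"image size must be positive, got {self.width}x{self.height}"
            )
        if self.image is not None:
            if self.image.ndim != 2:
                raise BoxValidationError("image must be a 2D grayscale array")
            h, w = self.image.shape
            if (w, h) != (self.width, self.height):
                raise BoxValidationError(
                    f"declared size {self.width}x{self.height} != array {w}x{h}"
                )
        for i, b in enumerate(self.boxes):
            if not b.within(self.width, self.height):
                raise BoxValidationError(
                    f"object {i} box {b.as_tuple()} outside image "
                    f"{self.width}x{self.height}"
                )


class ClassCatalog:
    """Ordered, immutable class-name list with a name<->index map."""

    def __init__(self, names: Sequence[str]):
        names = list(names)
        if len(set(names)) != len(names):
            raise CatalogError(f"duplicate class names in {names}")
        if not names:
            raise CatalogError("class catalog must not be empty")
        self._names = tuple(names)
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self):
        return iter(self._names)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClassCatalog) and other._names == self._names

    def __repr__(self) -> str:
        return f"ClassCatalog({list(self._names)!r})"

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise CatalogError(
                f"label {label!r} not in catalog {list(self._names)}"
            ) from None

    def label(self, index: int) -> str:
        if not 0 <= index < len(self._names):
            raise CatalogError(
                f"class index {index} outside catalog of size {len(self._names)}"
            )
        return self._names[index]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ClassCatalog":
        return cls(list(counts))

    def write(self, path: str | os.PathLike) -> None:
        Path(path).write_text("\n".join(self._names) + "\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "ClassCatalog":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls([ln for ln in lines if ln])


# ---------------------------------------------------------------------------
# PASCAL VOC XML
# ---------------------------------------------------------------------------

def read_voc(source: str | os.PathLike | bytes) -> AnnotatedRadiograph:
    """Parse a PASCAL VOC XML document into an :class:`AnnotatedRadiograph`.

    Only the annotations are loaded; the pixel data referenced by
    ``<filename>`` must be read separately.  On-disk 1-based inclusive
    coordinates are converted to the internal 0-based half-open convention.
    """
    name = "<bytes>"
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            name = str(source)
            root = etree.parse(str(source)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise AnnotationError(f"cannot parse VOC XML {name}: {exc}") from exc

    size = root.find("size")
    if size is None:
        raise AnnotationError(f"VOC XML {name} has no <size> element")
    try:
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"VOC XML {name} has a malformed <size>") from exc

    boxes: list[Box] = []
    for i, obj in enumerate(root.iter("object")):
        label = obj.findtext("name")
        bnd = obj.find("bndbox")
        if label is None or bnd is None:
            raise AnnotationError(f"object {i} in {name} lacks <name>/<bndbox>")
        try:
            xmin = int(round(float(bnd.findtext("xmin"))))
            ymin = int(round(float(bnd.findtext("ymin"))))
            xmax = int(round(float(bnd.findtext("xmax"))))
            ymax = int(round(float(bnd.findtext("ymax"))))
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"object {i} in {name}: bad coordinates") from exc
        try:
            box = Box(xmin - 1, ymin - 1, xmax, ymax, label)
        except BoxValidationError as exc:
            raise BoxValidationError(f"object {i} in {name}: {exc}") from exc
        if not box.within(width, height):
            raise BoxValidationError(
                f"object {i} in {name}: box {box.as_tuple()} outside "
                f"declared size {width}x{height}"
            )
        boxes.append(box)

    filename = root.findtext("filename") or ""
    source_id = Path(filename).stem if filename else Path(name).stem
    return AnnotatedRadiograph(
        width=width, height=height, boxes=boxes, source_id=source_id
    )


def write_voc(record: AnnotatedRadiograph, path: str | os.PathLike | None = None,
              filename: str | None = None) -> bytes:
    """Serialize a record to VOC XML (1-based inclusive boxes, list order).

    Returns the XML bytes; additionally writes them to ``path`` if given.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = (
        filename if filename is not None else f"{record.source_id}.png"
    )
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(record.width)
    etree.SubElement(size, "height").text = str(record.height)
    etree.SubElement(size, "depth").text = "1"
    for box in record.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = box.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(box.x_min + 1)
        etree.SubElement(bnd, "ymin").text = str(box.y_min + 1)
        etree.SubElement(bnd, "xmax").text = str(box.x_max)
        etree.SubElement(bnd, "ymax").text = str(box.y_max)
    data = etree.tostring(root, pretty_print=True, encoding="utf-8")
    if path is not None:
        Path(path).write_bytes(data)
    return data


# ---------------------------------------------------------------------------
# YOLO text
# ---------------------------------------------------------------------------

def box_to_yolo(box: Box, image_w: int, image_h: int, catalog: ClassCatalog) -> str:
    """Render one box as a YOLO line: ``idx cx cy w h`` (6 decimal places)."""
    if not box.within(image_w, image_h):
        raise BoxValidationError(
            f"box {box.as_tuple()} outside image {image_w}x{image_h}"
        )
    idx = catalog.index(box.label)
    cx = (box.x_min + box.x_max) / (2.0 * image_w)
    cy = (box.y_min + box.y_max) / (2.0 * image_h)
    w = box.width / image_w
    h = box.height / image_h
    return f"{idx} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def read_yolo(source: str | os.PathLike | Iterable[str], image_w: int,
              image_h: int, catalog: ClassCatalog) -> list[Box]:
    """Parse YOLO lines back to boxes (nearest-pixel, clamped to bounds)."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        lines = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)

    boxes: list[Box] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationError(
                f"YOLO line {lineno}: expected 5 fields, got {len(parts)}: {raw!r}"
            )
        try:
            idx = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise AnnotationError(f"YOLO line {lineno}: non-numeric field") from exc
        label = catalog.label(idx)
        x_min = max(0, _round_half_up(cx * image_w - w * image_w / 2.0))
        x_max = min(image_w, _round_half_up(cx * image_w + w * image_w / 2.0))
        y_min = max(0, _round_half_up(cy * image_h - h * image_h / 2.0))
        y_max = min(image_h, _round_half_up(cy * image_h + h * image_h / 2.0))
        try:
            boxes.append(Box(x_min, y_min, x_max, y_max, label))
        except BoxValidationError as exc:
            raise BoxValidationError(f"YOLO line {lineno}: {exc}") from exc
    return boxes


def write_yolo(record: AnnotatedRadiograph, catalog: ClassCatalog,
               path: str | os.PathLike | None = None) -> str:
    """Serialize all boxes of a record to YOLO text (one line per box)."""
    buf = io.StringIO()
    for box in record.boxes:
        buf.write(box_to_yolo(box, record.width, record.height, catalog))
        buf.write("\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
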