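"""Radiograph reassembly: paste seed crops on a black plane, grid layout.

Synthetic radiographs are composed by overlaying a matrix of extracted (and
possibly augmented) seeds on an all-zero canvas.  Placement is a regular
grid with a fixed cell size and margin — crops centered in disjoint cells
can never overlap, so emitted boxes are pairwise disjoint by construction.
Compositing copies only mask-foreground pixels; crop background never
overwrites the plane.  Each emitted annotation box is the pasted mask's
tight bounding box.

The default canvas is 2368x2340 px, the native detector resolution of the
acquisitions this emulates; tests and examples use much smaller canvases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annot_io import AnnotatedRadiograph, Box, ClassCatalog
from .datasets import save_dataset
from .decompose import SeedCrop
from .errors import ConfigurationError, LayoutOverflowError
from .rng import derive_rng

__all__ = [
    "DEFAULT_CANVAS",
    "LayoutPlan",
    "plan_layout",
    "assemble_radiograph",
    "assemble_dataset",
]

DEFAULT_CANVAS = (2368, 2340)


@dataclass(frozen=True)
class LayoutPlan:
    """A grid of disjoint cells plus the page count for ``n_items`` crops."""

    canvas_size: tuple[int, int]   # (width, height)
    cell_size: tuple[int, int]     # (width, height)
    margin: int
    rows: int
    cols: int
    positions: tuple[tuple[int, int], ...]  # top-left (x, y), row-major
    n_items: int
    pages: int

    @property
    def capacity(self) -> int:
        return self.rows * self.cols


def plan_layout(n_items: int, canvas_size: tuple[int, int] = DEFAULT_CANVAS,
                cell_size: tuple[int, int] = (220, 220),
                margin: int = 10) -> LayoutPlan:
    """Compute the grid: ``cols = floor((W - margin) / (cell_w + margin))``,
    rows likewise, row-major filling, ``pages = ceil(n / capacity)``."""
    if n_items < 0:
        raise ConfigurationError(f"n_items must be >= 0, got {n_items}")
    if margin < 0:
        raise ConfigurationError(f"margin must be >= 0, got {margin}")
    cw, ch = cell_size
    w, h = canvas_size
    cols = (w - margin) // (cw + margin)
    rows = (h - margin) // (ch + margin)
    if cols < 1 or rows < 1:
        raise ConfigurationError(
            f"cell {cw}x{ch} + margin {margin} does not fit canvas {w}x{h}"
        )
    positions = tuple(
        (margin + c * (cw + margin), margin + r * (ch + margin))
        for r in range(rows) for c in range(cols)
    )
    pages = math.ceil(n_items / (rows * cols)) if n_items else 0
    return LayoutPlan(
        canvas_size=(w, h), cell_size=(cw, ch), margin=int(margin),
        rows=rows, cols=cols, positions=positions,
        n_items=int(n_items), pages=pages,
    )


def assemble_radiograph(crops: list[SeedCrop], plan: LayoutPlan,
                        source_id: str = "assembled") -> AnnotatedRadiograph:
    """Compose one page: paste each crop centered in its grid cell.

    ``crops`` must not exceed the plan capacity.  Raises
    :class:`LayoutOverflowError` naming any crop larger than the cell.
    """
    if len(crops) > plan.capacity:
        raise LayoutOverflowError(
            f"{len(crops)} crops exceed page capacity {plan.capacity}"
        )
    w, h = plan.canvas_size
    cw, ch = plan.cell_size
    canvas = np.zeros((h, w), dtype=np.uint8)
    boxes: list[Box] = []
    for i, crop in enumerate(crops):
        ph, pw = crop.patch.shape
        if pw > cw or ph > ch:
            raise LayoutOverflowError(
                f"crop {i} ({crop.source_id!r}, {pw}x{ph}) exceeds cell "
                f"{cw}x{ch}"
            )
        cell_x, cell_y = plan.positions[i]
        x0 = cell_x + (cw - pw) // 2
        y0 = cell_y + (ch - ph) // 2
        region = canvas[y0:y0 + ph, x0:x0 + pw]
        region[crop.mask] = crop.patch[crop.mask]
        ys, xs = np.nonzero(crop.mask)
        boxes.append(Box(
            x_min=x0 + int(xs.min()), y_min=y0 + int(ys.min()),
            x_max=x0 + int(xs.max()) + 1, y_max=y0 + int(ys.max()) + 1,
            label=crop.label,
        ))
    return AnnotatedRadiograph(
        width=w, height=h, boxes=boxes, source_id=source_id, image=canvas,
    )


def assemble_dataset(crops: list[SeedCrop], plan: LayoutPlan,
                     output_dir: str | Path, catalog: ClassCatalog,
                     rng_seed: int, prefix: str = "synthetic"
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle crops (seeded), partition into pages, write every page.

    Returns ``(manifest, placements)`` where placements maps every crop to
    its page, emitted box and label — the ground-truth table for the
    composed dataset.  Total seeds are conserved: the manifest's box count
    equals ``len(crops)``.
    """
    rng = derive_rng(rng_seed, "assemble")
    order = rng.permutation(len(crops))
    shuffled = [crops[i] for i in order]

    cap = plan.capacity
    records = []
    placement_rows = []
    for page in range(math.ceil(len(shuffled) / cap) if shuffled else 0):
        page_crops = shuffled[page * cap:(page + 1) * cap]
        rec = assemble_radiograph(page_crops, plan,
                                  source_id=f"{prefix}_{page:04d}")
        records.append(rec)
        for crop, box in zip(page_crops, rec.boxes):
            placement_rows.append({
                "image_id": rec.source_id,
                "label": crop.label,
                "x_min": box.x_min, "y_min": box.y_min,
                "x_max": box.x_max, "y_max": box.y_max,
                "source_id": crop.source_id,
            })
    manifest = save_dataset(records, catalog, output_dir)
    placements = pd.DataFrame(
        placement_rows,
        columns=["image_id", "label", "x_min", "y_min", "x_max", "y_max",
                 "source_id"],
    )
    placements.to_csv(Path(output_dir) / "placements.csv", index=False)
    return manifest, placements
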