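"""Radiograph decomposition: per-box seed extraction and segmentation.

Seeds are bright objects on a near-black background (the sample holder has
very weak X-ray attenuation), so a per-crop global Otsu threshold separates
seed from background.  The committed segmentation operator is:

    Otsu threshold -> keep largest 8-connected component -> fill holes.

Hole filling matters because empty seeds are shells: their dark interior
still belongs to the seed for detection purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .annot_io import AnnotatedRadiograph, Box
from .errors import EmptyMaskError

__all__ = ["SeedCrop", "segment_crop", "extract_seeds"]


@dataclass
class SeedCrop:
    """An extracted seed patch with its binary mask and provenance.

    ``history`` accumulates a human-readable entry per transform applied
    since extraction, so every augmented copy can be traced back to its
    source radiograph and box.
    """

    patch: np.ndarray          # 2D uint8
    mask: np.ndarray           # 2D bool, same shape
    label: str
    source_id: str
    source_box: Box | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patch.ndim != 2:
            raise EmptyMaskError("patch must be 2D")
        if self.patch.shape != self.mask.shape:
            raise EmptyMaskError(
                f"patch {self.patch.shape} and mask {self.mask.shape} differ"
            )
        if not self.mask.any():
            raise EmptyMaskError(f"crop from {self.source_id!r} has empty mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape

    @property
    def foreground_area(self) -> int:
        return int(self.mask.sum())

    def is_connected(self) -> bool:
        """True when the mask foreground is one 8-connected component."""
        return cc_label(self.mask, connectivity=2).max() == 1

    def copy(self) -> "SeedCrop":
        return SeedCrop(
            patch=self.patch.copy(),
            mask=self.mask.copy(),
            label=self.label,
            source_id=self.source_id,
            source_box=self.source_box,
            history=list(self.history),
        )


def segment_crop(patch: np.ndarray) -> np.ndarray:
    """Segment the seed inside one crop; returns a boolean mask.

    Raises :class:`EmptyMaskError` for an all-uniform patch, where no
    threshold can separate seed from background.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise EmptyMaskError("empty patch")
    if patch.max() == patch.min():
        raise EmptyMaskError("uniform patch: no foreground separable")
    thr = threshold_otsu(patch)
    fg = patch > thr
    if not fg.any():
        raise EmptyMaskError("no pixel above the Otsu threshold")
    labels = cc_label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(mask)


def extract_seeds(record: AnnotatedRadiograph,
                  on_empty: str = "raise") -> list[SeedCrop]:
    """Decompose a radiograph into one :class:`SeedCrop` per annotated box.

    The patch is the image restricted to the box (no padding); the mask comes
    from :func:`segment_crop`.  ``on_empty`` controls what happens when a box
    segments to nothing: ``"raise"`` (default) or ``"skip"``.
    """
    if record.image is None:
        raise EmptyMaskError(
            f"record {record.source_id!r} carries no pixel data to decompose"
        )
    if on_empty not in ("raise", "skip"):
        raise ValueError(f"on_empty must be 'raise' or 'skip', got {on_empty!r}")

    crops: list[SeedCrop] = []
    for i, box in enumerate(record.boxes):
        patch = record.image[box.y_min:box.y_max, box.x_min:box.x_max]
        try:
            mask = segment_crop(patch)
        except EmptyMaskError as exc:
            if on_empty == "skip":
                continue
            raise EmptyMaskError(
                f"box {i} {box.as_tuple()} of {record.source_id!r}: {exc}"
            ) from exc
        crops.append(
            SeedCrop(
                patch=patch.copy(),
                mask=mask,
                label=box.label,
                source_id=record.source_id,
                source_box=box,
                history=[f"extract(source={record.source_id}, box={box.as_tuple()})"],
            )
        )
    return crops
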