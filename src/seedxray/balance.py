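"""Class balancing and batch geometric augmentation of seed crops.

Balancing is interleaved undersample-then-replicate: every class is first
undersampled (uniformly, without replacement) down to the minority-class
count, then every retained seed is replicated ``replication_factor - 1``
times with randomly sampled geometric transforms, keeping the original.
With the default ``replication_factor = 2`` each class ends at exactly
``2 x minority`` seeds: e.g. sugar beet counts {M: 1046, N: 5852, E: 1164}
balance to 2092 per class, and faba bean {D: 2908, UD: 1793} to 3586.

Geometric augmentation composes, in this fixed order: flips, shear,
rotation about the patch center, isotropic scaling.  Default parameter
ranges: rotation 0-180 deg, scale 0.5-4, shear 0-0.2, both flips allowed.
Patches are warped with bilinear interpolation, masks with nearest-neighbor
(re-binarized at 0.5), and the output canvas is enlarged so no foreground
pixel is clipped before re-cropping to the transformed mask's tight box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import AffineTransform, warp

from .decompose import SeedCrop
from .errors import ConfigurationError, EmptyMaskError, ParameterError, SizeError
from .rng import derive_rng

__all__ = [
    "Interval",
    "AugmentationSpec",
    "GeometricParams",
    "BalancePlan",
    "compute_balance_plan",
    "undersample",
    "sample_geometric_params",
    "apply_geometric",
    "execute_balance_plan",
]


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ParameterError(f"interval lower {self.lo} > upper {self.hi}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.lo == self.hi:
            return self.lo
        return float(rng.uniform(self.lo, self.hi))

    @property
    def is_degenerate(self) -> bool:
        return self.lo == self.hi


def _as_interval(v) -> Interval:
    if isinstance(v, Interval):
        return v
    lo, hi = v
    return Interval(float(lo), float(hi))


@dataclass(frozen=True)
class AugmentationSpec:
    """Augmentation parameter ranges; defaults are the standard batch ranges
    (rotation 0-180 deg, scaling 0.5-4, shearing 0-0.2, both flips,
    contrast 0.8-1.25, brightness 0-1)."""

    rotation_deg: Interval = Interval(0.0, 180.0)
    scale: Interval = Interval(0.5, 4.0)
    shear: Interval = Interval(0.0, 0.2)
    hflip: bool = True
    vflip: bool = True
    contrast: Interval = Interval(0.8, 1.25)
    brightness: Interval = Interval(0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "scale", "shear", "contrast", "brightness"):
            object.__setattr__(self, name, _as_interval(getattr(self, name)))
        if self.scale.lo <= 0:
            raise ParameterError("scale interval must be strictly positive")

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        return cls(rotation_deg=Interval(0, 0), scale=Interval(1, 1),
                   shear=Interval(0, 0), hflip=False, vflip=False,
                   contrast=Interval(1, 1), brightness=Interval(0, 0))


@dataclass(frozen=True)
class GeometricParams:
    rotation_deg: float = 0.0
    scale: float = 1.0
    shear: float = 0.0
    hflip: bool = False
    vflip: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"scale must be positive, got {self.scale}")

    @property
    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0 and self.scale == 1.0
                and self.shear == 0.0 and not self.hflip and not self.vflip)


@dataclass(frozen=True)
class BalancePlan:
    """Per-class targets: undersample to the minority count, then replicate."""

    class_counts_in: dict[str, int]
    minority_count: int
    replication_factor: int
    target_per_class: int

    def shares_in_pct(self) -> dict[str, float]:
        """Original class shares, in percent rounded to one decimal."""
        total = sum(self.class_counts_in.values())
        return {k: round(100.0 * v / total, 1)
                for k, v in self.class_counts_in.items()}

    def shares_out_pct(self) -> dict[str, float]:
        """Post-balance class shares (equal by construction), one decimal."""
        k = len(self.class_counts_in)
        return {name: round(100.0 / k, 1) for name in self.class_counts_in}

    @property
    def total_out(self) -> int:
        return self.target_per_class * len(self.class_counts_in)


def compute_balance_plan(class_counts: dict[str, int],
                         replication_factor: int = 2) -> BalancePlan:
    """Derive per-class targets from the minority count.

    ``target_per_class = min(counts) * replication_factor``.
    """
    if not class_counts:
        raise ConfigurationError("class count map is empty")
    for name, count in class_counts.items():
        if count < 1:
            raise ConfigurationError(f"class {name!r} has count {count} < 1")
    if replication_factor < 1:
        raise ConfigurationError(
            f"replication_factor must be >= 1, got {replication_factor}"
        )
    minority = min(class_counts.values())
    return BalancePlan(
        class_counts_in=dict(class_counts),
        minority_count=minority,
        replication_factor=int(replication_factor),
        target_per_class=minority * int(replication_factor),
    )


def undersample(items: list, target_count: int,
                rng_seed: int | np.random.Generator) -> list:
    """Uniform sample without replacement; deterministic for a fixed seed."""
    if target_count > len(items):
        raise SizeError(
            f"target {target_count} exceeds population {len(items)}"
        )
    rng = derive_rng(rng_seed)
    idx = rng.choice(len(items), size=target_count, replace=False)
    return [items[i] for i in idx]


def sample_geometric_params(spec: AugmentationSpec,
                            rng_seed: int | np.random.Generator
                            ) -> GeometricParams:
    """Draw one parameter set: continuous fields uniform on their interval,
    flips Bernoulli(1/2) when allowed."""
    rng = derive_rng(rng_seed)
    return GeometricParams(
        rotation_deg=spec.rotation_deg.sample(rng),
        scale=spec.scale.sample(rng),
        shear=spec.shear.sample(rng),
        hflip=bool(rng.integers(2)) if spec.hflip else False,
        vflip=bool(rng.integers(2)) if spec.vflip else False,
    )


def _geometry_matrix(params: GeometricParams) -> np.ndarray:
    """2x2 linear part, composition order: flip -> shear -> rotate -> scale."""
    f = np.diag([-1.0 if params.hflip else 1.0,
                 -1.0 if params.vflip else 1.0])
    sh = np.array([[1.0, params.shear], [0.0, 1.0]])
    t = math.radians(params.rotation_deg)
    r = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    s = params.scale * np.eye(2)
    return s @ r @ sh @ f


def apply_geometric(crop: SeedCrop, params: GeometricParams) -> SeedCrop:
    """Apply one geometric transform to patch and mask identically.

    The output canvas is sized from the transformed pixel-center extent of
    the input, so nothing is clipped; the result is then re-cropped to the
    transformed mask's tight bounding box.  Identity parameters return an
    exact copy.  The transform is appended to the crop's history.
    """
    entry = (f"geom(rot={params.rotation_deg:.3f},scale={params.scale:.4f},"
             f"shear={params.shear:.4f},hflip={params.hflip},"
             f"vflip={params.vflip})")
    if params.is_identity:
        out = crop.copy()
        out.history.append(entry)
        return out

    h, w = crop.patch.shape
    a = _geometry_matrix(params)
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    # transformed extent of the pixel-center corners (x, y)
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    tc = (a @ (corners - center).T).T
    mn = tc.min(axis=0)
    mx = tc.max(axis=0)
    out_w = int(np.ceil(mx[0] - mn[0])) + 1
    out_h = int(np.ceil(mx[1] - mn[1])) + 1

    # forward map: q = A (p - center) - mn ; warp needs the inverse map
    a_inv = np.linalg.inv(a)
    hinv = np.eye(3)
    hinv[:2, :2] = a_inv
    hinv[:2, 2] = a_inv @ mn + center
    tform = AffineTransform(matrix=hinv)

    patch_t = warp(crop.patch.astype(float), tform,
                   output_shape=(out_h, out_w), order=1, cval=0.0,
                   preserve_range=True)
    mask_t = warp(crop.mask.astype(float), tform,
                  output_shape=(out_h, out_w), order=0, cval=0.0,
                  preserve_range=True) > 0.5
    if not mask_t.any():
        raise EmptyMaskError("transformed mask is empty (internal error)")
    # nearest-neighbor warping can in rare cases pinch off slivers; the mask
    # invariant requires one component, so keep the largest
    labels = cc_label(mask_t, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask_t = labels == int(np.argmax(counts))

    ys, xs = np.nonzero(mask_t)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return SeedCrop(
        patch=np.clip(np.round(patch_t[y0:y1, x0:x1]), 0, 255).astype(np.uint8),
        mask=mask_t[y0:y1, x0:x1],
        label=crop.label,
        source_id=crop.source_id,
        source_box=crop.source_box,
        history=list(crop.history) + [entry],
    )


def execute_balance_plan(crops: list[SeedCrop], plan: BalancePlan,
                         spec: AugmentationSpec,
                         rng_seed: int) -> list[SeedCrop]:
    """Undersample each class to the minority count, then add augmented
    replicates so every class reaches ``target_per_class``.

    Each retained original appears exactly once unmodified plus
    ``replication_factor - 1`` augmented copies.  Fully deterministic for a
    fixed seed.
    """
    by_class: dict[str, list[SeedCrop]] = {}
    for crop in crops:
        by_class.setdefault(crop.label, []).append(crop)
    if set(by_class) != set(plan.class_counts_in):
        raise ConfigurationError(
            f"crop labels {sorted(by_class)} do not match plan classes "
            f"{sorted(plan.class_counts_in)}"
        )

    out: list[SeedCrop] = []
    for ci, name in enumerate(sorted(by_class)):
        kept = undersample(by_class[name], plan.minority_count,
                           derive_rng(rng_seed, "undersample", ci))
        out.extend(kept)
        for rep in range(plan.replication_factor - 1):
            for j, crop in enumerate(kept):
                params = sample_geometric_params(
                    spec, derive_rng(rng_seed, "augment", ci, rep, j))
                out.append(apply_geometric(crop, params))
    return out
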