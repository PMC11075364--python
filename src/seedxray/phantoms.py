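"""Parametric phantom seeds: synthetic radiographs with exact ground truth.

No annotated seed radiographs are publicly deposited, so every pipeline
stage is exercised on geometric phantoms that mimic the two species styles:

* sugar beet — internal-morphology classes: full monogerm ``N`` (one bright
  germ inside the body), multigerm ``M`` (2-3 germs), empty ``E`` (a bright
  shell around a dark cavity);
* faba bean — physical-quality classes: undamaged ``UD`` (solid bright
  body) and damaged ``D`` (body with a dark insect tunnel biting the
  boundary).

Phantoms are bright ellipses on a zero background with jittered size,
eccentricity and orientation.  Default intensity levels: background 0,
shell 120-180, germ 200-240, tunnel/cavity <= 40 — bimodal against the
background (so Otsu segmentation is exact) with internal contrast carrying
the class signal.  Every generated seed comes with its exact mask and a
structure record (germ-blob count, tunnel/hollow flags) from which a
trivial rule separates all classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .annot_io import ClassCatalog
from .decompose import SeedCrop
from .errors import CatalogError, ConfigurationError
from .project import ImageStack
from .reassemble import assemble_dataset, plan_layout
from .rng import derive_rng

__all__ = [
    "SPECIES_CLASSES",
    "PhantomSpec",
    "generate_seed_phantom",
    "generate_phantom_crops",
    "generate_phantom_dataset",
    "make_phantom_scene",
    "generate_phantom_stack",
    "classify_structure",
]

SPECIES_CLASSES = {
    "sugar_beet": ("M", "N", "E"),
    "faba_bean": ("D", "UD"),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions for one synthetic dataset.

    ``class_mix`` maps class names to seed counts; classes must belong to
    the chosen species style.  ``seed_size_px`` is the nominal seed diameter
    range; intensity levels are 8-bit gray values.
    """

    species_style: str = "sugar_beet"
    class_mix: dict[str, int] = field(
        default_factory=lambda: {"M": 10, "N": 10, "E": 10})
    seed_size_px: tuple[int, int] = (48, 64)
    shell_intensity: tuple[int, int] = (120, 180)
    germ_intensity: tuple[int, int] = (200, 240)
    cavity_intensity: int = 15
    canvas: tuple[int, int] = (640, 640)
    margin: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.species_style not in SPECIES_CLASSES:
            raise ConfigurationError(
                f"unknown species style {self.species_style!r}; "
                f"choose from {sorted(SPECIES_CLASSES)}"
            )
        allowed = set(SPECIES_CLASSES[self.species_style])
        bad = set(self.class_mix) - allowed
        if bad:
            raise ConfigurationError(
                f"classes {sorted(bad)} not valid for {self.species_style} "
                f"(allowed: {sorted(allowed)})"
            )
        if any(v < 0 for v in self.class_mix.values()):
            raise ConfigurationError("class counts must be >= 0")
        lo, hi = self.seed_size_px
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"bad seed size interval {self.seed_size_px}")

    @property
    def catalog(self) -> ClassCatalog:
        return ClassCatalog(list(SPECIES_CLASSES[self.species_style]))

    @property
    def cell_size(self) -> tuple[int, int]:
        # scale-4 augmented seeds are not placed by default layouts; cell
        # covers the raw phantom extent with slack for rotation growth
        c = int(np.ceil(self.seed_size_px[1] * 1.25))
        return (c, c)


_ALL_LABELS = {c for v in SPECIES_CLASSES.values() for c in v}


def generate_seed_phantom(class_label: str, size_px: int, rng_seed,
                          shell_intensity: tuple[int, int] = (120, 180),
                          germ_intensity: tuple[int, int] = (200, 240),
                          cavity_intensity: int = 15,
                          coated: bool = False,
                          ) -> tuple[SeedCrop, dict]:
    """Draw one phantom seed; returns (crop, structure record).

    The crop is tight around its exact mask.  The structure record carries
    ``blob_count`` (interior germs), ``tunnel`` and ``hollow`` flags — the
    class-defining facts of the drawing.
    """
    if class_label not in _ALL_LABELS:
        raise CatalogError(f"unknown phantom class {class_label!r}")
    rng = derive_rng(rng_seed)
    n = int(size_px * 1.4)  # working canvas with room for eccentric bodies
    patch = np.zeros((n, n), dtype=np.float64)
    cy = cx = n / 2.0

    a = size_px / 2.0 * rng.uniform(0.88, 1.0)          # semi-major
    b = a * rng.uniform(0.62, 0.88)                     # semi-minor
    angle = rng.uniform(0.0, np.pi)
    shell = rng.uniform(*shell_intensity)

    body = np.zeros((n, n), dtype=bool)
    rr, cc = ellipse(cy, cx, a, b, shape=(n, n), rotation=angle)
    body[rr, cc] = True
    patch[body] = shell
    # mild internal texture so bodies are not perfectly flat
    patch[body] += rng.normal(0.0, 4.0, size=int(body.sum()))

    mask = body.copy()
    blob_count = 0
    tunnel = False
    hollow = False
    u = np.array([np.cos(angle), np.sin(angle)])   # major-axis direction (y, x)
    v = np.array([-np.sin(angle), np.cos(angle)])  # minor-axis direction

    if class_label == "N":
        germ = rng.uniform(*germ_intensity)
        rr, cc = ellipse(cy, cx, a * 0.45, b * 0.45, shape=(n, n),
                         rotation=angle)
        patch[rr, cc] = germ
        blob_count = 1
    elif class_label == "M":
        blob_count = int(rng.integers(2, 4))
        offsets = np.linspace(-0.45, 0.45, blob_count)
        for off in offsets:
            germ = rng.uniform(*germ_intensity)
            gy = cy + off * a * u[0]
            gx = cx + off * a * u[1]
            rr, cc = ellipse(gy, gx, a * 0.18, b * 0.28, shape=(n, n),
                             rotation=angle)
            patch[rr, cc] = germ
    elif class_label == "E":
        hollow = True
        rr, cc = ellipse(cy, cx, a * 0.62, b * 0.62, shape=(n, n),
                         rotation=angle)
        interior = np.zeros((n, n), dtype=bool)
        interior[rr, cc] = True
        patch[interior] = cavity_intensity
        # mask keeps the full body: hole filling includes shell interiors
    elif class_label == "D":
        tunnel = True
        radius = b * rng.uniform(0.35, 0.5)  # prominent exit-hole bite
        edge = np.array([cy, cx]) + a * u  # boundary point on the major axis
        rr, cc = disk((edge[0], edge[1]), radius, shape=(n, n))
        hole = np.zeros((n, n), dtype=bool)
        hole[rr, cc] = True
        patch[hole & body] = cavity_intensity * 0.5
        mask &= ~hole
    # "UD": solid body, nothing to add

    if coated:
        rr, cc = ellipse(cy, cx, a * 1.18, b * 1.18, shape=(n, n),
                         rotation=angle)
        halo = np.zeros((n, n), dtype=bool)
        halo[rr, cc] = True
        halo &= ~body
        patch[halo] = rng.uniform(60.0, 90.0)

    patch = np.clip(np.round(patch), 0, 255).astype(np.uint8)
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop = SeedCrop(
        patch=patch[y0:y1, x0:x1],
        mask=mask[y0:y1, x0:x1],
        label=class_label,
        source_id=f"phantom_{class_label}",
        history=["phantom"],
    )
    structure = {
        "label": class_label,
        "blob_count": blob_count,
        "tunnel": tunnel,
        "hollow": hollow,
        "coated": coated,
        "semi_major": float(a),
        "semi_minor": float(b),
        "angle_rad": float(angle),
    }
    return crop, structure


def classify_structure(structure: dict) -> str:
    """Rule-based class from a structure record; phantoms are separable."""
    if structure["tunnel"]:
        return "D"
    if structure["hollow"]:
        return "E"
    if structure["blob_count"] >= 2:
        return "M"
    if structure["blob_count"] == 1:
        return "N"
    return "UD"


def generate_phantom_crops(spec: PhantomSpec
                           ) -> tuple[list[SeedCrop], list[dict]]:
    """All seeds of a spec's class mix, deterministically from its seed."""
    crops: list[SeedCrop] = []
    structures: list[dict] = []
    for label in SPECIES_CLASSES[spec.species_style]:
        for i in range(spec.class_mix.get(label, 0)):
            rng = derive_rng(spec.rng_seed, "seed", label, i)
            size = int(rng.integers(spec.seed_size_px[0],
                                    spec.seed_size_px[1] + 1))
            crop, structure = generate_seed_phantom(
                label, size, rng,
                shell_intensity=spec.shell_intensity,
                germ_intensity=spec.germ_intensity,
                cavity_intensity=spec.cavity_intensity,
            )
            crop.source_id = f"phantom_{label}_{i:04d}"
            structure["source_id"] = crop.source_id
            crops.append(crop)
            structures.append(structure)
    return crops, structures


def generate_phantom_dataset(spec: PhantomSpec, output_dir: str | Path
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate, lay out and write a full annotated phantom dataset.

    Returns ``(manifest, truth)``; the truth table records every seed's
    emitted box, class and structure, and is written as ``truth.csv``.
    """
    crops, structures = generate_phantom_crops(spec)
    plan = plan_layout(len(crops), canvas_size=spec.canvas,
                       cell_size=spec.cell_size, margin=spec.margin)
    manifest, placements = assemble_dataset(
        crops, plan, output_dir, spec.catalog,
        rng_seed=derive_rng(spec.rng_seed, "layout").integers(2**31),
        prefix="phantom",
    )
    struct_frame = pd.DataFrame(structures)
    truth = placements.merge(
        struct_frame[["source_id", "blob_count", "tunnel", "hollow"]],
        on="source_id", how="left", validate="one_to_one",
    )
    truth.to_csv(Path(output_dir) / "truth.csv", index=False)
    return manifest, truth


def make_phantom_scene(spec: PhantomSpec) -> np.ndarray:
    """One assembled phantom radiograph (uint8), used as a 3D-stack scene."""
    crops, _ = generate_phantom_crops(spec)
    plan = plan_layout(len(crops), canvas_size=spec.canvas,
                       cell_size=spec.cell_size, margin=spec.margin)
    if plan.pages > 1:
        raise ConfigurationError(
            "scene spec must fit one page; enlarge the canvas or drop seeds"
        )
    rec = assemble_radiograph_ordered(crops, plan, spec.rng_seed)
    return rec


def assemble_radiograph_ordered(crops, plan, rng_seed) -> np.ndarray:
    from .reassemble import assemble_radiograph

    rng = derive_rng(rng_seed, "scene")
    order = rng.permutation(len(crops))
    rec = assemble_radiograph([crops[i] for i in order], plan, "scene")
    return rec.image


def generate_phantom_stack(scene_spec: PhantomSpec, n_slices: int,
                           slice_noise_sigma: float, rng_seed: int
                           ) -> tuple[ImageStack, np.ndarray]:
    """A 3D stack of one shared scene plus i.i.d. per-slice Gaussian noise.

    Returns ``(stack, scene)`` so callers can measure how well the mean
    Z-projection recovers the scene.  With ``slice_noise_sigma = 0`` all
    slices equal the scene exactly.
    """
    if n_slices < 1:
        raise ConfigurationError(f"n_slices must be >= 1, got {n_slices}")
    scene = make_phantom_scene(scene_spec)
    if slice_noise_sigma == 0:
        slices = np.repeat(scene[None, ...], n_slices, axis=0)
    else:
        rng = derive_rng(rng_seed, "stack")
        noise = rng.normal(0.0, slice_noise_sigma,
                           size=(n_slices, *scene.shape))
        slices = np.clip(np.round(scene.astype(np.float64) + noise),
                         0, 255).astype(np.uint8)
    return ImageStack(slices), scene
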