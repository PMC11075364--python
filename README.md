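# seedxray

Data-processing toolkit for X-ray seed phenotyping. Internal seed defects —
empty sugar-beet seeds, insect-damaged faba beans — are visible in 2D X-ray
radiographs, but training robust detectors on them is hard: defect classes
are rare, annotated radiographs are scarce, and acquisition settings (tube
voltage, exposure time, magnification) vary between laboratories. `seedxray`
implements the data side of that problem as a reusable library:

* **Decomposition** — split annotated radiographs into per-seed crops with
  foreground masks (Otsu threshold → largest 8-connected component → hole
  fill), keeping full annotation provenance.
* **Balancing + geometric augmentation** — undersample every class to the
  minority-class count, then replicate each retained seed with random
  affine transforms (rotation 0–180°, scale 0.5–4, shear 0–0.2, flips).
  With replication factor *r*, every class ends at exactly
  `r × min_k(count_k)` seeds.
* **Radiograph reassembly** — compose synthetic annotated radiographs by
  pasting crops (mask-foreground pixels only) onto a black plane in a
  disjoint grid, emitting mask-tight boxes as PASCAL VOC XML and YOLO text.
* **Degradation simulation** — additive zero-mean Gaussian noise with
  σ ∈ [0, 25] gray levels, blind noise estimation (Immerkær's
  difference-of-Laplacians method), and photometric perturbation
  `out = clip(c·(in − 127.5) + 127.5 + b·255)` with contrast
  c ∈ [0.8, 1.25] and brightness b ∈ [0, 1].
* **Z-projection** — reduce a 3D tomography stack to 2D by the per-pixel
  mean `P(x, y) = (1/N) Σₙ Iₙ(x, y)`, then min–max normalize to 8 bit.
* **Evaluation** — class-aware greedy IoU matching and macro-averaged
  metrics, `P = (100/K) Σₖ TPₖ/(TPₖ+FPₖ)`, `R = (100/K) Σₖ TPₖ/(TPₖ+FNₖ)`,
  `F1 = 2PR/(P+R)`.
* **Phantoms** — a parametric generator of synthetic seed radiographs
  (monogerm / multigerm / empty, damaged / undamaged) with exact masks and
  structure ground truth, so the whole pipeline is testable without any
  real data.

Detector training itself (Faster R-CNN, YOLO, SSD, …) is out of scope; the
package produces the datasets such models train on and scores their
outputs.

## Worked example

```python
import seedxray as sx

plan = sx.compute_balance_plan({"M": 1046, "N": 5852, "E": 1164},
                               replication_factor=2)
print(plan.shares_in_pct())   # {'M': 13.0, 'N': 72.6, 'E': 14.4}
print(plan.target_per_class)  # 2092
```

The minority class (multigerm, 1046 of 8062 seeds = 13.0%) sets the target:
monogerm and empty are undersampled to 1046, then every retained seed gains
one augmented copy, giving 2092 seeds per class (33.3% each). The same
arithmetic takes faba bean {D: 2908, UD: 1793} (61.9% damaged) to 3586 per
class.

Running the full pipeline on generated phantoms:

```python
spec = sx.PhantomSpec(class_mix={"M": 30, "N": 10, "E": 20},
                      canvas=(700, 700), rng_seed=11)
sx.generate_phantom_dataset(spec, "input")
report = sx.run_pipeline(sx.PipelineConfig(
    input_dir="input", output_dir="run", rng_seed=3,
    scale=(0.5, 1.5), canvas=(900, 900), sigma_max=10.0))
print(report["stages"]["balance"]["class_counts"])
# {'M': 20, 'N': 20, 'E': 20}
```

Stage outputs (crop store, balanced store, reassembled radiographs with
VOC/YOLO annotations, degraded copies with a per-image parameter log) are
materialized under `run/`, and re-running with the same config reproduces
them byte for byte.

The `examples/` directory holds one short script per capability; each
prints the quantities it computes and a line on what they mean. A thin CLI
mirrors the library (`seedxray gen-phantoms | decompose | balance |
assemble | degrade | project | evaluate | run`).

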