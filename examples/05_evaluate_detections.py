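"""Detection scoring with IoU matching and macro-averaged metrics.

Scores three detection sets against a phantom dataset's ground truth:
perfect detections, detections with one dropped box and one wrong class,
and an empty set — showing how TP/FP/FN and macro P/R/F1 respond.
"""

import tempfile
from pathlib import Path

import seedxray as sx
from seedxray.datasets import load_dataset

out = Path(tempfile.mkdtemp(prefix="seedxray_"))
spec = sx.PhantomSpec(class_mix={"M": 5, "N": 5, "E": 5}, canvas=(520, 520),
                      rng_seed=9)
sx.generate_phantom_dataset(spec, out)
records, catalog, _ = load_dataset(out, with_images=False)
gt = {r.source_id: r.boxes for r in records}


def score(name, dets):
    report, _ = sx.evaluate_dataset(gt, dets, classes=list(catalog))
    print(f"{name}: P={report.macro_precision:.1f}% "
          f"R={report.macro_recall:.1f}% F1={report.macro_f1:.1f}%")
    return report


perfect = {k: [sx.Detection(box=b, label=b.label, score=0.95) for b in v]
           for k, v in gt.items()}
score("perfect detections ", perfect)

flawed = {k: list(v) for k, v in perfect.items()}
key = next(iter(flawed))
dropped = flawed[key].pop()                      # one missed seed -> FN
wrong = flawed[key][0]
other = next(c for c in catalog if c != wrong.label)
flawed[key][0] = sx.Detection(box=wrong.box, label=other, score=0.9)
report = score("one miss, one confusion", flawed)
print(report.summary())
# The mislabeled box counts as a false positive of its predicted class AND
# leaves its ground truth unmatched (a false negative): cross-class
# confusions are penalized twice, once per class involved.

score("no detections        ", {})
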