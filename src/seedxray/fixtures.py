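"""Golden fixtures: small frozen text artifacts pinned by checksum.

The fixture set (annotation files, class list, truth table, manifest and a
metrics report) is regenerated deterministically from a fixed seed by
:func:`regenerate_fixtures`; the committed registry (``registry.json``)
records a SHA-256 per file so any drift in serialization or generation is
caught by re-running the generator and comparing.  Only plain-text
artifacts are registered; images are regenerated at run time.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from pathlib import Path

from .errors import FixtureDriftError

__all__ = [
    "FIXTURE_SEED",
    "sha256_file",
    "regenerate_fixtures",
    "write_registry",
    "verify_fixtures",
]

FIXTURE_SEED = 7

_GENERATING_COMMAND = (
    "python -c \"from seedxray.fixtures import regenerate_fixtures; "
    "regenerate_fixtures('fixtures')\""
)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def regenerate_fixtures(target_dir: str | Path) -> dict[str, Path]:
    """Regenerate every fixture file into ``target_dir`` from fixed seeds.

    Returns a name -> path map.  The same seed always yields byte-identical
    files, so two runs agree checksum-for-checksum.
    """
    from .evaluate import ClassCounts, macro_metrics
    from .phantoms import PhantomSpec, generate_phantom_dataset

    target_dir = Path(target_dir)
    target_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    spec = PhantomSpec(
        species_style="sugar_beet",
        class_mix={"M": 2, "N": 2, "E": 2},
        canvas=(360, 360),
        seed_size_px=(40, 52),
        rng_seed=FIXTURE_SEED,
    )
    with tempfile.TemporaryDirectory() as tmp:
        manifest, _ = generate_phantom_dataset(spec, tmp)
        tmp = Path(tmp)
        first = manifest.iloc[0]
        copies = {
            "golden_voc.xml": tmp / first["voc_path"],
            "golden_yolo.txt": tmp / first["yolo_path"],
            "classes.txt": tmp / "classes.txt",
            "manifest.csv": tmp / "manifest.csv",
            "truth.csv": tmp / "truth.csv",
        }
        for name, src in copies.items():
            dst = target_dir / name
            shutil.copyfile(src, dst)
            out[name] = dst

    # worked two-class metrics example: P=87.5, R=75, F1~80.769
    counts = ClassCounts(tp={"A": 3, "B": 2}, fp={"A": 1, "B": 0},
                         fn={"A": 0, "B": 2})
    report = macro_metrics(counts, classes=["A", "B"])
    metrics_path = target_dir / "golden_metrics.csv"
    report.to_frame().to_csv(metrics_path, index=False,
                             float_format="%.6f")
    out["golden_metrics.csv"] = metrics_path
    return out


def write_registry(fixtures_dir: str | Path) -> Path:
    """(Re)build ``registry.json`` for the files present in the fixture dir."""
    fixtures_dir = Path(fixtures_dir)
    entries = []
    for path in sorted(fixtures_dir.iterdir()):
        if path.name == "registry.json" or not path.is_file():
            continue
        entries.append({
            "name": path.name,
            "path": path.name,
            "sha256": sha256_file(path),
            "command": _GENERATING_COMMAND,
            "seed": FIXTURE_SEED,
        })
    registry_path = fixtures_dir / "registry.json"
    registry_path.write_text(
        json.dumps({"fixtures": entries}, indent=2, sort_keys=True) + "\n"
    )
    return registry_path


def verify_fixtures(fixtures_dir: str | Path) -> dict[str, str]:
    """Regenerate the fixture set and compare against the registry.

    Returns name -> checksum on success; raises :class:`FixtureDriftError`
    naming the first drifted or unregistered fixture otherwise.
    """
    fixtures_dir = Path(fixtures_dir)
    registry = json.loads((fixtures_dir / "registry.json").read_text())
    registered = {e["name"]: e["sha256"] for e in registry["fixtures"]}

    present = {p.name for p in fixtures_dir.iterdir()
               if p.is_file() and p.name != "registry.json"}
    unregistered = present - set(registered)
    if unregistered:
        raise FixtureDriftError(
            f"files present but not in registry: {sorted(unregistered)}"
        )

    with tempfile.TemporaryDirectory() as tmp:
        fresh = regenerate_fixtures(tmp)
        for name, expected in registered.items():
            if name not in fresh:
                raise FixtureDriftError(f"registry names unknown fixture {name!r}")
            actual = sha256_file(fresh[name])
            if actual != expected:
                raise FixtureDriftError(
                    f"fixture {name!r} drifted: regenerated {actual[:12]}..., "
                    f"registered {expected[:12]}..."
                )
            committed = fixtures_dir / name
            if sha256_file(committed) != expected:
                raise FixtureDriftError(
                    f"committed fixture {name!r} does not match its "
                    f"registered checksum"
                )
    return registered
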