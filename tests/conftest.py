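import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seedxray as sx

settings.register_profile(
    "ci", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def catalog():
    return sx.ClassCatalog(["M", "N", "E"])


def make_disk_crop(radius=12, intensity=200, label="N", pad=2):
    """A bright disk crop with exact mask, tight to the mask."""
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[:n, :n]
    mask = (yy - n / 2 + 0.5) ** 2 + (xx - n / 2 + 0.5) ** 2 <= radius ** 2
    patch = np.where(mask, intensity, 0).astype(np.uint8)
    ys, xs = np.nonzero(mask)
    sl = np.s_[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    return sx.SeedCrop(patch=patch[sl], mask=mask[sl], label=label,
                       source_id="disk")


def make_rect_crop(width=30, height=20, intensity=180, label="M"):
    """A solid rectangle crop (mask all-true)."""
    return sx.SeedCrop(
        patch=np.full((height, width), intensity, np.uint8),
        mask=np.ones((height, width), bool),
        label=label, source_id="rect",
    )


@pytest.fixture()
def sugar_beet_spec():
    return sx.PhantomSpec(
        species_style="sugar_beet",
        class_mix={"M": 3, "N": 3, "E": 3},
        canvas=(420, 420), rng_seed=5,
    )


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """A small written phantom dataset shared across read-only tests."""
    out = tmp_path_factory.mktemp("phantom_ds")
    spec = sx.PhantomSpec(
        species_style="sugar_beet",
        class_mix={"M": 4, "N": 4, "E": 4},
        canvas=(520, 520), rng_seed=21,
    )
    manifest, truth = sx.generate_phantom_dataset(spec, out)
    return {"dir": out, "spec": spec, "manifest": manifest, "truth": truth}
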