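"""Undersample-then-replicate balancing and geometric augmentation."""

import numpy as np
import pytest

import seedxray as sx
from seedxray.balance import GeometricParams
from seedxray.errors import ConfigurationError, SizeError
from tests.conftest import make_disk_crop, make_rect_crop


class TestBalancePlan:
    def test_identity_when_already_balanced(self):
        plan = sx.compute_balance_plan({"A": 7, "B": 7}, replication_factor=1)
        assert plan.target_per_class == 7
        assert plan.minority_count == 7

    def test_minority_times_replication(self):
        plan = sx.compute_balance_plan({"a": 10, "b": 30, "c": 12}, 3)
        assert plan.minority_count == 10
        assert plan.target_per_class == 30
        assert plan.total_out == 90

    @pytest.mark.parametrize("counts,factor", [
        ({}, 2), ({"A": 0, "B": 5}, 2), ({"A": 5}, 0),
    ])
    def test_invalid_configuration_rejected(self, counts, factor):
        with pytest.raises(ConfigurationError):
            sx.compute_balance_plan(counts, factor)


class TestUndersample:
    def test_exact_count_distinct(self):
        items = list(range(500))
        out = sx.undersample(items, 120, rng_seed=4)
        assert len(out) == 120
        assert len(set(out)) == 120

    def test_full_population(self):
        items = list(range(9))
        assert sorted(sx.undersample(items, 9, 0)) == items

    def test_deterministic_per_seed_and_seed_sensitive(self):
        items = list(range(100))
        a = sx.undersample(items, 40, 11)
        b = sx.undersample(items, 40, 11)
        c = sx.undersample(items, 40, 12)
        assert a == b
        assert set(a) != set(c)

    def test_oversized_target_raises(self):
        with pytest.raises(SizeError):
            sx.undersample([1, 2, 3], 4, 0)


class TestSampleParams:
    def test_degenerate_spec_yields_identity(self):
        spec = sx.AugmentationSpec.identity()
        params = sx.sample_geometric_params(spec, 3)
        assert params.is_identity

    def test_deterministic_per_seed(self):
        spec = sx.AugmentationSpec()
        assert sx.sample_geometric_params(spec, 9) == \
            sx.sample_geometric_params(spec, 9)

    def test_scale_uniform_on_interval(self):
        # U(0.5, 4): mean 2.25, sd 3.5/sqrt(12); check mean within 3 SE
        spec = sx.AugmentationSpec()
        rng = np.random.default_rng(123)
        scales = np.array([
            sx.sample_geometric_params(spec, rng).scale for _ in range(10_000)
        ])
        assert scales.min() >= 0.5 and scales.max() <= 4.0
        se = (3.5 / np.sqrt(12)) / np.sqrt(len(scales))
        assert abs(scales.mean() - 2.25) < 3 * se


class TestApplyGeometric:
    def test_identity_unchanged(self):
        crop = make_disk_crop()
        out = sx.apply_geometric(crop, GeometricParams())
        assert np.array_equal(out.patch, crop.patch)
        assert np.array_equal(out.mask, crop.mask)
        assert out.history[-1].startswith("geom(")

    def test_hflip_is_involution(self):
        crop = make_rect_crop()
        crop.patch[:, :5] = 90  # asymmetric content
        once = sx.apply_geometric(crop, GeometricParams(hflip=True))
        twice = sx.apply_geometric(once, GeometricParams(hflip=True))
        assert not np.array_equal(once.patch, crop.patch)
        assert np.array_equal(twice.patch, crop.patch)
        assert np.array_equal(twice.mask, crop.mask)

    @pytest.mark.parametrize("params,expected", [
        (GeometricParams(scale=2.0), lambda w, h: (2 * w, 2 * h)),
        (GeometricParams(rotation_deg=90.0), lambda w, h: (h, w)),
        (GeometricParams(rotation_deg=180.0), lambda w, h: (w, h)),
    ])
    def test_rectangle_extent_closed_form(self, params, expected):
        w, h = 30, 20
        out = sx.apply_geometric(make_rect_crop(w, h), params)
        oh, ow = out.shape
        ew, eh = expected(w, h)
        assert abs(ow - ew) <= 2 and abs(oh - eh) <= 2  # within 1 px per side

    @pytest.mark.parametrize("scale", [0.5, 1.0, 2.0, 4.0])
    def test_area_scales_quadratically_on_convex_mask(self, scale):
        crop = make_disk_crop(radius=16)
        out = sx.apply_geometric(crop, GeometricParams(scale=scale))
        expected = crop.foreground_area * scale ** 2
        assert abs(out.foreground_area - expected) / expected < 0.05

    def test_label_and_provenance_preserved(self):
        crop = make_disk_crop(label="E")
        crop.history = ["extract(x)"]
        out = sx.apply_geometric(
            crop, GeometricParams(rotation_deg=37.0, scale=1.3, shear=0.1,
                                  hflip=True))
        assert out.label == "E"
        assert out.source_id == crop.source_id
        assert out.history[0] == "extract(x)" and len(out.history) == 2
        assert out.is_connected()

    def test_output_tight_to_mask(self):
        out = sx.apply_geometric(make_disk_crop(),
                                 GeometricParams(rotation_deg=45.0))
        assert out.mask[:, 0].any() and out.mask[:, -1].any()
        assert out.mask[0, :].any() and out.mask[-1, :].any()


class TestExecutePlan:
    def _crops(self, counts):
        crops = []
        for label, n in counts.items():
            for i in range(n):
                c = make_disk_crop(radius=8 + i % 3, label=label)
                c.source_id = f"{label}{i}"
                crops.append(c)
        return crops

    def test_exact_targets_and_replication(self):
        counts = {"M": 9, "N": 3, "E": 5}
        crops = self._crops(counts)
        plan = sx.compute_balance_plan(counts, 2)
        out = sx.execute_balance_plan(crops, plan, sx.AugmentationSpec(),
                                      rng_seed=1)
        got = {}
        for c in out:
            got[c.label] = got.get(c.label, 0) + 1
        assert got == {"M": 6, "N": 6, "E": 6}
        # each retained original appears replication_factor times:
        # once as-is plus one augmented copy sharing its source_id
        for label in counts:
            per_source = {}
            for c in out:
                if c.label == label:
                    per_source[c.source_id] = per_source.get(c.source_id, 0) + 1
            assert set(per_source.values()) == {2}
            augmented = [c for c in out if c.label == label
                         and any(h.startswith("geom(") for h in c.history)]
            assert len(augmented) == plan.minority_count

    def test_deterministic(self):
        counts = {"M": 4, "N": 6}
        plan = sx.compute_balance_plan(counts, 2)
        a = sx.execute_balance_plan(self._crops(counts), plan,
                                    sx.AugmentationSpec(), rng_seed=2)
        b = sx.execute_balance_plan(self._crops(counts), plan,
                                    sx.AugmentationSpec(), rng_seed=2)
        assert [c.source_id for c in a] == [c.source_id for c in b]
        assert all(np.array_equal(x.patch, y.patch) for x, y in zip(a, b))

    def test_label_mismatch_rejected(self):
        plan = sx.compute_balance_plan({"M": 2, "N": 2}, 1)
        with pytest.raises(ConfigurationError):
            sx.execute_balance_plan(self._crops({"M": 2}), plan,
                                    sx.AugmentationSpec(), 0)
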