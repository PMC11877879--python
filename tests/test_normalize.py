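"""Max / ratio / baseline normalization and healthy-reference contexts."""

import numpy as np
import pytest

from skinspec import (
    Channel,
    Modality,
    NormalizationContext,
    build_context,
    normalize_baseline,
    normalize_max,
    normalize_ratio,
    normalize_spectrum,
)
from skinspec.datamodel import ConfigError, DataError, Dataset, SkinSite

from conftest import make_spectrum

AF = Channel(Modality.AF2, 1)
DR = Channel(Modality.DR, 1)


def af_spectrum(values, start=440.0):
    values = np.asarray(values, dtype=float)
    return make_spectrum(values, channel=AF, wavelengths=start + np.arange(values.size))


def make_ctx(channel, grid, global_mean, lesion_mean, lesion="L1"):
    return NormalizationContext(
        grids={channel.key: np.asarray(grid, dtype=float)},
        global_mean={channel.key: np.asarray(global_mean, dtype=float)},
        global_scalar={channel.key: float(np.mean(global_mean))},
        lesion_mean={(lesion, channel.key): np.asarray(lesion_mean, dtype=float)},
    )


class TestMaxNormalization:
    def test_divides_by_window_maximum(self):
        s = af_spectrum([1.0, 5.0, 2.0], start=500.0)
        out = normalize_max(s)
        np.testing.assert_allclose(out.intensities, [0.2, 1.0, 0.4])

    def test_output_window_max_is_one(self, rng):
        vals = rng.uniform(1.0, 100.0, size=300)
        s = af_spectrum(vals, start=420.0)
        out = normalize_max(s)
        mask = out.window_mask(420.0, 600.0)
        assert out.intensities[mask].max() == pytest.approx(1.0)

    def test_values_outside_window_may_exceed_one(self):
        # global peak at 650 nm lies outside the AF search window (420-600)
        w = 420.0 + np.arange(300.0)
        vals = np.ones(300)
        vals[w == 500.0] = 2.0  # window max
        vals[w == 650.0] = 10.0  # out-of-window peak
        out = normalize_max(make_spectrum(vals, channel=AF, wavelengths=w))
        assert out.intensities[w == 650.0][0] == pytest.approx(5.0)
        assert out.intensities[out.window_mask(420, 600)].max() == pytest.approx(1.0)

    def test_dr_window_is_630_690(self):
        w = 340.0 + np.arange(446.0)
        vals = np.ones(w.size)
        vals[w == 660.0] = 4.0
        out = normalize_max(make_spectrum(vals, channel=DR, wavelengths=w))
        assert out.intensities[w == 400.0][0] == pytest.approx(0.25)

    def test_nonpositive_window_max_is_error(self):
        s = af_spectrum([0.0, 0.0, 0.0], start=500.0)
        with pytest.raises(DataError, match="max"):
            normalize_max(s)


class TestRatioNormalization:
    def test_unit_factor_is_identity(self):
        grid = [500.0, 501.0]
        ctx = make_ctx(AF, grid, global_mean=[4.0, 4.0], lesion_mean=[4.0, 2.0])
        s = make_spectrum([3.0, 5.0], channel=AF, wavelengths=grid)
        out = normalize_ratio(s, ctx, "L1")  # scalar 4 / max(ref) 4 = 1
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_factor_is_constant_scalar(self):
        grid = [500.0, 501.0, 502.0]
        ctx = make_ctx(AF, grid, global_mean=[2.0, 2.0, 2.0], lesion_mean=[4.0, 1.0, 1.0])
        s = make_spectrum([3.0, 6.0, 9.0], channel=AF, wavelengths=grid)
        out = normalize_ratio(s, ctx, "L1")
        ratio = out.intensities / s.intensities
        np.testing.assert_allclose(ratio, 0.5)  # 2 / 4
        # shape preserved: argmax and pairwise ratios unchanged
        assert np.argmax(out.intensities) == np.argmax(s.intensities)

    def test_missing_lesion_reference_is_error(self):
        grid = [500.0, 501.0]
        ctx = make_ctx(AF, grid, [1.0, 1.0], [1.0, 1.0], lesion="L1")
        s = make_spectrum([1.0, 2.0], channel=AF, wavelengths=grid)
        with pytest.raises(DataError, match="no healthy reference"):
            normalize_ratio(s, ctx, "L99")


class TestBaselineNormalization:
    def test_pointwise_hand_example(self):
        grid = [500.0, 501.0]
        ctx = make_ctx(AF, grid, global_mean=[2.0, 2.0], lesion_mean=[1.0, 2.0])
        s = make_spectrum([2.0, 2.0], channel=AF, wavelengths=grid)
        out = normalize_baseline(s, ctx, "L1")
        np.testing.assert_allclose(out.intensities, [4.0, 2.0])

    def test_lesion_mean_maps_to_global_mean(self):
        grid = 440.0 + np.arange(50.0)
        ref = 1.0 + np.linspace(0, 3, 50)
        gmean = 2.0 + np.sin(np.linspace(0, 3, 50))
        ctx = make_ctx(AF, grid, gmean, ref)
        out = normalize_baseline(
            make_spectrum(ref, channel=AF, wavelengths=grid), ctx, "L1"
        )
        np.testing.assert_allclose(out.intensities, gmean, atol=1e-12)

    def test_equal_references_are_identity(self):
        grid = [500.0, 501.0]
        ctx = make_ctx(AF, grid, global_mean=[3.0, 4.0], lesion_mean=[3.0, 4.0])
        s = make_spectrum([7.0, 8.0], channel=AF, wavelengths=grid)
        np.testing.assert_allclose(
            normalize_baseline(s, ctx, "L1").intensities, [7.0, 8.0]
        )

    def test_near_zero_reference_floored_with_warning(self):
        grid = [500.0, 501.0]
        ctx = make_ctx(AF, grid, global_mean=[1.0, 1.0], lesion_mean=[0.0, 1.0])
        s = make_spectrum([1.0, 1.0], channel=AF, wavelengths=grid)
        with pytest.warns(UserWarning, match="near-zero"):
            out = normalize_baseline(s, ctx, "L1")
        assert np.all(np.isfinite(out.intensities))


class TestModes:
    def test_none_is_identity_and_unknown_mode_rejected(self):
        s = af_spectrum([1.0, 2.0, 3.0])
        assert normalize_spectrum(s, "none") is s
        with pytest.raises(ConfigError, match="unknown normalization"):
            normalize_spectrum(s, "snv")


def _mini_dataset():
    grid = np.array([500.0, 501.0])
    ds = Dataset()
    ds.sites = {
        "L1-L": SkinSite("L1-L", "P1", "L1", "L", "BCC"),
        "L1-NL1": SkinSite("L1-NL1", "P1", "L1", "NL", "H"),
        "L1-NL2": SkinSite("L1-NL2", "P1", "L1", "NL", "H"),
        "L2-L": SkinSite("L2-L", "P2", "L2", "L", "AK"),
        "L2-NL1": SkinSite("L2-NL1", "P2", "L2", "NL", "H"),
    }
    v = np.array([2.0, 4.0])
    ds.averaged = {
        ("L1-L", AF): make_spectrum([5.0, 5.0], channel=AF, wavelengths=grid),
        ("L1-NL1", AF): make_spectrum(v, channel=AF, wavelengths=grid),
        ("L1-NL2", AF): make_spectrum(v, channel=AF, wavelengths=grid),
        ("L2-L", AF): make_spectrum([1.0, 1.0], channel=AF, wavelengths=grid),
        ("L2-NL1", AF): make_spectrum([6.0, 8.0], channel=AF, wavelengths=grid),
    }
    return ds


class TestBuildContext:
    def test_two_identical_healthy_sites_give_that_reference(self):
        ds = _mini_dataset()
        ctx = build_context(ds, training_site_ids=set(ds.sites))
        np.testing.assert_array_equal(ctx.lesion_mean[("L1", AF.key)], [2.0, 4.0])

    def test_global_mean_of_single_healthy_site(self):
        ds = _mini_dataset()
        ctx = build_context(ds, training_site_ids={"L2-NL1"})
        np.testing.assert_array_equal(ctx.global_mean[AF.key], [6.0, 8.0])
        assert ctx.global_scalar[AF.key] == pytest.approx(7.0)

    def test_scalar_of_constant_spectrum_is_that_constant(self):
        ds = _mini_dataset()
        ds.averaged[("L1-NL1", AF)] = make_spectrum(
            [3.0, 3.0], channel=AF, wavelengths=[500.0, 501.0]
        )
        ctx = build_context(ds, training_site_ids={"L1-NL1"})
        assert ctx.global_scalar[AF.key] == pytest.approx(3.0)

    def test_test_fold_sites_never_reach_global_means(self):
        """Contexts built from disjoint training sets differ; held-out healthy
        sites contribute to local lesion references but not to global means."""
        ds = _mini_dataset()
        ctx_a = build_context(ds, training_site_ids={"L1-NL1", "L1-NL2"})
        ctx_b = build_context(ds, training_site_ids={"L2-NL1"})
        assert not np.array_equal(ctx_a.global_mean[AF.key], ctx_b.global_mean[AF.key])
        # poisoning a held-out healthy site leaves the global mean untouched
        ds.averaged[("L2-NL1", AF)] = make_spectrum(
            [1e9, 1e9], channel=AF, wavelengths=[500.0, 501.0]
        )
        ctx_a2 = build_context(ds, training_site_ids={"L1-NL1", "L1-NL2"})
        np.testing.assert_array_equal(
            ctx_a.global_mean[AF.key], ctx_a2.global_mean[AF.key]
        )

    def test_lesions_without_healthy_sites_are_flagged(self):
        ds = _mini_dataset()
        del ds.averaged[("L2-NL1", AF)]
        ctx = build_context(ds, training_site_ids=set(ds.sites))
        assert "L2" in ctx.lesions_without_reference
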