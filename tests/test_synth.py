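"""Synthetic bead-image generator: bead statistics, rendering, noise,
displacement application, traction islands, benchmark assembly."""

import numpy as np
import pytest

from tfmuq import synth
from tfmuq.synth import (
    BeadField,
    DisplacementSpec,
    TractionIsland,
    TractionFieldSpec,
    snr_to_sigma,
    sigma_to_snr,
)


class TestBeadField:
    def test_zero_density_empty(self):
        field = synth.generate_bead_field((64, 64), 0.0, 7)
        assert field.centroids.shape == (0, 2)

    def test_poisson_mean_count(self):
        """Constant density d gives counts with Poisson mean d*area."""
        d, shape = 0.01, (64, 64)
        counts = [
            len(synth.generate_bead_field(shape, d, seed).centroids)
            for seed in range(100)
        ]
        mean_expected = d * shape[0] * shape[1]
        # mean of 100 Poisson(40.96) draws: sd of mean = sqrt(40.96/100)
        assert np.mean(counts) == pytest.approx(
            mean_expected, abs=5 * np.sqrt(mean_expected / 100)
        )

    def test_density_gradient_left_heavier(self):
        profile = lambda x: 0.02 * (1 - x / 256)
        left = right = 0
        for seed in range(20):
            c = synth.generate_bead_field((256, 256), profile, seed).centroids
            left += (c[:, 0] < 128).sum()
            right += (c[:, 0] >= 128).sum()
        assert left > 2 * right

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_bead_field((64, 64), -1e-3, 0)
        with pytest.raises(ValueError):
            synth.generate_bead_field((64, 64), lambda x: -np.ones_like(x), 0)

    def test_reproducible_under_seed(self):
        a = synth.generate_bead_field((64, 64), 0.01, 42).centroids
        b = synth.generate_bead_field((64, 64), 0.01, 42).centroids
        assert np.array_equal(a, b)


class TestRender:
    def test_single_bead_peak_at_center(self):
        field = BeadField(np.array([[10.0, 20.0]]), bead_sigma=1.5)
        img = synth.render_image(field, (64, 64))
        # pixel (row 20, col 10) has center (10, 20)
        assert img[20, 10] == pytest.approx(1000.0)

    def test_gaussian_profile_value_at_sigma(self):
        sig = 2.0
        field = BeadField(np.array([[10.0, 20.0]]), bead_sigma=sig)
        img = synth.render_image(field, (64, 64))
        assert img[20, 12] == pytest.approx(1000.0 * np.exp(-0.5), rel=1e-6)

    def test_empty_field_black_image(self):
        img = synth.render_image(BeadField(np.empty((0, 2))), (32, 32))
        assert not img.any()

    def test_overlapping_beads_clip_at_saturation(self):
        field = BeadField(np.array([[16.5, 16.5], [16.6, 16.5]]))
        img = synth.render_image(field, (32, 32))
        assert img.max() == pytest.approx(1000.0)


class TestNoise:
    def test_snr_sigma_formula(self):
        assert snr_to_sigma(50.0) == pytest.approx(3.1623, abs=1e-3)
        for snr in (0.0, 17.3, 40.0, 80.0):
            assert sigma_to_snr(snr_to_sigma(snr)) == pytest.approx(snr)

    def test_infinite_snr_is_identity(self):
        img = np.full((32, 32), 500.0)
        assert np.array_equal(synth.add_pixel_noise(img, np.inf, 0), img)

    def test_empirical_noise_std(self):
        """On a mid-gray image (no clipping) the added noise std matches
        the SNR formula; SNR 20 dB -> sigma = 100 a.u."""
        img = np.full((1000, 1000), 500.0)
        noisy = synth.add_pixel_noise(img, 20.0, 123)
        assert np.std(noisy - img) == pytest.approx(100.0, rel=0.01)

    def test_output_clipped(self):
        img = np.full((64, 64), 990.0)
        noisy = synth.add_pixel_noise(img, 10.0, 0)
        assert noisy.max() <= 1000.0 and noisy.min() >= 0.0


class TestDisplacement:
    def test_uniform_exact_shift(self):
        field = BeadField(np.array([[10.0, 10.0], [50.0, 30.0]]))
        spec = DisplacementSpec.uniform((2.0, 0.6))
        out = synth.apply_displacement(field, spec, (64, 64))
        assert np.allclose(out.centroids - field.centroids, [2.0, 0.6])

    def test_zero_field_identity(self):
        field = BeadField(np.array([[10.0, 10.0]]))
        out = synth.apply_displacement(
            field, DisplacementSpec.uniform((0.0, 0.0)), (64, 64)
        )
        assert np.array_equal(out.centroids, field.centroids)

    def test_forward_then_backward_restores(self):
        rng = np.random.default_rng(0)
        field = BeadField(rng.uniform(10, 54, size=(20, 2)))
        u = (1.7, -2.3)
        fwd = synth.apply_displacement(
            field, DisplacementSpec.uniform(u), (64, 64)
        )
        back = synth.apply_displacement(
            fwd, DisplacementSpec.uniform((-u[0], -u[1])), (64, 64)
        )
        assert np.allclose(back.centroids, field.centroids, atol=1e-12)

    def test_shear_fixed_point_at_center(self):
        """The linear shear field vanishes at the normalized origin."""
        field = BeadField(np.array([[32.0, 32.0]]))
        out = synth.apply_displacement(
            field, DisplacementSpec.shear(), (64, 64)
        )
        assert np.allclose(out.centroids, field.centroids, atol=1e-12)

    def test_shear_magnitude_at_corner(self):
        spec = DisplacementSpec.shear(alpha_deg=45.0, g=20.0)
        u = spec.evaluate(np.array([[64.0, 64.0]]), (64, 64))
        expected = 20.0 * (np.sqrt(2) / 2) ** 3
        assert np.allclose(u, [expected, expected])

    def test_out_of_frame_beads_dropped(self):
        field = BeadField(np.array([[63.0, 10.0], [5.0, 5.0]]))
        out = synth.apply_displacement(
            field, DisplacementSpec.uniform((3.0, 0.0)), (64, 64)
        )
        assert len(out.centroids) == 1

    def test_unknown_kind_rejected(self):
        field = BeadField(np.array([[10.0, 10.0]]))
        with pytest.raises(ValueError, match="unknown"):
            synth.apply_displacement(
                field, DisplacementSpec(kind="warp"), (64, 64)
            )


class TestIslandTraction:
    def test_peak_value_at_center(self):
        spec = synth.default_island_spec(354.49)
        tx, ty = synth.build_island_traction(spec)(
            np.array(354.49 / 4), np.array(354.49 / 4)
        )
        assert np.hypot(tx, ty) == pytest.approx(500.0, rel=1e-6)

    def test_far_field_vanishes(self):
        spec = TractionFieldSpec(
            [TractionIsland(center=(50.0, 50.0))], domain_side=400.0
        )
        tx, ty = synth.build_island_traction(spec)(np.array(350.0), np.array(350.0))
        assert abs(tx) < 1e-10 and abs(ty) < 1e-10

    def test_four_island_net_force_zero(self):
        """The symmetric default layout carries no net force."""
        spec = synth.default_island_spec(354.49)
        n = 512
        xs = (np.arange(n) + 0.5) * 354.49 / n
        X, Y = np.meshgrid(xs, xs)
        tx, ty = synth.build_island_traction(spec)(X, Y)
        cell = (354.49 / n) ** 2
        net = np.hypot(tx.sum(), ty.sum()) * cell
        total = np.hypot(tx, ty).sum() * cell
        assert net < 1e-6 * total

    def test_direction_convention(self):
        """Left-half islands point +x, right-half islands point -x."""
        L = 354.49
        spec = synth.default_island_spec(L)
        f = synth.build_island_traction(spec)
        tx_left, _ = f(np.array(L / 4), np.array(L / 4))
        tx_right, _ = f(np.array(3 * L / 4), np.array(L / 4))
        assert tx_left > 0 > tx_right

    def test_island_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            TractionFieldSpec(
                [TractionIsland(center=(500.0, 50.0))], domain_side=400.0
            )


class TestBenchmark:
    def test_zero_traction_identical_images(self):
        cfg = synth.BenchmarkConfig(
            image_side=128,
            snr_db=np.inf,
            islands=TractionFieldSpec(
                [TractionIsland(center=(20.0, 20.0), tp=0.0)],
                domain_side=128 * synth.DEFAULT_PIXEL_SIZE_UM,
            ),
        )
        bench = synth.build_benchmark(cfg, seed=0)
        assert np.array_equal(bench.ref, bench.session)

    def test_displacement_maxima_at_islands(self):
        """The forward-solved displacement magnitude peaks at the
        traction islands."""
        cfg = synth.BenchmarkConfig(image_side=256,
                                    pixel_size=synth.DEFAULT_PIXEL_SIZE_UM * 4)
        ux, uy = synth.forward_displacement_field(cfg)
        mag = np.hypot(ux, uy)
        iy, ix = np.unravel_index(mag.argmax(), mag.shape)
        centers_px = [
            (isl.center[0] / cfg.pixel_size, isl.center[1] / cfg.pixel_size)
            for isl in cfg.islands.islands
        ]
        d = min(np.hypot(ix - cx, iy - cy) for cx, cy in centers_px)
        assert d < 15.0 / cfg.pixel_size  # within one island width

    def test_distinct_realizations_same_truth(self):
        cfg = synth.BenchmarkConfig(image_side=128,
                                    pixel_size=synth.DEFAULT_PIXEL_SIZE_UM * 8)
        b1 = synth.build_benchmark(cfg, seed=1)
        b2 = synth.build_benchmark(cfg, seed=2)
        assert not np.array_equal(b1.ref, b2.ref)
        assert np.array_equal(b1.ux_px, b2.ux_px)

    def test_default_calibration_75_pa(self):
        assert synth.ground_truth_rms() == pytest.approx(75.0, abs=0.1)


class TestPropertyInvariants:
    """Derandomized property checks over broad parameter ranges."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=-20.0, max_value=120.0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_snr_sigma_relation_exact_for_all_levels(self, snr):
        assert sigma_to_snr(snr_to_sigma(snr)) == pytest.approx(snr, abs=1e-9)
        assert snr_to_sigma(snr) > 0

    @given(
        st.floats(min_value=-30.0, max_value=30.0),
        st.floats(min_value=-30.0, max_value=30.0),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_displace_then_undisplace_is_identity(self, ux, uy):
        field = BeadField(np.array([[100.0, 100.0], [120.0, 90.0]]))
        big = (256, 256)
        fwd = synth.apply_displacement(
            field, DisplacementSpec.uniform((ux, uy)), big
        )
        back = synth.apply_displacement(
            fwd, DisplacementSpec.uniform((-ux, -uy)), big
        )
        if len(back.centroids) == len(field.centroids):
            assert np.allclose(back.centroids, field.centroids, atol=1e-9)
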