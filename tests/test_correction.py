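"""Scatter-correction algorithm tests: sampling, interpolation, subtract, merge."""

import numpy as np
import pytest

import slitcbct as sc
from slitcbct.acquisition import ScatterSimulator, project_primary
from slitcbct.correction import correct_view
from slitcbct.errors import InsufficientSamplesError, PairingError
from slitcbct.geometry import DetectorMask, detector_coords


@pytest.fixture(scope="module")
def mask10(geom):
    return sc.build_mask(sc.MSCSpec(10.0), geom, "A")


class TestSampleClosedScatter:
    @pytest.mark.parametrize("mode", ["pixel", "band"])
    def test_constant_field_sampled_exactly(self, geom, mask10, mode):
        pix = np.full((geom.n_v, geom.n_u), 0.37)
        vc, smp = sc.sample_closed_scatter(pix, mask10, geom, mode=mode)
        assert np.allclose(smp, 0.37)
        assert np.all(np.diff(vc) > 0)

    @pytest.mark.parametrize("mode", ["pixel", "band"])
    def test_linear_field_sampled_on_the_line(self, geom, mask10, mode):
        """Band means of a linear field sit exactly at the band's mean v, so
        both sampling modes reproduce a*v + b with no bias."""
        _, v = detector_coords(geom)
        a, b = 0.004, 1.5
        pix = np.broadcast_to((a * v + b)[:, None], (geom.n_v, geom.n_u)).copy()
        vc, smp = sc.sample_closed_scatter(pix, mask10, geom, mode=mode)
        assert np.allclose(smp, (a * vc + b)[:, None], rtol=1e-12)

    def test_fewer_than_two_closed_bands_rejected(self, geom):
        single = DetectorMask(values=np.ones((geom.n_v, geom.n_u)),
                              open_bands=[(-150.0, 100.0)],
                              closed_bands=[(100.0, 150.0)], phase="A")
        with pytest.raises(InsufficientSamplesError):
            sc.sample_closed_scatter(np.ones((geom.n_v, geom.n_u)), single, geom)

    def test_guard_pixels_shrink_bands(self, geom, mask10):
        pix = np.ones((geom.n_v, geom.n_u))
        vc0, s0 = sc.sample_closed_scatter(pix, mask10, geom, mode="pixel")
        vc1, s1 = sc.sample_closed_scatter(pix, mask10, geom, mode="pixel",
                                           guard_pixels=1)
        assert len(vc1) < len(vc0)


class TestInterpolateScatter:
    def test_constant_samples_give_constant_plane(self, geom, mask10):
        pix = np.full((geom.n_v, geom.n_u), 2.0)
        vc, smp = sc.sample_closed_scatter(pix, mask10, geom)
        for extrap in ("slope", "constant"):
            est = sc.interpolate_scatter(vc, smp, geom, extrapolation=extrap)
            assert np.allclose(est.values, 2.0, rtol=1e-12)

    @pytest.mark.parametrize("method", ["pchip", "linear"])
    def test_linear_field_recovered_exactly(self, geom, mask10, method):
        """Collinear samples reproduce the plane everywhere, margins included
        (slope extrapolation continues the line)."""
        _, v = detector_coords(geom)
        plane = np.broadcast_to((0.01 * v + 3.0)[:, None],
                                (geom.n_v, geom.n_u)).copy()
        vc, smp = sc.sample_closed_scatter(plane, mask10, geom)
        est = sc.interpolate_scatter(vc, smp, geom, method=method)
        assert np.allclose(est.values, plane, rtol=1e-9)

    def test_estimate_tracks_smooth_truth_scatter(self, geom, simple_phantom,
                                                  scatter_params):
        """Against an injected truth plane (Gaussian-blurred primary), the
        estimate errs by well under 5% of the truth maximum."""
        prim = project_primary(simple_phantom, geom, 0.0).pixels
        truth = ScatterSimulator(geom, scatter_params).shape(prim)
        mask = sc.build_mask(sc.MSCSpec(10.0), geom, "A")
        vc, smp = sc.sample_closed_scatter(truth, mask, geom)
        est = sc.interpolate_scatter(vc, smp, geom)
        assert np.abs(est.values - truth).max() / truth.max() <= 0.05

    def test_single_sample_rejected(self, geom):
        with pytest.raises(InsufficientSamplesError):
            sc.interpolate_scatter(np.array([0.0]), np.zeros((1, geom.n_u)), geom)

    def test_estimate_clipped_non_negative(self, geom):
        vc = np.array([-100.0, 0.0, 100.0])
        smp = np.tile([[1.0], [0.001], [1.0]], (1, geom.n_u))
        est = sc.interpolate_scatter(vc, smp, geom, method="linear")
        assert np.all(est.values >= 0.0)

    def test_error_scales_quadratically_with_band_pitch(self, geom, simple_phantom,
                                                        scatter_params):
        """Halving the septum pitch cuts the linear-interpolation error of a
        smooth scatter field by about 4x (second-order convergence)."""
        prim = project_primary(simple_phantom, geom, 0.0).pixels
        truth = ScatterSimulator(geom, scatter_params).shape(prim)
        _, v = detector_coords(geom)
        errs = {}
        for w in (20.0, 10.0, 5.0):
            mask = sc.build_mask(sc.MSCSpec(w), geom, "A")
            vc, smp = sc.sample_closed_scatter(truth, mask, geom, mode="band")
            est = sc.interpolate_scatter(vc, smp, geom, method="linear",
                                         extrapolation="constant")
            open_rows = np.zeros(len(v), bool)
            for lo, hi in mask.open_bands:
                open_rows |= (v >= lo) & (v < hi)
            sel = (np.abs(v) <= 60.0) & open_rows
            errs[w] = np.abs(est.values - truth)[sel].max()
        assert errs[20.0] / errs[10.0] >= 3.4
        assert errs[10.0] / errs[5.0] >= 3.4


class TestSubtractMerge:
    def test_exact_estimate_recovers_masked_primary(self, geom, simple_phantom,
                                                    scatter_params):
        pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(10.0), scatter_params,
                          angles=np.array([0.0]))
        truth = pair.truth_scatter_a.pixels[0]
        est = sc.ScatterEstimate(values=truth, v_centers=np.array([0.0, 1.0]),
                                 samples=np.zeros((2, geom.n_u)))
        half, clipped = sc.subtract_scatter(pair.stack_a.pixels[0], est,
                                            pair.mask_a, geom)
        expected = pair.mask_a.values * pair.truth_primary.pixels[0]
        assert np.allclose(half, expected, atol=1e-12)
        assert clipped == 0

    def test_oversubtraction_clips_to_zero_and_counts(self, geom, mask10):
        pix = np.full((geom.n_v, geom.n_u), 0.5)
        est = sc.ScatterEstimate(values=np.ones_like(pix),
                                 v_centers=np.array([0.0, 1.0]),
                                 samples=np.zeros((2, geom.n_u)))
        half, clipped = sc.subtract_scatter(pix, est, mask10, geom)
        assert np.all(half == 0.0)
        assert clipped == int(mask10.values.sum())

    def test_zero_estimate_returns_masked_total(self, geom, mask10):
        pix = np.random.default_rng(3).uniform(0.1, 1.0, (geom.n_v, geom.n_u))
        est = sc.ScatterEstimate(values=np.zeros_like(pix),
                                 v_centers=np.array([0.0, 1.0]),
                                 samples=np.zeros((2, geom.n_u)))
        half, _ = sc.subtract_scatter(pix, est, mask10, geom)
        assert np.array_equal(half, mask10.values * pix)

    def test_merge_is_partition_sum_for_ideal_masks(self, geom):
        msc = sc.MSCSpec(10.0)
        a = sc.build_mask(msc, geom, "A")
        b = sc.build_mask(msc, geom, "B")
        ha = a.values * 2.0
        hb = b.values * 3.0
        merged = sc.merge_pair(ha, hb, a, b)
        assert np.array_equal(merged, ha + hb)
        assert np.array_equal(sc.merge_pair(ha, np.zeros_like(hb), a, b), ha)

    def test_merge_rejects_mismatched_angles(self, geom):
        msc = sc.MSCSpec(10.0)
        a = sc.build_mask(msc, geom, "A")
        b = sc.build_mask(msc, geom, "B")
        z = np.zeros((geom.n_v, geom.n_u))
        with pytest.raises(PairingError):
            sc.merge_pair(z, z, a, b, angle_a=0.0, angle_b=1.0)

    def test_soft_edge_merge_renormalizes(self, geom):
        msc = sc.MSCSpec(10.0, soft_edge_sigma=2.0)
        a = sc.build_mask(msc, geom, "A")
        b = sc.build_mask(msc, geom, "B")
        prim = np.full((geom.n_v, geom.n_u), 5.0)
        merged = sc.merge_pair(a.values * prim, b.values * prim, a, b)
        assert np.allclose(merged, prim, rtol=1e-9)


class TestCorrectStack:
    def test_zero_scatter_stack_identity(self, geom, simple_phantom):
        """With no scatter the merged corrected stack equals the primary
        stack bitwise."""
        pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(10.0), None,
                          angles=np.arange(0.0, 360.0, 30.0))
        corrected, report = sc.correct_stack(pair)
        assert np.array_equal(corrected.pixels, pair.truth_primary.pixels)
        assert report["max_residual_vs_primary"] == 0.0

    def test_correction_never_increases_any_pixel(self, geom, simple_phantom,
                                                  scatter_params):
        pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(20.0), scatter_params,
                          angles=np.array([0.0]))
        corrected, _ = sc.correct_stack(pair)
        raw_merged = pair.stack_a.pixels + pair.stack_b.pixels
        assert np.all(corrected.pixels <= raw_merged + 1e-15)

    def test_idempotent_on_scatter_free_data(self, geom, simple_phantom):
        """Re-masking an already-corrected zero-scatter stack and correcting
        again changes nothing."""
        angles = np.array([0.0, 120.0, 240.0])
        pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(10.0), None, angles=angles)
        corrected, _ = sc.correct_stack(pair)
        pair2 = sc.AcquisitionPair(
            stack_a=sc.ProjectionStack(angles, pair.mask_a.values * corrected.pixels,
                                       sc.Plane.TOTAL),
            stack_b=sc.ProjectionStack(angles, pair.mask_b.values * corrected.pixels,
                                       sc.Plane.TOTAL),
            mask_a=pair.mask_a, mask_b=pair.mask_b, geometry=geom, msc=pair.msc,
        )
        corrected2, _ = sc.correct_stack(pair2)
        assert np.array_equal(corrected2.pixels, corrected.pixels)

    def test_mismatched_phase_stacks_rejected(self, geom, simple_phantom):
        pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(10.0), None,
                          angles=np.array([0.0, 90.0]))
        pair.stack_b.angles = np.array([0.0, 91.0])
        with pytest.raises(PairingError):
            sc.correct_stack(pair)

    def test_corrected_ap_view_matches_primary_within_two_percent(self, geom,
                                                                  ap_bench):
        """End-to-end w=10 simple-phantom bench: central z profile within 2%."""
        pair, corrected = ap_bench[("simple", 10.0)]
        cu = geom.n_u // 2
        prim = pair.truth_primary.pixels[0][:, cu]
        res = sc.relative_error_profile(corrected.pixels[0][:, cu], prim,
                                        reference_floor=0.01 * prim.max())
        assert res["max_abs"] <= 2.0

    def test_correct_view_reports_estimates(self, geom, simple_phantom,
                                            scatter_params):
        pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(10.0), scatter_params,
                          angles=np.array([0.0]))
        cp = correct_view(pair.stack_a.pixels[0], pair.stack_b.pixels[0], pair, 0.0)
        assert cp.estimate_a is not None and cp.estimate_b is not None
        assert np.all(cp.estimate_a.values >= 0)
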