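"""Surround subtraction/addition, smoothing, masking, epoch averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvrquant import (
    AcquisitionTimeline,
    ProcessedSeries,
    compute_wb_mask,
    epoch_average,
    make_phantom_masks,
    roi_time_course,
    smooth_gaussian,
    surround_add,
    surround_subtract,
)


def alternating(control, label, n, first="control"):
    s = np.empty(n)
    if first == "control":
        s[0::2], s[1::2] = control, label
    else:
        s[0::2], s[1::2] = label, control
    return s


def surround_subtract_bruteforce(s, first="control"):
    """Loop reference: dM_i = parity * (s_i - mean of available neighbours)."""
    n = len(s)
    out = np.empty(n)
    for i in range(n):
        sign = 1.0 if (i % 2 == 0) == (first == "control") else -1.0
        if i == 0:
            nb = s[1]
        elif i == n - 1:
            nb = s[n - 2]
        else:
            nb = 0.5 * (s[i - 1] + s[i + 1])
        out[i] = sign * (s[i] - nb)
    return out


class TestSmoothGaussian:
    def test_fwhm_zero_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 4, 6))
        assert smooth_gaussian(vol, 0.0, 2.0) is vol

    def test_constant_preserved(self):
        vol = np.full((10, 10, 6), 3.5)
        out = smooth_gaussian(vol, 4.0, 2.0)
        np.testing.assert_allclose(out, 3.5, rtol=1e-12)

    def test_delta_kernel_ratio(self):
        # neighbour/centre ratio of a smoothed delta equals the sampled
        # Gaussian kernel ratio exp(-1 / (2 sigma_vox^2))
        fwhm, voxel = 4.0, 2.0
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = smooth_gaussian(vol, fwhm, voxel)
        ratio = out[8, 7, 7] / out[7, 7, 7]
        assert ratio == pytest.approx(np.exp(-1 / (2 * sigma_vox**2)), rel=1e-6)

    def test_anisotropic_voxels_per_axis(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = smooth_gaussian(vol, 6.0, (2.0, 3.0, 6.0))
        # sigma in voxels is largest along the finest-sampled axis, so the
        # delta spreads farthest (largest neighbour value) along that axis
        assert out[8, 7, 7] > out[7, 8, 7] > out[7, 7, 8]

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((8, 8, 4)), -1.0, 2.0)


class TestComputeWbMask:
    def test_recovers_phantom_wb(self, small_masks):
        mean_vol = np.where(small_masks.wb, 800.0, 0.0)
        rec = compute_wb_mask(mean_vol)
        overlap = (rec & small_masks.wb).sum() / small_masks.wb.sum()
        assert overlap >= 0.99

    def test_all_zero_volume_errors(self):
        with pytest.raises(ValueError):
            compute_wb_mask(np.zeros((8, 8, 4)))

    def test_threshold_zero_keeps_all_positive_voxels(self):
        vol = np.zeros((8, 8, 4))
        vol[2:6, 2:6, 1:3] = 1.0
        rec = compute_wb_mask(vol, threshold_frac=0.0)
        assert np.array_equal(rec, vol > 0)


class TestSurroundSubtract:
    def test_constant_control_label_difference(self):
        s = alternating(102.0, 100.0, 10)
        out = surround_subtract(s).values
        np.testing.assert_allclose(out, 2.0, rtol=1e-12)

    def test_label_first_parity(self):
        s = alternating(102.0, 100.0, 10, first="label")
        out = surround_subtract(s, first_volume_type="label").values
        np.testing.assert_allclose(out, 2.0, rtol=1e-12)

    def test_linear_drift_cancels_at_interior_points(self):
        s = alternating(102.0, 100.0, 12)
        drifted = s + 0.7 * np.arange(12)
        out = surround_subtract(drifted).values
        np.testing.assert_allclose(out[1:-1], 2.0, rtol=1e-12)
        assert abs(out[0] - 2.0) > 0.1 and abs(out[-1] - 2.0) > 0.1

    def test_identical_volumes_give_zero(self):
        out = surround_subtract(np.full(8, 5.0)).values
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            surround_subtract(np.array([1.0, 2.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=3, max_size=12,
        ),
        st.sampled_from(["control", "label"]),
    )
    def test_matches_bruteforce_on_short_series(self, values, first):
        s = np.array(values)
        out = surround_subtract(s, first_volume_type=first).values
        np.testing.assert_allclose(
            out, surround_subtract_bruteforce(s, first), rtol=1e-12, atol=1e-9
        )

    def test_linearity(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        fa = surround_subtract(a).values
        fb = surround_subtract(b).values
        fab = surround_subtract(a + b).values
        np.testing.assert_allclose(fab, fa + fb, rtol=1e-10, atol=1e-12)

    def test_4d_matches_1d_per_voxel(self, rng):
        vol = rng.normal(size=(3, 2, 2, 9))
        out = surround_subtract(vol).values
        for idx in np.ndindex(3, 2, 2):
            np.testing.assert_allclose(
                out[idx], surround_subtract(vol[idx]).values, rtol=1e-12
            )


class TestSurroundAdd:
    def test_cancels_alternation(self):
        s = alternating(102.0, 100.0, 10)
        out = surround_add(s).values
        np.testing.assert_allclose(out, 101.0, rtol=1e-12)

    def test_constant_unchanged(self):
        out = surround_add(np.full(8, 7.0)).values
        np.testing.assert_allclose(out, 7.0, rtol=1e-12)

    def test_step_preserved_with_one_sample_blur(self):
        s = np.concatenate([np.zeros(10), np.ones(10)])
        out = surround_add(s).values
        np.testing.assert_allclose(out[:9], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[11:], 1.0, rtol=1e-12)
        assert 0.0 < out[9] < 1.0 and 0.0 < out[10] < 1.0

    def test_linearity(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        np.testing.assert_allclose(
            surround_add(a + b).values,
            surround_add(a).values + surround_add(b).values,
            rtol=1e-10, atol=1e-12,
        )


class TestRoiTimeCourse:
    def _series(self, arr):
        return ProcessedSeries(values=arr, kind="bold", sampling_interval=1.0)

    def test_single_voxel(self, rng):
        vol = rng.normal(size=(3, 3, 2, 5))
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[1, 2, 0] = True
        np.testing.assert_array_equal(
            roi_time_course(self._series(vol), mask), vol[1, 2, 0]
        )

    def test_two_voxel_mean(self):
        vol = np.zeros((2, 1, 1, 4))
        vol[0, 0, 0], vol[1, 0, 0] = 1.0, 3.0
        mask = np.ones((2, 1, 1), dtype=bool)
        np.testing.assert_allclose(
            roi_time_course(self._series(vol), mask), 2.0
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_time_course(
                self._series(np.zeros((2, 2, 2, 4))), np.zeros((2, 2, 2), bool)
            )


class TestEpochAverage:
    def _tl(self):
        return AcquisitionTimeline(
            tr=1.0, n_volumes=600, gas_switch_time=240.0,
            ra_window=(0.0, 240.0), hc_window=(360.0, 600.0),
        )

    def _series(self, values):
        return ProcessedSeries(
            values=values, kind="bold", sampling_interval=1.0
        )

    def test_step_series_ignores_transition(self, rng):
        tl = self._tl()
        t = tl.volume_times
        vals = np.where(t < 240.0, 1.0, 2.0)
        vals[(t >= 240) & (t < 360)] = rng.normal(50.0, 30.0, ((t >= 240) & (t < 360)).sum())
        means = epoch_average(self._series(vals), tl)
        assert means.s_ra == pytest.approx(1.0, abs=1e-12)
        assert means.s_hc == pytest.approx(2.0, abs=1e-12)

    def test_constant_series_equal_epochs(self):
        tl = self._tl()
        means = epoch_average(self._series(np.full(600, 4.2)), tl)
        assert means.s_ra == means.s_hc == pytest.approx(4.2)

    def test_half_open_boundary_excludes_endpoint_volume(self):
        tl = self._tl()
        vals = np.ones(600)
        vals[240] = 1e6  # acquired exactly at ra_window end: must not count
        means = epoch_average(self._series(vals), tl)
        assert means.s_ra == pytest.approx(1.0, abs=1e-12)

    def test_middle_window_invariance(self, rng):
        tl = self._tl()
        base = rng.normal(size=600)
        modified = base.copy()
        sel = (tl.volume_times >= 250) & (tl.volume_times < 350)
        modified[sel] += rng.normal(0, 100, sel.sum())
        a = epoch_average(self._series(base), tl)
        b = epoch_average(self._series(modified), tl)
        assert a.s_ra == b.s_ra and a.s_hc == b.s_hc
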