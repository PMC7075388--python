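"""Profiles, IEC flatness, gamma index and the dip metric."""
import numpy as np
import pytest

from flatbeam.dose import DoseMap
from flatbeam.metrics import (Profile, dip_depth, extract_profile,
                              gamma_pass_rate, iec_flatness, tng_dip_metric)


def flat_map(value=1.0, half=6.0, res=0.2):
    n = int(round(2 * half / res)) + 1
    vals = np.full((n, n), value)
    return DoseMap(vals, res, -half, -half)


def smooth_random_map(seed, half=6.0, res=0.2):
    rng = np.random.default_rng(seed)
    n = int(round(2 * half / res)) + 1
    from scipy.ndimage import gaussian_filter
    vals = gaussian_filter(rng.random((n, n)), sigma=6) + 0.5
    return DoseMap(vals, res, -half, -half)


def brute_force_gamma(eval_map, ref_map, dose_crit, dta_cm, threshold):
    """Independent O(n^2 m^2) local-gamma oracle with fine interpolation."""
    from scipy.interpolate import RegularGridInterpolator
    cax = ref_map.cax_value()
    interp = RegularGridInterpolator((ref_map.y, ref_map.x), ref_map.values,
                                     bounds_error=False, fill_value=np.nan)
    step = dta_cm / 10.0
    span = 3.0 * dta_cm
    offs = np.arange(-span, span + step / 2, step)
    OY, OX = np.meshgrid(offs, offs, indexing="ij")
    disk = (OY ** 2 + OX ** 2) <= span ** 2 + 1e-12
    gammas = []
    for iy, y in enumerate(eval_map.y):
        for ix, x in enumerate(eval_map.x):
            r = interp([[y, x]])[0]
            if not np.isfinite(r) or r < threshold / 100.0 * cax:
                continue
            d = eval_map.values[iy, ix]
            pts = np.stack([(y + OY[disk]).ravel(), (x + OX[disk]).ravel()],
                           axis=1)
            rv = interp(pts)
            dist2 = (OY[disk] ** 2 + OX[disk] ** 2) / dta_cm ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                g2 = ((d - rv) / (dose_crit / 100.0 * np.abs(rv))) ** 2 + dist2
            g2 = np.where(np.isfinite(g2), g2, np.inf)
            gammas.append(np.sqrt(g2.min()))
    gammas = np.array(gammas)
    return 100.0 * float((gammas <= 1.0).sum()) / len(gammas)


class TestProfile:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            Profile(np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]))

    def test_extract_normalizes_cax_to_one(self):
        d = flat_map(7.3)
        p = extract_profile(d, "crossline")
        assert p.values[len(p.values) // 2] == pytest.approx(1.0)

    def test_symmetric_map_gives_symmetric_profile(self):
        d = flat_map()
        d.values[:] += np.exp(-(d.x[None, :] ** 2) / 8.0)
        p = extract_profile(d, "crossline")
        np.testing.assert_allclose(p.values, p.values[::-1], atol=1e-6)

    def test_inline_axis_and_offset(self):
        d = flat_map()
        d.values[d.values.shape[0] // 2 + 5, :] = 2.0  # stripe at y = +1
        p = extract_profile(d, "inline", offset=0.0)
        assert p.values[np.argmin(np.abs(p.positions - 1.0))] == pytest.approx(2.0)

    def test_offset_outside_map_rejected(self):
        with pytest.raises(ValueError):
            extract_profile(flat_map(), "crossline", offset=100.0)

    def test_reference_field_fwhm(self, machine):
        from flatbeam.beam import flat_reference_beam
        from flatbeam.contours import builtin_contour
        from flatbeam.dose import reference_flat_dose
        from flatbeam.grid import rasterize_contour
        grid = rasterize_contour(builtin_contour("square", side=10.0),
                                 machine, 0.2)
        ref = reference_flat_dose(grid, flat_reference_beam(), resolution=0.1)
        p = extract_profile(ref, "crossline")
        above = p.positions[p.values >= 0.5]
        assert above[-1] - above[0] == pytest.approx(10.0, abs=0.1)


class TestFlatness:
    def test_uniform_profile_zero(self):
        p = Profile(np.linspace(-6, 6, 61), np.ones(61))
        assert iec_flatness(p, (-5.0, 5.0)) == 0.0

    def test_textbook_value(self):
        pos = np.linspace(-6, 6, 121)
        vals = np.ones(121)
        vals[np.abs(pos) < 4.0] = 1.03
        vals[np.abs(pos) < 2.0] = 0.97
        p = Profile(pos, vals)
        # Dmax=1.03, Dmin=0.97 -> 100*0.06/2.00 = 3.0
        assert iec_flatness(p, (-5.0, 5.0)) == pytest.approx(3.0)

    def test_scaling_invariance(self):
        pos = np.linspace(-6, 6, 121)
        rng = np.random.default_rng(0)
        vals = 1.0 + 0.05 * rng.random(121)
        p1 = Profile(pos, vals)
        p2 = Profile(pos, 7.7 * vals)
        assert iec_flatness(p1, (-5, 5)) == pytest.approx(
            iec_flatness(p2, (-5, 5)))

    def test_profile_must_span_bounds(self):
        p = Profile(np.linspace(-2, 2, 21), np.ones(21))
        with pytest.raises(ValueError):
            iec_flatness(p, (-5.0, 5.0))


class TestGamma:
    def test_identical_maps_all_zero(self):
        d = smooth_random_map(1)
        g = gamma_pass_rate(d, d)
        assert g.pass_fraction == 100.0
        assert np.nanmax(g.gamma) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_two_percent_offset_on_flat_reference(self):
        ref = flat_map(1.0)
        ev = flat_map(1.02)
        g = gamma_pass_rate(ev, ref, dose_crit=3.0, dta_mm=3.0)
        inc = np.isfinite(g.gamma)
        np.testing.assert_allclose(g.gamma[inc], 2.0 / 3.0, atol=1e-6)
        assert g.pass_fraction == 100.0

    def test_uniform_five_percent_offset_fails_everywhere(self):
        ref = flat_map(1.0)
        ev = flat_map(1.05)
        g = gamma_pass_rate(ev, ref, dose_crit=3.0, dta_mm=3.0)
        inc = np.isfinite(g.gamma)
        np.testing.assert_allclose(g.gamma[inc], 5.0 / 3.0, atol=1e-6)
        assert g.pass_fraction == 0.0

    def test_asymmetric_in_eval_and_ref(self):
        ref = smooth_random_map(2)
        ev = DoseMap(ref.values * (1 + 0.04 * np.sign(ref.x)[None, :]),
                     ref.resolution, ref.x0, ref.y0)
        g1 = gamma_pass_rate(ev, ref).pass_fraction
        g2 = gamma_pass_rate(ref, ev).pass_fraction
        assert g1 != pytest.approx(g2, abs=1e-6)

    def test_below_threshold_voxels_excluded(self):
        ref = flat_map(1.0, half=4.0)
        ref.values[:, ref.x < -2.0] = 0.01     # below the 10% cut
        ev = DoseMap(ref.values * 1.5, ref.resolution, ref.x0, ref.y0)
        g = gamma_pass_rate(ev, ref)
        assert np.all(~np.isfinite(g.gamma[:, ref.x < -2.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        ref = smooth_random_map(seed, half=2.0, res=0.4)
        rng = np.random.default_rng(100 + seed)
        from scipy.ndimage import gaussian_filter
        pert = 1.0 + 0.03 * gaussian_filter(rng.normal(size=ref.values.shape), 2)
        ev = DoseMap(ref.values * pert, ref.resolution, ref.x0, ref.y0)
        fast = gamma_pass_rate(ev, ref, dose_crit=2.0, dta_mm=3.0).pass_fraction
        slow = brute_force_gamma(ev, ref, dose_crit=2.0, dta_cm=0.3,
                                 threshold=10.0)
        assert fast == pytest.approx(slow, abs=0.5)

    def test_all_below_threshold_raises(self):
        ref = flat_map(0.0)
        ref.values[0, 0] = 1e-12
        with pytest.raises(ValueError):
            gamma_pass_rate(flat_map(1.0), ref)


class TestDipMetric:
    def _notched(self, depth, width=0.8):
        pos = np.linspace(-8, 8, 321)
        vals = np.ones_like(pos)
        vals -= depth * np.exp(-((pos - 1.0) / (width / 2.355)) ** 2 / 2)
        return Profile(pos, vals)

    def test_identical_profiles_zero_difference(self):
        p = self._notched(0.05)
        r = tng_dip_metric(p, p)
        assert r.difference == pytest.approx(0.0)

    def test_single_notch_depth_recovered(self):
        smooth = Profile(np.linspace(-8, 8, 321), np.ones(321))
        notched = self._notched(0.05)
        r = tng_dip_metric(notched, smooth)
        assert r.depth_with == pytest.approx(0.0, abs=1e-6)
        assert r.depth_without == pytest.approx(5.0, rel=0.05)
        assert r.difference == pytest.approx(5.0, rel=0.05)

    def test_narrow_noise_features_ignored(self):
        pos = np.linspace(-8, 8, 321)
        vals = np.ones_like(pos)
        vals[160] = 0.9    # single-sample spike, well under 0.5 cm wide
        assert dip_depth(Profile(pos, vals)) == 0.0

    def test_mismatched_grids_rejected(self):
        p1 = Profile(np.linspace(-8, 8, 321), np.ones(321))
        p2 = Profile(np.linspace(-8, 8, 161), np.ones(161))
        with pytest.raises(ValueError):
            tng_dip_metric(p1, p2)
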