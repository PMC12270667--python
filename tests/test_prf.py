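"""Divisive-normalization pRF model, size tuning, and stimulus derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamline.prf import (
    PRFParams,
    ScreenGeometry,
    StimulusSpec,
    SizeTuningCurve,
    design_stimulus_set,
    disc_mask,
    dn_response,
    filter_prf_candidates,
    largest_annulus_radius,
    medium_annulus_radius,
    optimal_center_size,
    render_checkerboard,
    size_tuning_curve,
    spatial_profile_markers,
)


class TestDNResponse:
    def test_empty_stimulus_gives_zero(self, excitatory_prf, screen):
        mask = np.zeros_like(disc_mask(1.0, (0, 0), screen))
        assert dn_response(mask, excitatory_prf, screen) == pytest.approx(0.0, abs=1e-12)

    def test_full_field_matches_gaussian_integral(self, excitatory_prf, screen):
        """Without normalization the response is the raster sum of G1, which
        approximates the analytic integral amp_act * 2*pi*sigma1^2 px^2."""
        mask = np.ones_like(disc_mask(1.0, (0, 0), screen))
        got = dn_response(mask, excitatory_prf, screen)
        expected = 2 * np.pi * excitatory_prf.sigma1**2 * screen.pixels_per_dva**2
        assert got == pytest.approx(expected, rel=1e-3)

    def test_disc_matches_encircled_energy(self, excitatory_prf):
        """Centered disc of radius r: closed-form encircled Gaussian energy
        amp_act * (1 - exp(-r^2 / (2 sigma1^2))) * 2 pi sigma1^2 px^2."""
        fine = ScreenGeometry(8.0, 4.5, 50.0)
        for r in (0.5, 1.0, 2.0):
            mask = disc_mask(r, (excitatory_prf.x, excitatory_prf.y), fine)
            got = dn_response(mask, excitatory_prf, fine)
            s2 = excitatory_prf.sigma1**2
            expected = (1 - np.exp(-(r**2) / (2 * s2))) * 2 * np.pi * s2 * fine.pixels_per_dva**2
            # raster quantization at the disc edge dominates at small radii
            assert got == pytest.approx(expected, rel=1e-2)

    def test_truncated_support_warns(self, screen):
        prf = PRFParams(x=7.0, y=0.0, sigma1=1.0, sigma2=2.0)
        mask = disc_mask(1.0, (7.0, 0.0), screen)
        with pytest.warns(UserWarning, match="truncated pRF support"):
            dn_response(mask, prf, screen)

    @given(dx=st.floats(-2, 2), dy=st.floats(-1, 1))
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, dx, dy):
        """Translating stimulus and pRF jointly leaves the response unchanged
        (up to pixel-sampling error)."""
        screen = ScreenGeometry(8.0, 4.5, 10.0)
        base = PRFParams(x=0.0, y=0.0, sigma1=0.8, sigma2=1.6, amp_norm=0.5, d=1.0)
        moved = PRFParams(x=dx, y=dy, sigma1=0.8, sigma2=1.6, amp_norm=0.5, d=1.0)
        r0 = dn_response(disc_mask(1.0, (0.0, 0.0), screen), base, screen)
        r1 = dn_response(disc_mask(1.0, (dx, dy), screen), moved, screen)
        assert r1 == pytest.approx(r0, rel=0.02, abs=1e-3)


class TestSizeTuning:
    def test_no_suppression_is_monotone(self, excitatory_prf, screen):
        """No normalization pool means no surround suppression: the curve is
        non-decreasing with no interior peak, and the largest radius attains
        the maximum (a plateau appears once the disc covers the screen)."""
        curve = size_tuning_curve(excitatory_prf, screen, n_radii=51)
        assert np.all(np.diff(curve.responses) >= -1e-12)
        assert curve.responses[-1] == pytest.approx(curve.responses.max(), rel=1e-12)

    def test_zero_radius_gives_zero(self, suppressive_prf, screen):
        curve = size_tuning_curve(suppressive_prf, screen, n_radii=21)
        assert curve.responses[0] == pytest.approx(0.0, abs=1e-12)

    def test_interior_peak_matches_fine_grid_oracle(self, suppressive_prf, screen):
        """The 101-point argmax agrees with a brute-force 1001-point search
        within one coarse grid step."""
        coarse = size_tuning_curve(suppressive_prf, screen, n_radii=101)
        fine = size_tuning_curve(suppressive_prf, screen, n_radii=1001)
        r_coarse = optimal_center_size(coarse)
        r_fine = fine.radii[np.argmax(fine.responses)]
        assert 0 < r_fine < 10.0  # genuinely interior peak
        assert abs(r_coarse - r_fine) <= 10.0 / 100


class TestOptimalCenterSize:
    def test_hand_examples(self):
        curve = SizeTuningCurve([0, 1, 2, 3], [0, 1, 3, 2])
        assert optimal_center_size(curve) == 2
        mono = SizeTuningCurve(np.linspace(0, 10, 11), np.arange(11, dtype=float))
        assert optimal_center_size(mono) == 10

    def test_tie_goes_to_smaller_radius(self):
        curve = SizeTuningCurve([0, 1, 2], [0.0, 5.0, 5.0])
        assert optimal_center_size(curve) == 1

    def test_flat_curve_raises(self):
        with pytest.raises(ValueError, match="flat tuning curve"):
            optimal_center_size(SizeTuningCurve([0, 1], [2.0, 2.0]))


class TestAnnulusGeometry:
    def test_smallest_edge_distance(self, screen):
        prf = PRFParams(x=2.0, y=1.0, sigma1=1.0, sigma2=1.0)
        assert largest_annulus_radius(prf, screen) == pytest.approx(3.5)

    def test_centered_prf(self, screen):
        prf = PRFParams(x=0.0, y=0.0, sigma1=1.0, sigma2=1.0)
        assert largest_annulus_radius(prf, screen) == pytest.approx(4.5)

    def test_horizontal_midline(self, screen):
        prf = PRFParams(x=1.3, y=0.0, sigma1=1.0, sigma2=1.0)
        assert largest_annulus_radius(prf, screen) == pytest.approx(screen.half_height)

    def test_off_screen_prf_raises(self, screen):
        with pytest.raises(ValueError):
            largest_annulus_radius(PRFParams(x=9.0, y=0.0, sigma1=1.0, sigma2=1.0), screen)

    def test_outer_radius_fits_on_screen(self, screen):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(-7, 7)
            y = rng.uniform(-4, 4)
            prf = PRFParams(x=x, y=y, sigma1=1.0, sigma2=1.0)
            r = largest_annulus_radius(prf, screen)
            assert r <= min(screen.half_width, screen.half_height) + prf.eccentricity + 1e-9
            # the ring touches but never crosses the constraining edge
            assert r <= min(
                screen.half_width - abs(x), screen.half_height - abs(y)
            ) + 2 * max(abs(x), abs(y)) + 1e-9

    def test_medium_halfway(self):
        mid, ring = medium_annulus_radius(1.0, 5.0)
        assert mid == 3.0 and ring == (2.0, 4.0)
        mid, _ = medium_annulus_radius(1.4, 6.0)
        assert mid == pytest.approx(3.7)

    def test_medium_overlap_warns(self):
        with pytest.warns(UserWarning, match="overlap"):
            mid, ring = medium_annulus_radius(1.0, 3.0)
        assert mid == 2.0 and ring == (1.0, 3.0)


class TestCheckerboard:
    spec = StimulusSpec("large", inner_radius=1.5, outer_radius=3.5)

    def test_zero_outside_ring(self, excitatory_prf, screen):
        img = render_checkerboard(self.spec, excitatory_prf, screen)
        X, Y = screen.grids()
        r = np.hypot(X - excitatory_prf.x, Y - excitatory_prf.y)
        assert np.all(img[r > self.spec.outer_radius] == 0)
        assert np.all(img[r < self.spec.inner_radius] == 0)
        assert np.any(img != 0)

    def test_phase_inverts_contrast(self, excitatory_prf, screen):
        a = render_checkerboard(self.spec, excitatory_prf, screen, phase=0)
        b = render_checkerboard(self.spec, excitatory_prf, screen, phase=1)
        assert np.array_equal(b, -a)

    def test_contrast_balance(self, excitatory_prf, screen):
        """Square waves balance dark and light checks: ring mean ~ 0."""
        img = render_checkerboard(self.spec, excitatory_prf, screen)
        ring = img[img != 0]
        assert abs(ring.mean()) < 0.02

    def test_area_stable_across_resolutions(self, excitatory_prf):
        areas = []
        for ppd in (20.0, 40.0):
            scr = ScreenGeometry(8.0, 4.5, ppd)
            img = render_checkerboard(self.spec, excitatory_prf, scr)
            areas.append(np.count_nonzero(img) / ppd**2)
        assert areas[1] == pytest.approx(areas[0], rel=0.02)


class TestSpatialMarkers:
    def test_gaussian_fwhm_closed_form(self):
        prf = PRFParams(x=0, y=0, sigma1=0.9, sigma2=0.9, amp_norm=0.0)
        (lo, hi), zc = spatial_profile_markers(prf)
        assert hi - lo == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.9, rel=1e-4)
        assert zc is None

    def test_zero_crossing_matches_grid_scan(self, suppressive_prf):
        """Sign change of the DN profile located by brute-force bracketing on
        a 2001-point grid."""
        prf = PRFParams(x=0, y=0, sigma1=0.8, sigma2=2.4, amp_act=1.0,
                        amp_norm=0.5, b=0.2, d=0.4)
        rs = np.linspace(0, 10, 2001)
        g1 = np.exp(-(rs**2) / (2 * prf.sigma1**2))
        g2 = np.exp(-(rs**2) / (2 * prf.sigma2**2))
        p = (prf.amp_act * g1 + prf.b) / (prf.amp_norm * g2 + prf.d) - prf.b / prf.d
        signchange = np.nonzero(np.diff(np.sign(p)))[0]
        assert signchange.size > 0, "fixture must produce a suppressive lobe"
        _, zc = spatial_profile_markers(prf)
        assert zc is not None
        assert rs[signchange[0]] <= zc[1] <= rs[signchange[0] + 1]


class TestCandidateFilter:
    def test_kept_and_boundary_rows(self):
        table = pd.DataFrame(
            {
                "eccentricity": [2.0, 2.0],
                "merid_dist": [1.5, 1.5],
                "r2": [0.6, 0.55],  # second row sits on the strict boundary
                "sigma1": [0.7, 0.7],
            }
        )
        out = filter_prf_candidates(table)
        assert list(out.index) == [0]

    def test_toy_table_single_survivor(self):
        """Four rows each violating a different rule except one."""
        table = pd.DataFrame(
            {
                "eccentricity": [2.0, 1.0, 2.5, 2.0],
                "merid_dist": [1.2, 1.5, 0.5, 1.5],
                "r2": [0.70, 0.70, 0.70, 0.70],
                "sigma1": [0.8, 0.8, 0.8, 0.4],
            }
        )
        out = filter_prf_candidates(table)
        assert len(out) == 1 and out.index[0] == 0

    def test_empty_result_warns(self):
        table = pd.DataFrame(
            {"eccentricity": [5.0], "merid_dist": [2.0], "r2": [0.9], "sigma1": [1.0]}
        )
        with pytest.warns(UserWarning):
            out = filter_prf_candidates(table)
        assert out.empty


def test_design_stimulus_set_geometry(suppressive_prf, screen):
    """The derived set is a center disc, and two 2-dva-wide annuli with the
    medium ring halfway between the center and large stimuli."""
    stimuli = design_stimulus_set(suppressive_prf, screen)
    center, medium, large = stimuli["center"], stimuli["medium"], stimuli["large"]
    assert center.inner_radius == 0.0
    assert large.outer_radius == pytest.approx(
        largest_annulus_radius(suppressive_prf, screen)
    )
    assert large.outer_radius - large.inner_radius == pytest.approx(2.0)
    assert medium.outer_radius - medium.inner_radius == pytest.approx(2.0)
    mid = (medium.inner_radius + medium.outer_radius) / 2
    assert mid == pytest.approx((center.outer_radius + large.outer_radius) / 2)
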