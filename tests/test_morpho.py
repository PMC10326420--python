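"""Moment-ellipse fitting and cross-section/series morphometrics."""

import math

import numpy as np
import pytest

from conftest import brute_force_axes
from scmorpho import morpho, phantom, segment
from scmorpho.morpho import CrossSectionMorphometry


def _fit_mask(mask, lat=1.0, ax=1.0):
    (c,) = segment.extract_components(mask, lat, ax)
    return morpho.fit_ellipse(c)


class TestFitEllipse:
    def test_square_closed_form(self):
        a = 12
        mask = np.zeros((a + 4, a + 4), bool)
        mask[2 : 2 + a, 2 : 2 + a] = True
        fit = _fit_mask(mask)
        expected = 2 * a / math.sqrt(3)
        assert fit.major_axis_um == pytest.approx(expected, rel=1e-12)
        assert fit.minor_axis_um == pytest.approx(expected, rel=1e-12)

    def test_disk_axes(self):
        rr, cc = np.mgrid[0:50, 0:50]
        mask = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20**2
        fit = _fit_mask(mask)
        assert fit.major_axis_um == pytest.approx(40.0, rel=0.01)
        assert fit.minor_axis_um == pytest.approx(40.0, rel=0.01)
        major, minor = brute_force_axes(mask, 1.0, 1.0)
        assert fit.major_axis_um == pytest.approx(major, rel=1e-9)
        assert fit.minor_axis_um == pytest.approx(minor, rel=1e-9)

    def test_phantom_ellipse_on_oct_grid(self):
        spec = phantom.PhantomSpec(width0_um=280, height0_um=26, n_bscans=2)
        stack, truth = phantom.generate_mask_stack(spec, 0.0, seed=1)
        (c,) = segment.extract_components(stack.masks[0], 7.0, 1.3)
        fit = morpho.fit_ellipse(c)
        assert fit.major_axis_um == pytest.approx(truth.width_um, rel=0.03)
        assert fit.minor_axis_um == pytest.approx(truth.height_um, rel=0.03)

    def test_single_pixel_component_never_degenerate(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        fit = _fit_mask(mask, lat=7.0, ax=1.3)
        assert fit.major_axis_um == pytest.approx(2 * 7.0 / math.sqrt(3), rel=1e-12)
        assert fit.minor_axis_um == pytest.approx(2 * 1.3 / math.sqrt(3), rel=1e-12)

    def test_matches_skimage_regionprops_on_isotropic_grid(self, rng):
        """Independent toolbox cross-check (pixel units, so 1 um/px).

        skimage's axis lengths are 4*sqrt(eigenvalue) of the uncorrected
        covariance; adding the isotropic 1/12 pixel-extent term shifts both
        eigenvalues by exactly 1/12, which maps its convention onto ours.
        """
        from skimage.measure import regionprops

        for _ in range(5):
            mask = np.zeros((40, 40), bool)
            r0, c0 = rng.integers(10, 30, 2)
            rr, cc = np.mgrid[0:40, 0:40]
            mask |= ((rr - r0) / rng.uniform(3, 8)) ** 2 + (
                (cc - c0) / rng.uniform(3, 12)
            ) ** 2 <= 1
            props = regionprops(mask.astype(np.uint8))[0]
            fit = _fit_mask(mask)
            expect_major = 4 * math.sqrt((props.axis_major_length / 4) ** 2 + 1 / 12)
            expect_minor = 4 * math.sqrt((props.axis_minor_length / 4) ** 2 + 1 / 12)
            assert fit.major_axis_um == pytest.approx(expect_major, rel=1e-9)
            assert fit.minor_axis_um == pytest.approx(expect_minor, rel=1e-9)

    def test_rotation_invariance_on_isotropic_grid(self):
        spec = phantom.PhantomSpec(
            width0_um=80, height0_um=30, n_bscans=2,
            lateral_um_per_px=1.0, axial_um_per_px=1.0,
        )
        stack, _ = phantom.generate_mask_stack(spec, 0.0, seed=2)
        fit = _fit_mask(stack.masks[0])
        fit_rot = _fit_mask(np.rot90(stack.masks[0]).copy())
        assert fit_rot.major_axis_um == pytest.approx(fit.major_axis_um, rel=1e-12)
        assert fit_rot.minor_axis_um == pytest.approx(fit.minor_axis_um, rel=1e-12)

    def test_unit_covariance(self):
        """Scaling both pixel sizes by k scales axes by k and area by k^2."""
        rr, cc = np.mgrid[0:30, 0:30]
        mask = ((rr - 15) / 6) ** 2 + ((cc - 15) / 11) ** 2 <= 1
        k = 3.5
        (c1,) = segment.extract_components(mask, 2.0, 1.0)
        (c2,) = segment.extract_components(mask, 2.0 * k, 1.0 * k)
        f1, f2 = morpho.fit_ellipse(c1), morpho.fit_ellipse(c2)
        assert f2.major_axis_um == pytest.approx(k * f1.major_axis_um, rel=1e-12)
        assert f2.minor_axis_um == pytest.approx(k * f1.minor_axis_um, rel=1e-12)
        assert c2.area_um2 == pytest.approx(k**2 * c1.area_um2, rel=1e-12)

    def test_convergence_with_finer_pixels(self):
        errs = []
        for factor in (1.0, 0.5):
            spec = phantom.PhantomSpec(
                width0_um=240, height0_um=24, n_bscans=2,
                lateral_um_per_px=7.0 * factor, axial_um_per_px=1.3 * factor,
            )
            stack, truth = phantom.generate_mask_stack(spec, 0.0, seed=4)
            (c,) = segment.extract_components(
                stack.masks[0], spec.lateral_um_per_px, spec.axial_um_per_px
            )
            fit = morpho.fit_ellipse(c)
            errs.append(abs(fit.minor_axis_um - truth.height_um)
                        + abs(fit.major_axis_um - truth.width_um))
        assert errs[1] < errs[0]


class TestCrossSection:
    def _fits(self, pairs):
        """Build EllipseFits from (area, major, minor) triples."""
        out = []
        for area, major, minor in pairs:
            comp = segment.LumenComponent(
                bscan_index=0, pixel_count=int(area), area_um2=float(area),
                centroid_lateral_um=0, centroid_axial_um=0,
                mu20=0, mu02=0, mu11=0, lateral_um_per_px=1, axial_um_per_px=1,
                rows=np.array([0]), cols=np.array([0]),
            )
            out.append(morpho.EllipseFit(major, minor, 0.0, comp))
        return out

    def test_single_component_identity(self):
        cs = morpho.cross_section_morphometry(self._fits([(500, 210, 18)]), 0)
        assert cs.width_um == 210 and cs.height_um == 18 and cs.area_um2 == 500

    def test_area_weighted_height(self):
        cs = morpho.cross_section_morphometry(
            self._fits([(300, 150, 10), (100, 60, 6)]), 0
        )
        assert cs.height_um == pytest.approx(9.0, abs=1e-12)
        assert cs.width_um == pytest.approx(210.0)
        assert 6 <= cs.height_um <= 10  # between extreme minors

    def test_empty_section_flagged(self):
        cs = morpho.cross_section_morphometry([], 3)
        assert cs.empty and cs.area_um2 == 0.0
        assert math.isnan(cs.width_um) and math.isnan(cs.height_um)


class TestSeries:
    @staticmethod
    def _sections(areas, height=20.0, width=200.0):
        return [
            CrossSectionMorphometry(i, a, width if a else math.nan,
                                    height if a else math.nan, 1 if a else 0)
            for i, a in enumerate(areas)
        ]

    def test_constant_profile_volume_identity(self):
        sections = self._sections([1000.0] * 100)
        summary = morpho.series_morphometry(sections, 15.0, window_um=1500.0)
        assert summary.volume_um3 == pytest.approx(1.5e6, rel=1e-12)
        assert summary.length_analyzed_um == pytest.approx(1500.0)

    def test_window_restricts_sections(self):
        sections = self._sections([1000.0] * 200)
        summary = morpho.series_morphometry(sections, 15.0, window_um=1500.0)
        assert summary.n_sections_analyzed == 100
        assert summary.volume_um3 == pytest.approx(1.5e6)

    def test_empty_sections_zero_volume_but_unchanged_means(self):
        full = morpho.series_morphometry(self._sections([800.0] * 40), 10.0)
        half = morpho.series_morphometry(
            self._sections([800.0, 0.0] * 20), 10.0
        )
        assert half.volume_um3 == pytest.approx(full.volume_um3 / 2)
        assert half.mean_height_um == pytest.approx(full.mean_height_um)
        assert half.mean_width_um == pytest.approx(full.mean_width_um)

    def test_all_empty_flagged(self):
        summary = morpho.series_morphometry(self._sections([0.0] * 10), 10.0)
        assert summary.volume_um3 == 0.0
        assert math.isnan(summary.mean_height_um)

    def test_area_length_profile(self):
        profile = morpho.area_length_profile(self._sections([10.0, 20.0, 30.0]), 5.0)
        assert profile.tolist() == [[0.0, 10.0], [5.0, 20.0], [10.0, 30.0]]

    def test_noiseless_phantom_recovers_truth_height(self):
        from scmorpho import pipeline

        spec = phantom.PhantomSpec(
            width0_um=200, height0_um=24, n_bscans=10, noise_px=0.0
        )
        stack, truth = phantom.generate_mask_stack(spec, 0.0, seed=6)
        _, summary = pipeline.measure_stack(stack)
        assert summary.mean_height_um == pytest.approx(truth.height_um, rel=0.03)
        assert summary.mean_width_um == pytest.approx(truth.width_um, rel=0.03)
        assert summary.volume_um3 == pytest.approx(truth.volume_um3, rel=0.03)


class TestAuxiliaryQuantifications:
    def test_cornea_thickness_arithmetic(self):
        pairs = [
            (np.zeros(5), np.full(5, 70.0)),
            (np.zeros(5), np.full(5, 80.0)),
            (np.zeros(5), np.full(5, 90.0)),
        ]
        assert morpho.cornea_thickness(pairs, 1.3) == pytest.approx(104.0, abs=1e-9)

    def test_identical_boundaries_zero(self):
        b = np.linspace(10, 20, 7)
        assert morpho.cornea_thickness([(b, b)] * 3, 1.3) == 0.0

    def test_crossing_boundaries_rejected(self):
        with pytest.raises(ValueError, match="crosses"):
            morpho.cornea_thickness([(np.full(4, 10.0), np.full(4, 5.0))], 1.3)

    def test_known_separation_field_recovered(self, rng):
        """Synthetic wavy boundaries: recovery within one axial pixel."""
        x = np.linspace(0, 2 * np.pi, 60)
        sections = []
        true_means = []
        for k in range(3):
            anterior = 40 + 3 * np.sin(x + k)
            sep = 75 + 5 * np.cos(2 * x + k) + rng.normal(0, 0.3, x.size)
            sections.append((anterior, anterior + sep))
            true_means.append(sep.mean())
        got = morpho.cornea_thickness(sections, 1.3)
        assert got == pytest.approx(np.mean(true_means) * 1.3, abs=1.3)

    def test_sc_area_per_field(self, rng):
        masks = [rng.random((20, 20)) < 0.3 for _ in range(4)]
        expected = np.mean([m.sum() for m in masks]) * 4.0
        assert morpho.sc_area_per_field(masks, 2.0) == pytest.approx(expected)
        assert morpho.sc_area_per_field([np.zeros((5, 5))], 1.0) == 0.0
        with pytest.raises(ValueError):
            morpho.sc_area_per_field([], 1.0)
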