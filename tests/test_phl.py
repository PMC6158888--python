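"""Tests for halo-layer detection: shell, band profile, background, threshold.

The independent oracles here are geometric: an analytic spherical shell with
known thickness for the band-thickness estimator, and a closed-form
Gaussian-blurred sphere profile for the end-to-end detection on a radial
phantom.
"""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf

from halopet.core import DetectionError, ParameterError, SUVVolume, make_roi
from halopet.deciles import LayerLabelMap, WindowSettings, decile_label_map, window_top
from halopet.phantom import concentric_label_map
from halopet.phl import (
    analysis_shell,
    background_band,
    band_profile,
    detect_phl,
    segment,
    segment_phl,
)

# ---------------------------------------------------------------------------
# analysis shell


class TestAnalysisShell:
    def test_shell_covers_lesion_plus_rim(self, capsule_s10):
        vol, truth, roi, _ = capsule_s10
        shell = analysis_shell(vol, roi, margin_mm=15.0)
        assert shell[roi.seed]
        # lesion interior is inside, but clipping keeps it within the ROI box
        inside_box = np.zeros_like(shell)
        inside_box[roi.box_slices()] = True
        assert np.all(shell[truth.mask & inside_box])
        assert not shell[~inside_box].any()

    def test_margin_zero_is_supra_threshold_component(self, capsule_s10):
        vol, _, roi, _ = capsule_s10
        shell = analysis_shell(vol, roi, margin_mm=0.0)
        top = window_top(roi.suvmax)
        # every shell voxel is supra-threshold; it is one connected component
        assert np.all(vol.values[shell] >= 0.2 * top)

    def test_uniform_background_raises(self):
        vol = SUVVolume(values=np.ones((12, 12, 12)))
        roi = make_roi(vol, ((2, 9), (2, 9), (2, 9)), seed=(5, 5, 5))
        # window top 1.1 -> 20% level 0.22 < 1.0, so everything is supra;
        # shrink the box to force an empty annulus downstream instead
        labels = decile_label_map(vol, roi)
        with pytest.raises(DetectionError):
            background_band(vol, roi, labels)

    def test_seed_below_level_raises(self):
        vals = np.ones((15, 15, 15)) * 0.01
        vals[7, 7, 7] = 10.0
        vol = SUVVolume(values=vals)
        roi = make_roi(vol, ((0, 14), (0, 14), (0, 14)), seed=(1, 1, 1))
        with pytest.raises(DetectionError):
            analysis_shell(vol, roi)


# ---------------------------------------------------------------------------
# band thickness


class TestBandProfile:
    def test_analytic_spherical_shell_thickness(self):
        """A 2 mm shell (outer r 10 mm, inner r 8 mm) at 0.5 mm voxels."""
        n = 61
        v = 0.5
        c = (n - 1) / 2.0
        ii, jj, kk = np.indices((n, n, n))
        r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) * v
        labels = np.zeros((n, n, n), dtype=np.int8)
        labels[r < 10.0] = 4  # the band under test
        labels[r < 8.0] = 9  # hotter interior
        lmap = LayerLabelMap(labels=labels, window=WindowSettings(top=1.0), source_suvmax=1.0)
        shell = np.ones((n, n, n), dtype=bool)
        bands = {b.k: b for b in band_profile(lmap, shell, (v, v, v))}
        assert bands[4].thickness_mm == pytest.approx(2.0, rel=0.15)

    def test_absent_band_is_omitted(self):
        lmap, shell = concentric_label_map([(9, 6), (7, 12), (2, 20)], background_label=1)
        ks = {b.k for b in band_profile(lmap, shell, (2.65,) * 3)}
        assert ks == {1, 2, 7, 9}

    def test_tiny_band_flagged_unreliable(self):
        labels = np.zeros((8, 8, 8), dtype=np.int8)
        labels[4, 4, 4] = 5  # single voxel band
        lmap = LayerLabelMap(labels=labels, window=WindowSettings(top=1.0), source_suvmax=1.0)
        shell = np.ones((8, 8, 8), dtype=bool)
        bands = {b.k: b for b in band_profile(lmap, shell, (1.0, 1.0, 1.0))}
        assert not bands[5].reliable
        assert bands[0].reliable

    def test_empty_shell_raises(self):
        lmap = LayerLabelMap(
            labels=np.zeros((4, 4, 4), dtype=np.int8),
            window=WindowSettings(top=1.0),
            source_suvmax=1.0,
        )
        with pytest.raises(DetectionError):
            band_profile(lmap, np.zeros((4, 4, 4), dtype=bool), (1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# background band


class TestBackgroundBand:
    def _phantom_with_background(self, background, peak=13.07):
        n = 41
        v = 2.65
        c = (n - 1) / 2.0
        ii, jj, kk = np.indices((n, n, n))
        r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) * v
        vals = np.full((n, n, n), background)
        vals[r <= 8.0] = peak
        vol = SUVVolume(values=vals)
        roi = make_roi(vol, ((8, 32), (8, 32), (8, 32)))
        return vol, roi

    def test_low_background_is_layer_zero(self):
        """B=1.0 with top 13.1: floor(10 * 1.0 / 13.1) = 0."""
        vol, roi = self._phantom_with_background(1.0)
        labels = decile_label_map(vol, roi)
        assert background_band(vol, roi, labels) == 0

    def test_background_in_second_layer(self):
        """Background in the 10-20% layer, the canonical halo geometry."""
        vol, roi = self._phantom_with_background(1.4)
        labels = decile_label_map(vol, roi)
        assert background_band(vol, roi, labels) == 1

    def test_boundary_value_follows_floor(self):
        """A background exactly at 20% of the top lands in layer 2 by floor."""
        vol, roi = self._phantom_with_background(2.62)
        labels = decile_label_map(vol, roi)
        assert labels.window.top == pytest.approx(13.1)
        assert background_band(vol, roi, labels) == 2


# ---------------------------------------------------------------------------
# halo detection on hand-built configurations


def _nested_halo(background_label, halo_label, halo_thickness=8.0, thin=2.5):
    """Concentric configuration: thin inner bands, one thick halo band."""
    bands = [(9, 6.0)]
    r = 6.0
    for k in range(8, halo_label, -1):
        r += thin
        bands.append((k, r))
    r += halo_thickness
    bands.append((halo_label, r))
    return concentric_label_map(bands, background_label=background_label, voxel_mm=1.0)


class TestDetectPHL:
    def test_halo_adjacent_to_low_background(self):
        """Background 10-20%, abruptly thick 20-30% layer -> threshold 30%."""
        lmap, shell = _nested_halo(background_label=1, halo_label=2)
        bands = band_profile(lmap, shell, (1.0, 1.0, 1.0))
        res = detect_phl(bands, b=1, top=13.1)
        assert res.threshold_percent == 30
        assert res.phl_band == 2
        assert res.detection_mode == "abrupt_increase"
        assert res.threshold_suv == pytest.approx(0.30 * 13.1)

    def test_halo_at_fifty_sixty_layer(self):
        """Background 40-50%, halo 50-60% -> threshold 60% (homogeneous lesion)."""
        lmap, shell = _nested_halo(background_label=4, halo_label=5)
        bands = band_profile(lmap, shell, (1.0, 1.0, 1.0))
        res = detect_phl(bands, b=4, top=2.1)
        assert res.threshold_percent == 60
        assert res.detection_mode == "abrupt_increase"

    def test_fallback_when_no_abrupt_increase(self):
        """Uniformly thin bands: threshold defaults to the band next to background."""
        bands_spec = [(9, 6.0)] + [(k, 6.0 + 2.5 * (9 - k)) for k in range(8, 1, -1)]
        lmap, shell = concentric_label_map(bands_spec, background_label=1, voxel_mm=1.0)
        bands = band_profile(lmap, shell, (1.0, 1.0, 1.0))
        res = detect_phl(bands, b=1, top=10.0)
        assert res.detection_mode == "fallback_adjacent"
        assert res.phl_band == 2
        assert res.threshold_percent == 30

    def test_interior_thick_band_not_selected(self):
        """An irregular thick inner layer must not masquerade as the halo."""
        bands_spec = [(9, 6.0), (8, 8.5), (7, 11.0), (6, 21.0), (5, 23.5), (4, 26.0),
                      (3, 28.5), (2, 37.0)]
        lmap, shell = concentric_label_map(bands_spec, background_label=1, voxel_mm=1.0)
        bands = band_profile(lmap, shell, (1.0, 1.0, 1.0))
        res = detect_phl(bands, b=1, top=10.0)
        # the halo run stops at band 2/3; the thick band 6 is interior
        assert res.phl_band in (2, 3)

    @pytest.mark.parametrize("b", range(0, 8))
    def test_threshold_always_on_the_20_90_grid(self, b):
        """Whatever the background layer, the threshold is a multiple of 10
        within 20-90% (the observed clinical range)."""
        halo = min(b + 1, 8)
        lmap, shell = _nested_halo(background_label=b, halo_label=halo)
        bands = band_profile(lmap, shell, (1.0, 1.0, 1.0))
        res = detect_phl(bands, b=b, top=10.0)
        assert res.threshold_percent in range(20, 100, 10)

    def test_rho_and_b_validation(self):
        lmap, shell = _nested_halo(1, 2)
        bands = band_profile(lmap, shell, (1.0, 1.0, 1.0))
        with pytest.raises(ParameterError):
            detect_phl(bands, b=9)
        with pytest.raises(ParameterError):
            detect_phl(bands, b=1, rho=1.0)

    def test_determinism(self, capsule_s10):
        vol, _, roi, _ = capsule_s10
        r1, m1, _ = segment_phl(vol, roi)
        r2, m2, _ = segment_phl(vol, roi)
        assert r1.as_dict() == r2.as_dict()
        np.testing.assert_array_equal(m1.mask, m2.mask)


# ---------------------------------------------------------------------------
# agreement with a 1-D radial-profile oracle


def _blurred_sphere_suv(r, radius, sigma, peak, background):
    """Closed-form Gaussian-blurred sphere profile."""
    r = max(float(r), 1e-9)
    a = (radius - r) / (sigma * np.sqrt(2.0))
    b = (radius + r) / (sigma * np.sqrt(2.0))
    h = 0.5 * (erf(a) + erf(b)) - sigma / (r * np.sqrt(2.0 * np.pi)) * (
        np.exp(-((radius - r) ** 2) / (2 * sigma**2))
        - np.exp(-((radius + r) ** 2) / (2 * sigma**2))
    )
    return background + (peak - background) * h


def test_detection_agrees_with_radial_band_width_oracle(sphere_s10):
    """Brute-force 1-D band-width analysis of the analytic profile must give
    the same background band and threshold as the voxel-based detection."""
    vol, truth, roi, spec = sphere_s10
    res, _, labels = segment_phl(vol, roi)
    top = labels.window.top
    sigma = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    radius = spec.diameter_mm / 2.0
    S, B = spec.peak_suv, spec.background_suv

    # oracle: band boundary radii from the closed-form profile
    b_oracle = int(np.floor(10 * B / top))
    r_of = {}
    for k in range(b_oracle + 1, 10):
        level = k * top / 10.0
        if level >= _blurred_sphere_suv(0, radius, sigma, S, B):
            continue
        r_of[k] = brentq(
            lambda r: _blurred_sphere_suv(r, radius, sigma, S, B) - level, 1e-6, 60.0
        )
    widths = {k: r_of[k] - r_of[k + 1] for k in sorted(r_of) if k + 1 in r_of}
    rho = 2.0
    k = b_oracle + 1
    k_phl = k  # fallback default: band adjacent to background
    if k in widths and k + 1 in widths and widths[k] >= rho * widths[k + 1]:
        while k + 1 in widths and k + 2 in widths and widths[k + 1] >= rho * widths[k + 2]:
            k += 1
        k_phl = k
    threshold_oracle = max(20, min(90, 10 * (k_phl + 1)))

    assert res.background_band == b_oracle
    assert res.threshold_percent == threshold_oracle


# ---------------------------------------------------------------------------
# segmentation


class TestSegment:
    def test_threshold_above_suvmax_gives_empty_mask(self, capsule_s10):
        vol, _, roi, _ = capsule_s10
        mask = segment(vol, roi, roi.suvmax + 1.0)
        assert mask.empty

    def test_low_threshold_recovers_supra_region(self, capsule_s10):
        vol, truth, roi, _ = capsule_s10
        mask = segment(vol, roi, 1e-6)
        # everything is connected at a near-zero threshold
        assert mask.n_voxels == vol.values.size

    def test_two_blobs_only_seed_component(self, two_blob_volume):
        vol, blob1, blob2 = two_blob_volume
        seed = tuple(np.argwhere(blob1)[0])
        roi = make_roi(vol, ((0, 40), (0, 40), (0, 40)), seed=seed)
        mask = segment(vol, roi, 3.0)
        assert np.all(mask.mask[blob1])
        assert not mask.mask[blob2].any()

    def test_nesting_across_thresholds(self, noisy_capsule):
        vol, _, roi, _ = noisy_capsule
        prev = None
        for t in (1.5, 2.5, 4.0, 6.0):
            mask = segment(vol, roi, t).mask
            if prev is not None:
                assert np.all(mask <= prev)  # higher threshold is a subset
            prev = mask

    def test_every_mask_voxel_supra_threshold(self, noisy_capsule):
        vol, _, roi, _ = noisy_capsule
        mask = segment(vol, roi, 3.0)
        assert np.all(vol.values[mask.mask] >= 3.0)
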