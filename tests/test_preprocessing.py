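"""Spectral indices, cloud scoring/masking, compositing, gap filling and
band selection."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maizemap.constants import BAND_NAMES, CHANNELS
from maizemap.preprocessing import (
    build_feature_sequence,
    cloud_score,
    composite_monthly,
    compute_evi,
    compute_ndmi,
    compute_ndsi,
    compute_ndvi,
    fill_gaps,
    mask_clouds,
    month_window,
    select_bands,
    SequenceFeaturizer,
)
from maizemap.synthetic import (
    DEFAULT_PHENOLOGY,
    generate_pixel_series,
)
from maizemap.types import FeatureSequence, PixelTimeSeries, SpectralSample


def spectra(**kw) -> SpectralSample:
    vals = {f"rho_{b}": 0.0 for b in BAND_NAMES}
    vals.update({f"rho_{k}": v for k, v in kw.items()})
    return SpectralSample(**vals)


class TestIndices:
    @pytest.mark.parametrize(
        "fn, kw, expected",
        [
            (compute_ndvi, dict(nir=0.3, red=0.3), 0.0),
            (compute_ndvi, dict(nir=0.5, red=0.1), 0.4 / 0.6),
            (compute_ndvi, dict(nir=0.0, red=0.2), -1.0),
            (compute_evi, dict(nir=0.3, red=0.3, blue=0.1), 0.0),
            (compute_evi, dict(nir=0.5, red=0.1, blue=0.05), 1.0 / 1.725),
            (compute_evi, dict(nir=0.2, red=0.0, blue=0.0), 0.5 / 1.2),
            (compute_ndsi, dict(green=0.2, swir1=0.2), 0.0),
            (compute_ndsi, dict(green=0.6, swir1=0.2), 0.5),
            (compute_ndmi, dict(red=0.1, swir1=0.3), -0.5),
        ],
    )
    def test_hand_computed_values(self, fn, kw, expected):
        assert fn(spectra(**kw)) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("fn", [compute_ndvi, compute_ndsi, compute_ndmi])
    def test_zero_denominator_is_missing_not_fatal(self, fn):
        assert np.isnan(fn(spectra()))

    @given(
        a=st.floats(0.0, 1.5), b=st.floats(0.0, 1.5)
    )
    @settings(max_examples=200, deadline=None)
    def test_normalized_differences_bounded(self, a, b):
        s = spectra(nir=a, red=b, green=a, swir1=b)
        for fn in (compute_ndvi, compute_ndsi):
            v = fn(s)
            if not np.isnan(v):
                assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestCloudScore:
    def test_dark_pixel_scores_zero(self):
        assert cloud_score(spectra()) == 0.0

    def test_saturated_pixel_clamps_to_one(self):
        s = spectra(**{b: 1.0 for b in BAND_NAMES})
        assert cloud_score(s) == 1.0

    def test_cloud_beats_clear_vegetation(self):
        cloud = spectra(aerosols=0.55, blue=0.55, green=0.6, red=0.6,
                        nir=0.55, swir1=0.5, swir2=0.5)
        veg = spectra(aerosols=0.07, blue=0.06, green=0.1, red=0.05,
                      nir=0.4, swir1=0.18, swir2=0.1)
        assert cloud_score(cloud) > cloud_score(veg)

    @given(
        base=st.floats(0.0, 0.6),
        bump=st.floats(0.0, 0.4),
        band=st.sampled_from(["blue", "aerosols", "red", "green"]),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_brightness_bands(self, base, bump, band):
        kw = {b: base for b in BAND_NAMES}
        lo = cloud_score(spectra(**kw))
        kw[band] = base + bump
        hi = cloud_score(spectra(**kw))
        assert hi >= lo - 1e-12

    def test_missing_band_identified(self):
        bad = np.full(9, 0.2)
        bad[BAND_NAMES.index("nir")] = np.nan
        with pytest.raises(ValueError, match="nir"):
            cloud_score(bad)


class TestMaskClouds:
    def test_threshold_one_removes_nothing(self, maize_params):
        s = generate_pixel_series(replace(maize_params, cloud_prob=0.5), seed=1)
        assert not mask_clouds(s, 1.0).cloud_flag.any()

    def test_threshold_zero_removes_everything_bright(self, maize_params):
        s = generate_pixel_series(maize_params, seed=1)
        masked = mask_clouds(s, 0.0)
        scores = cloud_score(s.bands)
        assert np.array_equal(masked.cloud_flag, scores > 0)

    def test_recall_of_injected_clouds(self, maize_params):
        hits = total = 0
        for seed in range(30):
            s = generate_pixel_series(replace(maize_params, cloud_prob=0.3),
                                      seed=seed)
            det = mask_clouds(s).cloud_flag
            hits += int((det & s.cloud_flag).sum())
            total += int(s.cloud_flag.sum())
        assert total > 0 and hits / total >= 0.9


def series_from_windows(doys, values_nir, cloud=None):
    """Build a series whose nir band takes given values; others constant."""
    bands = np.full((len(doys), 9), 0.2)
    bands[:, BAND_NAMES.index("nir")] = values_nir
    flags = np.zeros(len(doys), bool) if cloud is None else np.array(cloud)
    return PixelTimeSeries(np.array(doys), bands, flags)


class TestCompositing:
    def test_window_boundaries(self):
        assert list(month_window([90, 119, 120, 270, 300])) == [0, 0, 1, 6, 6]
        assert list(month_window([89, 301])) == [-1, -1]

    def test_median_of_three(self):
        s = series_from_windows([91, 100, 110], [0.2, 0.6, 0.4])
        comp = composite_monthly(s)
        assert comp.channel("nir")[0] == pytest.approx(0.4)

    def test_single_acquisition_passthrough_and_gaps(self):
        s = series_from_windows([95, 125], [0.3, 0.7])
        comp = composite_monthly(s)
        assert comp.channel("nir")[0] == 0.3
        assert comp.channel("nir")[1] == 0.7
        assert comp.gap_mask[2:, :].all()

    def test_all_masked_window_is_gap(self):
        s = series_from_windows([95, 100], [0.3, 0.4], cloud=[True, True])
        comp = composite_monthly(s)
        assert comp.gap_mask[0].all()

    def test_idempotent_on_monthly_gap_free_series(self):
        doys = [105, 135, 165, 195, 225, 255, 285]
        vals = [0.1, 0.2, 0.4, 0.6, 0.5, 0.3, 0.15]
        comp = composite_monthly(series_from_windows(doys, vals))
        assert np.allclose(comp.channel("nir"), vals)
        again = composite_monthly(
            series_from_windows(doys, comp.channel("nir"))
        )
        assert np.allclose(again.values, comp.values)

    def test_median_robust_to_single_outlier(self):
        clean = series_from_windows([91, 100, 110], [0.2, 0.4, 0.6])
        spiked = series_from_windows([91, 100, 105, 110], [0.2, 0.4, 99.0, 0.6])
        a = composite_monthly(clean).channel("nir")[0]
        b = composite_monthly(spiked).channel("nir")[0]
        assert abs(b - a) <= 0.2 + 1e-12  # gap between adjacent order stats


class TestGapFilling:
    def make_seq(self, col, gaps):
        values = np.tile(np.asarray(col, float)[:, None], (1, 8))
        gap = np.zeros((7, 8), bool)
        gap[list(gaps), :] = True
        values[gap] = np.nan
        return FeatureSequence(values, CHANNELS[:8], gap, None)

    def test_midpoint_interpolation(self):
        seq = self.make_seq([0.1, 0.2, 0.0, 0.4, 0.5, 0.6, 0.7], gaps=[2])
        filled = fill_gaps(seq)
        assert filled.values[2, 0] == pytest.approx(0.3)
        assert filled.fill_mask[2].all() and not filled.gap_mask.any()

    def test_two_consecutive_gaps_at_thirds(self):
        seq = self.make_seq([0.3, 0.0, 0.0, 0.6, 0.6, 0.6, 0.6], gaps=[1, 2])
        filled = fill_gaps(seq)
        assert filled.values[1, 0] == pytest.approx(0.4)
        assert filled.values[2, 0] == pytest.approx(0.5)

    def test_leading_and_trailing_extension(self):
        seq = self.make_seq([0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.0], gaps=[0, 6])
        filled = fill_gaps(seq)
        assert filled.values[0, 0] == 0.5 and filled.values[6, 0] == 0.5

    def test_all_gap_channel_errors_with_name(self):
        seq = self.make_seq([0.0] * 7, gaps=range(7))
        with pytest.raises(ValueError, match="blue"):
            fill_gaps(seq)

    @pytest.mark.parametrize("masked", [(1,), (3, 4), (1, 2, 3, 4, 5)])
    def test_affine_series_recovered_exactly(self, masked):
        months = np.arange(7, dtype=float)
        truth = 0.1 + 0.05 * months
        seq = self.make_seq(truth, gaps=masked)
        filled = fill_gaps(seq)
        assert np.max(np.abs(filled.values[:, 0] - truth)) <= 1e-12


class TestBandSelection:
    def _series(self, bands):
        n = bands.shape[0]
        doy = np.linspace(90, 300, n).astype(int)
        return PixelTimeSeries(doy, bands, np.zeros(n, bool))

    def test_duplicate_band_removed_with_unit_r(self, rng):
        bands = rng.random((50, 9))
        bands[:, 2] = bands[:, 1]  # green duplicates blue
        rep = select_bands([self._series(bands[:25]), self._series(bands[25:40]),
                            self._series(bands[40:])])
        removed = {b: (p, r) for b, p, r in rep.removed}
        assert "green" in removed
        partner, r = removed["green"]
        assert partner == "blue" and r == pytest.approx(1.0)

    def test_independent_noise_bands_all_retained(self, rng):
        bands = rng.random((1000, 9))
        series = [self._series(bands[i::10]) for i in range(10)]
        rep = select_bands(series)
        assert rep.removed == []
        assert list(rep.retained) == list(BAND_NAMES)

    def test_no_retained_pair_exceeds_threshold(self, rng):
        # exhaustive pair check over randomly correlated structures
        for trial in range(10):
            latent = rng.random((200, 3))
            mix = rng.random((3, 9))
            bands = latent @ mix + 0.001 * rng.random((200, 9))
            rep = select_bands([self._series(bands[i::4]) for i in range(4)],
                               threshold=0.98)
            kept = [BAND_NAMES.index(b) for b in rep.retained]
            corr = np.corrcoef(bands, rowvar=False)
            for i in kept:
                for j in kept:
                    if i < j:
                        assert abs(corr[i, j]) <= 0.98 + 1e-9

    def test_constant_band_retained_with_warning(self, rng):
        bands = rng.random((60, 9))
        bands[:, 0] = 0.5
        with pytest.warns(UserWarning, match="aerosols"):
            rep = select_bands([self._series(bands[i::3]) for i in range(3)])
        assert "aerosols" in rep.retained

    def test_generator_reproduces_eight_channel_outcome(self):
        # exactly one of the near-collinear aerosols/blue pair survives the
        # screen, leaving the eight channels the classifiers consume
        samples = [
            generate_pixel_series(DEFAULT_PHENOLOGY["maize"], seed=s)
            for s in range(40)
        ]
        rep = select_bands(samples)
        assert len(rep.retained) == 8
        (band, partner, r) = rep.removed[0]
        assert {band, partner} == {"aerosols", "blue"} and abs(r) > 0.98

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            select_bands([self._series(rng.random((5, 9)))])


class TestBuildFeatureSequence:
    def test_constant_series_gives_constant_channels(self):
        s = series_from_windows([105, 135, 165, 195, 225, 255, 285], [0.4] * 7)
        fs = build_feature_sequence(s, mask=False)
        assert fs.values.shape == (7, 10)
        assert np.allclose(fs.values, fs.values[0])

    def test_ndvi_peaks_in_peak_month(self, quiet_maize):
        s = generate_pixel_series(quiet_maize, seed=0)
        fs = build_feature_sequence(s)
        peak_window = int(month_window([int(quiet_maize.peak_doy)])[0])
        assert int(np.argmax(fs.channel("ndvi"))) == peak_window

    def test_shape_contract_under_cloud_gaps(self, maize_params):
        s = generate_pixel_series(replace(maize_params, cloud_prob=0.6), seed=2)
        fs = build_feature_sequence(s)
        assert fs.values.shape == (7, 10)
        assert np.isfinite(fs.values).all()

    def test_featurizer_layouts(self, small_sample_set):
        series = [s for _, s in small_sample_set[:5]]
        flat = SequenceFeaturizer(flatten=True).transform(series)
        seq = SequenceFeaturizer(flatten=False).transform(series)
        assert flat.shape == (5, 70) and seq.shape == (5, 7, 10)
        assert np.array_equal(flat, seq.reshape(5, -1))
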