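"""Motility quantification: segmentation, axis, areas, extrema, and metrics."""

import numpy as np
import pytest

from gastrokt._geom import polyline_length
from gastrokt.motility import (
    AreaTimeSeries,
    antral_axis,
    contraction_amplitude,
    contraction_frequency,
    cross_section_areas,
    detect_extrema,
    gastric_volume,
    measure_motility,
    propagation_velocity,
    segment_lumen,
)
from gastrokt.pipeline import antrum_hints
from gastrokt.types import ImageSeries


def _sinusoid_series(freq_cpm=5.0, dt=2.0, duration=240.0, mean=20.0, amp=5.0, noise=0.0,
                     phase=0.0, seed=0):
    t = np.arange(0.0, duration, dt)
    rng = np.random.default_rng(seed)
    a = mean + amp * np.cos(2 * np.pi * freq_cpm / 60.0 * t - phase)
    if noise:
        a = a + rng.normal(0, noise, t.size)
    return AreaTimeSeries(0.0, t, np.clip(a, 0, None))


class TestSegmentation:
    def test_dice_against_ground_truth(self, static_tube):
        series, truth = static_tube
        seg = segment_lumen(series)
        gt = truth.lumen_mask
        dice = 2 * np.sum(seg & gt) / (seg.sum() + gt.sum())
        assert dice >= 0.95

    def test_all_zero_image_rejected(self):
        s = ImageSeries(np.zeros((8, 8, 2, 2)), (1, 1, 1), [0.0, 1.0])
        with pytest.raises(ValueError):
            segment_lumen(s)

    def test_zero_threshold_keeps_whole_foreground(self):
        v = np.ones((6, 6, 2, 1))
        s = ImageSeries(v, (1, 1, 1), [0.0])
        seg = segment_lumen(s, threshold=0.0)
        assert seg.all()

    def test_soft_mask_fraction_range_and_interior(self, static_tube):
        series, truth = static_tube
        soft = segment_lumen(series, soft=True)
        assert soft.min() >= 0.0 and soft.max() <= 1.0
        interior = truth.lumen_occupancy == 1.0
        assert np.all(soft[interior] > 0.99)


class TestAntralAxis:
    def test_axis_follows_tube_centreline(self, static_tube, static_tube_config):
        series, _ = static_tube
        mask = segment_lumen(series)
        hints = ((6.0, 10.0, 3.0), (27.0, 10.0, 3.0))
        axis = antral_axis(mask, series.voxel_size, hint_points=hints)
        # centreline is y = 10, z = 3; tolerate one in-plane voxel
        assert np.all(np.abs(axis[:, 1] - 10.0) <= 0.5)
        assert np.all(np.abs(axis[:, 2] - 3.0) <= 1.5)

    def test_axis_length_matches_hint_span(self, static_tube):
        series, _ = static_tube
        mask = segment_lumen(series)
        hints = ((6.0, 10.0, 3.0), (27.0, 10.0, 3.0))
        axis = antral_axis(mask, series.voxel_size, hint_points=hints)
        assert polyline_length(axis) == pytest.approx(21.0, rel=0.05)

    def test_equal_hints_rejected(self, static_tube):
        series, _ = static_tube
        mask = segment_lumen(series)
        with pytest.raises(ValueError, match="distinct"):
            antral_axis(mask, series.voxel_size, hint_points=((1, 2, 3), (1, 2, 3)))

    def test_disconnected_mask_rejected(self):
        m = np.zeros((20, 8, 2, 1), bool)
        m[2:5, 3:6, :, 0] = True
        m[14:18, 3:6, :, 0] = True
        with pytest.raises(ValueError, match="disconnected"):
            antral_axis(m, (1, 1, 1), hint_points=((3.0, 4.0, 1.0), (16.0, 4.0, 1.0)))


class TestCrossSections:
    def test_static_tube_area_matches_circle(self, static_tube, static_tube_config):
        series, truth = static_tube
        # threshold at the lumen/tissue midpoint so boundary voxels follow the
        # majority-occupancy rule
        tis = truth.tissue
        mask = segment_lumen(series, threshold=0.5 * (tis.lumen_signal + tis.tissue_signal))
        axis = np.asarray(static_tube_config.antrum_axis, float)
        st = cross_section_areas(
            mask, axis, [12.0], series.voxel_size, series.frame_times, plane_thickness=1.0
        )[0]
        expected = np.pi * static_tube_config.antrum_radius**2
        assert st.areas[0] == pytest.approx(expected, rel=0.10)

    def test_occluded_area_ratio(self, static_tube_config):
        """Scaling the radius by (1 - A) scales the area by (1 - A)^2."""
        from dataclasses import asdict

        from gastrokt.phantom import TissueProperties, generate_phantom

        amp = 0.231
        occluded = type(static_tube_config)(
            **{**asdict(static_tube_config), "antrum_radius": (1 - amp) * 2.6}
        )
        times = [0.0]
        a = generate_phantom(static_tube_config, TissueProperties(), times)
        b = generate_phantom(occluded, TissueProperties(), times)
        axis = np.asarray(static_tube_config.antrum_axis, float)
        sa = cross_section_areas(
            segment_lumen(a, soft=True), axis, [12.0], a.voxel_size, times
        )[0]
        sb = cross_section_areas(
            segment_lumen(b, soft=True), axis, [12.0], b.voxel_size, times
        )[0]
        assert sb.areas[0] / sa.areas[0] == pytest.approx((1 - amp) ** 2, abs=0.04)

    def test_empty_mask_frame_has_zero_area(self):
        m = np.zeros((10, 10, 2, 2), bool)
        m[4:6, 4:6, :, 0] = True
        axis = np.array([[0.0, 5.0, 1.0], [10.0, 5.0, 1.0]])
        st = cross_section_areas(m, axis, [5.0], (1, 1, 1), [0.0, 1.0])[0]
        assert st.areas[1] == 0.0

    def test_position_outside_axis_rejected(self):
        m = np.ones((10, 10, 2, 1), bool)
        axis = np.array([[0.0, 5.0, 1.0], [10.0, 5.0, 1.0]])
        with pytest.raises(ValueError, match="positions"):
            cross_section_areas(m, axis, [15.0], (1, 1, 1), [0.0])


class TestExtrema:
    def test_sinusoid_counts_and_alternation(self):
        # phase-shifted so no extremum sits on the record boundary: 10 cycles
        st = _sinusoid_series(freq_cpm=5.0, dt=1.0, duration=120.0, phase=1.0)
        ref = detect_extrema(st)
        assert ref.peak_indices.size == 10
        assert ref.valley_indices.size == 10
        events = sorted(
            [(i, "p") for i in ref.peak_indices] + [(i, "v") for i in ref.valley_indices]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_constant_series_rejected(self):
        st = AreaTimeSeries(0.0, np.arange(10.0), np.full(10, 5.0))
        with pytest.raises(ValueError):
            detect_extrema(st)

    def test_noise_robustness_at_snr_20(self):
        clean = detect_extrema(_sinusoid_series(dt=1.0, duration=120.0, phase=1.0))
        noisy = detect_extrema(
            _sinusoid_series(dt=1.0, duration=120.0, phase=1.0, noise=0.25, seed=5)
        )
        assert noisy.peak_indices.size == clean.peak_indices.size
        assert noisy.valley_indices.size == clean.valley_indices.size


class TestAmplitude:
    def test_hand_arithmetic(self):
        areas = np.array([10.0, 7.5, 10.0, 7.5, 10.0])
        st = AreaTimeSeries(0.0, np.arange(5.0), areas)
        st.peak_indices = np.array([0, 2, 4])
        st.valley_indices = np.array([1, 3])
        assert contraction_amplitude(st) == pytest.approx(0.25)

    def test_valley_equal_peak_gives_zero(self):
        st = AreaTimeSeries(0.0, np.arange(4.0), np.full(4, 8.0))
        st.peak_indices = np.array([0])
        st.valley_indices = np.array([1])
        assert contraction_amplitude(st) == 0.0

    def test_no_pair_rejected(self):
        st = AreaTimeSeries(0.0, np.arange(4.0), np.arange(4.0))
        st.peak_indices = np.array([3])
        st.valley_indices = np.array([0])
        with pytest.raises(ValueError, match="pair"):
            contraction_amplitude(st)


class TestFrequency:
    def test_sinusoid_bin_arithmetic(self):
        # 5 cpm sampled every 2 s for 4 min -> exactly on an FFT bin
        st = _sinusoid_series(freq_cpm=5.0, dt=2.0, duration=240.0)
        assert contraction_frequency(st) == pytest.approx(5.0, abs=1e-9)

    def test_off_bin_frequency_within_one_bin(self):
        st = _sinusoid_series(freq_cpm=5.3, dt=2.0, duration=600.0)
        bin_cpm = 60.0 / 600.0
        assert abs(contraction_frequency(st) - 5.3) <= bin_cpm

    def test_constant_series_rejected(self):
        st = AreaTimeSeries(0.0, np.arange(16.0), np.full(16, 2.0))
        with pytest.raises(ValueError):
            contraction_frequency(st)

    def test_too_short_record_rejected(self):
        st = AreaTimeSeries(0.0, np.arange(4.0), np.array([1.0, 2.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="samples"):
            contraction_frequency(st)

    def test_invariant_to_positive_scaling(self):
        st = _sinusoid_series(freq_cpm=5.3, dt=2.0, duration=300.0)
        scaled = AreaTimeSeries(st.position, st.times, 7.3 * st.areas)
        assert contraction_frequency(scaled) == contraction_frequency(st)


class TestVelocity:
    def test_imposed_delay_arithmetic(self):
        # 3 mm apart, wave delayed by 5.357 s -> 0.56 mm/s
        delay = 3.0 / 0.56
        omega = 2 * np.pi * 5.3 / 60.0
        a = _sinusoid_series(freq_cpm=5.3, dt=1.0, duration=240.0)
        b = _sinusoid_series(freq_cpm=5.3, dt=1.0, duration=240.0, phase=omega * delay)
        v = propagation_velocity(a, b, 3.0)
        assert v == pytest.approx(0.56, rel=0.02)

    def test_identical_series_rejected(self):
        a = _sinusoid_series()
        with pytest.raises(ValueError):
            propagation_velocity(a, a, 3.0)

    def test_nonpositive_distance_rejected(self):
        a = _sinusoid_series()
        b = _sinusoid_series(phase=0.5)
        with pytest.raises(ValueError, match="distance"):
            propagation_velocity(a, b, 0.0)


class TestVolume:
    def test_cohort_scale_arithmetic(self):
        # 13,867 voxels of 0.5 x 0.5 x 1.5 mm^3 (0.375 uL) -> 5.20 mL
        m = np.zeros((40, 40, 10, 1), bool)
        m.reshape(-1, 1)[:13867, 0] = True
        _, mean = gastric_volume(m, (0.5, 0.5, 1.5))
        assert mean == pytest.approx(5.2001, abs=1e-3)

    def test_empty_mask_is_zero(self):
        _, mean = gastric_volume(np.zeros((4, 4, 2, 3), bool), (1, 1, 1))
        assert mean == 0.0

    def test_linear_in_slice_thickness(self):
        m = np.random.default_rng(0).random((8, 8, 2, 2)) > 0.5
        _, v1 = gastric_volume(m, (0.5, 0.5, 1.5))
        _, v2 = gastric_volume(m, (0.5, 0.5, 3.0))
        assert v2 == pytest.approx(2 * v1)


class TestParameterRecovery:
    """End-to-end recovery of the configured motility on the default phantom."""

    def test_noiseless_fully_sampled_recovery(self, default_phantom, default_config):
        series, _ = default_phantom
        m = measure_motility(
            series, axis_hints=antrum_hints(default_config), positions=[2.0, 5.0]
        )
        radius_eq = 1.0 - np.sqrt(1.0 - m.amplitude)
        assert radius_eq == pytest.approx(default_config.contraction_amplitude, abs=0.02)
        bin_cpm = 60.0 / (series.frame_times[-1] - series.frame_times[0])
        assert abs(m.frequency - default_config.contraction_frequency) <= bin_cpm
        assert m.velocity == pytest.approx(default_config.contraction_velocity, rel=0.10)

    def test_recovery_with_noise_snr20(self, default_config, default_tissue):
        from dataclasses import asdict

        from gastrokt.phantom import PhantomConfig
        from gastrokt.pipeline import default_phantom_series

        cfg = PhantomConfig(**{**asdict(default_config), "noise_sigma": 0.05, "seed": 11})
        series = default_phantom_series(n_frames=60, config=cfg, tissue=default_tissue)
        m = measure_motility(series, axis_hints=antrum_hints(cfg), positions=[2.0, 5.0])
        radius_eq = 1.0 - np.sqrt(1.0 - m.amplitude)
        assert radius_eq == pytest.approx(cfg.contraction_amplitude, abs=0.02)
        assert m.velocity == pytest.approx(cfg.contraction_velocity, rel=0.10)

    def test_volume_against_analytic(self, default_phantom, default_config):
        from gastrokt.phantom import lumen_volume

        series, _ = default_phantom
        soft = segment_lumen(series, soft=True)
        _, vol = gastric_volume(soft, series.voxel_size)
        analytic = np.mean(
            [lumen_volume(default_config, t) for t in series.frame_times[::6]]
        )
        assert vol == pytest.approx(analytic, rel=0.05)
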