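"""Stimulus battery: geometry, luminance neutrality, events, round trips."""

import numpy as np
import pytest

from omskit import stimulus as st

GEO = dict(fov_um=480.0, pixel_pitch=8.0, frame_rate=30.0)


def modulated_mean(clip, label="modulation"):
    """Frame means within an epoch."""
    a, b = clip.event_window(label)
    t = clip.times()
    return clip.frame_means()[(t >= a) & (t < b)]


class TestSpotSeries:
    def test_disc_levels_match_michelson_contrast(self):
        clip = st.make_spot_series([100.0], contrast=0.96, order_seed=0, **GEO)[0]
        y, x = clip.grid()
        disc = (y[:, None] ** 2 + x[None, :] ** 2) <= 100.0**2
        a, _ = clip.event_window("spot_on")
        i_on = int(round((a + 0.1) * clip.frame_rate))
        b, _ = clip.event_window("spot_off")
        i_off = int(round((b + 0.1) * clip.frame_rate))
        assert np.allclose(clip.frames[i_on][disc], 0.5 * 1.96, atol=1e-6)
        assert np.allclose(clip.frames[i_off][disc], 0.5 * 0.04, atol=1e-6)
        assert np.allclose(clip.frames[i_on][~disc], 0.5, atol=1e-6)

    def test_zero_contrast_is_constant(self):
        clip = st.make_spot_series([100.0], contrast=0.0, order_seed=0, **GEO)[0]
        assert float(clip.frames.std()) == 0.0

    def test_order_seeded_and_first_repeated(self):
        radii = [50.0, 100.0, 150.0]
        a = st.make_spot_series(radii, order_seed=7, **GEO)
        b = st.make_spot_series(radii, order_seed=7, **GEO)
        order_a = [c.meta["radius_um"] for c in a]
        assert order_a == [c.meta["radius_um"] for c in b]
        assert len(a) == len(radii) + 1
        assert order_a[-1] == order_a[0]
        assert sorted(order_a[:-1]) == radii

    def test_radius_beyond_field_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            st.make_spot_series([300.0], **GEO)

    def test_events_cover_all_cycles(self):
        clip = st.make_spot_series([100.0], n_cycles=2, period_s=4.0, **GEO)[0]
        ev = clip.events_frame()
        assert (ev["label"] == "spot_on").sum() == 2
        assert (ev["label"] == "spot_off").sum() == 2
        on = ev[ev.label == "spot_on"].iloc[0]
        assert on.end_s - on.start_s == pytest.approx(2.0)


class TestSplitField:
    def test_even_split_is_luminance_neutral(self):
        clip = st.make_split_field(0.5, **GEO)
        m = modulated_mean(clip)
        assert np.abs(m - clip.mean_intensity).max() < 0.01 * clip.mean_intensity

    def test_biased_split_mean_amplitude_scales_with_bias(self):
        # area-weighted sum of anti-phase sinusoids leaves a residual
        # proportional to (2*bias - 1)
        amps = {}
        for bias in (0.625, 0.75):
            clip = st.make_split_field(bias, diameter=240.0, **GEO)
            m = modulated_mean(clip) - clip.mean_intensity
            t = np.arange(len(m)) / clip.frame_rate
            amps[bias] = 2 * abs(np.mean(m * np.exp(-2j * np.pi * 2.0 * t)))
        ratio = amps[0.75] / amps[0.625]
        assert ratio == pytest.approx((2 * 0.75 - 1) / (2 * 0.625 - 1), rel=0.05)

    def test_region_pixels_modulate_at_stimulus_frequency(self):
        clip = st.make_split_field(0.5, temporal_frequency=2.0, **GEO)
        a, b = clip.event_window("modulation")
        i0, i1 = int(a * clip.frame_rate), int(b * clip.frame_rate)
        ny, nx = clip.frames.shape[1:]
        px = clip.frames[i0:i1, ny // 2, nx // 2 - 5].astype(float) - clip.mean_intensity
        spec = np.abs(np.fft.rfft(px))
        freqs = np.fft.rfftfreq(len(px), 1 / clip.frame_rate)
        assert freqs[np.argmax(spec)] == pytest.approx(2.0)

    @pytest.mark.parametrize("bias", [0.0, 1.0, -0.2, 1.4])
    def test_bias_outside_open_interval_rejected(self, bias):
        with pytest.raises(ValueError):
            st.make_split_field(bias, **GEO)


class TestCounterphaseAnnulus:
    @pytest.mark.parametrize("bar_width", [25.0, 50.0])
    def test_annulus_mean_is_flat(self, bar_width):
        clip = st.make_counterphase_annulus(bar_width=bar_width, inner_r=80,
                                            outer_r=230, **GEO)
        m = modulated_mean(clip)
        assert np.abs(m - clip.mean_intensity).max() < 0.01 * clip.mean_intensity

    def test_single_bar_filling_annulus_modulates_mean(self):
        # a bar wider than the annulus, phase-shifted so the whole annulus
        # falls in one half-cycle, has no cancelling partner
        clip = st.make_counterphase_annulus(bar_width=460.0, inner_r=80, outer_r=230,
                                            spatial_phase_um=-230.0, **GEO)
        m = modulated_mean(clip) - clip.mean_intensity
        t = np.arange(len(m)) / clip.frame_rate
        amp = 2 * abs(np.mean(m * np.exp(-2j * np.pi * 2.0 * t)))
        assert amp > 0.1 * clip.mean_intensity

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            st.make_counterphase_annulus(bar_width=-5.0, **GEO)
        with pytest.raises(ValueError):
            st.make_counterphase_annulus(bar_width=1000.0, inner_r=80, outer_r=230, **GEO)


class TestTextureMotion:
    def test_unknown_segment_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            st.make_texture_motion("diagonal", **GEO)

    @pytest.mark.parametrize("segment", st.TEXTURE_SEGMENTS)
    def test_luminance_neutral_over_motion_cycles(self, segment):
        # a square grating masked by a disc is balanced over whole motion
        # cycles (a displacement of one spatial period), not per frame
        clip = st.make_texture_motion(segment, duration_s=2.0, **GEO)
        m = modulated_mean(clip, segment)
        per = 2 * 50.0 / 400.0  # one motion cycle: spatial period / speed
        block = int(round(2 * per * clip.frame_rate))  # 2 cycles = whole frames
        cyc = m[: (len(m) // block) * block].reshape(-1, block).mean(axis=1)
        assert np.abs(cyc - clip.mean_intensity).max() < 0.01 * clip.mean_intensity
        assert np.abs(m - clip.mean_intensity).max() < 0.05 * clip.mean_intensity

    def test_diff_center_leaves_surround_static(self):
        clip = st.make_texture_motion("diff_center", **GEO)
        y, x = clip.grid()
        rr2 = y[:, None] ** 2 + x[None, :] ** 2
        surround = rr2 >= (100.0 + 25.0) ** 2
        a, _ = clip.event_window("diff_center")
        i0 = int(a * clip.frame_rate)
        assert np.all(clip.frames[i0:, surround] == clip.frames[i0, surround])

    def test_global_moves_center_and_surround_identically(self):
        g = st.make_texture_motion("global", **GEO)
        c = st.make_texture_motion("diff_center", **GEO)
        y, x = g.grid()
        rr2 = y[:, None] ** 2 + x[None, :] ** 2
        center = rr2 <= 100.0**2
        assert np.array_equal(g.frames[:, center], c.frames[:, center])


class TestMovingBar:
    def test_edge_crossing_interval_is_width_over_speed(self):
        clip = st.make_moving_bar(height=200.0, width=200.0, speed=400.0, **GEO)
        t_le, _ = clip.event_window("leading_edge")
        t_te, _ = clip.event_window("trailing_edge")
        assert t_te - t_le == pytest.approx(200.0 / 400.0)

    def test_doubling_speed_halves_edge_interval(self):
        intervals = {}
        for v in (400.0, 800.0):
            clip = st.make_moving_bar(height=200.0, width=400.0, speed=v, **GEO)
            intervals[v] = (clip.event_window("trailing_edge")[0]
                            - clip.event_window("leading_edge")[0])
        assert intervals[400.0] == pytest.approx(2 * intervals[800.0])

    def test_dark_bar_level(self):
        clip = st.make_moving_bar(height=200.0, speed=400.0, polarity="dark",
                                  contrast=0.96, **GEO)
        assert clip.frames.min() == pytest.approx(0.5 * (1 - 0.96), abs=1e-6)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            st.make_moving_bar(height=200.0, speed=0.0, **GEO)


class TestDriftingGrating:
    def test_frame_mean_constant_over_whole_periods(self):
        clip = st.make_drifting_grating(45.0, spatial_period=120.0, duration_s=2.0, **GEO)
        a, b = clip.event_window("drift")
        t = clip.times()
        m = clip.frame_means()[(t >= a) & (t < b)]
        # average over each full temporal period
        per = int(clip.frame_rate / 2.0)
        cyc = m[: (len(m) // per) * per].reshape(-1, per).mean(axis=1)
        assert np.abs(cyc - clip.mean_intensity).max() < 0.01 * clip.mean_intensity

    def test_eight_direction_battery(self):
        clips = [st.make_drifting_grating(d, **GEO) for d in range(0, 360, 45)]
        assert len(clips) == 8
        assert len({c.frames.shape for c in clips}) == 1

    def test_opposite_directions_mirror_spatial_phase(self):
        c0 = st.make_drifting_grating(0.0, **GEO)
        c180 = st.make_drifting_grating(180.0, **GEO)
        # direction 180 at x equals direction 0 at -x
        assert np.allclose(c180.frames, c0.frames[:, :, ::-1], atol=1e-5)


class TestWhiteNoise:
    def test_sequence_length_and_determinism(self):
        wn1 = st.make_white_noise(duration_s=10.0, seed=5, fov_um=160.0,
                                  pixel_pitch=8.0, center_radius=60.0)
        wn2 = st.make_white_noise(duration_s=10.0, seed=5, fov_um=160.0,
                                  pixel_pitch=8.0, center_radius=60.0)
        assert len(wn1.meta["sequence"]) == 300  # 30 Hz x 10 s
        assert np.array_equal(wn1.frames, wn2.frames)

    def test_ten_minute_run_has_18000_values(self):
        seq, _ = st.white_noise_sequence(30.0, 0.4, 600.0, seed=0)
        assert len(seq) == 18000

    def test_rms_contrast_realized(self):
        seq, clip_frac = st.white_noise_sequence(30.0, 0.4, 600.0, seed=1)
        assert np.std(seq) == pytest.approx(0.4 * 0.5, rel=0.05)
        assert 0.0 <= clip_frac < 0.02

    def test_zero_rms_is_constant(self):
        seq, _ = st.white_noise_sequence(30.0, 0.0, 10.0, seed=0)
        assert float(np.std(seq)) == 0.0

    def test_rms_of_one_rejected(self):
        with pytest.raises(ValueError):
            st.white_noise_sequence(30.0, 1.0, 10.0, seed=0)


class TestClipRoundTrip:
    @pytest.fixture()
    def clip(self):
        return st.make_split_field(0.6, duration_s=1.0, **GEO)

    def test_npz_round_trip_bit_exact(self, clip, tmp_path):
        path = tmp_path / "clip.npz"
        clip.to_npz(path)
        back = st.StimulusClip.from_npz(path)
        assert np.array_equal(back.frames, clip.frames)
        assert back.events == clip.events
        assert back.frame_rate == clip.frame_rate
        assert back.pixel_pitch == clip.pixel_pitch

    def test_hdf5_round_trip_bit_exact(self, clip, tmp_path):
        path = str(tmp_path / "clip.h5")
        clip.to_hdf5(path)
        back = st.StimulusClip.from_hdf5(path)
        assert np.array_equal(back.frames, clip.frames)
        assert back.events == clip.events

    def test_event_csv_reconstructs_windows(self, clip, tmp_path):
        import pandas as pd
        path = tmp_path / "events.csv"
        clip.events_to_csv(path)
        ev = pd.read_csv(path)
        for label, a, b in clip.events:
            row = ev[ev.label == label].iloc[0]
            assert (row.start_s, row.end_s) == (a, b)
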