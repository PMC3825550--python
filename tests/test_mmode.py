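"""M-mode construction, dimension/volume/velocity/rate measurement."""

import numpy as np
import pytest

from zfcardio import (
    AnalysisError,
    BeatParams,
    ExtremePoint,
    FrameStack,
    MModeImage,
    analyze_mmode,
    build_mmode,
    compute_ef_fs,
    compute_volumes,
    count_heartbeats,
    extract_wall_trace,
    measure_dimensions,
    simulate_beating_ventricle,
    wall_velocities,
)


def _stack_from_frames(frames, fps=20.0, pixel_size=1.0):
    return FrameStack(np.asarray(frames), fps=fps, pixel_size=pixel_size)


class TestBuildMMode:
    def test_static_video_gives_identical_columns(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 255, size=(32, 32)).astype(np.uint8)
        stack = _stack_from_frames([frame] * 5)
        m = build_mmode(stack, center=(16, 16), line_angle_deg=0.0)
        assert np.all(m.matrix == m.matrix[:, :1])

    def test_matrix_shape_is_line_length_by_frames(self, default_sim):
        _, stack, _ = default_sim
        m = build_mmode(stack, center=(63.5, 63.5), line_angle_deg=90.0)
        assert m.matrix.shape == (m.positions_px.size, stack.n_frames)

    def test_axis_aligned_line_is_exact_row_extraction(self):
        rng = np.random.default_rng(1)
        frames = rng.random((3, 16, 16))
        stack = _stack_from_frames(frames)
        m = build_mmode(stack, center=(8, 5), line_angle_deg=0.0)
        cols = (8 + m.positions_px).astype(int)
        for t in range(3):
            assert np.array_equal(m.matrix[:, t], frames[t, 5, cols])

    def test_center_outside_frame_errors(self, default_sim):
        _, stack, _ = default_sim
        with pytest.raises(AnalysisError):
            build_mmode(stack, center=(500, 10))

    def test_short_axis_width_oscillates_between_systole_and_diastole(
        self, default_sim
    ):
        p, stack, _ = default_sim
        m = build_mmode(stack, center=(63.5, 63.5), axis="short",
                        line_angle_deg=90.0)
        trace = extract_wall_trace(m)
        assert trace.width_um.min() == pytest.approx(2 * p.b_ES, abs=2.0)
        assert trace.width_um.max() == pytest.approx(2 * p.b_ED, abs=2.0)


class TestExtractWallTrace:
    def _mmode(self, matrix, positions):
        n = matrix.shape[1]
        return MModeImage(
            matrix=matrix,
            positions_px=np.asarray(positions, dtype=float),
            axis="short",
            angle_deg=90.0,
            center=(0.0, 0.0),
            pixel_size=1.0,
            fps=20.0,
            times_ms=np.arange(n) * 50.0,
        )

    def test_symmetric_profile_gives_symmetric_edges(self):
        positions = np.arange(-20, 21)
        profile = np.where(np.abs(positions) <= 8, 1000.0, 50.0)
        m = self._mmode(np.tile(profile[:, None], (1, 6)), positions)
        trace = extract_wall_trace(m, smooth_sigma_px=1.0)
        assert np.all(np.abs(trace.edge_lo_um + trace.edge_hi_um) <= 0.5)

    def test_uniform_bright_column_flagged_and_interpolated(self):
        positions = np.arange(-20, 21)
        good = np.where(np.abs(positions) <= 8, 1000.0, 50.0)
        matrix = np.tile(good[:, None], (1, 12))
        matrix[:, 4] = 1000.0  # line entirely inside the lumen
        m = self._mmode(matrix, positions)
        with pytest.warns(UserWarning, match="flagged"):
            trace = extract_wall_trace(m)
        assert trace.flags[4] and not trace.flags[3]
        assert np.isfinite(trace.width_um[4])

    def test_noise_free_simulation_width_matches_truth(self, default_sim):
        p, stack, truth = default_sim
        m = build_mmode(stack, center=(63.5, 63.5), axis="short",
                        line_angle_deg=90.0)
        trace = extract_wall_trace(m)
        err = np.abs(trace.width_um - 2 * truth.b_um)
        assert err.max() <= 2.0 * stack.pixel_size


class TestMeasureDimensions:
    def test_cosine_width_analytic_extrema(self):
        times = np.arange(65) * 50.0           # 3.25 s at 20 fps
        width = 60.0 + 20.0 * np.cos(2 * np.pi * times / 500.0)
        vds, vdd, detail = measure_dimensions(width, n_cycles=5, times_ms=times)
        assert vds == pytest.approx(40.0, abs=1e-9)
        assert vdd == pytest.approx(80.0, abs=1e-9)
        assert detail["n_cycles"] == 5

    def test_constant_width_vds_equals_vdd(self):
        with pytest.warns(UserWarning, match="no cycles"):
            vds, vdd, _ = measure_dimensions(np.full(50, 42.0))
        assert vds == vdd == pytest.approx(42.0)

    def test_fewer_cycles_than_requested_warns(self):
        times = np.arange(30) * 50.0           # 1.5 s: ~3 cycles at 2 Hz
        width = 60.0 + 20.0 * np.cos(2 * np.pi * times / 500.0)
        with pytest.warns(UserWarning, match="cycle"):
            vds, vdd, _ = measure_dimensions(width, n_cycles=5, times_ms=times)
        assert vdd > vds


class TestVolumesAndEF:
    def test_printed_prolate_formula(self):
        edv, esv, sv = compute_volumes(36.0, 60.0, 80.0, 100.0)
        assert edv == pytest.approx(60.0)       # 4*50*30^2/3 um^3 = 60 pl
        assert sv == pytest.approx(edv - esv)

    def test_include_pi_scales_by_pi(self):
        edv, _, _ = compute_volumes(36.0, 60.0, 80.0, 100.0, include_pi=True)
        assert edv == pytest.approx(60.0 * np.pi)

    def test_zero_dimension_gives_zero_volume(self):
        edv, esv, _ = compute_volumes(0.0, 60.0, 0.0, 100.0)
        assert esv == 0.0
        assert edv > 0

    def test_negative_sv_warns(self):
        with pytest.warns(UserWarning, match="negative stroke volume"):
            compute_volumes(70.0, 60.0, 110.0, 100.0)

    def test_ef_and_fs_formulas(self):
        ef, fs = compute_ef_fs(60.0, 30.0, 36.0, 60.0)
        assert ef == pytest.approx(0.5)
        assert fs == pytest.approx(40.0)

    def test_equal_volumes_give_zero_ef_and_fs(self):
        ef, fs = compute_ef_fs(60.0, 60.0, 60.0, 60.0)
        assert ef == 0.0
        assert fs == 0.0

    def test_zero_denominators_error(self):
        with pytest.raises(AnalysisError):
            compute_ef_fs(0.0, 0.0, 36.0, 60.0)
        with pytest.raises(AnalysisError):
            compute_ef_fs(60.0, 30.0, 36.0, 0.0)


class TestWallVelocities:
    @staticmethod
    def _triangular_points(n_inward=6, excursion=10.0, t_sys=100.0, t_dia=150.0):
        pts, t = [], 0.0
        for i in range(2 * n_inward - 1):
            if i % 2 == 0:
                pts.append(ExtremePoint(t, -35.0, "outward"))
                t += t_sys
            else:
                pts.append(ExtremePoint(t, -35.0 + excursion, "inward"))
                t += t_dia
        return pts

    def test_triangular_wave_slopes(self):
        pts = self._triangular_points()
        mvwvs, mvwvd = wall_velocities(pts)
        assert mvwvs == pytest.approx(0.100)
        assert mvwvd == pytest.approx(10.0 / 150.0)

    def test_static_wall_gives_zero_velocities(self):
        pts = [
            ExtremePoint(100.0 * i, -30.0, "outward" if i % 2 == 0 else "inward")
            for i in range(11)
        ]
        mvwvs, mvwvd = wall_velocities(pts)
        assert mvwvs == 0.0 and mvwvd == 0.0

    def test_non_alternating_points_error(self):
        pts = [
            ExtremePoint(0.0, -35.0, "outward"),
            ExtremePoint(100.0, -25.0, "outward"),
            ExtremePoint(200.0, -35.0, "inward"),
        ]
        with pytest.raises(AnalysisError):
            wall_velocities(pts)

    def test_simulation_systolic_velocity_matches_waveform_mean(self, default_sim):
        p, stack, _ = default_sim
        metrics = analyze_mmode(stack)
        # short-axis ventral edge moves b_ED - b_ES um over the systolic interval
        t_sys = p.systole_fraction * p.period_ms
        expected = (p.b_ED - p.b_ES) / t_sys
        assert metrics.mVWVs == pytest.approx(expected, rel=0.10)


class TestCountHeartbeats:
    def test_two_hz_beat_over_fifteen_seconds(self):
        times = np.arange(300) * 50.0
        values = np.cos(2 * np.pi * times / 500.0)
        hr = count_heartbeats(values, times, window_s=15.0)
        assert hr.bpm == pytest.approx(120.0, abs=0.01)
        assert not hr.extrapolated
        assert hr.beats in (29, 30)

    def test_short_trace_extrapolates(self):
        times = np.arange(100) * 50.0          # 5 s
        values = np.cos(2 * np.pi * times / 400.0)
        hr = count_heartbeats(values, times, window_s=15.0)
        assert hr.extrapolated
        assert hr.bpm == pytest.approx(150.0, abs=0.01)

    def test_flat_trace_reports_zero(self):
        with pytest.warns(UserWarning, match="no heartbeat"):
            hr = count_heartbeats(np.full(100, 3.0), np.arange(100) * 50.0)
        assert hr.bpm == 0.0 and hr.beats == 0


class TestAnalyzeMMode:
    def test_dimension_ordering_invariant(self, default_sim):
        _, stack, _ = default_sim
        m = analyze_mmode(stack)
        assert m.short_VDd >= m.short_VDs
        assert m.long_VDd >= m.long_VDs
        assert m.EDV >= m.ESV
        assert 0.0 <= m.EF <= 1.0
        assert 0.0 <= m.FS_pct <= 100.0

    def test_ef_increases_as_systolic_axes_shrink(self):
        weak = BeatParams(a_ES=45.0, b_ES=27.0)
        strong = BeatParams(a_ES=35.0, b_ES=18.0)
        efs = []
        for p in (weak, strong):
            stack, _ = simulate_beating_ventricle(p, n_frames=40)
            efs.append(analyze_mmode(stack, n_cycles=3).EF)
        assert efs[1] > efs[0]

    def test_image_axes_mode_matches_principal_for_unrotated_heart(
        self, default_sim
    ):
        _, stack, truth = default_sim
        m_principal = analyze_mmode(stack)
        m_image = analyze_mmode(stack, axes="image")
        assert m_image.EF == pytest.approx(m_principal.EF, abs=0.02)
        assert m_image.EF == pytest.approx(truth.EF, abs=0.05)
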