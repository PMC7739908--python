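"""Mass-balance metering, occlusion timing and intensity-peak localization."""
import numpy as np
import pytest

import stenoflow as sf
from stenoflow.errors import (
    AlignmentError,
    AnnotationError,
    DegenerateProfileError,
    WindowError,
)
from stenoflow.occlusion_analysis import CornerAnnotation, ImageStack, MassTrace


class TestEvaporationCorrection:
    def test_zero_slope_reference_leaves_trace_unchanged(self):
        t = np.arange(0.0, 50.0)
        trace = MassTrace(times=t, mass=2e-6 * t, reference=np.full_like(t, 0.05))
        corr = sf.correct_evaporation(trace)
        assert np.allclose(corr.mass, trace.mass)

    def test_linear_superposition_of_slopes(self):
        """Trace slope (q - r) plus reference slope (-r) corrects to slope q."""
        t = np.arange(0.0, 100.0)
        q, r = 2.46e-6, 2e-8
        trace = MassTrace(times=t, mass=(q - r) * t, reference=0.05 - r * t)
        corr = sf.correct_evaporation(trace)
        slope = np.polyfit(corr.times, corr.mass, 1)[0]
        assert slope == pytest.approx(q, rel=1e-9)

    def test_disjoint_supports_rejected(self):
        trace = MassTrace(times=np.arange(0.0, 10.0), mass=np.zeros(10))
        ref = MassTrace(times=np.arange(100.0, 110.0), mass=np.zeros(10))
        with pytest.raises(AlignmentError):
            sf.correct_evaporation(trace, ref)

    def test_programmed_rate_recovered_under_noise(self):
        """Q = 2.4e-9 m^3/s with evaporation -2e-8 kg/s and 1e-6 kg noise -> 1%."""
        spec = sf.ExperimentSpec(
            seed=5, evaporation_rate=-2e-8, balance_noise=1e-6, occlusion_time=120.0
        )
        corr = sf.correct_evaporation(sf.synth_mass_trace(spec))
        q = sf.flow_rate(corr, (5.0, 110.0))
        assert q == pytest.approx(spec.flow_rate, rel=0.01)


class TestFlowRate:
    def test_exact_linear_trace(self):
        t = np.arange(0.0, 60.0)
        trace = MassTrace(times=t, mass=2.46e-6 * t, density=1025.0, corrected=True)
        assert sf.flow_rate(trace, (0.0, 59.0)) == pytest.approx(2.4e-9, rel=1e-9)

    def test_short_window_rejected(self):
        t = np.arange(0.0, 60.0)
        trace = MassTrace(times=t, mass=2.46e-6 * t, corrected=True)
        with pytest.raises(WindowError):
            sf.flow_rate(trace, (0.0, 3.0))


class TestOcclusionTime:
    def test_unimodal_trace_argmax_exact(self):
        t = np.arange(0.0, 100.0)
        m = -((t - 40.0) ** 2)
        occ = sf.occlusion_time(MassTrace(times=t, mass=m, corrected=True))
        assert occ.time == 40.0
        assert not occ.censored

    def test_plateau_returns_temporal_center(self):
        """Mass flat at its maximum from 100 s to 104 s -> 102 s."""
        t = np.arange(0.0, 120.0)
        m = np.minimum(t, 100.0)
        m[105:] = 100.0 - 0.5 * (t[105:] - 104.0)
        occ = sf.occlusion_time(MassTrace(times=t, mass=m, corrected=True))
        assert occ.time == pytest.approx(102.0)
        assert occ.plateau == (100.0, 104.0)

    def test_monotone_rising_trace_right_censored(self):
        t = np.arange(0.0, 50.0)
        occ = sf.occlusion_time(MassTrace(times=t, mass=2.46e-6 * t, corrected=True))
        assert occ.censored

    def test_synthetic_occlusion_within_one_sample(self):
        """Detected time = programmed flow-stop time, +/- one balance sample."""
        for seed in (0, 1, 2):
            spec = sf.ExperimentSpec(seed=seed, occlusion_time=60.0)
            corr = sf.correct_evaporation(sf.synth_mass_trace(spec))
            occ = sf.occlusion_time(corr)
            assert abs(occ.time - 60.0) <= 1.0 / spec.balance_rate
            assert not occ.censored

    def test_frame_mapping_nearest_timestamp(self):
        t = np.arange(0.0, 120.0)
        m = np.minimum(t, 100.0)
        m[105:] = 100.0 - 0.5 * (t[105:] - 104.0)
        frames = np.arange(0.0, 120.0, 0.5)
        occ = sf.occlusion_time(
            MassTrace(times=t, mass=m, corrected=True), frame_times=frames
        )
        assert occ.frame_index == 204  # frame at t = 102.0


def blob_frame(nz=60, nx=200, x0=120, amp=0.3, sign=1.0):
    x = np.arange(nx)
    frame = np.full((nz, nx), 0.5)
    frame += sign * amp * np.exp(-0.5 * ((x - x0) / 8.0) ** 2)[None, :]
    return frame


def square_corners(z0=5, z1=54, xa=40.0, xb=100.0):
    return CornerAnnotation(corners=np.array([[xa, z0], [xa, z1], [xb, z0], [xb, z1]]))


def make_stack(frames, modality="WB", px=2e-6):
    frames = np.asarray(frames, dtype=float)
    return ImageStack(
        frames=frames,
        times=np.arange(frames.shape[0]) * 0.5,
        pixel_size=px,
        modality=modality,
    )


class TestIntensityProfile:
    def test_uniform_frame_flagged_degenerate(self):
        stack = make_stack([np.full((60, 200), 0.5)])
        prof = sf.intensity_profile(stack, 0, square_corners())
        assert prof.degenerate
        assert not prof.intensity.any()
        with pytest.raises(DegenerateProfileError):
            sf.occlusion_distance(prof)

    def test_bright_blob_peak_within_one_pixel(self):
        stack = make_stack([blob_frame(x0=120)])
        prof = sf.intensity_profile(stack, 0, square_corners(xa=40.0))
        peak = sf.occlusion_distance(prof)
        assert abs(peak.distance - (120 - 40.0) * 2e-6) <= 2e-6

    def test_prp_inversion_matches_wb(self):
        """Dark PRP blob and bright WB blob localize identically after inversion."""
        wb = make_stack([blob_frame(sign=+1.0)], modality="WB")
        prp = make_stack([blob_frame(sign=-1.0)], modality="PRP")
        p_wb = sf.intensity_profile(wb, 0, square_corners())
        p_prp = sf.intensity_profile(prp, 0, square_corners())
        assert np.allclose(p_wb.intensity, p_prp.intensity, atol=1e-9)
        assert p_prp.inverted and not p_wb.inverted

    def test_corners_outside_frame_rejected(self):
        stack = make_stack([blob_frame()])
        with pytest.raises(AnnotationError):
            sf.intensity_profile(stack, 0, square_corners(z1=500))

    def test_alignment_reference_at_throat_corner(self):
        stack = make_stack([blob_frame(x0=40)])
        prof = sf.intensity_profile(stack, 0, square_corners(xa=40.0))
        peak = sf.occlusion_distance(prof)
        assert peak.distance == pytest.approx(0.0, abs=1e-12)


class TestOcclusionDistance:
    def test_tie_reports_first_and_flags(self):
        prof = sf.IntensityProfile(
            x=np.arange(5) * 1e-6,
            intensity=np.array([0.0, 1.0, 0.5, 1.0, 0.0]),
            modality="WB",
            inverted=False,
        )
        peak = sf.occlusion_distance(prof)
        assert peak.index == 1
        assert peak.tie

    def test_downstream_brighter_blob_never_moves_peak_upstream(self):
        """Adding a brighter blob strictly downstream moves the peak downstream."""
        base = blob_frame(x0=100, amp=0.2)
        corners = square_corners()
        p0 = sf.occlusion_distance(
            sf.intensity_profile(make_stack([base]), 0, corners)
        )
        for amp2 in (0.25, 0.3, 0.4):
            frame = base + (blob_frame(x0=160, amp=amp2) - 0.5)
            p1 = sf.occlusion_distance(
                sf.intensity_profile(make_stack([frame]), 0, corners)
            )
            assert p1.distance >= p0.distance


class TestAggregate:
    def make_profile(self, peak_um):
        x = np.arange(0.0, 300.0) * 1e-6
        inten = np.exp(-0.5 * ((x - peak_um * 1e-6) / 20e-6) ** 2)
        return sf.IntensityProfile(x=x, intensity=inten, modality="WB", inverted=False)

    def test_single_profile_is_identity(self):
        p = self.make_profile(80.0)
        mean, curves = sf.aggregate_profiles([p])
        assert np.allclose(mean.intensity, p.intensity)
        assert len(curves) == 1

    def test_identical_profiles_average_to_same(self):
        p = self.make_profile(80.0)
        mean, _ = sf.aggregate_profiles([p, p])
        assert np.allclose(mean.intensity, p.intensity)

    def test_mean_peak_between_component_peaks(self):
        mean, _ = sf.aggregate_profiles([self.make_profile(80.0), self.make_profile(90.0)])
        peak = mean.x[np.argmax(mean.intensity)]
        assert 80e-6 <= peak <= 90e-6

    def test_y_shift_removes_offsets(self):
        p1 = self.make_profile(85.0)
        p2 = sf.IntensityProfile(
            x=p1.x, intensity=p1.intensity + 0.3, modality="PRP", inverted=True
        )
        mean, curves = sf.aggregate_profiles([p1, p2], y_shift=True)
        assert np.allclose(curves[0].intensity, curves[1].intensity, atol=1e-12)

    def test_disjoint_supports_rejected(self):
        p1 = self.make_profile(80.0)
        p2 = sf.IntensityProfile(
            x=p1.x + 1.0, intensity=p1.intensity, modality="WB", inverted=False
        )
        with pytest.raises(AlignmentError):
            sf.aggregate_profiles([p1, p2])


class TestEndToEnd:
    def test_pipeline_recovers_programmed_experiment(self):
        spec = sf.ExperimentSpec(seed=11, occlusion_time=30.0, clot_center=85e-6)
        stack, corners = sf.synth_image_stack(spec)
        trace = sf.synth_mass_trace(spec)
        result = sf.analyze_occlusion(stack, trace, corners)
        assert abs(result.occlusion.time - 30.0) <= 1.0
        assert abs(result.distance.distance - 85e-6) <= spec.pixel_size
        assert not result.occlusion.censored

    def test_stack_tiff_roundtrip(self, tmp_path):
        spec = sf.ExperimentSpec(seed=3, occlusion_time=10.0, record_duration=12.0)
        stack, _ = sf.synth_image_stack(spec)
        path = str(tmp_path / "stack.tiff")
        stack.to_tiff(path)
        back = ImageStack.from_tiff(path)
        assert np.allclose(back.frames, stack.frames)
        assert back.modality == stack.modality
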