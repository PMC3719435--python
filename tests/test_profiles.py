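import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrospect import (
    ImageStack,
    RunConfig,
    SyntheticConstructSpec,
    alignment_profile,
    analyze_slice,
    analyze_stack,
    detect_rotation_jumps,
    generate_fiber_image,
    generate_rotating_stack,
    rotation_profile,
    rotation_range,
    rotation_slope,
)
from fibrospect.profiles import _axial_delta


def _stack_of(img, n, z_step=0.5):
    return ImageStack([img.copy() for _ in range(n)], z_step_um=z_step)


@pytest.fixture(scope="module")
def steady_stack():
    """Five identical slices of a concentrated fiber field at 75 deg."""
    spec = SyntheticConstructSpec(
        n_slices=1, orientation_schedule=[75.0], kappa=1e6, noise_model="none", seed=17
    )
    img, _ = generate_fiber_image(spec, 0)
    return _stack_of(img, 5)


class TestAxialDelta:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0, max_value=179.999),
        b=st.floats(min_value=0, max_value=179.999),
    )
    def test_minimal_representative_properties(self, a, b):
        d = _axial_delta(a, b)
        assert -90.0 < d <= 90.0
        # adding the delta reproduces b on the axial circle
        assert abs((a + d - b) % 180.0) % 180.0 == pytest.approx(0.0, abs=1e-9) or \
            abs(((a + d - b) % 180.0) - 180.0) <= 1e-9

    def test_wraparound_prefers_small_step(self):
        assert _axial_delta(89.0, 91.0) == pytest.approx(2.0)
        assert _axial_delta(91.0, 89.0) == pytest.approx(-2.0)
        assert _axial_delta(2.0, 178.0) == pytest.approx(-4.0)

    def test_exact_quarter_turn_resolves_positive(self):
        assert _axial_delta(10.0, 100.0) == pytest.approx(90.0)


class TestAlignmentProfile:
    def test_identical_slices_give_constant_range(self, steady_stack):
        prof = alignment_profile(steady_stack)
        assert np.ptp(prof.range_deg) <= 1.0  # within one bin
        assert not prof.empty_flags.any()
        np.testing.assert_allclose(prof.z_um, np.arange(5) * 0.5)

    def test_isotropic_upper_half_aligned_lower_half(self):
        n = 6
        top = SyntheticConstructSpec(
            n_slices=n, orientation_schedule=(0.0, 0.0), kappa=0.0, seed=23
        )
        bottom = SyntheticConstructSpec(
            n_slices=n, orientation_schedule=(40.0, 0.0), kappa=8.0, seed=24
        )
        s_top, _ = generate_rotating_stack(top)
        s_bot, _ = generate_rotating_stack(bottom)
        stack = ImageStack(list(s_top) + list(s_bot), z_step_um=0.5)
        prof = alignment_profile(stack)
        assert prof.range_deg[:n].mean() > prof.range_deg[n:].mean() + 20.0

    def test_all_empty_stack_is_flagged_not_crashing(self):
        stack = _stack_of(np.zeros((64, 64)), 4)
        prof = alignment_profile(stack)
        assert prof.all_empty
        assert np.isnan(prof.mean_range_deg())


class TestRotationProfile:
    def test_identical_slices_flat_track(self, steady_stack):
        rot = rotation_profile(steady_stack)
        np.testing.assert_allclose(rot.step_deltas_deg, 0.0)
        assert rotation_range(rot) == pytest.approx(0.0)

    def test_wraparound_step_is_minimal(self):
        spec = SyntheticConstructSpec(
            n_slices=2, orientation_schedule=[89.0, 91.0], kappa=1e6,
            noise_model="none", seed=29,
        )
        stack, _ = generate_rotating_stack(spec)
        rot = rotation_profile(stack)
        assert 0.0 < rot.step_deltas_deg[1] < 10.0  # +2 deg, never -178

    def test_programmed_rotation_rate_recovered(self):
        spec = SyntheticConstructSpec(
            n_slices=40, orientation_schedule=(10.0, 2.0), kappa=50.0, seed=31
        )
        stack, _ = generate_rotating_stack(spec)
        rot = rotation_profile(stack)
        assert rotation_slope(rot) == pytest.approx(2.0, abs=0.2)
        assert rotation_range(rot) == pytest.approx(78.0, abs=4.0)

    def test_unwrapping_identity(self):
        spec = SyntheticConstructSpec(
            n_slices=20, orientation_schedule=(150.0, 4.0), kappa=50.0, seed=37
        )
        stack, _ = generate_rotating_stack(spec)
        rot = rotation_profile(stack)
        config = RunConfig()
        for i, sl in enumerate(stack):
            _, s = analyze_slice(sl, config)
            assert rot.angle_deg_unwrapped[i] % 180.0 == pytest.approx(
                s.median_angle_deg % 180.0, abs=1e-9
            )
        # track increments equal the stored deltas exactly
        np.testing.assert_allclose(
            np.diff(rot.angle_deg_unwrapped), rot.step_deltas_deg[1:], atol=1e-12
        )

    def test_reversal_antisymmetry(self):
        spec = SyntheticConstructSpec(
            n_slices=15, orientation_schedule=(20.0, 3.0), kappa=50.0, seed=41
        )
        stack, _ = generate_rotating_stack(spec)
        rev = ImageStack(list(stack)[::-1], z_step_um=stack.z_step_um)
        fwd = rotation_profile(stack)
        bwd = rotation_profile(rev)
        np.testing.assert_allclose(
            bwd.step_deltas_deg[1:], -fwd.step_deltas_deg[1:][::-1], atol=1e-9
        )
        assert rotation_range(bwd) == pytest.approx(rotation_range(fwd), abs=1e-9)

    def test_empty_slice_carries_forward_without_fabricating_jumps(self):
        spec = SyntheticConstructSpec(
            n_slices=6, orientation_schedule=(30.0, 1.0), kappa=50.0, seed=43
        )
        stack, _ = generate_rotating_stack(spec)
        slices = list(stack)
        slices[3] = np.zeros_like(slices[3])  # a dark plane mid-stack
        broken = ImageStack(slices, z_step_um=0.5)
        rot = rotation_profile(broken)
        assert rot.empty_flags[3]
        assert rot.step_deltas_deg[3] == 0.0
        assert rot.angle_deg_unwrapped[3] == rot.angle_deg_unwrapped[2]
        assert detect_rotation_jumps(rot, 30.0) == []

    def test_single_defined_slice_degenerate(self):
        spec = SyntheticConstructSpec(
            n_slices=1, orientation_schedule=[60.0], kappa=1e6, noise_model="none", seed=47
        )
        img, _ = generate_fiber_image(spec, 0)
        stack = ImageStack([np.zeros_like(img), img, np.zeros_like(img)], z_step_um=0.5)
        rot = rotation_profile(stack)
        align = alignment_profile(stack)
        assert rotation_range(rot) == pytest.approx(0.0)
        _, s = analyze_slice(img, RunConfig())
        assert align.range_deg[1] == pytest.approx(s.range_deg)

    def test_all_empty_rotation_is_flagged(self):
        stack = _stack_of(np.zeros((64, 64)), 3)
        rot = rotation_profile(stack)
        assert rot.all_empty
        assert np.isnan(rotation_range(rot))

    def test_peak_angle_stat_variant(self, steady_stack):
        rot = rotation_profile(steady_stack, angle_stat="peak")
        assert abs((rot.angle_deg_unwrapped[0] - 75.0 + 90) % 180 - 90) <= 2.0
        with pytest.raises(ValueError):
            rotation_profile(steady_stack, angle_stat="mode")


class TestJumpDetection:
    def test_flat_track_no_jumps(self, steady_stack):
        rot = rotation_profile(steady_stack)
        assert detect_rotation_jumps(rot, 30.0) == []

    def test_programmed_jump_found_at_correct_depth(self):
        sched = [20.0] * 10 + [65.0] * 10  # single 45 deg jump arriving at slice 10
        spec = SyntheticConstructSpec(
            n_slices=20, orientation_schedule=sched, kappa=50.0, seed=53
        )
        stack, _ = generate_rotating_stack(spec)
        jumps = detect_rotation_jumps(rotation_profile(stack), 30.0)
        assert len(jumps) == 1
        z, delta = jumps[0]
        assert z == pytest.approx(10 * 0.5)
        assert delta == pytest.approx(45.0, abs=5.0)

    def test_smooth_rotation_below_threshold(self):
        spec = SyntheticConstructSpec(
            n_slices=30, orientation_schedule=(0.0, 1.0), kappa=50.0, seed=59
        )
        stack, _ = generate_rotating_stack(spec)
        assert detect_rotation_jumps(rotation_profile(stack), 30.0) == []


class TestAnalyzeStack:
    def test_tables_are_consistent(self):
        spec = SyntheticConstructSpec(
            n_slices=8, orientation_schedule=(10.0, 2.0), kappa=50.0, seed=61
        )
        stack, _ = generate_rotating_stack(spec)
        out = analyze_stack(stack)
        assert len(out["per_slice"]) == 8
        assert len(out["polar_profiles"]) == 8
        s = out["summary"].iloc[0]
        assert s["n_slices"] == 8
        assert s["rotation_range_deg"] == pytest.approx(
            rotation_range(out["rotation"]), abs=1e-12
        )
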