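"""Energy metrics: closed forms, invariances, refinement oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arthroskill import (
    EnergyMetrics,
    ToolRole,
    compute_metrics,
    derive_kinematics,
    lowpass,
    normalize,
    potential_metric,
    rotational_kinetic_metric,
    translational_kinetic_metric,
    work_metric,
)
from arthroskill.energy import _total_variation

from conftest import make_trial

FS = 20.0


class TestPotential:
    def test_constant_height_zero(self):
        assert potential_metric(np.full(10, 0.3)) == 0.0

    def test_three_unit_moves(self):
        assert potential_metric([0.0, 0.01, 0.0, 0.01]) == pytest.approx(0.03)

    def test_sinusoid_total_variation_is_4A(self):
        """One full period of A sin(2 pi t), densely sampled, approaches 4A."""
        t = np.linspace(0.0, 1.0, 1001)  # 1 kHz
        for amp in (1.0, 0.25):
            tv = potential_metric(amp * np.sin(2 * np.pi * t))
            assert tv == pytest.approx(4 * amp, rel=0.005)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            potential_metric([0.0, np.nan, 1.0])


class TestTranslationalKinetic:
    def test_constant_speed_zero(self):
        assert translational_kinetic_metric(np.full(8, 2.5)) == 0.0

    def test_hand_example(self):
        assert translational_kinetic_metric([0.0, 4.0, 1.0]) == pytest.approx(7.0)

    def test_triangular_speed_profile(self):
        """0 -> vmax -> 0 speed ramp: total variation of v^2 is 2 vmax^2."""
        vmax = 0.8
        v = np.concatenate([np.linspace(0, vmax, 50), np.linspace(vmax, 0, 50)[1:]])
        assert translational_kinetic_metric(v**2) == pytest.approx(2 * vmax**2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            translational_kinetic_metric([0.0, -1.0, 2.0])


class TestRotationalKinetic:
    def test_constant_omega_zero(self):
        omega = np.tile([0.0, 0.7, 0.0], (10, 1))
        t = np.arange(10) / FS
        assert rotational_kinetic_metric(omega, t) == 0.0

    def test_hand_example(self):
        # squared-angular-speed sequence [0, 2, 1] -> |2-0| + |1-2| = 3
        omega = np.column_stack([np.sqrt([0.0, 2.0, 1.0]), np.zeros(3), np.zeros(3)])
        t = np.arange(3) / FS
        assert rotational_kinetic_metric(omega, t) == pytest.approx(3.0)

    def test_sine_rate_half_period(self):
        """omega = (sin t, 0, 0) on [0, pi]: integral of |d(sin^2 t)/dt| = 2."""
        t = np.linspace(0.0, np.pi, 4001)
        omega = np.column_stack([np.sin(t), np.zeros_like(t), np.zeros_like(t)])
        assert rotational_kinetic_metric(omega, t) == pytest.approx(2.0, rel=0.005)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rotational_kinetic_metric(np.zeros((5, 3)), np.zeros(4))


class TestWork:
    def test_zero_force_zero(self):
        assert work_metric(np.zeros(10), np.full(9, 0.01)) == 0.0

    def test_constant_force_times_path(self):
        # 2 N over a total path of 0.5 m -> 1.0 N*m
        assert work_metric(np.full(11, 2.0), np.full(10, 0.05)) == pytest.approx(1.0)

    def test_matches_refined_line_integral(self, rng):
        """Midpoint-rule work on piecewise-linear force/path matches the
        trapezoidal line integral evaluated at 10x resolution within 1%."""
        n = 41
        t = np.arange(n) / FS
        t_fine = np.arange((n - 1) * 10 + 1) / (10 * FS)
        force = 1.0 + 0.5 * np.sin(2 * np.pi * 0.4 * t) + 0.2 * np.cos(2 * np.pi * 0.25 * t)
        arc = 0.1 * t + 0.02 * np.sin(2 * np.pi * 0.3 * t)  # cumulative path length
        coarse = work_metric(force, np.diff(arc))
        force_f = np.interp(t_fine, t, force)
        arc_f = np.interp(t_fine, t, arc)
        fine = np.sum(0.5 * (force_f[:-1] + force_f[1:]) * np.diff(arc_f))
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            work_metric(np.array([1.0, -0.1, 1.0]), np.array([0.01, 0.01]))


class TestComputeMetrics:
    def test_motionless_force_free_trial_all_zero(self):
        trial = make_trial(np.zeros((64, 3)), force=np.zeros(64))
        m = compute_metrics(trial)
        assert (m.ep, m.etk, m.erk, m.w) == (0.0, 0.0, 0.0, 0.0)

    def test_arthroscope_has_no_work(self, smooth_trial):
        arthro = make_trial(
            smooth_trial.position, smooth_trial.orientation,
            tool_role=ToolRole.ARTHROSCOPE,
        )
        m = compute_metrics(arthro)
        assert m.w is None
        assert m.ep > 0 and m.etk > 0 and m.erk > 0

    def test_matches_manual_composition(self, smooth_trial):
        m = compute_metrics(smooth_trial, cutoff_hz=6.0)
        kin = derive_kinematics(smooth_trial, cutoff_hz=6.0)
        assert m.ep == pytest.approx(potential_metric(kin.height), rel=1e-12)
        assert m.etk == pytest.approx(translational_kinetic_metric(kin.speed_sq), rel=1e-12)
        assert m.erk == pytest.approx(
            rotational_kinetic_metric(kin.omega, kin.time), rel=1e-12
        )
        filtered = np.clip(lowpass(smooth_trial.force, 6.0, FS), 0.0, None)
        assert m.w == pytest.approx(work_metric(filtered, kin.path_increment), rel=1e-12)

    def test_duration_is_completion_time(self, smooth_trial):
        assert compute_metrics(smooth_trial).duration == pytest.approx(10.0)


class TestInvariances:
    def test_time_shift_and_translation(self, smooth_trial):
        m0 = compute_metrics(smooth_trial)
        shifted = make_trial(
            smooth_trial.position + np.array([0.5, -0.3, 0.2]),
            smooth_trial.orientation,
            smooth_trial.force,
            t0=99.0,
        )
        m1 = compute_metrics(shifted)
        # tolerance absorbs float jitter of the shifted time base
        assert m1.ep == pytest.approx(m0.ep, rel=1e-6)
        assert m1.etk == pytest.approx(m0.etk, rel=1e-6)
        assert m1.erk == pytest.approx(m0.erk, rel=1e-6)
        assert m1.w == pytest.approx(m0.w, rel=1e-6)

    def test_ep_invariant_to_rotation_about_gravity_axis(self, smooth_trial):
        theta = 0.7
        rot_z = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = make_trial(
            smooth_trial.position @ rot_z.T, smooth_trial.orientation, smooth_trial.force
        )
        assert compute_metrics(rotated).ep == pytest.approx(
            compute_metrics(smooth_trial).ep, rel=1e-9
        )

    def test_homogeneity_of_position_scaling(self, smooth_trial):
        c = 3.0
        scaled = make_trial(
            smooth_trial.position * c, smooth_trial.orientation, smooth_trial.force
        )
        m0, m1 = compute_metrics(smooth_trial), compute_metrics(scaled)
        assert m1.ep == pytest.approx(c * m0.ep, rel=1e-9)
        assert m1.etk == pytest.approx(c**2 * m0.etk, rel=1e-9)
        assert m1.erk == pytest.approx(m0.erk, rel=1e-12)

    def test_normalized_metrics_unit_invariant(self, smooth_trial, rng):
        """Rescaling trial and ideal positions together (mm vs m) leaves the
        normalized ratios unchanged."""
        ideal = make_trial(
            smooth_trial.position * 0.5 + 0.01 * rng.standard_normal((201, 3)) * 0,
            smooth_trial.orientation,
            smooth_trial.force * 0.8,
        )
        nm_m = normalize(compute_metrics(smooth_trial), compute_metrics(ideal))
        trial_mm = make_trial(
            smooth_trial.position * 1000, smooth_trial.orientation, smooth_trial.force
        )
        ideal_mm = make_trial(
            ideal.position * 1000, ideal.orientation, ideal.force
        )
        nm_mm = normalize(compute_metrics(trial_mm), compute_metrics(ideal_mm))
        assert nm_mm.ep_n == pytest.approx(nm_m.ep_n, rel=1e-9)
        assert nm_mm.etk_n == pytest.approx(nm_m.etk_n, rel=1e-9)
        assert nm_mm.erk_n == pytest.approx(nm_m.erk_n, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=2, max_value=6))
    def test_decimation_subadditivity(self, step):
        """Metrics on a decimated trace never exceed the full-trace value."""
        rng = np.random.default_rng(step)
        series = np.cumsum(rng.standard_normal(120))
        assert _total_variation(series[::step]) <= _total_variation(series) + 1e-12


class TestNormalize:
    def test_identical_to_ideal_gives_ones(self):
        m = EnergyMetrics(ep=0.2, etk=0.1, erk=5.0, w=0.3, duration=10.0)
        nm = normalize(m, m)
        assert (nm.ep_n, nm.etk_n, nm.erk_n, nm.w_n) == (1.0, 1.0, 1.0, 1.0)

    def test_ratio_example(self):
        m = EnergyMetrics(ep=0.06, etk=1.0, erk=1.0, w=None, duration=5.0)
        ideal = EnergyMetrics(ep=0.02, etk=1.0, erk=1.0, w=None, duration=5.0)
        assert normalize(m, ideal).ep_n == pytest.approx(3.0)

    def test_absent_component_absent_in_result(self):
        m = EnergyMetrics(ep=1.0, etk=1.0, erk=1.0, w=None, duration=1.0)
        ideal = EnergyMetrics(ep=1.0, etk=1.0, erk=1.0, w=2.0, duration=1.0)
        assert normalize(m, ideal).w_n is None

    def test_zero_ideal_component_errors_by_name(self):
        m = EnergyMetrics(ep=1.0, etk=1.0, erk=1.0, w=None, duration=1.0)
        ideal = EnergyMetrics(ep=0.0, etk=1.0, erk=1.0, w=None, duration=1.0)
        with pytest.raises(ValueError, match="ep"):
            normalize(m, ideal)
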