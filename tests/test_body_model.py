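"""CoM reconstruction, angular momentum, torque and joint angles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vppgait.body_model import (
    SegmentParameterTable,
    compute_angles,
    compute_angular_momentum,
    compute_ankle_torque,
    compute_com,
    default_segment_table,
)
from vppgait.config import ConfigurationError, ValidationError
from vppgait.io import MarkerStream


def make_table(rows):
    return SegmentParameterTable(pd.DataFrame(
        rows, columns=["segment", "proximal_marker", "distal_marker",
                       "mass_fraction", "com_fraction", "gyration_fraction"]))


def stream_from(positions, n=5, dt=1 / 240):
    t = np.arange(n) * dt
    return MarkerStream(time=t, positions={
        k: np.tile(np.asarray(v, float), (n, 1)) for k, v in positions.items()})


class TestSegmentTable:
    def test_default_table_is_valid_and_resolvable(self, default_table):
        from vppgait.io import MARKER_NAMES

        assert default_table.required_markers() <= set(MARKER_NAMES)
        assert default_table.frame["mass_fraction"].sum() == pytest.approx(1.0)

    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            make_table([("a", "p", "d", 0.6, 0.5, 0.3),
                        ("b", "p", "d", 0.3, 0.5, 0.3)])

    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            make_table([("a", "p", "d", 1.0, 1.5, 0.3)])

    def test_csv_round_trip(self, tmp_path, default_table):
        path = tmp_path / "table.csv"
        default_table.to_csv(path)
        again = SegmentParameterTable.from_csv(path)
        pd.testing.assert_frame_equal(
            again.frame, default_table.frame[again.frame.columns])


class TestComputeCom:
    def test_single_segment_midpoint(self):
        table = make_table([("rod", "p", "d", 1.0, 0.5, 0.3)])
        stream = stream_from({"p": [0, 0, 0], "d": [1, 0, 0]})
        com = compute_com(stream, table)
        assert np.allclose(com, [[0.5, 0, 0]] * 5)

    def test_two_equal_segments_average(self):
        table = make_table([("a", "p1", "d1", 0.5, 0.5, 0.3),
                            ("b", "p2", "d2", 0.5, 0.5, 0.3)])
        stream = stream_from({"p1": [0, 0, 0], "d1": [2, 0, 0],
                              "p2": [0, 0, 2], "d2": [0, 0, 4]})
        com = compute_com(stream, table)
        assert np.allclose(com, [[0.5, 0, 1.5]] * 5)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
    def test_translation_equivariance(self, tx, ty, tz):
        table = default_segment_table()
        rng = np.random.default_rng(1)
        base = {name: rng.normal(0, 1, (4, 3))
                for name in table.required_markers()}
        t = np.arange(4) / 240
        s0 = MarkerStream(time=t, positions=base)
        s1 = MarkerStream(time=t, positions={
            k: v + np.array([tx, ty, tz]) for k, v in base.items()})
        shift = compute_com(s1, table) - compute_com(s0, table)
        assert np.allclose(shift, [tx, ty, tz], atol=1e-9)

    def test_missing_marker_reported_by_name(self):
        table = make_table([("rod", "present", "absent", 1.0, 0.5, 0.3)])
        stream = stream_from({"present": [0, 0, 0]})
        with pytest.raises(ConfigurationError, match="absent"):
            compute_com(stream, table)


class TestAngularMomentum:
    def test_static_body_has_zero_momentum(self):
        table = make_table([("rod", "p", "d", 1.0, 0.5, 0.3)])
        stream = stream_from({"p": [0, 0, 0], "d": [1, 0, 0]}, n=50)
        L = compute_angular_momentum(stream, table, 70.0)["angular_momentum"]
        assert np.allclose(L, 0.0, atol=1e-12)

    def test_rigid_translation_has_zero_momentum(self):
        table = default_segment_table()
        rng = np.random.default_rng(3)
        base = {name: rng.normal(0, 1, 3)
                for name in table.required_markers()}
        n, dt = 100, 1 / 240
        t = np.arange(n) * dt
        vel = np.array([1.3, 0.0, 0.2])
        stream = MarkerStream(time=t, positions={
            k: v[None, :] + t[:, None] * vel[None, :]
            for k, v in base.items()})
        L = compute_angular_momentum(stream, table, 60.0)["angular_momentum"]
        assert np.abs(L).max() < 1e-9

    def test_point_mass_on_circle_matches_m_r2_omega(self):
        """A short segment (nearly a point mass) orbiting the CoM-origin:
        |L| ~ m r^2 w.  A massive counterweight segment pins the CoM."""
        m, r, w = 70.0, 0.8, 2.0
        n, dt = 2000, 1 / 960
        t = np.arange(n) * dt
        eps = 1e-4  # tiny rod => negligible spin term
        ang = w * t
        center = np.column_stack([r * np.cos(ang), np.zeros(n),
                                  r * np.sin(ang)])
        axis = np.column_stack([np.cos(ang), np.zeros(n), np.sin(ang)])
        table = make_table([("orbit", "p", "d", 0.5, 0.5, 0.01),
                            ("anchor", "q", "e", 0.5, 0.5, 0.01)])
        stream = MarkerStream(time=t, positions={
            "p": center - eps * axis, "d": center + eps * axis,
            "q": -center - eps * axis, "e": -center + eps * axis})
        L = compute_angular_momentum(stream, table, m)["angular_momentum"]
        expected = 2 * (0.5 * m) * r**2 * w  # both halves orbit at radius r
        interior = slice(n // 4, -n // 4)
        assert np.median(L[interior]) == pytest.approx(expected, rel=0.01)

    def test_bar_spinning_about_its_com_matches_rod_inertia(self):
        m, length, w = 60.0, 1.0, 3.0
        n, dt = 2000, 1 / 960
        t = np.arange(n) * dt
        ang = w * t
        half = length / 2 * np.column_stack([np.cos(ang), np.zeros(n),
                                             np.sin(ang)])
        gyr = 1 / np.sqrt(12)  # uniform rod about its centre
        table = make_table([("bar", "p", "d", 1.0, 0.5, gyr)])
        stream = MarkerStream(time=t, positions={"p": -half, "d": half})
        L = compute_angular_momentum(stream, table, m)["angular_momentum"]
        expected = m * (gyr * length) ** 2 * w
        interior = slice(n // 4, -n // 4)
        assert np.median(L[interior]) == pytest.approx(expected, rel=0.01)

    def test_normalization_requires_positive_scales(self):
        table = make_table([("rod", "p", "d", 1.0, 0.5, 0.3)])
        stream = stream_from({"p": [0, 0, 0], "d": [1, 0, 0]}, n=10)
        with pytest.raises(ValidationError):
            compute_angular_momentum(stream, table, 70.0, mean_speed=0.0,
                                     com_height=1.0)
        out = compute_angular_momentum(stream, table, 70.0, mean_speed=1.2,
                                       com_height=0.95)
        assert np.allclose(out["normalized"],
                           out["angular_momentum"] / (70.0 * 1.2 * 0.95))


class TestAnkleTorque:
    def test_cop_at_ankle_ground_level_gives_zero(self):
        grf = np.array([[0.0, 0.0, 700.0]])
        cop = np.array([[0.3, 0.0]])
        ankle = np.array([[0.3, 0.0, 0.0]])
        assert compute_ankle_torque(grf, cop, ankle, 70.0)[0] == 0.0

    def test_decimeter_lever_vertical_force(self):
        grf = np.array([[0.0, 0.0, 700.0]])
        cop = np.array([[0.4, 0.0]])
        ankle = np.array([[0.3, 0.0, 0.0]])
        tau = compute_ankle_torque(grf, cop, ankle, 70.0)
        assert tau[0] == pytest.approx(1.0)

    def test_matches_cross_product_oracle_and_translation_invariance(self):
        rng = np.random.default_rng(7)
        n = 40
        grf = np.column_stack([rng.normal(0, 100, n), np.zeros(n),
                               rng.uniform(100, 900, n)])
        cop = np.column_stack([rng.normal(0, 0.2, n), np.zeros(n)])
        ankle = np.column_stack([rng.normal(0, 0.2, n), np.zeros(n),
                                 rng.uniform(0.05, 0.1, n)])
        tau = compute_ankle_torque(grf, cop, ankle, 65.0)
        lever = np.column_stack([cop[:, 0] - ankle[:, 0], -ankle[:, 2]])
        oracle = (lever[:, 0] * grf[:, 2] - lever[:, 1] * grf[:, 0]) / 65.0
        assert np.allclose(tau, oracle)
        # shifting the lab origin moves CoP and ankle together: no change
        tau_shift = compute_ankle_torque(grf, cop + [1.7, 0.0],
                                         ankle + [1.7, 0.0, 0.0], 65.0)
        assert np.allclose(tau_shift, tau, atol=1e-9)


class TestAngles:
    def _walker(self, **over):
        pos = {"L5": [0, 0, 1.0], "R_acromion": [0, -0.2, 1.5],
               "L_acromion": [0, 0.2, 1.5],
               "R_trochanter": [0, -0.1, 0.9], "R_knee": [0, -0.1, 0.5],
               "R_lat_malleolus": [0, -0.1, 0.1], "R_toe": [0.2, -0.1, 0.1]}
        pos.update(over)
        return stream_from(pos)

    def test_upright_trunk_angle_zero(self):
        angles = compute_angles(self._walker())
        assert np.allclose(angles["trunk"], 0.0, atol=1e-9)

    def test_forward_lean_positive(self):
        angles = compute_angles(self._walker(
            R_acromion=[0.5, -0.2, 1.5], L_acromion=[0.5, 0.2, 1.5]))
        assert np.all(angles["trunk"] > 0)

    def test_collinear_leg_fully_extended(self):
        angles = compute_angles(self._walker())
        assert np.allclose(angles["knee"], 180.0, atol=1e-9)

    def test_right_angle_foot(self):
        angles = compute_angles(self._walker(R_toe=[0.2, -0.1, 0.1]))
        # shank straight down, foot straight forward: 90 degrees
        assert np.allclose(angles["ankle"], 90.0, atol=1e-9)

    def test_degenerate_vectors_masked(self):
        angles = compute_angles(self._walker(R_toe=[0, -0.1, 0.1]))
        assert np.all(np.isnan(angles["ankle"]))

    def test_handstand_uses_arm_chain(self):
        pos = {"L5": [0, 0, 1.0], "R_acromion": [0, -0.2, 1.5],
               "L_acromion": [0, 0.2, 1.5], "R_elbow": [0, -0.2, 1.0],
               "R_wrist": [0, -0.2, 0.5], "R_finger": [0.1, -0.2, 0.5]}
        angles = compute_angles(stream_from(pos), handstand=True)
        assert np.allclose(angles["knee"], 180.0, atol=1e-9)  # elbow straight
        assert np.allclose(angles["ankle"], 90.0, atol=1e-9)  # wrist square

    def test_synthetic_walker_matches_generator_truth(self, clean_trial):
        trial, truth = clean_trial
        angles = compute_angles(trial.markers, side="R")
        assert np.allclose(angles["trunk"], truth["angles"]["trunk"],
                           atol=1e-9)
        assert np.allclose(angles["knee"], truth["angles"]["knee_R"],
                           atol=1e-9)
        assert np.allclose(angles["ankle"], truth["angles"]["ankle_R"],
                           atol=1e-9)
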