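"""Core VPP geometry: least-squares fit, R^2 statistic, classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import grid_search_vpp, random_line_instance
from vppgait.config import (
    DegenerateGeometryError,
    UndefinedStatisticError,
)
from vppgait.synthetic import FanSpec, generate_force_fan
from vppgait.vpp import (
    ForceLineSet,
    VPPFit,
    aggregate,
    classify_vpp,
    compute_r_squared,
    fit_vpp,
    median_mad,
)


def _lines(origins, directions):
    origins = np.asarray(origins, float)
    d = np.asarray(directions, float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    n = len(origins)
    return ForceLineSet(origins, d, np.ones(n), np.zeros(n, dtype=int))


class TestFitVpp:
    def test_two_lines_exact_intersection(self):
        # vertical line through x=0 and diagonal through (0.3, 0) at 45 deg
        lines = _lines([[0.0, 0.0], [0.3, 0.0]], [[0, 1], [-1, 1]])
        fit = fit_vpp(lines)
        assert fit.x == pytest.approx(0.0, abs=1e-12)
        assert fit.z == pytest.approx(0.3, abs=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-18)

    def test_noiseless_fan_recovers_plant(self):
        fan = generate_force_fan(FanSpec(vpp_x=0.02, vpp_z=0.42, n_samples=33))
        fit = fit_vpp(fan)
        assert abs(fit.x - 0.02) < 1e-9
        assert abs(fit.z - 0.42) < 1e-9

    def test_parallel_lines_raise(self):
        lines = _lines([[0, 0], [0.1, 0], [0.2, 0]], [[0, 1]] * 3)
        with pytest.raises(DegenerateGeometryError):
            fit_vpp(lines)

    def test_single_line_raises(self):
        lines = _lines([[0, 0]], [[0, 1]])
        with pytest.raises(DegenerateGeometryError):
            fit_vpp(lines)

    def test_matches_grid_oracle_on_noisy_fan(self):
        fan = generate_force_fan(FanSpec(vpp_z=0.3, angle_noise_sd=3.0,
                                         n_samples=200, seed=42))
        fit = fit_vpp(fan)
        gx, gz = grid_search_vpp(fan, coarse=0.01)
        assert abs(fit.x - gx) <= 1e-3
        assert abs(fit.z - gz) <= 1e-3

    def test_two_stage_oracle_equals_exhaustive(self):
        """Refined sweep = single-stage exhaustive sweep (convex objective)."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            inst, _ = random_line_instance(rng, n_lines=15)
            fast = grid_search_vpp(inst, resolution=2e-3, coarse=0.02)
            full = grid_search_vpp(inst, resolution=2e-3, coarse=None)
            assert fast == pytest.approx(full, abs=1e-9)

    @given(st.floats(-0.3, 0.3), st.floats(-0.3, 0.3))
    def test_translation_equivariance(self, dx, dz):
        fan = generate_force_fan(FanSpec(vpp_z=0.3, angle_noise_sd=2.0,
                                         n_samples=40, seed=3))
        fit0 = fit_vpp(fan)
        shifted = ForceLineSet(fan.origins + [dx, dz], fan.directions,
                               fan.magnitudes, fan.trial_ids)
        fit1 = fit_vpp(shifted)
        assert fit1.x == pytest.approx(fit0.x + dx, abs=1e-9)
        assert fit1.z == pytest.approx(fit0.z + dz, abs=1e-9)

    def test_weighted_variant_reduces_to_unweighted_for_equal_weights(self):
        fan = generate_force_fan(FanSpec(vpp_z=0.3, angle_noise_sd=2.0,
                                         n_samples=40, seed=9))
        f0 = fit_vpp(fan, weight_by_force=False)
        f1 = fit_vpp(fan, weight_by_force=True)  # all magnitudes are 1
        assert (f0.x, f0.z) == pytest.approx((f1.x, f1.z), abs=1e-12)


class TestRSquared:
    def test_perfect_fit_gives_one(self):
        fan = generate_force_fan(FanSpec(vpp_z=0.3, n_samples=60))
        fit = fit_vpp(fan)
        assert compute_r_squared(fan, fit) == pytest.approx(1.0, abs=1e-12)

    def test_grand_mean_prediction_gives_zero(self):
        """theta_exp symmetric about 90 deg, VPP predicting exactly 90 deg
        everywhere => numerator equals denominator => R^2 = 0."""
        theta = np.radians([80.0, 90.0, 100.0])
        d = np.column_stack([np.cos(theta), np.sin(theta)])
        origins = np.array([[-0.1, -1.0], [0.0, -1.0], [0.1, -1.0]])
        lines = ForceLineSet(origins, d, np.ones(3), np.zeros(3, dtype=int))
        # a pivot far above each origin predicts ~90 deg: build exact 90 deg
        # predictions by placing the pivot directly over each CoP -- use the
        # formula directly through a fit whose position is checked instead
        vpp = VPPFit(x=0.0, z=1e9, residual=0.0, n_lines=3)
        r2 = compute_r_squared(lines, vpp)
        assert r2 == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_pairs(self):
        """Five (theta_exp, theta_vpp) pairs evaluated against independent
        spreadsheet-style arithmetic of the definition."""
        theta_exp = np.radians([70.0, 80.0, 95.0, 100.0, 110.0])
        origins = np.column_stack([np.linspace(-0.2, 0.2, 5),
                                   np.full(5, -1.0)])
        d = np.column_stack([np.cos(theta_exp), np.sin(theta_exp)])
        lines = ForceLineSet(origins, d, np.ones(5), np.zeros(5, dtype=int))
        vpp = VPPFit(x=0.05, z=0.25, residual=0.0, n_lines=5)
        delta = np.array([0.05, 0.25]) - origins
        theta_vpp = np.arctan2(delta[:, 1], delta[:, 0])
        expected = 1.0 - (np.sum((theta_exp - theta_vpp) ** 2)
                          / np.sum((theta_exp - theta_exp.mean()) ** 2))
        assert compute_r_squared(lines, vpp) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_all_angles_equal_is_undefined(self):
        lines = _lines([[0, -1], [0.1, -1]], [[0, 1], [0, 1]])
        vpp = VPPFit(x=0.0, z=0.3, residual=0.0, n_lines=2)
        with pytest.raises(UndefinedStatisticError):
            compute_r_squared(lines, vpp)

    def test_rotation_invariance(self):
        """Rigidly rotating the whole line set about the CoM changes every
        angle by the same constant, leaving R^2 unchanged."""
        fan = generate_force_fan(FanSpec(vpp_z=0.3, angle_noise_sd=2.0,
                                         n_samples=50, seed=21))
        fit = fit_vpp(fan)
        r2 = compute_r_squared(fan, fit)
        phi = np.radians(17.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        rotated = ForceLineSet(fan.origins @ rot.T, fan.directions @ rot.T,
                               fan.magnitudes, fan.trial_ids)
        fit_r = fit_vpp(rotated)
        r2_r = compute_r_squared(rotated, fit_r)
        assert r2_r == pytest.approx(r2, abs=1e-9)

    def test_per_trial_predictions_pool_grand_mean(self):
        """Per-trial mode: each trial predicted by its own VPP, grand mean
        pooled -- must match a direct evaluation."""
        fans = [generate_force_fan(FanSpec(vpp_z=0.3, angle_noise_sd=2.0,
                                           n_samples=30, seed=s))
                for s in (1, 2)]
        pooled = ForceLineSet.concatenate(fans)
        fits = {i: fit_vpp(f) for i, f in enumerate(fans)}
        r2 = compute_r_squared(pooled, fits)
        theta = pooled.theta_exp
        num = 0.0
        for i, fan in enumerate(fans):
            delta = fits[i].position[None, :] - fan.origins
            tv = np.arctan2(delta[:, 1], delta[:, 0])
            num += float(np.sum((fan.theta_exp - tv) ** 2))
        den = float(np.sum((theta - theta.mean()) ** 2))
        assert r2 == pytest.approx(1 - num / den, rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize("r2,expected", [
        (0.93, True),        # typical walking value: a point
        (-32.74, False),     # extreme outlier: clearly not a point
        (0.6, False),        # boundary: strict inequality
        (0.600001, True),
        (float("-inf"), False),
    ])
    def test_threshold_rule(self, r2, expected):
        assert classify_vpp(r2, 0.6) is expected

    def test_noise_monotonicity(self):
        """R^2 decreases monotonically with planted angular noise."""
        from scipy.stats import spearmanr

        sds = [0.5, 1.0, 2.0, 4.0, 8.0]
        med = []
        for sd in sds:
            r2s = []
            for s in range(20):
                fan = generate_force_fan(FanSpec(vpp_z=0.3, angle_noise_sd=sd,
                                                 n_samples=100, seed=s))
                r2s.append(compute_r_squared(fan, fit_vpp(fan)))
            med.append(np.median(r2s))
        rho = spearmanr(sds, med).statistic
        assert rho < -0.9


class TestRecovery:
    def test_horizontal_position_is_well_identified(self):
        """Median |VPPx - plant| over seeded noisy fans stays within the
        +/-0.01 m envelope typical of walking data."""
        errs = [abs(fit_vpp(generate_force_fan(
            FanSpec(vpp_x=0.0, vpp_z=0.3, angle_noise_sd=2.0,
                    n_samples=50, seed=s))).x) for s in range(50)]
        assert np.median(errs) < 0.01

    def test_vertical_error_grows_with_noise_and_attenuates_downward(self):
        """VPPz is the weakly identified coordinate of a narrow fan: its
        error grows with angular noise, and angular noise systematically
        pulls the intersection down toward the CoP origins (an
        attenuation effect of the perpendicular-distance objective,
        confirmed by the grid-search oracle)."""
        med_signed, med_abs = [], []
        for sd in (0.5, 2.0, 5.0):
            errors = [fit_vpp(generate_force_fan(
                FanSpec(vpp_z=0.3, angle_noise_sd=sd, n_samples=50,
                        seed=s))).z - 0.3 for s in range(100)]
            med_signed.append(np.median(errors))
            med_abs.append(np.median(np.abs(errors)))
        assert med_abs[0] < med_abs[1] < med_abs[2]
        assert all(m < 0 for m in med_signed)  # downward attenuation
        assert med_abs[0] < 0.06  # frozen from the grid-search oracle runs


class TestAggregate:
    def test_median_mad_basics(self):
        assert median_mad([1, 1, 1]) == (1.0, 0.0)
        assert median_mad([0, 1, 100]) == (1.0, 1.0)

    def test_vpp_variables_use_median_mad_others_mean_sd(self):
        per_participant = {
            "P1": {"vpp_z": 0.0, "speed": 1.0},
            "P2": {"vpp_z": 1.0, "speed": 2.0},
            "P3": {"vpp_z": 100.0, "speed": 3.0},
        }
        out = aggregate(per_participant)
        assert out["vpp_z"]["center"] == 1.0 and out["vpp_z"]["spread"] == 1.0
        assert out["speed"]["center"] == pytest.approx(2.0)
        assert out["speed"]["spread"] == pytest.approx(1.0)

    def test_missing_participant_recorded_not_zeroed(self):
        out = aggregate({"P1": {"vpp_z": float("nan")},
                         "P2": {"vpp_z": 0.4}})
        assert out["vpp_z"]["n"] == 1
        assert out["vpp_z"]["center"] == pytest.approx(0.4)
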