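import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def grid_search_vpp(lines, xlim=(-0.5, 0.5), zlim=(-0.5, 1.5),
                    resolution=1e-3, coarse=None):
    """Brute-force VPP oracle: grid minimiser of the summed squared
    perpendicular distances.

    The objective is a convex quadratic, so a coarse sweep followed by a
    fine exhaustive sweep around the coarse minimum finds the same grid
    point as a full fine sweep (verified directly in the test suite).
    Pass ``coarse=None`` for the single-stage exhaustive search.
    """
    def objective(grid_x, grid_z):
        gx, gz = np.meshgrid(grid_x, grid_z, indexing="ij")
        total = np.zeros_like(gx)
        for p, d in zip(lines.origins, lines.directions):
            rx = gx - p[0]
            rz = gz - p[1]
            along = rx * d[0] + rz * d[1]
            total += rx * rx + rz * rz - along * along
        return total

    def sweep(x0, x1, z0, z1, step):
        grid_x = np.arange(x0, x1 + step / 2, step)
        grid_z = np.arange(z0, z1 + step / 2, step)
        total = objective(grid_x, grid_z)
        i, j = np.unravel_index(np.argmin(total), total.shape)
        return float(grid_x[i]), float(grid_z[j])

    if coarse is None:
        return sweep(*xlim, *zlim, resolution)
    cx, cz = sweep(*xlim, *zlim, coarse)
    w = 2 * coarse
    return sweep(max(xlim[0], cx - w), min(xlim[1], cx + w),
                 max(zlim[0], cz - w), min(zlim[1], cz + w), resolution)


def random_line_instance(rng, n_lines=None, xlim=(-0.4, 0.4), zlim=(-0.3, 1.3)):
    """A random well-posed line bundle through a random planted point."""
    from vppgait.vpp import ForceLineSet

    n = n_lines or int(rng.integers(5, 51))
    planted = np.array([rng.uniform(*xlim), rng.uniform(*zlim)])
    origins = np.column_stack([rng.uniform(-0.3, 0.3, n),
                               rng.uniform(-1.2, -0.8, n)])
    aim = planted[None, :] - origins
    ang = np.arctan2(aim[:, 1], aim[:, 0]) + rng.normal(0, np.radians(3), n)
    dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    return ForceLineSet(origins, dirs, np.ones(n), np.zeros(n, dtype=int)), planted


@pytest.fixture(scope="session")
def default_table():
    from vppgait.body_model import default_segment_table

    return default_segment_table()


@pytest.fixture(scope="session")
def clean_trial():
    """One noiseless synthetic trial plus its ground truth."""
    from vppgait.synthetic import FanSpec, TrialSpec, generate_gait_trial

    spec = TrialSpec(seed=11, vpp=FanSpec(vpp_x=0.0, vpp_z=0.3,
                                          angle_noise_sd=0.0))
    return generate_gait_trial(spec)
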