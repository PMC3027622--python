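import numpy as np
import pandas as pd
import pytest

from brbud import VarianceParams, build_segments, filter_segments


def fixes_frame(rows, animal="a1"):
    """Fixes frame from (t, x, y[, p]) tuples."""
    recs = []
    for r in rows:
        t, x, y = r[:3]
        p = r[3] if len(r) > 3 else 1.0
        recs.append((animal, float(t), float(x), float(y), float(p)))
    return pd.DataFrame(recs, columns=["id", "t", "x", "y", "p"])


def single_segment(z0, z1, T, params=None, T_R=None):
    """Segments frame holding one included segment."""
    T_R = T if T_R is None else T_R
    L = float(np.hypot(z1[0] - z0[0], z1[1] - z0[1]))
    return pd.DataFrame([{
        "id": "a1", "t0": 0.0, "t1": T_R,
        "x0": z0[0], "y0": z0[1], "x1": z1[0], "y1": z1[1],
        "T_R": T_R, "T": T, "L": L, "p": T / T_R,
        "included": True, "reason": "none", "null_d": False,
    }])


@pytest.fixture
def buffalo_params():
    """Parameter regime of the worked example: sigma_min 100 m,
    D 440 m^2/min, T_max 180 min, constant-weight variance."""
    return VarianceParams(100.0, 440.0, 180.0, "constant_weight")


@pytest.fixture
def triangle_fixes():
    """3-4-5 track: (0,0) -> (300,400) in 30 min."""
    return fixes_frame([(0, 0, 0), (30, 300, 400)])


def filtered_brownian_segments(seed, n_steps, speed=20.0, T_R=30.0,
                               T_max=180.0):
    """Brownian track subsampled to T_R and filtered; returns (segments, D)."""
    from brbud import WalkParams, diffusion_coefficient, gps_subsample, \
        simulate_walk

    p = WalkParams(step_dt=1.0, speed=speed, c=0.0, kind="brownian",
                   seed=seed)
    fixes = simulate_walk(p, n_steps)
    sub = gps_subsample(fixes, T_R)
    return filter_segments(build_segments(sub), T_max), \
        diffusion_coefficient(p)
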