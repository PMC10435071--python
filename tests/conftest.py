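import numpy as np
import pytest

import ofr
from ofr.kinematics import VelocityTrace, default_grid


@pytest.fixture
def truth():
    """Default generator ground truth."""
    return ofr.GroundTruth()


@pytest.fixture
def clean_truth():
    """Noiseless truth with no delay modulation: latency 60 ms, ramp fittable."""
    return ofr.GroundTruth(
        base_latency=60.0, latency_delay_slope=0.0, gain_delay_decay=1e9,
        congruence_factor=1.0, noise_sd=0.0,
    )


@pytest.fixture
def delay_session(truth):
    """A small postsaccadic-delay session (20 trials per delay level)."""
    design = ofr.make_design("delay", 10, seed=11)
    return ofr.Session(traces=ofr.simulate_session(design, truth, 11))


def make_noise_traces(rng, labels, grid=None, scale=1.0):
    """Velocity traces of pure white noise carrying arbitrary labels."""
    if grid is None:
        grid = default_grid()
    traces = []
    for tid, lab in enumerate(labels):
        v = rng.normal(0.0, scale, len(grid))
        traces.append(
            VelocityTrace(
                trial_id=tid, t_aligned=grid, vx=v, vy=v, v_along=v,
                valid_mask=np.ones(len(grid), bool), meta=dict(lab),
            )
        )
    return traces
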