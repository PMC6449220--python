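import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def two_sided_cdf_trials(p, n_per_side, rng, deadline=3.0):
    """Same table via the fast inverse-CDF sampler (simple model only)."""
    from rtvalid.diffusion import sample_fpt_inverse_cdf

    frames = []
    for stim in ("L", "R"):
        rt, up, to = sample_fpt_inverse_cdf(p, stim, n_per_side, deadline, rng)
        frames.append(
            pd.DataFrame(
                {
                    "stimulus": stim,
                    "response": np.where(up, "R", "L"),
                    "rt": rt,
                    "timed_out": to,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = (out["response"] == out["stimulus"]) & ~out["timed_out"]
    out["participant"] = 0
    return out


@pytest.fixture(scope="session")
def session_table():
    """One default factorial session, shared across tests."""
    import rtvalid as rv

    return rv.simulate_factorial_session(rng_seed=20260925)


@pytest.fixture(scope="session")
def relabelled_session(session_table):
    import rtvalid as rv

    return rv.relabel_trials(session_table)


@pytest.fixture(scope="session")
def experiments(relabelled_session):
    import rtvalid as rv

    return rv.construct_pseudo_experiments(relabelled_session, rng_seed=7)
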