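import numpy as np
import pandas as pd
import pytest

import delaychoice as dc


@pytest.fixture(scope="session")
def catalog():
    return dc.default_catalog()


def synth_trials(k, beta, n, rng, delays=(1, 30, 365, 1825, 3650)):
    """Valued trials with choices drawn from the softmax model at (k, beta).

    The trials follow the task's smaller-sooner/larger-later construction:
    a clearly pleasant delayed option (undiscounted value near the top of
    the rating scale, as the monetary task's immediate-plus-extra payoffs
    are) against a less pleasant immediate option drawn between indifference
    and that value, with delays spanning the delay sets of all task variants
    (1 day to 10 years) so that both shallow and steep discount rates are
    identifiable.
    """
    rd = rng.uniform(8.0, 10.0, n)
    vi = rng.uniform(0.0, rd)
    d = rng.choice(delays, n).astype(float)
    vd = rd / (1.0 + k * d)
    p_imp = 1.0 / (1.0 + np.exp(-(vi - vd) / beta))
    choice = np.where(rng.random(n) < p_imp, "impulsive", "nonimpulsive")
    return pd.DataFrame({"Vi": vi, "R_d": rd, "D_days": d, "choice": choice})


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def healthy_cohort():
    """Small healthy cohort reused by read-only tests."""
    import dataclasses
    cfg = dc.CohortConfig(
        groups=[dataclasses.replace(dc.GROUP_PRESETS["healthy"], n=8)],
        n_episodic_sessions=1,
    )
    return dc.simulate_cohort(cfg, seed=11)
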