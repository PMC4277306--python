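import warnings

import numpy as np
import pytest
from hypothesis import settings

import streamtemp as st

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def circ_diff(a, b):
    """Wrapped angular difference in (-pi, pi]."""
    return (np.asarray(a) - np.asarray(b) + np.pi) % (2 * np.pi) - np.pi


@pytest.fixture(scope="session")
def recovery_8y():
    """Small generative fixture with a moderate-length fit, shared by tests
    that only need a converged posterior (not a precise one)."""
    pa, pq, lk = st.default_recovery_setup(8, seed=42)
    truth = st.simulate_m1_generative(pa, pq, lk, seed=1)
    model = st.build_m1(truth.wt, truth.at, truth.q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = model.fit(n_chains=3, n_burn=2000, n_keep=2000, seed=2)
    return {"truth": truth, "pa": pa, "pq": pq, "lk": lk, "model": model, "post": post}
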