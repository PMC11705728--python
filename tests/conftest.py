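"""Shared fixtures: small synthetic bundles and survival fixtures.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hiwinter.synthetic import discovery_config, simulate_bundle, validation_config


@pytest.fixture(scope="session")
def small_bundle():
    """150-sample, 20-probe null bundle (two centers)."""
    cfg = discovery_config(seed=1, n_probes=20, n_per_center=75, centers=("A", "B"))
    return cfg, simulate_bundle(cfg)


@pytest.fixture(scope="session")
def null_pair():
    """Independent discovery/validation null cohorts sharing probe ids."""
    cd = discovery_config(seed=11, n_probes=40, n_per_center=150, centers=("A", "B"))
    cv = validation_config(seed=12, n_probes=40, n_per_center=250)
    return (cd, simulate_bundle(cd, with_expression=False)), (
        cv,
        simulate_bundle(cv, with_expression=False),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_survival(rng, n, p=2, censor_frac=0.3, betas=None):
    """Tiny random censored survival fixture for oracle comparisons."""
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
    )
    if betas is None:
        betas = np.zeros(p)
    lp = X.to_numpy() @ np.asarray(betas)
    t = rng.exponential(np.exp(-lp))
    if censor_frac > 0:
        c = rng.exponential(np.quantile(t, 1 - censor_frac) * 2, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
    else:
        time, event = t, np.ones(n, dtype=int)
    if event.sum() == 0:
        event[np.argmin(time)] = 1
    return time, event, X
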