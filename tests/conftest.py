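"""Shared fixtures: small simulated METs and toy designs."""

import numpy as np
import pandas as pd
import pytest

from metgs.met_design import MetDataset, ModelSpec
from metgs.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def tiny_met():
    """s=2, v=40, p=30 simulated MET (p <= v so both parameterizations run)."""
    cfg = SimConfig(v=40, p=30, reps=2, rows=4)
    data, markers, truth = simulate(cfg, 21)
    return data, markers, truth


@pytest.fixture(scope="session")
def small_met():
    """s=2, v=60, p=120 simulated MET for model-level checks."""
    cfg = SimConfig(v=60, p=120, reps=3, rows=6)
    data, markers, truth = simulate(cfg, 7)
    return data, markers, truth


@pytest.fixture()
def oneway_dataset():
    """Balanced one-way layout: 8 lines x 4 reps, single trial, no blocks."""
    rng = np.random.default_rng(3)
    g, r = 8, 4
    sg, se = 2.0, 1.0
    u = rng.normal(0, np.sqrt(sg), g)
    recs = []
    for i in range(g):
        for j in range(r):
            recs.append(
                {
                    "trial": "T1",
                    "line": f"L{i:02d}",
                    "block": "B1",
                    "row": j + 1,
                    "col": i + 1,
                    "y": 5.0 + u[i] + rng.normal(0, np.sqrt(se)),
                }
            )
    return MetDataset(pd.DataFrame(recs)), (g, r)


def brute_force_reml_loglik(y, X, V):
    """Independent dense evaluation of the REML log-likelihood at known V."""
    import numpy as np

    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    n2l = (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + y @ P @ y
    )
    return -0.5 * n2l
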