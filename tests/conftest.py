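import numpy as np
import pandas as pd
import pytest
from scipy import special

from driftstrand.gridding import QuadratGrid


def grid_integration_oracle(N, m, n_grid=400, upper=100.0):
    """Independent dense-grid integration of the hierarchical posterior.

    Integrates the marginal beta-binomial likelihood (p_j analytically
    removed) over (alpha, beta) on a uniform grid under the Uniform(0, upper)
    prior, returning posterior means of alpha, beta and each p_j.
    """
    a = np.linspace(1e-3, upper, n_grid)
    b = np.linspace(1e-3, upper, n_grid)
    A, B = np.meshgrid(a, b, indexing="ij")
    loglik = np.zeros_like(A)
    for Nj, mj in zip(N, m):
        loglik += special.betaln(A + mj, B + Nj - mj) - special.betaln(A, B)
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    p_means = [float(np.sum(w * (A + mj) / (A + B + Nj))) for Nj, mj in zip(N, m)]
    return float(np.sum(w * A)), float(np.sum(w * B)), p_means


def brute_force_tally(deployments, recoveries, grid: QuadratGrid):
    """Nested-loop per-record quadrat tally (oracle for tabulate_counts)."""
    import math

    stranded = {
        rid
        for rid in recoveries["drifter_id"]
        if str(rid).lower() != "unreadable"
    }
    tally: dict[tuple[int, int], list[int]] = {}
    for _, rec in deployments.iterrows():
        r = math.floor((rec["release_lat"] - grid.origin_lat) / grid.cell_size_deg)
        c = math.floor((rec["release_lon"] - grid.origin_lon) / grid.cell_size_deg)
        nm = tally.setdefault((r, c), [0, 0])
        nm[0] += 1
        if rec["drifter_id"] in stranded:
            nm[1] += 1
    return {k: tuple(v) for k, v in tally.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_counts():
    return pd.DataFrame({"N": [120, 95, 140], "m": [10, 4, 15]})


@pytest.fixture
def fast_mcmc():
    """Scaled-down chain settings for unit tests."""
    from driftstrand import McmcConfig

    return McmcConfig(seed=42, n_chains=4, n_tune=2000, n_sample=8000, thin=2)
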