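"""Shared fixtures: hand-traceable toys, random instances, and the
calibrated synthetic ensemble used by the ensemble-level checks."""
from __future__ import annotations

import numpy as np
import pytest

from kitration import (
    SyntheticConfig,
    WeeklySeries,
    generate_ensemble,
    sweep_filling_rates,
)

#: Filling-rate grid used for ensemble-level sweeps.
F_GRID = (0.4, 0.55, 0.7, 0.85, 1.0)


@pytest.fixture
def toy_series() -> WeeklySeries:
    """T=8 season with 10 patients in each active week (5..8): every
    strategy trajectory on it is traceable by hand."""
    return WeeklySeries("toy", "toy-season", (0, 0, 0, 0, 10, 10, 10, 10))


def random_instance(rng: np.random.Generator) -> tuple[WeeklySeries, int]:
    """Small random series + stock: T <= 12, counts <= 20, W_init <= 50."""
    T = int(rng.integers(7, 13))
    counts = tuple(int(c) for c in rng.integers(0, 21, size=T))
    W_init = int(rng.integers(1, 51))
    return WeeklySeries(f"rand", "r", counts), W_init


@pytest.fixture(scope="session")
def calibrated_ensemble():
    """50 Poisson-noisy single-peak institutions (17/17/16 across volume
    groups A/B/C, T=25) drawn within the calibrated parameter ranges."""
    config = SyntheticConfig(
        group_mix={"A": 17, "B": 17, "C": 16}, T=25, noise="poisson", seed=0
    )
    series, groups, latent = generate_ensemble(config)
    return series, groups, latent


@pytest.fixture(scope="session")
def calibrated_sweep(calibrated_ensemble):
    """Full loss sweep of strategies M, S1, S2 over the calibrated ensemble
    (rolling forecasts are fitted once per institution and shared)."""
    series, groups, _ = calibrated_ensemble
    return sweep_filling_rates(
        series, strategies=("M", "S1", "S2"), f_grid=F_GRID, groups=groups
    )
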