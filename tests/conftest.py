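import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from metgain.simulate import SimConfig, simulate_series


@pytest.fixture(scope="session")
def tiny_series():
    """2 sites x 4 genotypes x 2 reps, one trial: small enough for dense oracles."""
    cfg = SimConfig(
        n_trials=1, n_genotypes=4, n_sites_per_me={"ME1": 1, "ME4": 1},
        n_reps=2, n_subblocks=2, seed=42,
    )
    return simulate_series(cfg)


@pytest.fixture(scope="session")
def small_series():
    """One full-size trial at 6 sites: the MET working fixture."""
    cfg = SimConfig(
        n_trials=1, n_genotypes=50, n_sites_per_me={"ME1": 4, "ME4": 1, "ME5": 1},
        seed=7,
    )
    return simulate_series(cfg)


@pytest.fixture(scope="session")
def small_fit(small_series):
    from metgain.met import MetSpec, fit_met

    records, _, _ = small_series
    return fit_met(records, MetSpec(model_variant="fa", fa_order=1, seed=1))
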