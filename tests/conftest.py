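"""Shared fixtures.

The heavy session fixtures build the desk-scale equilibrium training set and
neutral scan replicates once; several acceptance checks share them.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mmcscan import DemographyModel, desk_profile
from mmcscan.engine import simulate_observed
from mmcscan.model_choice import build_training_set
from mmcscan.scan import make_windows, scan_chromosome

DESK_SEED = 7


@pytest.fixture(scope="session")
def desk():
    return desk_profile(seed=DESK_SEED)


@pytest.fixture(scope="session")
def equilibrium():
    return DemographyModel()


@pytest.fixture(scope="session")
def eq_training(desk, equilibrium):
    """Desk-scale equilibrium training set: 2000 Kingman + 2000 MMC."""
    return build_training_set(desk["params"], equilibrium, desk["psi"],
                              n_per_model=2000, seed=DESK_SEED)


@pytest.fixture(scope="session")
def eq_neutral_pmmc(desk, equilibrium, eq_training):
    """Per-window MMC posteriors on neutral equilibrium chromosomes.

    Returns (threshold_set, calibration_set): 110 chromosomes' windows for
    estimating the neutral 99% threshold and 110 independent chromosomes'
    windows (>=2000) for checking its calibration.  The posterior has point
    masses at its extremes (zero-variation windows share one imputed
    vector), so the nearest-rank percentile needs a set large enough that
    its order statistic sits outside the top atom.
    """
    op = desk["obs_params"]
    windows = make_windows(op.L, desk["window"], desk["step"])
    vals = []
    for r in range(220):
        m = simulate_observed(op, equilibrium, None, seed=100_000 + r)
        sc = scan_chromosome(m, eq_training, desk["tolerance"],
                             windows=windows)
        vals.append(sc.p_mmc)
    vals = np.array(vals)
    n_thr = 110
    return (np.concatenate(vals[:n_thr]), np.concatenate(vals[n_thr:]))
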