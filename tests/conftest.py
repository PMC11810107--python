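"""Shared fixtures: small, seeded simulated datasets reused across tests."""

import numpy as np
import pandas as pd
import pytest

from sizeflux.config import Perturbation, SimConfig, default_perturbations
from sizeflux.simulate import simulate_snapshot, simulate_tracks


@pytest.fixture(scope="session")
def base_cfg() -> SimConfig:
    return SimConfig(seed=101, n_wells=4, cells_per_well=600)


@pytest.fixture(scope="session")
def control_snapshot(base_cfg) -> pd.DataFrame:
    """Asynchronous control population, 3 x 600 cells, 24 h fixation."""
    return simulate_snapshot(base_cfg, "control", 24.0)


@pytest.fixture(scope="session")
def noiseless_snapshot(base_cfg) -> pd.DataFrame:
    cfg = base_cfg.replace(staining_noise_cv=0.0, well_effect_cv=0.0)
    return simulate_snapshot(cfg, "control", 24.0)


@pytest.fixture(scope="session")
def k48_pair_cfg() -> SimConfig:
    """Well layout of the ΔK48 assay: 9 replicate wells per CFZ arm."""
    return SimConfig(seed=202, n_wells=9, cells_per_well=150, burn_in_h=20.0)


@pytest.fixture(scope="session")
def k48_pair(k48_pair_cfg) -> pd.DataFrame:
    return pd.concat(
        [
            simulate_snapshot(k48_pair_cfg, "control", 24.0, cfz=False),
            simulate_snapshot(k48_pair_cfg, "control", 24.0, cfz=True),
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def plant_cfg() -> SimConfig:
    """Pure-exponential growth (beta = 0) with isolated planted arms."""
    perts = default_perturbations()
    perts["g1_plant"] = Perturbation(g1_duration_mult=1.32)
    perts["growth_plant"] = Perturbation(growth_mult=0.79)
    return SimConfig(seed=11, compensation_exponent=0.0, perturbations=perts)


@pytest.fixture(scope="session")
def control_tracks(plant_cfg) -> pd.DataFrame:
    return simulate_tracks(plant_cfg, "control", 100)


def make_cells(dna, geminin, **extra) -> pd.DataFrame:
    """Minimal CellRecord-like table for staging/trajectory unit tests."""
    n = len(dna)
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "well_id": "w0",
        "condition": "control",
        "fixation_time_h": 24.0,
        "cfz_flag": False,
        "chx_flag": False,
        "dna": np.asarray(dna, dtype=float),
        "geminin": np.asarray(geminin, dtype=float),
        "size_se": np.ones(n),
    }
    base.update(extra)
    return pd.DataFrame(base)
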