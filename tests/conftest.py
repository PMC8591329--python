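import numpy as np
import pandas as pd
import pytest

from tactqg import Pedigree, SimConfig, simulate_pedigree


def make_frame(rows):
    """Build a standard pedigree frame from (id, sex, tactic, year, length,
    rs, dam, sire, generation) tuples."""
    cols = ["id", "sex", "tactic", "year", "length_mm", "rs", "dam_id", "sire_id", "generation"]
    return pd.DataFrame(rows, columns=cols)


TINY_ROWS = [
    ("D1", "female", "female", 2002, 700.0, 2, None, None, "parent"),
    ("S1", "male", "hooknose", 2002, 650.0, 2, None, None, "parent"),
    ("S2", "male", "jack", 2003, 450.0, 1, None, None, "parent"),
    ("O1", "female", "female", 2004, 720.0, 1, "D1", "S1", "offspring"),
    ("O2", "male", "jack", 2005, 430.0, 0, "D1", "S1", "offspring"),
    ("O3", "male", "hooknose", 2004, 680.0, 2, "D1", "S2", "offspring"),
]


@pytest.fixture()
def tiny_frame():
    return make_frame(TINY_ROWS)


@pytest.fixture()
def tiny_ped(tiny_frame):
    return Pedigree(tiny_frame)


@pytest.fixture()
def tiny_csv(tmp_path, tiny_ped):
    path = tmp_path / "ped.csv"
    tiny_ped.to_csv(path)
    return path


@pytest.fixture(scope="session")
def default_ped():
    """Study-scale simulated pedigree under the default configuration."""
    return simulate_pedigree(SimConfig(seed=11))


@pytest.fixture(scope="session")
def large_ped():
    """A denser pedigree for regressions that need well-filled grid cells."""
    cfg = SimConfig(n_dams=400, n_sires=400, jack_fraction=0.3, n_offspring=2500, seed=7)
    return simulate_pedigree(cfg)
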