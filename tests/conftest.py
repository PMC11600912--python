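import numpy as np
import pandas as pd
import pytest

from herdblup import Pedigree, ModelSpec
from herdblup.simulate import SimConfig, simulate_herd


def make_pedigree(rows):
    """rows: (id, sire, dam, sex, birth_year) tuples; '0' = unknown."""
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_year"])
    return Pedigree.from_frame(df)


def random_pedigree(rng, n=60, n_founders=12, start_year=2000):
    """Random multi-generation pedigree for property tests."""
    rows = []
    for i in range(n_founders):
        rows.append((f"P{i}", "0", "0", "M" if i % 3 == 0 else "F", start_year))
    for i in range(n_founders, n):
        year = start_year + 1 + (i - n_founders) // max((n - n_founders) // 6, 1)
        prev = [r for r in rows]
        males = [r[0] for r in prev if r[3] == "M"]
        females = [r[0] for r in prev if r[3] == "F"]
        sire = rng.choice(males) if males and rng.random() > 0.1 else "0"
        dam = rng.choice(females) if females and rng.random() > 0.1 else "0"
        rows.append((f"P{i}", sire, dam, "M" if rng.random() < 0.3 else "F", year))
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=1, n_years=8, cows_per_year=50, bulls_per_year=4,
                     n_founders=40, n_markers=200, n_qtl=60)


@pytest.fixture(scope="session")
def small_herd(small_config):
    return simulate_herd(small_config)


@pytest.fixture(scope="session")
def small_spec(small_config):
    return ModelSpec(G0=small_config.G0, R0=small_config.R0,
                     flavour="ssgblup", w_pg=0.5)


@pytest.fixture(scope="session")
def medium_herd():
    cfg = SimConfig(seed=11, n_years=12, cows_per_year=70, bulls_per_year=6,
                    n_founders=50, n_markers=250, n_qtl=70)
    return simulate_herd(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
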