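import numpy as np
import pandas as pd
import pytest

from litvar.config import SimConfig
from litvar.pedigree import Pedigree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_litters():
    """Three does: two seasons, mixed parity-lactation classes."""
    rows = [
        ("d1", 1, "s1", "first", 10),
        ("d1", 2, "s1", "later_lactating", 10),
        ("d1", 3, "s2", "later_lactating", 8),
        ("d2", 1, "s1", "first", 8),
        ("d2", 2, "s2", "later_nonlactating", 8),
        ("d3", 1, "s2", "first", 12),
    ]
    return pd.DataFrame(
        rows, columns=["doe", "parity", "year_season", "lactation_class", "litter_size"]
    )


def make_pedigree(rows):
    return Pedigree(
        pd.DataFrame(
            rows, columns=["id", "sire", "dam", "sex", "line", "generation"]
        )
    )


@pytest.fixture
def trio_pedigree():
    """Sire, dam and their offspring."""
    return make_pedigree(
        [
            ("s", "0", "0", "M", "Base", 0),
            ("d", "0", "0", "F", "Base", 0),
            ("o", "s", "d", "F", "Base", 1),
        ]
    )


def random_pedigree(rng, n_base=6, n_desc=14):
    """Random multi-generation pedigree of n_base + n_desc animals."""
    rows = []
    for i in range(n_base):
        rows.append((f"b{i}", "0", "0", "M" if i % 2 else "F", "Base", 0))
    ids = [r[0] for r in rows]
    sexes = {r[0]: r[3] for r in rows}
    for i in range(n_desc):
        males = [a for a in ids if sexes[a] == "M"]
        females = [a for a in ids if sexes[a] == "F"]
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        sex = "M" if rng.random() < 0.5 else "F"
        name = f"x{i}"
        rows.append((name, sire, dam, sex, "Base", 1 + i))
        ids.append(name)
        sexes[name] = sex
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def calibrated_experiment():
    """One full-scale calibrated experiment shared across test modules."""
    from litvar.pipeline import calibrated_config
    from litvar.simulate import run_experiment

    return run_experiment(calibrated_config(seed=20240917))


@pytest.fixture
def small_config():
    """Reduced experiment: 2 lines x 25 does, 4 generations."""
    return SimConfig(
        n_generations=4,
        does_per_line=25,
        sires_per_line=5,
        dams_per_sire=5,
        seed=1,
    )
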