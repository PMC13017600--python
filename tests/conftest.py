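import numpy as np
import pytest

from kinmethyl import (
    SimConfig, build_pedigree, run_ewas, simulate_dataset,
)


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two founders, their two offspring (full sibs), and an inbred pup."""
    return build_pedigree(
        [
            {"id": "A", "sire": "0", "dam": "0", "sex": "M"},
            {"id": "B", "sire": "0", "dam": "0", "sex": "F"},
            {"id": "C", "sire": "A", "dam": "B", "sex": "M"},
            {"id": "D", "sire": "A", "dam": "B", "sex": "F"},
            {"id": "E", "sire": "C", "dam": "D", "sex": "M"},
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default planted colony + methylome (the package's study conditions)."""
    ped, ds = simulate_dataset(SimConfig(seed=11))
    return ped, ds


@pytest.fixture(scope="session")
def default_ewas(default_dataset):
    _, ds = default_dataset
    return run_ewas(ds)


def random_pedigree(rng, n: int):
    """Random valid pedigree records of size n (founders + random matings)."""
    records = []
    males, females = [], []
    n_founders = max(4, n // 3)
    for k in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        if k < n_founders or len(males) == 0 or len(females) == 0:
            sire = dam = "0"
        else:
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
        ident = f"I{k:02d}"
        records.append({"id": ident, "sire": sire, "dam": dam, "sex": sex})
        (males if sex == "M" else females).append(ident)
    return records
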