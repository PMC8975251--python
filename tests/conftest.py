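import numpy as np
import pandas as pd
import pytest

from nmrclock.agetx import SpeciesParams, TransformSpec
from nmrclock.simdata import SimConfig, simulate_methylation_study

NMR = {"naked_mole_rat": SpeciesParams(37.0, maturity_years=1.0)}
HUMAN_NMR = {
    "human": SpeciesParams(122.5, maturity_years=15.0),
    "naked_mole_rat": SpeciesParams(37.0, maturity_years=1.0),
}


@pytest.fixture(scope="session")
def identity_spec():
    return TransformSpec("identity", dict(NMR))


@pytest.fixture(scope="session")
def relative_spec():
    return TransformSpec("relative", dict(HUMAN_NMR))


@pytest.fixture(scope="session")
def small_study():
    """A compact single-species study with planted age/sex structure."""
    cfg = SimConfig(
        seed=1,
        n_cpgs=500,
        n_samples_per_tissue=20,
        tissues=("blood", "skin"),
        frac_age_related=0.1,
        noise_sd=0.15,
    )
    return simulate_methylation_study(cfg), cfg


def make_exact_correlation(n: int, r: float, seed: int = 0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e = e - x * (x @ e) / (x @ x)  # orthogonalize
    e = e / e.std()
    y = r * x + np.sqrt(1 - r**2) * e
    return x, y
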