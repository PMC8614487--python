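"""Shared fixtures: small pedigrees and simulated datasets."""

import numpy as np
import pytest

from pedreml import ModelSpec, Pedigree, build_design
from pedreml.pedigree import build_A_inverse
from pedreml.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def trio():
    """Sire, dam, one offspring; no inbreeding."""
    return Pedigree.from_records(
        [("S", None, None), ("D", None, None), ("O", "S", "D")]
    )


@pytest.fixture(scope="session")
def full_sib_mating():
    """Founder pair, two full sibs, and an offspring of the sib mating."""
    return Pedigree.from_records(
        [
            ("A", None, None),
            ("B", None, None),
            ("C", "A", "B"),
            ("D", "A", "B"),
            ("E", "C", "D"),
        ]
    )


def small_bivariate_config(**overrides):
    """Complete-record bivariate generator at unit-free desk scale.

    True parameters: h2 = 0.4 per trait, rg = 0.6, rp = 0.5
    (phenotypic variance 10 per trait before fixed effects).
    """
    base = dict(
        traits=("X", "Y"),
        trait_means=(20.0, 10.0),
        true_G=np.array([[4.0, 2.4], [2.4, 4.0]]),
        true_R=np.array([[6.0, 2.6], [2.6, 6.0]]),
        n_founders=80,
        n_generations=3,
        generation_size=300,
        phenotype_generations=2,
        n_slaughter_dates=20,
        date_effect_sd=(1.0, 1.0),
        age_slope=(0.05, 0.02),
        mating_scheme="half_sib",
        n_sires=15,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def bivariate_data():
    """One simulated bivariate dataset plus its design and relationships."""
    ds = simulate_dataset(small_bivariate_config(), seed=2024)
    spec = ModelSpec(
        traits=("X", "Y"),
        class_effects=("slaughter_date",),
        covariates=("slaughter_age",),
    )
    dm = build_design(ds.phenotypes, ds.pedigree, spec)
    rel = build_A_inverse(ds.pedigree)
    return ds, dm, rel


@pytest.fixture(scope="session")
def bivariate_fit(bivariate_data):
    from pedreml import fit

    ds, dm, rel = bivariate_data
    return fit(dm, rel)
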