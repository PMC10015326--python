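"""Shared fixtures: small simulated datasets reused across the model-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from pairedg.animal_model import ModelSpec, fit_reml
from pairedg.pedigree import build_A
from pairedg.synthetic_data import DesignParams, LocusSet, simulate_dataset

TRAITS2 = ("trait1", "trait2")


def make_additive_dataset(seed: int, n_pairs: int = 50, n_generations: int = 2, n_traits: int = 2,
                          n_loci: int = 40, a: float = 1.0, loading_scale: float = 0.2,
                          vial_var: float = 0.09, residual_var: float = 1.0):
    """Additive-only MCN dataset with known expected G."""
    loci = LocusSet.additive(n_loci, n_traits, q=0.5, a=a, seed=1000 + seed,
                             loading_scale=loading_scale)
    params = DesignParams(n_pairs=n_pairs, n_generations=n_generations,
                          n_traits=n_traits, seed=seed)
    ped, geno, phen = simulate_dataset(
        params, loci, vial_var * np.eye(n_traits), residual_var * np.eye(n_traits)
    )
    loadings = np.array([l.loadings for l in loci.loci])
    # per locus V_A = 2 p q a^2 on the genotypic-value scale, spread via loadings
    true_g = sum(2 * 0.25 * a * a * np.outer(lv, lv) for lv in loadings)
    return ped, phen, loci, true_g


@pytest.fixture(scope="session")
def additive_dataset():
    ped, phen, loci, true_g = make_additive_dataset(seed=7)
    return ped, phen, loci, true_g


@pytest.fixture(scope="session")
def additive_A(additive_dataset):
    ped = additive_dataset[0]
    return build_A(ped)


@pytest.fixture(scope="session")
def additive_fits(additive_dataset, additive_A):
    """Both-arm REML fits on the session additive dataset."""
    _, phen, _, _ = additive_dataset
    fits = {}
    for arm in ("outbred", "inbred"):
        fits[arm] = fit_reml(phen, additive_A, ModelSpec(traits=TRAITS2, arm=arm))
    return fits
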