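"""Shared fixtures: desk-scale simulated datasets and small pedigrees."""

import numpy as np
import pandas as pd
import pytest

from gsduroc import Pedigree, SimConfig, TraitArchitecture, simulate_dataset


def desk_config(seed: int, **overrides) -> SimConfig:
    """A small population: 500-boar cohort, 5 chromosomes, 2000 variants.

    Matches the generator's default family structure (few-parent burn-in
    generations building background relatedness) at a size every test can
    afford.
    """
    kw = dict(
        n_founders=60,
        n_generations=5,
        n_sires=(12, 12, 12, 12, 25),
        n_dams=(36, 36, 36, 36, 120),
        n_offspring=(100, 100, 100, 200, 500),
        n_chromosomes=5,
        n_seq_variants=2000,
        n_panel650_variants=800,
        n_panel80_variants=300,
        trait_architectures=(
            TraitArchitecture("OLI", 10, "oligogenic", qtl_maf_range=(0.05, 0.5)),
            TraitArchitecture("POL", 300, "polygenic"),
        ),
        h2_targets={"OLI": 0.5, "POL": 0.5},
        rng_seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def desk_data():
    """One simulated dataset reused by read-only tests."""
    return simulate_dataset(desk_config(2024), annotation_enrichment=1.0)


@pytest.fixture()
def small_pedigree() -> Pedigree:
    """Founders s/d plus offspring: a parent-offspring pair and full sibs."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["s1", "s2", "d1", "d2", "x", "y", "z"],
                "sire": ["0", "0", "0", "0", "s1", "s1", "s2"],
                "dam": ["0", "0", "0", "0", "d1", "d1", "d2"],
            }
        )
    )


def random_pedigree(n: int, rng: np.random.Generator, n_founders: int = 10) -> Pedigree:
    """Random acyclic pedigree: each non-founder draws parents upstream."""
    animal = [f"a{i}" for i in range(n)]
    sire, dam = [], []
    for i in range(n):
        if i < n_founders:
            sire.append("0")
            dam.append("0")
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sire.append(f"a{s}")
            dam.append(f"a{d}")
    return Pedigree(
        np.array(animal, object), np.array(sire, object), np.array(dam, object)
    )
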