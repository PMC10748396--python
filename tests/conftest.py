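"""Shared fixtures: a tiny hand-built dataset and a generated scenario."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from traitmoments import (
    CommunityComposition,
    Dataset,
    EnvironmentTable,
    SyntheticScenario,
    TraitMatrix,
    generate,
    relative_abundance,
)

TINY_TRAITS = ["height", "mass", "area"]


def tiny_trait_frame() -> pd.DataFrame:
    """12 individuals, 3 species x 2 communities, 3 traits, no missing."""
    rng = np.random.default_rng(7)
    rows = []
    i = 0
    for comm in ("cA", "cB"):
        for sp in ("s1", "s2", "s3"):
            for _ in range(2):
                i += 1
                rows.append(
                    {
                        "individual_id": f"i{i:02d}",
                        "species_id": sp,
                        "community_id": comm,
                        "height": 10 + 5 * int(sp[1]) + rng.normal(0, 1),
                        "mass": 2 + int(sp[1]) + rng.normal(0, 0.2),
                        "area": 50 - 3 * int(sp[1]) + rng.normal(0, 2),
                    }
                )
    return pd.DataFrame(rows)


def tiny_composition_frame() -> pd.DataFrame:
    rows = []
    covers = {
        ("pA1", "cA"): {"s1": 10.0, "s2": 6.0, "s3": 4.0},
        ("pA2", "cA"): {"s1": 8.0, "s2": 8.0, "s3": 2.0},
        ("pB1", "cB"): {"s1": 2.0, "s2": 9.0, "s3": 9.0},
        ("pB2", "cB"): {"s1": 4.0, "s2": 6.0, "s3": 10.0},
    }
    for (plot, comm), spcov in covers.items():
        for sp, cov in spcov.items():
            rows.append(
                {"plot_id": plot, "community_id": comm, "species_id": sp, "cover": cov}
            )
    return pd.DataFrame(rows)


def tiny_environment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": ["pA1", "pA2", "pB1", "pB2"],
            "altitude": [1300.0, 1320.0, 1500.0, 1480.0],
            "soil_depth": [25.0, 30.0, 50.0, 45.0],
        }
    )


@pytest.fixture
def tiny_dataset() -> Dataset:
    return Dataset(
        traits=TraitMatrix(tiny_trait_frame(), TINY_TRAITS, set()),
        composition=relative_abundance(CommunityComposition(tiny_composition_frame())),
        environment=EnvironmentTable(
            tiny_environment_frame(), ["altitude", "soil_depth"]
        ),
    )


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Down-scaled generated scenario shared across tests (fast)."""
    return SyntheticScenario(
        n_communities=4, plots_per_community=5, n_species=10, seed=11
    )


@pytest.fixture(scope="session")
def small_generated(small_scenario):
    return generate(small_scenario)
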