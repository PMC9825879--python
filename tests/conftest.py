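"""Shared fixtures: small synthetic regions and a recovery fixture with a
single known climate driver, reused across module tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tlpshift import climate, synthgen, traits


@pytest.fixture(scope="session")
def region():
    return synthgen.generate_region(6, 8, 2, seed=7)


@pytest.fixture(scope="session")
def truth():
    return synthgen.TruthModel()


@pytest.fixture(scope="session")
def pool(truth):
    return synthgen.generate_species_pool(120, 0.06, 0.35, truth, seed=7)


@pytest.fixture(scope="session")
def occurrences(region, pool):
    return synthgen.generate_occurrences(region, pool, seed=7)


@pytest.fixture(scope="session")
def trait_table(pool):
    reps = pool.replicates.merge(pool.species, on="species_id")
    return traits.species_trait_table(reps)


@pytest.fixture(scope="session")
def recovery_fixture():
    """6x8 region, 20-year climate, Psi_tlp driven by BIO1.95 alone.

    Returns (X, y, centroids): predictors on the survey grid, the trait
    response with 0.05 MPa noise, and cell centroid coordinates.
    """
    reg = synthgen.generate_region(6, 8, 2, seed=3)
    tm = synthgen.TruthModel(
        trait_coefficients={"bio1_95_c": -0.06}, noise_sd=0.05
    )
    cube = synthgen.generate_daily_climate(reg, 20, seed=3)
    tab = climate.period_tables(cube, {"full": (0, 19)})
    w = climate.overlap_weights(reg.cells, reg.climate_cells)
    sv = climate.extract_survey_values(
        tab.drop(columns=["period"]), w
    ).set_index("cell_id")
    X = sv[list(synthgen.PREDICTORS)]
    y = synthgen.generate_trait_response(X, tm, seed=3)
    cent = reg.cells.set_index("cell_id").loc[X.index, ["lon", "lat"]].to_numpy()
    return X, y, cent


def brute_force_surface(habitat_fractions: pd.DataFrame,
                        occurrences: pd.DataFrame,
                        abundance: pd.DataFrame,
                        psi: dict[str, float]) -> dict[str, float]:
    """Independent double-sum oracle for the four-step upscaling.

    Explicit loops over habitats and species; shares no code with the
    implementation under test.
    """
    out = {}
    for cell_id in occurrences.index:
        present = {
            s for s in occurrences.columns if occurrences.loc[cell_id, s] > 0
        }
        frac = habitat_fractions[habitat_fractions["cell_id"] == cell_id]
        num = den = 0.0
        for _, hrow in frac.iterrows():
            h, f = hrow["habitat"], hrow["fraction"]
            if f <= 0:
                continue
            wsum = psum = 0.0
            for _, arow in abundance.iterrows():
                if (
                    arow["habitat"] == h
                    and arow["weight"] > 0
                    and arow["species_id"] in present
                    and arow["species_id"] in psi
                ):
                    wsum += arow["weight"]
                    psum += arow["weight"] * psi[arow["species_id"]]
            if wsum > 0:
                num += f * (psum / wsum)
                den += f
        if den > 0:
            out[cell_id] = num / den
    return out
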