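import numpy as np
import pandas as pd
import pytest

from prolonger import DeathRecordSet, PopulationTable
from prolonger.scenario import DataBundle, prepare_pipeline
from prolonger.synthetic_city import CityConfig, generate_city


def bundle_from_city(city) -> DataBundle:
    return DataBundle(
        population=city.population,
        covariates=city.covariates,
        window=city.config.window,
        records=city.records,
        schema=city.config.schema,
    )


@pytest.fixture(scope="session")
def small_city():
    """An 8-geounit city: fast enough for per-test pipelines."""
    return generate_city(CityConfig(n_geounits=8, seed=7))


@pytest.fixture(scope="session")
def small_bundle(small_city):
    return bundle_from_city(small_city)


@pytest.fixture(scope="session")
def small_state(small_bundle):
    return prepare_pipeline(small_bundle, "heart_disease")


@pytest.fixture(scope="session")
def default_city():
    """The default study conditions: 55 geounits, 5 years, leading cause ~24%."""
    return generate_city(CityConfig())


@pytest.fixture(scope="session")
def default_bundle(default_city):
    return bundle_from_city(default_city)


@pytest.fixture(scope="session")
def default_state(default_bundle):
    return prepare_pipeline(default_bundle, "heart_disease")


@pytest.fixture
def toy_two_band_bundle():
    """One geounit, two bands (0-4, 5+), one year: hand-computable by design.

    Cause "target": 10 deaths in 0-4, 20 in 5+; cause "other": 30 in 5+;
    1,000 residents per band. With a single-year window there are no
    follow-up years, so averted deaths suffer no attrition.
    """
    from tests.helpers import two_band_schema

    schema = two_band_schema()
    rows = []
    rows += [{"year": 2015, "age": 2, "cause": "target", "geounit": "A"}] * 10
    rows += [{"year": 2015, "age": 7, "cause": "target", "geounit": "A"}] * 20
    rows += [{"year": 2015, "age": 9, "cause": "other", "geounit": "A"}] * 30
    records = DeathRecordSet(pd.DataFrame(rows), schema)
    pop = PopulationTable(pd.DataFrame([
        {"geounit": "A", "year": 2015, "age_band": "0-4", "population": 1000.0},
        {"geounit": "A", "year": 2015, "age_band": "5+", "population": 1000.0},
    ]), schema)
    cov = pd.DataFrame({
        "prop_black": [0.5], "prop_white": [0.4],
        "median_income": [45000.0], "prop_above_hs": [0.5],
    }, index=pd.Index(["A"], name="geounit"))
    return DataBundle(population=pop, covariates=cov, window=(2015, 2015),
                      records=records, schema=schema)
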