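"""A synthetic mid-sized US city with known ground truth.

Real neighbourhood-level vital-statistics files are restricted, so this
module fabricates one that looks like a Baltimore-sized city: ~55 geographic
units of 5,000-20,000 residents observed for 5 calendar years, an
age-structured Gompertz-Makeham mortality schedule calibrated to a chosen
city-level life expectancy (default 73.2 years), a leading cause of death
(default "heart_disease") contributing about 24.4% of all deaths with an
age-increasing profile, neighbourhood covariates (race composition, income,
education) that multiply mortality rates through stated coefficients, and
negative-binomial cell counts. The generator returns the ground truth
(true rates, true life expectancy per geounit) so parameter-recovery tests
can close the loop, and is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_ingest import (
    AgeBandSchema,
    AggregateDeathTable,
    DeathRecordSet,
    PopulationTable,
    aggregate_individual,
)
from .lifetable import build_chiang_table

__all__ = ["CityConfig", "CityBundle", "generate_city", "export_city", "load_city"]

#: city-wide population age structure (normalised in code), 0-4 ... 85+
_BASE_PYRAMID = np.array([
    0.065, 0.063, 0.062, 0.065, 0.075, 0.080, 0.075, 0.070, 0.065,
    0.063, 0.065, 0.065, 0.058, 0.048, 0.037, 0.028, 0.020, 0.016,
])

#: flat death-share weights for the non-leading cause groups
_DEFAULT_OTHER_CAUSES = {
    "cancer": 0.213,
    "stroke": 0.049,
    "drug_alcohol": 0.045,
    "clrd": 0.035,
}


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CityConfig:
    """Study conditions for the synthetic city.

    The mortality model is M_x(g) = (A e^{b x} + c) * mult_g, where x is the
    band midpoint, A is calibrated so the city-level Chiang e_0 equals
    ``target_e0``, and the geounit multiplier is
    ``mult_g = exp(covariate_effect * z_g + rate_sigma * eps_g)`` with z_g a
    latent disadvantage factor that also drives the covariates (so the
    smoothing model has real signal to recover). The leading cause's death
    share rises with age (logistic ramp centred at 60) and is scaled so its
    expected share of all deaths equals ``leading_share``; the remaining
    causes split the rest in proportion to ``other_cause_weights`` plus an
    implicit "other" remainder. Cell counts are NB2 with dispersion
    ``dispersion_alpha`` around the model mean.
    """

    n_geounits: int = 55
    pop_range: tuple[int, int] = (5_000, 20_000)
    window: tuple[int, int] = (2012, 2016)
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)
    leading_cause: str = "heart_disease"
    leading_share: float = 0.244
    other_cause_weights: tuple[tuple[str, float], ...] = tuple(_DEFAULT_OTHER_CAUSES.items())
    target_e0: float = 73.2
    gompertz_b: float = 0.085
    makeham_c: float = 5e-4
    dispersion_alpha: float = 0.3
    covariate_effect: float = 0.25
    rate_sigma: float = 0.15
    seed: int = 42

    def __post_init__(self) -> None:
        other = sum(w for _, w in self.other_cause_weights)
        if self.leading_share + other > 1.0 + 1e-9:
            raise ValueError(
                f"cause shares sum to {self.leading_share + other:.3f} > 1: infeasible"
            )
        if not 0 < self.leading_share < 1:
            raise ValueError("leading_share must be in (0,1)")
        if self.pop_range[0] > self.pop_range[1] or self.pop_range[0] <= 0:
            raise ValueError("invalid population range")
        if self.window[0] > self.window[1]:
            raise ValueError("invalid year window")
        if self.dispersion_alpha < 0 or self.rate_sigma < 0:
            raise ValueError("dispersion and sigma must be >= 0")

    @property
    def causes(self) -> tuple[str, ...]:
        return (self.leading_cause, *(c for c, _ in self.other_cause_weights), "other")

    @property
    def n_years(self) -> int:
        return self.window[1] - self.window[0] + 1


@dataclass
class CityBundle:
    """Generated data plus the ground truth it was generated from."""

    config: CityConfig
    records: DeathRecordSet
    population: PopulationTable
    covariates: pd.DataFrame            # indexed by geounit
    truth: dict                          # true rates, multipliers, true e0, calibration


def _band_midpoints(schema: AgeBandSchema) -> np.ndarray:
    mids = []
    for i in range(schema.n_bands):
        lo, up = schema.lowers[i], schema.uppers[i]
        mids.append(lo + 7.5 if up is None else (lo + up + 1) / 2.0)
    return np.asarray(mids)


def _calibrate_gompertz(config: CityConfig) -> np.ndarray:
    """Baseline schedule M_x = A e^{bx} + c with A bisected to hit target e0."""
    mids = _band_midpoints(config.schema)
    b, c = config.gompertz_b, config.makeham_c

    def e0_of(a: float) -> float:
        return build_chiang_table(a * np.exp(b * mids) + c, config.schema).e0

    lo_a, hi_a = 1e-8, 1e-2
    for _ in range(200):
        mid_a = np.sqrt(lo_a * hi_a)
        if e0_of(mid_a) > config.target_e0:
            lo_a = mid_a
        else:
            hi_a = mid_a
        if hi_a / lo_a < 1 + 1e-12:
            break
    a = np.sqrt(lo_a * hi_a)
    return a * np.exp(b * mids) + c


def _cause_share_matrix(config: CityConfig, base_m: np.ndarray,
                        band_pop: np.ndarray) -> pd.DataFrame:
    """Per-band death shares per cause; the leading cause's overall share is calibrated."""
    mids = _band_midpoints(config.schema)
    ramp = _expit((mids - 60.0) / 12.0)
    expected_deaths = band_pop * base_m          # city-level expected deaths per band
    scale = config.leading_share * expected_deaths.sum() / (ramp * expected_deaths).sum()
    lead = np.clip(scale * ramp, 0.0, 0.6)
    weights = dict(config.other_cause_weights)
    other_total = 1.0 - config.leading_share - sum(weights.values())
    weights["other"] = max(other_total, 0.0)
    wsum = sum(weights.values())
    shares = {config.leading_cause: lead}
    for cname, w in weights.items():
        shares[cname] = (1.0 - lead) * (w / wsum)
    return pd.DataFrame(shares, index=list(config.schema.labels))


def generate_city(config: CityConfig | None = None) -> CityBundle:
    """Generate records, populations, covariates and ground truth for one city."""
    config = config or CityConfig()
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    nb = schema.n_bands
    years = list(range(config.window[0], config.window[1] + 1))
    geounits = [f"G{i:02d}" for i in range(1, config.n_geounits + 1)]

    # --- covariates driven by a latent disadvantage factor z ---------------
    z = rng.normal(size=config.n_geounits)
    eps = rng.normal(size=(config.n_geounits, 5))
    prop_black = np.clip(_expit(0.4 + 1.1 * z + 0.35 * eps[:, 0]), 0.02, 0.98)
    prop_white = np.clip(0.9 * (1 - prop_black) + 0.05 * eps[:, 1], 0.01, 0.97)
    median_income = np.exp(np.log(48_000) - 0.35 * z + 0.15 * eps[:, 2])
    prop_above_hs = np.clip(_expit(0.3 - 0.7 * z + 0.3 * eps[:, 3]), 0.05, 0.95)
    log_mult = config.covariate_effect * z + config.rate_sigma * eps[:, 4]
    mult = np.exp(log_mult)
    covariates = pd.DataFrame({
        "prop_black": prop_black,
        "prop_white": prop_white,
        "median_income": median_income,
        "prop_above_hs": prop_above_hs,
    }, index=pd.Index(geounits, name="geounit"))

    # --- population: totals uniform in range, pyramid jittered per geounit --
    base = _BASE_PYRAMID / _BASE_PYRAMID.sum()
    totals = rng.integers(config.pop_range[0], config.pop_range[1] + 1,
                          size=config.n_geounits)
    shares = rng.dirichlet(base * 400, size=config.n_geounits)
    band_pop = np.round(shares * totals[:, None]).astype(int)   # (n_geo, n_bands)

    # --- mortality model ----------------------------------------------------
    base_m = _calibrate_gompertz(config)
    city_band_pop = band_pop.sum(axis=0).astype(float)
    share_mat = _cause_share_matrix(config, base_m, city_band_pop)
    causes = list(share_mat.columns)
    true_rates = base_m[None, :] * mult[:, None]                # all-cause, (n_geo, n_bands)

    # --- draw NB cell counts and expand to individual records ---------------
    alpha = config.dispersion_alpha
    rows = []
    for gi, g in enumerate(geounits):
        mu_band = band_pop[gi].astype(float) * true_rates[gi]   # per band per year
        for y in years:
            for ci, cname in enumerate(causes):
                mu = mu_band * share_mat[cname].to_numpy()
                if alpha > 0:
                    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.maximum(mu, 1e-300))
                    counts = rng.poisson(np.where(mu > 0, lam, 0.0))
                else:
                    counts = rng.poisson(mu)
                for bi in np.flatnonzero(counts):
                    k = int(counts[bi])
                    lo = schema.lowers[bi]
                    w = schema.width(bi)
                    ages = lo + rng.integers(0, w, size=k)
                    rows.append((g, y, cname, ages))

    parts = []
    for g, y, cname, ages in rows:
        parts.append(pd.DataFrame({
            "year": y, "age": ages, "cause": cname, "geounit": g,
        }))
    rec = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=["year", "age", "cause", "geounit"]))
    n = len(rec)
    if n:
        rec["sex"] = np.where(rng.random(n) < 0.5, "F", "M")
        pb = covariates["prop_black"].reindex(rec["geounit"]).to_numpy()
        pw = covariates["prop_white"].reindex(rec["geounit"]).to_numpy()
        u = rng.random(n)
        rec["race"] = np.where(u < pb, "black", np.where(u < pb + pw, "white", "other"))
    rec["pseudo"] = False
    records = DeathRecordSet(rec.reset_index(drop=True), schema)

    # --- population table (constant across years, split by sex 50/50) -------
    pop_rows = []
    for gi, g in enumerate(geounits):
        for y in years:
            for bi, lab in enumerate(schema.labels):
                half = band_pop[gi, bi] / 2.0
                pop_rows.append((g, y, lab, "F", half))
                pop_rows.append((g, y, lab, "M", band_pop[gi, bi] - half))
    population = PopulationTable(
        pd.DataFrame(pop_rows, columns=["geounit", "year", "age_band", "sex", "population"]),
        schema,
    )

    true_e0 = {g: build_chiang_table(true_rates[gi], schema).e0
               for gi, g in enumerate(geounits)}
    truth = {
        "base_schedule": pd.Series(base_m, index=list(schema.labels)),
        "cause_shares": share_mat,
        "multipliers": pd.Series(mult, index=geounits),
        "true_rates": pd.DataFrame(true_rates, index=geounits, columns=list(schema.labels)),
        "true_e0": pd.Series(true_e0),
        "band_population": pd.DataFrame(band_pop, index=geounits, columns=list(schema.labels)),
    }
    return CityBundle(config=config, records=records, population=population,
                      covariates=covariates, truth=truth)


def export_city(bundle: CityBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle in the package's CSV dialects; round-trips losslessly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "deaths": d / "deaths_individual.csv",
        "aggregate": d / "deaths_aggregate.csv",
        "population": d / "population.csv",
        "covariates": d / "covariates.csv",
        "truth": d / "truth.json",
    }
    records = bundle.records
    ordered = records.data.sort_values(
        ["geounit", "year", "cause", "age", "sex", "race"]).reset_index(drop=True)
    DeathRecordSet(ordered, records.schema).to_csv(paths["deaths"])
    aggregate_individual(records, records.schema).to_csv(paths["aggregate"])
    bundle.population.to_csv(paths["population"])
    bundle.covariates.reset_index().to_csv(paths["covariates"], index=False)
    truth = {
        "config": {
            "n_geounits": bundle.config.n_geounits,
            "pop_range": list(bundle.config.pop_range),
            "window": list(bundle.config.window),
            "leading_cause": bundle.config.leading_cause,
            "leading_share": bundle.config.leading_share,
            "target_e0": bundle.config.target_e0,
            "seed": bundle.config.seed,
        },
        "true_e0": {k: round(float(v), 6) for k, v in bundle.truth["true_e0"].items()},
        "multipliers": {k: round(float(v), 6) for k, v in bundle.truth["multipliers"].items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def load_city(directory: str | Path, schema: AgeBandSchema | None = None):
    """Read an exported city back as (records, population, covariates)."""
    from .io_ingest import read_covariates, read_individual_deaths, read_population

    d = Path(directory)
    schema = schema or AgeBandSchema.default()
    records, _ = read_individual_deaths(d / "deaths_individual.csv", schema)
    population, _ = read_population(d / "population.csv", schema)
    covariates, _ = read_covariates(d / "covariates.csv")
    return records, population, covariates
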