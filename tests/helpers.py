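"""Shared test utilities: independent oracles and schedule generators."""

from __future__ import annotations

import numpy as np

from prolonger import AgeBandSchema
from prolonger.synthetic_city import CityConfig, _calibrate_gompertz


def cohort_e0_microsim(m, schema: AgeBandSchema, n_agents: int,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Agent-based cohort life expectancy under piecewise-constant hazards.

    Every agent draws an exponential waiting time in each band; survival into
    the open terminal band adds a final exponential lifetime at rate M. This
    is an exact simulation of the continuous-time hazard model, fully
    independent of any life-table algebra. Returns (mean lifespan, Monte
    Carlo standard error of the mean).
    """
    m = np.asarray(m, dtype=float)
    life = np.zeros(n_agents)
    alive = np.ones(n_agents, dtype=bool)
    for i in range(schema.n_bands - 1):
        n = schema.uppers[i] - schema.lowers[i] + 1
        idx = np.flatnonzero(alive)
        if m[i] <= 0:
            life[idx] += n
            continue
        t = rng.exponential(1.0 / m[i], size=idx.size)
        dies = t < n
        life[idx] += np.where(dies, t, float(n))
        alive[idx[dies]] = False
    idx = np.flatnonzero(alive)
    life[idx] += rng.exponential(1.0 / m[-1], size=idx.size)
    return float(life.mean()), float(life.std(ddof=1) / np.sqrt(n_agents))


def random_human_schedule(rng: np.random.Generator,
                          schema: AgeBandSchema | None = None) -> np.ndarray:
    """A Gompertz-Makeham rate schedule with band noise, spanning the
    neighbourhood-level e0 range seen in US cities (roughly 66-85 years)."""
    schema = schema or AgeBandSchema.default()
    target = rng.uniform(66.4, 85.2)
    cfg = CityConfig(
        target_e0=target,
        gompertz_b=rng.uniform(0.07, 0.10),
        makeham_c=10 ** rng.uniform(-4, -3),
        schema=schema,
    )
    base = _calibrate_gompertz(cfg)
    return base * np.exp(rng.normal(0.0, 0.15, size=schema.n_bands))


def two_band_schema() -> AgeBandSchema:
    return AgeBandSchema(lowers=(0, 5), uppers=(4, None))
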