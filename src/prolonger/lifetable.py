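"""Abridged period life tables by the Chiang method.

Central death rates M_x on grouped age bands are converted to conditional
probabilities of death q_x via

    q_x = n_x * M_x / (1 + n_x * (1 - a_x) * M_x)

for closed bands (a_x is the average fraction of the interval lived by those
dying in it) and q = 1 in the open terminal band, whose person-years are
l_terminal / M_terminal (constant-hazard closure). The Chiang construction is
the standard choice for small-population life expectancy; no variance or
confidence interval is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_ingest import AgeBandSchema, AggregateDeathTable, PopulationTable

__all__ = [
    "RADIX",
    "AbridgedLifeTable",
    "default_a_fractions",
    "compute_rates",
    "build_chiang_table",
    "life_expectancy_at_birth",
]

RADIX = 100_000.0


class RateUndefinedError(ValueError):
    """Deaths observed in a cell with zero population: the rate is undefined."""


@dataclass
class AbridgedLifeTable:
    """Chiang columns per band: n, a, M, q, l, d, L, T, e (radix l_0 = 100,000)."""

    table: pd.DataFrame  # indexed by band label
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    @property
    def e0(self) -> float:
        """Life expectancy at birth, T_0 / l_0 (years)."""
        return float(self.table["e"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "band"})
        out.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AbridgedLifeTable {self.schema.n_bands} bands, e0={self.e0:.2f}y>"


def default_a_fractions(schema: AgeBandSchema) -> np.ndarray:
    """Default a_x: 0.5 everywhere; with separate <1 and 1-4 bands, the
    conventional infant adjustment a_0 = 0.1 and a_{1-4} = 0.4."""
    a = np.full(schema.n_bands, 0.5)
    if schema.n_bands >= 2 and schema.uppers[0] == 0:
        a[0] = 0.1
        if schema.uppers[1] == 4:
            a[1] = 0.4
    return a


def compute_rates(
    deaths: AggregateDeathTable,
    population: PopulationTable,
    window: tuple[int, int],
    geounit: str,
) -> pd.Series:
    """All-cause central death rates M_x pooled over a multi-year window.

    M_x = (sum of deaths over the window) / (sum of person-years), per band.
    Pooling the numerator and denominator over the window (rather than
    averaging per-year tables) matches how multi-year vital statistics are
    annualised. Raises :class:`RateUndefinedError` for any band with deaths
    but no population.
    """
    schema = deaths.schema
    d = deaths.collapse_strata().data
    d = d[(d["geounit"] == geounit) & (d["year"] >= window[0]) & (d["year"] <= window[1])]
    dx = d.groupby("age_band")["deaths"].sum().reindex(schema.labels, fill_value=0.0)
    px = population.person_years(geounit, window)
    bad = (px <= 0) & (dx > 0)
    if bad.any():
        cell = bad.idxmax()
        raise RateUndefinedError(
            f"geounit {geounit!r}, band {cell}: {dx[cell]:g} deaths with zero population"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(px > 0, dx / px, 0.0)
    return pd.Series(m, index=schema.labels, name="M")


def build_chiang_table(
    M: pd.Series | np.ndarray,
    schema: AgeBandSchema | None = None,
    a: np.ndarray | None = None,
) -> AbridgedLifeTable:
    """Build the abridged life table from per-band central death rates.

    The terminal rate must be positive (its person-years are l/M); upstream
    small-cell smoothing is responsible for preventing an empty open interval.
    """
    schema = schema or AgeBandSchema.default()
    m = np.asarray(M, dtype=float)
    if m.shape != (schema.n_bands,):
        raise ValueError(f"expected {schema.n_bands} rates, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("negative central death rate")
    if m[-1] <= 0:
        raise ValueError(
            "open-interval rate zero: terminal band person-years l/M are undefined "
            "(smooth or pool the terminal cell upstream)"
        )
    a = default_a_fractions(schema) if a is None else np.asarray(a, dtype=float)
    n = np.array([schema.uppers[i] - schema.lowers[i] + 1 for i in range(schema.n_bands - 1)]
                 + [np.nan], dtype=float)

    q = np.empty_like(m)
    nc, ac, mc = n[:-1], a[:-1], m[:-1]
    q[:-1] = nc * mc / (1.0 + nc * (1.0 - ac) * mc)
    q[:-1] = np.clip(q[:-1], 0.0, 1.0)
    q[-1] = 1.0

    k = schema.n_bands
    l = np.empty(k)
    l[0] = RADIX
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q
    L = np.empty(k)
    L[:-1] = nc * (l[1:] + ac * d[:-1])
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    tab = pd.DataFrame(
        {"n": n, "a": a, "M": m, "q": q, "l": l, "d": d, "L": L, "T": T, "e": e},
        index=list(schema.labels),
    )
    return AbridgedLifeTable(tab, schema)


def life_expectancy_at_birth(table: AbridgedLifeTable) -> float:
    """e_0 = T_0 / l_0: mean years a newborn lives under the period rates."""
    return table.e0
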