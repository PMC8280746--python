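"""Small-cell smoothing: replace sparse death counts with regression predictions.

Neighbourhood-level life tables suffer from cells with 0 or very few deaths
of a given cause, which can artificially inflate the resulting life
expectancy. Following CDC small-area practice, every (geounit x age band)
cell with fewer than 5 cause-specific deaths is replaced by the prediction
of a negative binomial regression (log link, NB2 dispersion fitted by
maximum likelihood) of the cell count on six cell-level covariates: age at
the start of the interval, age-specific population, proportion
non-Hispanic Black, proportion non-Hispanic white, median household income,
and proportion with educational attainment above high school. A predicted
count larger than the study-area-wide total of that cause in that age band
is capped at that total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

log = logging.getLogger(__name__)

__all__ = [
    "COVARIATE_COLUMNS",
    "SmoothingModel",
    "build_cell_covariates",
    "fit_smoothing_model",
    "smooth_small_cells",
]

#: the six cell-level covariates, in design-matrix order
COVARIATE_COLUMNS = (
    "age_start",
    "population",
    "prop_black",
    "prop_white",
    "median_income",
    "prop_above_hs",
)


class SingularDesignError(ValueError):
    """The covariate design matrix is rank deficient (collinear columns)."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear covariate column(s): {columns}")


@dataclass
class SmoothingModel:
    """A fitted count-regression model for cell-level death counts.

    Covariates are standardised internally for numerical stability; the
    coefficient/SE accessors report on the original covariate scale. ``kind``
    is ``"negbin"`` or, when the dispersion estimate degenerates (no
    overdispersion) or the likelihood fails to converge, ``"poisson"``.
    """

    kind: str
    params_std: np.ndarray          # intercept + slopes on the standardised scale
    bse_std: np.ndarray
    alpha: float                    # NB2 dispersion (0 for the Poisson fallback)
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    n_cells: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> pd.Series:
        """Intercept + slopes on the original covariate scale."""
        slopes = self.params_std[1:] / self.sds
        intercept = self.params_std[0] - np.sum(self.params_std[1:] * self.means / self.sds)
        return pd.Series(
            np.concatenate([[intercept], slopes]), index=["intercept", *self.columns]
        )

    @property
    def standard_errors(self) -> pd.Series:
        """Slope SEs on the original covariate scale (intercept SE not back-transformed)."""
        return pd.Series(
            np.concatenate([[self.bse_std[0]], self.bse_std[1:] / self.sds]),
            index=["intercept", *self.columns],
        )

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Predicted mean count per row of ``covariates``."""
        X = self._design(covariates)
        eta = X @ self.params_std
        return np.exp(eta)

    def _design(self, covariates: pd.DataFrame) -> np.ndarray:
        missing = set(self.columns) - set(covariates.columns)
        if missing:
            raise KeyError(f"covariates missing column(s) {sorted(missing)}")
        Z = (covariates[list(self.columns)].to_numpy(dtype=float) - self.means) / self.sds
        return np.column_stack([np.ones(len(Z)), Z])


def build_cell_covariates(
    population,
    geo_covariates: pd.DataFrame,
    window: tuple[int, int],
) -> pd.DataFrame:
    """Assemble the per-(geounit, age_band) covariate frame for model fitting.

    ``population`` is a :class:`~prolonger.io_ingest.PopulationTable`;
    ``geo_covariates`` is indexed by geounit with columns prop_black,
    prop_white, median_income, prop_above_hs. The cell population is the
    mean annual age-specific population over the window; age_start is the
    first single-year age of the band.
    """
    schema = population.schema
    pop = population.collapse_strata().data
    pop = pop[(pop["year"] >= window[0]) & (pop["year"] <= window[1])]
    n_years = window[1] - window[0] + 1
    cells = pop.groupby(["geounit", "age_band"], as_index=False)["population"].sum()
    cells["population"] = cells["population"] / n_years
    cells["age_start"] = [schema.lowers[schema.index_of_label(b)] for b in cells["age_band"]]
    geo = geo_covariates[["prop_black", "prop_white", "median_income", "prop_above_hs"]]
    out = cells.merge(geo, left_on="geounit", right_index=True, how="left")
    if out[list(geo.columns)].isna().any().any():
        missing = out.loc[out["prop_black"].isna(), "geounit"].unique()
        raise KeyError(f"no covariates for geounit(s) {sorted(missing)[:5]}")
    return out


def fit_smoothing_model(
    cells: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    columns: tuple[str, ...] = COVARIATE_COLUMNS,
) -> SmoothingModel:
    """Fit the cell-count regression by maximum likelihood.

    ``cells`` must contain a ``deaths`` column plus (or merged from
    ``covariates``, matched positionally on the shared geounit/age_band keys)
    the covariate columns. Zero-variance covariates are dropped with a
    warning; any remaining collinearity raises :class:`SingularDesignError`
    naming the offending columns. A degenerate dispersion estimate falls back
    to Poisson, logged on the returned model.
    """
    if covariates is not None:
        keys = [k for k in ("geounit", "age_band") if k in cells.columns and k in covariates.columns]
        if keys:
            cells = cells.merge(covariates, on=keys, how="left", suffixes=("", "_cov"))
        else:
            cells = pd.concat([cells.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    y = np.round(cells["deaths"].to_numpy(dtype=float)).astype(int)
    notes: list[str] = []

    usable = []
    for c in columns:
        if c not in cells.columns:
            raise KeyError(f"covariate column {c!r} not found")
        vals = cells[c].to_numpy(dtype=float)
        if np.std(vals) <= 1e-10 * max(1.0, float(np.abs(vals).max())):
            notes.append(f"dropped zero-variance covariate {c!r}")
            warnings.warn(f"covariate {c!r} has zero variance; dropped from the smoothing model")
        else:
            usable.append(c)

    if y.std() == 0:
        warnings.warn("zero-variance death counts; fitting intercept-only model")
        mu = max(float(y.mean()), 1e-12)
        return SmoothingModel(
            kind="poisson", params_std=np.array([np.log(mu)]), bse_std=np.array([np.nan]),
            alpha=0.0, columns=(), means=np.empty(0), sds=np.empty(0),
            n_cells=len(y), notes=notes + ["constant response: intercept-only"],
        )

    cols = tuple(usable)
    Zraw = cells[list(cols)].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
    means = Zraw.mean(axis=0) if cols else np.empty(0)
    sds = Zraw.std(axis=0) if cols else np.empty(0)
    Z = (Zraw - means) / sds if cols else Zraw
    X = np.column_stack([np.ones(len(y)), Z])

    if cols and np.linalg.matrix_rank(X) < X.shape[1]:
        # identify culprits: columns whose removal restores full rank
        bad = []
        for j, c in enumerate(cols):
            Xr = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                bad.append(c)
        raise SingularDesignError(bad or list(cols))

    kind, alpha, converged = "negbin", 0.0, True
    params = bse = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NegativeBinomial(y, X).fit(disp=0, maxiter=500, method="bfgs")
        alpha = float(res.params[-1])
        if np.isfinite(res.params).all() and alpha > 1e-6:
            params = res.params[:-1]
            bse = res.bse[:-1]
            converged = bool(res.mle_retvals.get("converged", True))
        else:
            notes.append(f"dispersion degenerate (alpha={alpha:.3g}); Poisson fallback")
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        notes.append(f"negative binomial fit failed ({exc}); Poisson fallback")
    if params is None:
        kind, alpha = "poisson", 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        log.info("smoothing model fell back to Poisson: %s", "; ".join(notes))

    return SmoothingModel(
        kind=kind, params_std=np.asarray(params), bse_std=np.asarray(bse), alpha=alpha,
        columns=cols, means=means, sds=sds, n_cells=len(y), converged=converged, notes=notes,
    )


def smooth_small_cells(
    cells: pd.DataFrame,
    model: SmoothingModel,
    threshold: float = 5.0,
    cap: str = "study_area",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace cell counts below ``threshold`` with model predictions.

    ``cells`` holds one row per (geounit, age_band) with a ``deaths`` column
    and the model's covariates. Cells at or above the threshold are returned
    bit-identically. Predictions exceeding the total deaths of the cause in
    that age band are replaced by that total; ``cap`` selects whether the
    total is taken over the whole study area (default, the reading under
    which a prediction can plausibly exceed it) or per geounit
    (``cap="geounit"``, where it degenerates to the observed cell count).
    Returns ``(smoothed cells, replacement log)``; the log records every
    replaced cell with its observed count, raw prediction, cap flag and
    final value. With ``threshold=0`` smoothing is the identity.
    """
    if cap not in ("study_area", "geounit"):
        raise ValueError("cap must be 'study_area' or 'geounit'")
    out = cells.copy()
    obs = np.array(out["deaths"], dtype=float, copy=True)
    small = obs < threshold
    logrows = []
    if small.any():
        pred = model.predict(out.loc[small])
        if not np.isfinite(pred).all():
            i = int(np.flatnonzero(~np.isfinite(pred))[0])
            bad = out.loc[small].iloc[i]
            raise ValueError(
                f"non-finite prediction for cell (geounit={bad.get('geounit')}, "
                f"band={bad.get('age_band')})"
            )
        if cap == "study_area":
            band_tot = cells.groupby("age_band")["deaths"].sum()
            caps = out.loc[small, "age_band"].map(band_tot).to_numpy(dtype=float)
        else:
            caps = obs[small]
        capped = pred > caps
        final = np.where(capped, caps, pred)
        out.loc[small, "deaths"] = final
        logrows = pd.DataFrame({
            "geounit": cells.loc[small, "geounit"].to_numpy() if "geounit" in cells else "",
            "age_band": cells.loc[small, "age_band"].to_numpy() if "age_band" in cells else "",
            "observed": obs[small],
            "predicted": pred,
            "capped": capped,
            "final": final,
        }, index=np.flatnonzero(small))
    replacement_log = (
        logrows if isinstance(logrows, pd.DataFrame)
        else pd.DataFrame(columns=["geounit", "age_band", "observed", "predicted", "capped", "final"])
    )
    return out, replacement_log
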