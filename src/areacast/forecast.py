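"""Forecasting future years and scoring one-year-ahead predictions.

Future observations are treated as missing: for every retained posterior
draw the temporal process is propagated forward (AR(1) recursion with
model-consistent innovation noise, spatial structure intact), covariates
and populations are carried forward from the last observed year (or
supplied), and future counts are drawn from the Poisson predictive.
Medians and 90% equal-tail intervals summarize rates and counts per
(area, future year), plus state-level totals aggregated at the draw
level (quantiles are not additive, so totals are summarized from summed
draws, never from summed per-area summaries).

Scoring follows the small-area evaluation protocol: root mean square
error, mean absolute error (with the signed mean error reported
alongside), and the rank difference — the fraction of areas whose
predicted quintile matches their observed quintile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import gmrf
from .graph import ArealGraph
from .mcmc import McmcConfig, PosteriorDraws, fit, summarize_samples
from .model import (
    ModelSpec,
    PanelData,
    linear_predictor,
    trend_basis,
)

__all__ = [
    "ForecastResult",
    "forecast",
    "rmse",
    "mae",
    "mean_error",
    "rank_difference",
    "one_year_ahead_evaluate",
    "forecast_to_frame",
    "forecast_to_geojson",
]

RATE_SCALE = 100_000.0  # deaths per 100,000 population, for display


@dataclass
class ForecastResult:
    """Posterior predictive summaries for future years."""

    area_ids: list[str]
    years: np.ndarray                  # future years, length H
    population: np.ndarray             # I x H populations used
    urban: np.ndarray
    rate_draws: np.ndarray             # (n_draws, I, H) latent rates mu
    count_draws: np.ndarray            # (n_draws, I, H) Poisson predictive counts

    def __post_init__(self) -> None:
        med = np.median(self.rate_draws, axis=0)
        if np.any(med <= 0):
            raise AssertionError("predicted rates must be strictly positive")

    @property
    def horizon(self) -> int:
        return len(self.years)

    def rate_summary(self, level: float = 0.90, per: float = 1.0) -> pd.DataFrame:
        """Per (area, year): rate median and interval, scaled by ``per``."""
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        q = np.quantile(self.rate_draws, [0.5, lo, hi], axis=0) * per
        for h, yr in enumerate(self.years):
            for i, a in enumerate(self.area_ids):
                rows.append({
                    "area_id": a, "year": int(yr), "horizon": h + 1,
                    "rate_median": q[0, i, h], "rate_lo90": q[1, i, h],
                    "rate_hi90": q[2, i, h],
                })
        return pd.DataFrame(rows)

    def count_summary(self, level: float = 0.90, rounded: bool = True) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        q = np.quantile(self.count_draws, [0.5, lo, hi], axis=0)
        if rounded:
            q = np.rint(q)
        rows = []
        for h, yr in enumerate(self.years):
            for i, a in enumerate(self.area_ids):
                rows.append({
                    "area_id": a, "year": int(yr), "horizon": h + 1,
                    "count_median": q[0, i, h], "count_lo90": q[1, i, h],
                    "count_hi90": q[2, i, h],
                })
        return pd.DataFrame(rows)

    def state_totals(self, level: float = 0.90, stratum: str = "all") -> pd.DataFrame:
        """Aggregate count and rate summaries from *summed draws*."""
        if stratum == "all":
            keep = np.ones(len(self.area_ids), bool)
        elif stratum == "urban":
            keep = self.urban.astype(bool)
        elif stratum == "rural":
            keep = ~self.urban.astype(bool)
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        totals = self.count_draws[:, keep, :].sum(axis=1)   # (n_draws, H)
        pop = self.population[keep].sum(axis=0)             # (H,)
        rows = []
        for h, yr in enumerate(self.years):
            cs = summarize_samples(totals[:, h], level)
            rs = summarize_samples(totals[:, h] / pop[h] * RATE_SCALE, level)
            rows.append({
                "year": int(yr), "stratum": stratum,
                "count_median": cs["median"], "count_lo90": cs["lo"],
                "count_hi90": cs["hi"],
                "rate_median": rs["median"], "rate_lo90": rs["lo"],
                "rate_hi90": rs["hi"],
            })
        return pd.DataFrame(rows)

    def point_rates(self) -> np.ndarray:
        """Posterior-median latent rate per (area, year); I x H."""
        return np.median(self.rate_draws, axis=0)

    def point_counts(self) -> np.ndarray:
        """Posterior-predictive median count per (area, year); I x H."""
        return np.median(self.count_draws, axis=0)

    def mean_interval_width(self, level: float = 0.90, scale: str = "rate") -> np.ndarray:
        """Mean CrI width per horizon step (length H)."""
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        draws = self.rate_draws if scale == "rate" else self.count_draws
        q = np.quantile(draws, [lo, hi], axis=0)
        return (q[1] - q[0]).mean(axis=0)


def forecast(
    spec: ModelSpec,
    draws: PosteriorDraws,
    data: PanelData,
    graph: ArealGraph,
    horizon: int = 1,
    future_covariates: np.ndarray | str = "carry_forward",
    future_population: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ForecastResult:
    """Posterior-predictive forecast for the ``horizon`` years after the data.

    ``future_covariates`` is either the string ``"carry_forward"`` (reuse
    the last observed year, as when future area-level covariates are
    unknown) or an ``I x horizon x K`` array on the same standardized
    scale as the fitted panel.  Populations carry forward unless given.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if rng is None:
        rng = np.random.default_rng(draws.config.seed + 1_000_003)
    I, T = data.n_areas, data.n_years
    K = data.n_covariates
    future_years = np.arange(data.years[-1] + 1, data.years[-1] + 1 + horizon)

    if isinstance(future_covariates, str):
        if future_covariates != "carry_forward":
            raise ValueError(f"unknown covariate policy {future_covariates!r}")
        Xf = np.repeat(data.covariates[:, -1:, :], horizon, axis=1)
    else:
        Xf = np.asarray(future_covariates, dtype=float)
        if Xf.shape != (I, horizon, K):
            raise ValueError(
                f"future covariates have shape {Xf.shape}, expected {(I, horizon, K)}"
            )
    if future_population is None:
        Nf = np.repeat(data.population[:, -1:], horizon, axis=1)
    else:
        Nf = np.asarray(future_population, dtype=float)
        if Nf.shape != (I, horizon):
            raise ValueError("future population must be I x horizon")

    B = trend_basis(spec, future_years, ref_years=data.years)   # (H, p)

    # spatial innovation structure for the interaction field
    if spec.variant in ("model2", "model3"):
        from .model import spatial_precision

        ref_state = draws.state(0)
        QS = spatial_precision(spec, ref_state, graph)
        w, V = np.linalg.eigh(QS.Q.toarray())
        w[np.abs(w) < 1e-10] = 0.0
        pos = w > 0
        rho_s_dependent = spec.variant == "model3" and spec.car_variant == "proper"

    n_draws = draws.n_draws
    rate_out = np.empty((n_draws, I, horizon))
    count_out = np.empty((n_draws, I, horizon))

    for d, st in enumerate(draws.states()):
        rho = st.rho_T if T > 1 else 0.0
        eta_fix = np.full((I, horizon), st.alpha)
        if B.shape[1]:
            eta_fix += (B @ st.trend_coefs)[None, :]
        nb = 0
        if spec.include_covariates or spec.include_urban_indicator:
            cols = []
            if spec.include_covariates:
                cols = [Xf[:, :, k] for k in range(K)]
            if spec.include_urban_indicator:
                cols.append(np.repeat(data.urban.astype(float)[:, None], horizon, axis=1))
            for c, b in zip(cols, st.beta):
                eta_fix += b * c
            nb = len(cols)

        if spec.variant == "model1":
            tau_e = np.exp(st.log_tau_eta)
            sd_innov = np.sqrt((1 - rho**2) / tau_e) if T > 1 else np.sqrt(1 / tau_e)
            prev = st.eta_t[-1]
            eta_rand = np.empty((I, horizon))
            for h in range(horizon):
                prev = rho * prev + sd_innov * rng.standard_normal()
                eta_rand[:, h] = st.alpha_area + prev
        else:
            tau = np.exp(st.log_tau)
            if rho_s_dependent:
                QS_d = spatial_precision(spec, st, graph)
                w, V = np.linalg.eigh(QS_d.Q.toarray())
                w[np.abs(w) < 1e-10] = 0.0
                pos = w > 0
            # omega_{t+1} = rho * omega_t + e,  e ~ N(0, ((1-rho^2)/tau) * QS^+)
            innov_var = (1 - rho**2) / tau if T > 1 else 1.0 / tau
            Vp = V[:, pos] * np.sqrt(innov_var / w[pos])
            prev_field = st.omega[:, -1]
            eta_rand = np.empty((I, horizon))
            for h in range(horizon):
                e = Vp @ rng.standard_normal(Vp.shape[1])
                prev_field = rho * prev_field + e
                eta_rand[:, h] = prev_field

        eta = eta_fix + eta_rand
        mu = np.exp(eta)
        rate_out[d] = mu
        count_out[d] = rng.poisson(Nf * mu)

    return ForecastResult(
        area_ids=data.area_ids,
        years=future_years,
        population=Nf,
        urban=data.urban,
        rate_draws=rate_out,
        count_draws=count_out,
    )


# ---------------------------------------------------------------------------
# Metrics


def _check_pair(pred, obs):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size == 0:
        raise ValueError("empty vectors")
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal length")
    return pred, obs


def rmse(pred, obs) -> float:
    """Root mean square error."""
    pred, obs = _check_pair(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def mae(pred, obs) -> float:
    """Mean absolute error."""
    pred, obs = _check_pair(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def mean_error(pred, obs) -> float:
    """Signed mean error (positive = overprediction)."""
    pred, obs = _check_pair(pred, obs)
    return float(np.mean(pred - obs))


def _quantile_groups(x: np.ndarray, n_groups: int) -> np.ndarray:
    """Quantile-group labels via average ranks and right-closed cuts.

    Ties (ubiquitous in sparse rural counts) get the average rank, so
    tied values always land in the same group.
    """
    r = rankdata(x, method="average") / len(x)
    cuts = np.arange(1, n_groups) / n_groups
    return np.searchsorted(cuts, r, side="left")


def rank_difference(pred, obs, n_groups: int = 5) -> float:
    """Fraction of areas whose predicted quantile group matches observed."""
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    pred, obs = _check_pair(pred, obs)
    if pred.size < n_groups:
        raise ValueError("need at least n_groups observations")
    gp = _quantile_groups(pred, n_groups)
    go = _quantile_groups(obs, n_groups)
    return float(np.mean(gp == go))


# ---------------------------------------------------------------------------
# Rolling-origin one-year-ahead evaluation


def _strata(urban: np.ndarray):
    urban = urban.astype(bool)
    return {"all": np.ones(len(urban), bool), "urban": urban, "rural": ~urban}


def _score_rows(
    year: int,
    label: str,
    pred_counts: np.ndarray,
    pred_rates: np.ndarray,
    obs_counts: np.ndarray,
    obs_rates: np.ndarray,
    urban: np.ndarray,
) -> list[dict]:
    rows = []
    for stratum, keep in _strata(urban).items():
        for scale, p, o in (
            ("count", pred_counts, obs_counts),
            ("rate", pred_rates, obs_rates),
        ):
            rd = (
                rank_difference(p[keep], o[keep])
                if keep.sum() >= 5 else float("nan")  # quintiles need >= 5 areas
            )
            rows.append({
                "year": int(year), "stratum": stratum, "scale": scale,
                "model": label,
                "rmse": rmse(p[keep], o[keep]),
                "mae": mae(p[keep], o[keep]),
                "mean_error": mean_error(p[keep], o[keep]),
                "rank_difference": rd,
            })
    return rows


def one_year_ahead_evaluate(
    spec_list: list[ModelSpec],
    data: PanelData,
    graph: ArealGraph,
    first_test_year: int,
    last_test_year: int,
    config: McmcConfig,
) -> pd.DataFrame:
    """Strict rolling-origin protocol: re-fit on years <= y-1, score year y.

    Returns the metrics table with one row per (test year, stratum in
    {all, urban, rural}, scale in {count, rate}, model).  Predicted
    counts are posterior-predictive medians; predicted rates are
    posterior-median rates per 100,000; observed rates use the held-out
    year's population.
    """
    if first_test_year <= int(data.years[0]):
        raise ValueError("first_test_year must leave at least one training year")
    if last_test_year > int(data.years[-1]):
        raise ValueError("last_test_year beyond the observed panel")
    rows: list[dict] = []
    for year in range(first_test_year, last_test_year + 1):
        train = data.subset_years(year - 1)
        if train.n_years < 3:
            raise ValueError("fewer than 3 training years")
        t_idx = int(np.flatnonzero(data.years == year)[0])
        obs_counts = data.deaths[:, t_idx]
        pop = data.population[:, t_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_rates = np.where(pop > 0, obs_counts / np.maximum(pop, 1e-12), 0.0) * RATE_SCALE
        for j, spec in enumerate(spec_list):
            cfg = McmcConfig(
                n_iterations=config.n_iterations,
                n_burnin=config.n_burnin,
                thin=config.thin,
                seed=config.seed + 101 * year + j,
                latent_step=config.latent_step,
                hyper_step=config.hyper_step,
                adapt=config.adapt,
            )
            draws = fit(spec, train, graph, cfg)
            fc = forecast(
                spec, draws, train, graph, horizon=1,
                future_population=pop[:, None],
                future_covariates=(
                    data.covariates[:, t_idx:t_idx + 1, :]
                    if spec.include_covariates else "carry_forward"
                ),
            )
            pred_counts = fc.point_counts()[:, 0]
            pred_rates = fc.point_rates()[:, 0] * RATE_SCALE
            rows += _score_rows(
                year, spec.label, pred_counts, pred_rates,
                obs_counts, obs_rates, data.urban,
            )
    table = pd.DataFrame(rows)
    assert np.all(table["mae"] <= table["rmse"] + 1e-12)
    return table


# ---------------------------------------------------------------------------
# Exports


def forecast_to_frame(fc: ForecastResult) -> pd.DataFrame:
    """Joined per-(area, year) rate (per 100,000) and count summaries."""
    rates = fc.rate_summary(per=RATE_SCALE)
    counts = fc.count_summary()
    return rates.merge(counts, on=["area_id", "year", "horizon"])


def forecast_to_geojson(
    fc: ForecastResult, geometries: dict, year: int | None = None
) -> dict:
    """GeoJSON FeatureCollection with forecast properties per area."""
    import json as _json

    from shapely.geometry import mapping

    year = int(fc.years[0]) if year is None else int(year)
    df = forecast_to_frame(fc)
    df = df[df["year"] == year].set_index("area_id")
    feats = []
    for a in fc.area_ids:
        if a not in geometries:
            raise ValueError(f"no geometry for area {a!r}")
        row = df.loc[a]
        feats.append({
            "type": "Feature",
            "id": a,
            "geometry": mapping(geometries[a]),
            "properties": {
                "rate_median": float(row["rate_median"]),
                "rate_lo90": float(row["rate_lo90"]),
                "rate_hi90": float(row["rate_hi90"]),
                "count_median": float(row["count_median"]),
            },
        })
    return {"type": "FeatureCollection", "features": feats}
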