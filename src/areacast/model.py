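"""Model definitions: Poisson observation layer and latent structure.

Three variants of the log mortality rate for area i, year t:

* model 1: ``log mu_it = alpha_i + S(t) + eta_t`` with exchangeable area
  intercepts and an AR(1) year effect — temporal pooling, no explicit
  spatial dependence.
* model 2: ``log mu_it = alpha + S(t) + omega_it`` with
  ``omega ~ GMRF(tau * Q_AR(1) (x) I)`` — an inseparable space-time
  interaction with exchangeable spatial structure.
* model 3: as model 2 with an intrinsic CAR spatial factor
  ``omega ~ GMRF(tau * Q_AR(1) (x) Q_CAR)`` — neighbouring areas share
  information.

Counts are ``Y_it ~ Poisson(N_it * mu_it)`` with the population ``N_it``
as an offset.  Covariates (standardized area-level proportions etc.) and
an urban/rural indicator can be added to any variant.  The marginal
trend S(t) defaults to linear in model 1 and to none in models 2-3,
whose interaction field absorbs temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import gamma as _gamma_dist

from . import gmrf
from .graph import ArealGraph

__all__ = [
    "PanelData",
    "ModelSpec",
    "PriorHyperparameters",
    "LatentState",
    "standardize_covariates",
    "trend_basis",
    "linear_predictor",
    "poisson_loglik",
    "log_prior",
    "log_posterior",
    "read_panel_csv",
    "write_panel_csv",
]


@dataclass
class PanelData:
    """The (Y, N, X, urban) rectangle over I areas x T consecutive years."""

    area_ids: list[str]
    years: np.ndarray                    # T consecutive integers
    deaths: np.ndarray                   # I x T nonnegative ints
    population: np.ndarray               # I x T nonnegative reals
    covariates: np.ndarray = None        # I x T x K
    urban: np.ndarray = None             # I bools
    covariate_names: list[str] = None
    covariate_transform: dict = None     # mean/sd per covariate, set by standardization

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        I, T = len(self.area_ids), len(self.years)
        if self.deaths.shape != (I, T) or self.population.shape != (I, T):
            raise ValueError("deaths/population must be I x T")
        if T > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly consecutive")
        if np.any(self.deaths < 0) or np.any(self.population < 0):
            raise ValueError("negative deaths or population")
        if np.any((self.population == 0) & (self.deaths > 0)):
            raise ValueError("deaths observed in a cell with zero population")
        if self.covariates is None:
            self.covariates = np.zeros((I, T, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape[:2] != (I, T):
            raise ValueError("covariates must be I x T x K")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain non-finite values")
        if self.urban is None:
            self.urban = np.zeros(I, dtype=bool)
        self.urban = np.asarray(self.urban, dtype=bool)
        if self.covariate_names is None:
            self.covariate_names = [f"cov_{k + 1}" for k in range(self.n_covariates)]

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[2]

    def subset_years(self, last_year: int) -> "PanelData":
        """Training window: all years up to and including ``last_year``."""
        keep = self.years <= last_year
        if keep.sum() == 0:
            raise ValueError("no years left after subsetting")
        return PanelData(
            area_ids=self.area_ids,
            years=self.years[keep],
            deaths=self.deaths[:, keep],
            population=self.population[:, keep],
            covariates=self.covariates[:, keep, :],
            urban=self.urban,
            covariate_names=self.covariate_names,
            covariate_transform=self.covariate_transform,
        )


@dataclass
class PriorHyperparameters:
    """Vague priors in the style of standard latent-Gaussian-model defaults.

    Gamma(shape, rate) on every precision; Normal(0, sd) on fixed
    effects; Normal(0, sd) on the Fisher-z transform of the AR(1)
    coefficient (and on the logit of a proper-CAR coefficient).
    """

    precision_shape: float = 1.0
    precision_rate: float = 5e-5
    fixed_effect_sd: float = 31.6
    rho_transform_sd: float = 2.6

    def __post_init__(self) -> None:
        for name in ("precision_shape", "precision_rate", "fixed_effect_sd", "rho_transform_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelSpec:
    """Which model variant to fit, and with what extras."""

    variant: str = "model3"              # model1 | model2 | model3
    include_covariates: bool = False
    include_urban_indicator: bool = False
    trend: str = None                    # none | linear | quadratic | spline(df); default per variant
    spline_df: int = 4
    car_variant: str = "intrinsic"       # intrinsic | proper
    priors: PriorHyperparameters = field(default_factory=PriorHyperparameters)

    def __post_init__(self) -> None:
        if self.variant not in ("model1", "model2", "model3"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.trend is None:
            self.trend = "linear" if self.variant == "model1" else "none"
        if self.trend not in ("none", "linear", "quadratic", "spline"):
            raise ValueError(f"unknown trend {self.trend!r}")
        if self.trend == "none" and self.variant == "model1":
            raise ValueError("model1 has no interaction term; trend='none' is only "
                             "meaningful for models 2-3")
        if self.car_variant not in ("intrinsic", "proper"):
            raise ValueError(f"unknown car_variant {self.car_variant!r}")

    @property
    def label(self) -> str:
        tag = self.variant
        if self.include_covariates or self.include_urban_indicator:
            tag += "+cov"
        return tag


@dataclass
class LatentState:
    """One point in parameter space for a given (spec, data, graph)."""

    alpha: float = 0.0                       # global intercept
    alpha_area: np.ndarray = None            # model 1 area deviations a_i (sum-to-zero)
    beta: np.ndarray = None                  # covariate (+ urban) coefficients
    trend_coefs: np.ndarray = None
    eta_t: np.ndarray = None                 # model 1 AR(1) year effect
    omega: np.ndarray = None                 # models 2-3 interaction, I x T
    log_tau: float = 0.0                     # precision of omega (models 2-3)
    log_tau_area: float = 0.0                # precision of a_i (model 1)
    log_tau_eta: float = 0.0                 # precision of eta_t (model 1)
    rho_T: float = 0.0                       # AR(1) coefficient
    rho_S: float = 0.5                       # proper-CAR coefficient, when used

    def copy(self) -> "LatentState":
        return replace(
            self,
            alpha_area=None if self.alpha_area is None else self.alpha_area.copy(),
            beta=None if self.beta is None else self.beta.copy(),
            trend_coefs=None if self.trend_coefs is None else self.trend_coefs.copy(),
            eta_t=None if self.eta_t is None else self.eta_t.copy(),
            omega=None if self.omega is None else self.omega.copy(),
        )


def standardize_covariates(data: PanelData) -> PanelData:
    """Center and scale each covariate over all (area, year) cells.

    The transform (mean, sd per covariate) is stored on the returned
    panel so that future-year covariates can be put on the same scale.
    If the panel already carries a transform it is reused verbatim,
    making repeated application idempotent.
    """
    if data.n_covariates == 0:
        raise ValueError("panel has no covariates to standardize")
    X = data.covariates
    if data.covariate_transform is not None:
        tf = data.covariate_transform
        means, sds = np.asarray(tf["mean"]), np.asarray(tf["sd"])
    else:
        means = X.reshape(-1, X.shape[2]).mean(axis=0)
        sds = X.reshape(-1, X.shape[2]).std(axis=0)
        for k, s in enumerate(sds):
            if s == 0:
                raise ValueError(
                    f"covariate {data.covariate_names[k]!r} has zero variance"
                )
    Z = (X - means) / sds
    return PanelData(
        area_ids=data.area_ids,
        years=data.years,
        deaths=data.deaths,
        population=data.population,
        covariates=Z,
        urban=data.urban,
        covariate_names=data.covariate_names,
        covariate_transform={"mean": means, "sd": sds},
    )


def trend_basis(spec: ModelSpec, years: np.ndarray, ref_years: np.ndarray = None) -> np.ndarray:
    """Design columns for the marginal trend S(t), evaluated at ``years``.

    ``ref_years`` fixes the centering/knots (the training years) so the
    basis extends consistently to future years.  Returns (len(years), p).
    """
    years = np.asarray(years, dtype=float)
    if ref_years is None:
        ref_years = years
    ref_years = np.asarray(ref_years, dtype=float)
    c = ref_years.mean()
    s = ref_years.std() if ref_years.std() > 0 else 1.0
    z = (years - c) / s
    if spec.trend == "none":
        return np.zeros((len(years), 0))
    if spec.trend == "linear":
        return z[:, None]
    if spec.trend == "quadratic":
        return np.column_stack([z, z * z])
    # cubic B-spline basis with interior knots at quantiles of the
    # reference years; extrapolates linearly beyond the boundary
    from scipy.interpolate import BSpline

    df = max(spec.spline_df, 3)
    n_interior = max(df - 3, 0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(ref_years, qs) if n_interior else np.array([])
    lo, hi = ref_years.min(), ref_years.max()
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    n_basis = len(knots) - 4
    B = np.empty((len(years), n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        B[:, j] = BSpline(knots, coef, 3, extrapolate=True)(years)
    return B


def covariate_design(spec: ModelSpec, data: PanelData) -> np.ndarray:
    """Flattened (n_cells, n_beta) design for covariates + urban flag.

    Cells are stacked area-fastest (cell ``t*I + i``).
    """
    I, T = data.n_areas, data.n_years
    cols = []
    if spec.include_covariates:
        for k in range(data.n_covariates):
            cols.append(data.covariates[:, :, k].T.ravel())  # area-fastest
    if spec.include_urban_indicator:
        cols.append(np.tile(data.urban.astype(float), T))
    return np.column_stack(cols) if cols else np.zeros((I * T, 0))


def n_beta(spec: ModelSpec, data: PanelData) -> int:
    return (data.n_covariates if spec.include_covariates else 0) + int(
        spec.include_urban_indicator
    )


def _ensure_state_shapes(spec: ModelSpec, state: LatentState, data: PanelData) -> None:
    I, T = data.n_areas, data.n_years
    nb = n_beta(spec, data)
    if nb and (state.beta is None or len(state.beta) != nb):
        raise ValueError("state.beta inconsistent with spec/data")
    p = trend_basis(spec, data.years).shape[1]
    if p and (state.trend_coefs is None or len(state.trend_coefs) != p):
        raise ValueError("state.trend_coefs inconsistent with trend spec")
    if spec.variant == "model1":
        if state.alpha_area is None or len(state.alpha_area) != I:
            raise ValueError("model1 requires alpha_area of length I")
        if state.eta_t is None or len(state.eta_t) != T:
            raise ValueError("model1 requires eta_t of length T")
    else:
        if state.omega is None or state.omega.shape != (I, T):
            raise ValueError("models 2-3 require omega of shape I x T")


def linear_predictor(spec: ModelSpec, state: LatentState, data: PanelData) -> np.ndarray:
    """The I x T log-rate surface eta_it."""
    _ensure_state_shapes(spec, state, data)
    I, T = data.n_areas, data.n_years
    eta = np.full((I, T), state.alpha)
    B = trend_basis(spec, data.years)
    if B.shape[1]:
        eta += (B @ state.trend_coefs)[None, :]
    if spec.variant == "model1":
        eta += state.alpha_area[:, None]
        eta += state.eta_t[None, :]
    else:
        eta += state.omega
    nb = n_beta(spec, data)
    if nb:
        X = covariate_design(spec, data)  # (I*T, nb) area-fastest
        eta += (X @ state.beta).reshape(T, I).T
    return eta


def poisson_loglik(data: PanelData, eta: np.ndarray) -> float:
    """Poisson log-likelihood with offset; zero-population cells drop out."""
    if eta.shape != data.deaths.shape:
        raise ValueError("eta shape does not match panel")
    Y, N = data.deaths, data.population
    if np.any((N == 0) & (Y > 0)):
        raise ValueError("deaths observed in a cell with zero population")
    mask = N > 0
    ll = Y[mask] * (np.log(N[mask]) + eta[mask]) - N[mask] * np.exp(eta[mask])
    ll -= gammaln(Y[mask] + 1.0)
    return float(ll.sum())


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return float(_gamma_dist.logpdf(x, a=shape, scale=1.0 / rate))


def _normal_logpdf(x: np.ndarray, sd: float) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(-0.5 * x.size * np.log(2 * np.pi) - x.size * np.log(sd)
                 - 0.5 * np.sum((x / sd) ** 2))


def spatial_precision(spec: ModelSpec, state: LatentState, graph: ArealGraph) -> gmrf.PrecisionMatrix:
    """The spatial factor Q_S of the interaction field (models 2-3)."""
    if spec.variant == "model2":
        return gmrf.iid_precision(graph.n_areas)
    if spec.car_variant == "proper":
        return gmrf.proper_car_precision(graph, state.rho_S)
    return gmrf.icar_precision(graph, island_adjust=True)


def log_prior(spec: ModelSpec, state: LatentState, data: PanelData, graph: ArealGraph) -> float:
    """Sum of all prior log-densities (with transform Jacobians).

    Returns -inf (never raises) for states outside the support.
    """
    pri = spec.priors
    if abs(state.rho_T) >= 1:
        return -np.inf
    if spec.car_variant == "proper" and not (0 <= state.rho_S < 1):
        return -np.inf
    _ensure_state_shapes(spec, state, data)
    lp = _normal_logpdf(state.alpha, pri.fixed_effect_sd)
    if state.beta is not None and len(state.beta):
        lp += _normal_logpdf(state.beta, pri.fixed_effect_sd)
    if state.trend_coefs is not None and len(state.trend_coefs):
        lp += _normal_logpdf(state.trend_coefs, pri.fixed_effect_sd)

    # AR(1) coefficient: Normal prior on z = atanh(rho), plus the
    # Jacobian dz/drho = 1/(1-rho^2) so the density is over rho itself.
    z = np.arctanh(state.rho_T)
    lp += _normal_logpdf(z, pri.rho_transform_sd) - np.log1p(-state.rho_T ** 2)

    if spec.variant == "model1":
        tau_a, tau_e = np.exp(state.log_tau_area), np.exp(state.log_tau_eta)
        # Gamma prior on the precision, with log-transform Jacobian tau
        lp += _gamma_logpdf(tau_a, pri.precision_shape, pri.precision_rate) + state.log_tau_area
        lp += _gamma_logpdf(tau_e, pri.precision_shape, pri.precision_rate) + state.log_tau_eta
        Qa = gmrf.PrecisionMatrix(tau_a * gmrf.iid_precision(data.n_areas).Q, 0)
        lp += gmrf.gmrf_logdensity(state.alpha_area, Qa)
        Qe_base = gmrf.ar1_precision(data.n_years, state.rho_T)
        Qe = gmrf.PrecisionMatrix(tau_e * Qe_base.Q, 0)
        lp += gmrf.gmrf_logdensity(state.eta_t, Qe)
    else:
        tau = np.exp(state.log_tau)
        lp += _gamma_logpdf(tau, pri.precision_shape, pri.precision_rate) + state.log_tau
        if spec.car_variant == "proper":
            zs = np.log(state.rho_S / (1 - state.rho_S)) if 0 < state.rho_S else None
            if zs is None:
                return -np.inf
            lp += _normal_logpdf(zs, pri.rho_transform_sd) - np.log(
                state.rho_S * (1 - state.rho_S)
            )
        Q_T = gmrf.ar1_precision(data.n_years, state.rho_T)
        Q_S = spatial_precision(spec, state, graph)
        Q = gmrf.interaction_precision(Q_T, Q_S, tau)
        lp += gmrf.gmrf_logdensity(state.omega.T.ravel(), Q)  # area-fastest
    return float(lp)


def log_posterior(
    spec: ModelSpec, state: LatentState, data: PanelData, graph: ArealGraph
) -> float:
    lp = log_prior(spec, state, data, graph)
    if not np.isfinite(lp):
        return -np.inf
    eta = linear_predictor(spec, state, data)
    return lp + poisson_loglik(data, eta)


def screen_covariates(data: PanelData) -> pd.DataFrame:
    """Univariate association screen: one Poisson regression per covariate.

    Fits ``deaths ~ covariate_k`` with a log population offset for each
    covariate separately and reports the coefficient, its standard
    error, and the Wald p-value — a quick triage of which area-level
    factors are marginally associated with mortality, not a substitute
    for the joint model.
    """
    import statsmodels.api as sm

    if data.n_covariates == 0:
        raise ValueError("panel has no covariates to screen")
    mask = data.population > 0
    y = data.deaths[mask]
    offset = np.log(data.population[mask])
    rows = []
    for k, name in enumerate(data.covariate_names):
        x = sm.add_constant(data.covariates[:, :, k][mask])
        res = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
        rows.append({
            "covariate": name,
            "coef": res.params[1],
            "se": res.bse[1],
            "p_value": res.pvalues[1],
        })
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# Tidy CSV panel IO


def write_panel_csv(data: PanelData, path: str | Path) -> None:
    I, T = data.n_areas, data.n_years
    rows = {
        "area_id": np.repeat(data.area_ids, T),
        "year": np.tile(data.years, I),
        "deaths": data.deaths.ravel().astype(int),
        "population": data.population.ravel(),
        "urban": np.repeat(data.urban.astype(int), T),
    }
    for k, name in enumerate(data.covariate_names):
        rows[name] = data.covariates[:, :, k].ravel()
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> PanelData:
    df = pd.read_csv(path, dtype={"area_id": str})
    area_ids = sorted(df["area_id"].unique())
    years = np.sort(df["year"].unique())
    cov_names = [c for c in df.columns
                 if c not in ("area_id", "year", "deaths", "population", "urban")]
    I, T, K = len(area_ids), len(years), len(cov_names)
    deaths = np.zeros((I, T))
    pop = np.zeros((I, T))
    covs = np.zeros((I, T, K))
    urban = np.zeros(I, dtype=bool)
    aidx = {a: i for i, a in enumerate(area_ids)}
    yidx = {y: t for t, y in enumerate(years)}
    for _, row in df.iterrows():
        i, t = aidx[row["area_id"]], yidx[row["year"]]
        deaths[i, t] = row["deaths"]
        pop[i, t] = row["population"]
        urban[i] = bool(row.get("urban", 0))
        for k, name in enumerate(cov_names):
            covs[i, t, k] = row[name]
    return PanelData(
        area_ids=area_ids, years=years, deaths=deaths, population=pop,
        covariates=covs, urban=urban, covariate_names=cov_names,
    )
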