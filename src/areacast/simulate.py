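"""Synthetic areal panels with the structure of a small-area mortality study.

The generator emulates the statistical design of a state-wide ZCTA-level
mortality panel: a few hundred areas observed over ~15 annual time
points, roughly three quarters of areas urban, urban areas holding the
large majority of person-years (log-normal populations with a much
larger urban log-mean), sparse rural counts with many zeros, and
ACS-style covariates that are proportions in (0, 1) held constant within
multi-year survey windows.  Counts are drawn from a chosen ground-truth
model — latent fields sampled from that model's own GMRF priors at fixed
hyperparameters — so parameter-recovery and forecast-evaluation
experiments have a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from . import gmrf
from .graph import ArealGraph, grid_graph
from .model import LatentState, ModelSpec, PanelData, linear_predictor, trend_basis

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "simulate_populations",
    "simulate_covariates",
    "simulate_panel",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass
class ScenarioConfig:
    """Study-design knobs of the synthetic generator.

    Defaults mirror the structure of the motivating study: ~73% urban
    areas, heterogeneous log-normal populations (urban areas an order of
    magnitude larger), a baseline rate of ~30 per 100,000, proportion
    covariates constant within 5-year windows.
    """

    n_rows: int = 10
    n_cols: int = 10
    n_years: int = 15
    start_year: int = 2005
    urban_fraction: float = 0.73
    urban_pop_logmean: float = 9.6     # ~ e^9.6 = 15k adults per urban area
    urban_pop_logsd: float = 0.6
    rural_pop_logmean: float = 7.2     # ~ 1.3k adults per rural area
    rural_pop_logsd: float = 0.7
    pop_drift_sd: float = 0.01         # year-on-year log-population jitter
    n_covariates: int = 3
    covariate_window: int = 5          # years per ACS-style window
    baseline_rate: float = 30e-5       # ~30 deaths per 100,000 person-years
    trend_slope: float = 0.0           # optional log-linear drift in truth

    def __post_init__(self) -> None:
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must be in [0, 1]")
        for name in ("n_rows", "n_cols", "n_years", "covariate_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Everything needed to check an estimate against the generator."""

    spec_label: str
    params: dict                        # true hyperparameters and coefficients
    eta: np.ndarray                     # realized I x T log-rate surface
    mu: np.ndarray                      # exp(eta), exactly
    seed: int

    def to_json(self) -> str:
        payload = {
            "spec_label": self.spec_label,
            "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.params.items()},
            "eta": self.eta.tolist(),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)


def simulate_populations(
    graph: ArealGraph, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Populations (I x T) and urban flags.

    Urban areas form a spatially contiguous block: a random seed area is
    grown by breadth-first search until the urban fraction is reached,
    which mimics the clustering of urban ZCTAs around cities.
    """
    I = graph.n_areas
    n_urban = int(round(config.urban_fraction * I))
    urban = np.zeros(I, dtype=bool)
    if n_urban > 0:
        start = int(rng.integers(I))
        frontier = [start]
        seen = {start}
        order = []
        while frontier and len(order) < n_urban:
            nxt = frontier.pop(0)
            order.append(nxt)
            nbrs = graph.adjacency[nxt].indices
            nbrs = nbrs[rng.permutation(len(nbrs))]
            for nb in nbrs:
                if nb not in seen:
                    seen.add(int(nb))
                    frontier.append(int(nb))
            if not frontier:  # disconnected graph: jump to a fresh area
                rest = [i for i in range(I) if i not in seen]
                if rest:
                    j = int(rng.choice(rest))
                    seen.add(j)
                    frontier.append(j)
        urban[order[:n_urban]] = True

    base = np.where(
        urban,
        rng.lognormal(config.urban_pop_logmean, config.urban_pop_logsd, I),
        rng.lognormal(config.rural_pop_logmean, config.rural_pop_logsd, I),
    )
    drift = np.cumsum(
        rng.normal(0.0, config.pop_drift_sd, (I, config.n_years)), axis=1
    )
    pop = base[:, None] * np.exp(drift)
    return pop, urban


def simulate_covariates(
    graph: ArealGraph, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """ACS-style proportion covariates, I x T x K.

    Each covariate is a latent Gaussian field with mild spatial
    smoothing (one-step neighbour averaging) pushed through a logistic
    link, redrawn once per multi-year window and held constant within
    it — no within-window variance, like 5-year survey estimates.
    """
    I, T, K = graph.n_areas, config.n_years, config.n_covariates
    X = np.empty((I, T, K))
    if K == 0:
        return X
    W = graph.adjacency
    deg = np.maximum(graph.neighbor_counts, 1.0)
    n_windows = int(np.ceil(T / config.covariate_window))
    for k in range(K):
        for w in range(n_windows):
            z = rng.standard_normal(I)
            z = 0.5 * z + 0.5 * (W @ z) / deg       # mild spatial correlation
            p = 1.0 / (1.0 + np.exp(-(z - 0.5)))    # proportions in (0,1)
            t0 = w * config.covariate_window
            t1 = min(T, t0 + config.covariate_window)
            X[:, t0:t1, k] = p[:, None]
    return X


def simulate_panel(
    spec: ModelSpec,
    true_params: dict,
    graph: ArealGraph,
    config: ScenarioConfig,
    rng: np.random.Generator,
    seed_note: int = -1,
) -> tuple[PanelData, TruthRecord]:
    """Draw a full panel from the generative model defined by ``spec``.

    ``true_params`` supplies the ground truth: ``alpha`` (default: log of
    the configured baseline rate), ``beta``, ``tau``, ``rho_T``, and the
    model-1 precisions.  Latent fields are sampled from the model's own
    GMRF priors (with exact sum-to-zero constraints for intrinsic CAR),
    then ``Y_it ~ Poisson(N_it exp(eta_it))``.
    """
    I, T = graph.n_areas, config.n_years
    pop, urban = simulate_populations(graph, config, rng)
    X = simulate_covariates(graph, config, rng)
    years = np.arange(config.start_year, config.start_year + T)

    params = dict(true_params)
    params.setdefault("alpha", float(np.log(config.baseline_rate)))
    st = LatentState(alpha=params["alpha"], rho_T=params.get("rho_T", 0.0))
    nb = (config.n_covariates if spec.include_covariates else 0) + int(
        spec.include_urban_indicator
    )
    if nb:
        beta = np.asarray(params.get("beta", np.zeros(nb)), dtype=float)
        if beta.shape != (nb,):
            raise ValueError(f"beta must have length {nb}")
        st.beta = beta
        params["beta"] = beta

    # Coefficients act on the standardized covariate scale — the scale
    # the fitted models use — so recovery experiments compare like with
    # like.  The panel itself keeps the raw proportions.
    shell = PanelData(
        area_ids=graph.area_ids, years=years,
        deaths=np.zeros((I, T)), population=pop,
        covariates=X, urban=urban,
    )
    if config.n_covariates and spec.include_covariates:
        from .model import standardize_covariates

        shell = standardize_covariates(shell)

    p_trend = trend_basis(spec, years).shape[1]
    if p_trend:
        tc = np.zeros(p_trend)
        tc[0] = params.get("trend_slope", config.trend_slope)
        st.trend_coefs = tc
        params["trend_coefs"] = tc

    if spec.variant == "model1":
        tau_a = params.setdefault("tau_area", 4.0)
        tau_e = params.setdefault("tau_eta", 4.0)
        st.log_tau_area = float(np.log(tau_a))
        st.log_tau_eta = float(np.log(tau_e))
        st.alpha_area = rng.normal(0.0, 1.0 / np.sqrt(tau_a), I)
        Qe = gmrf.ar1_precision(T, st.rho_T)
        st.eta_t = gmrf.sample_gmrf(
            gmrf.PrecisionMatrix(tau_e * Qe.Q, 0), rng=rng
        )
    else:
        tau = params.setdefault("tau", 4.0)
        st.log_tau = float(np.log(tau))
        Q_T = gmrf.ar1_precision(T, st.rho_T)
        if spec.variant == "model2":
            Q_S = gmrf.iid_precision(I)
            constraints = None
        elif spec.car_variant == "proper":
            st.rho_S = params.setdefault("rho_S", 0.9)
            Q_S = gmrf.proper_car_precision(graph, st.rho_S)
            constraints = None
        else:
            Q_S = gmrf.icar_precision(graph, island_adjust=True)
            constraints = gmrf.interaction_constraints(
                graph, T, include_islands=False
            )
        Q = gmrf.interaction_precision(Q_T, Q_S, tau)
        omega_flat = gmrf.sample_gmrf(Q, constraints, rng=rng)
        st.omega = omega_flat.reshape(T, I).T

    eta = linear_predictor(spec, st, shell)
    mu = np.exp(eta)
    deaths = rng.poisson(pop * mu).astype(float)
    deaths[pop == 0] = 0.0

    data = PanelData(
        area_ids=graph.area_ids, years=years, deaths=deaths,
        population=pop, covariates=X, urban=urban,
    )
    truth = TruthRecord(
        spec_label=spec.label, params=params, eta=eta, mu=mu, seed=seed_note
    )
    return data, truth


FIXTURE_NAMES = ("tiny", "standard", "sparse_rural")


def make_fixture(name: str, seed: int) -> tuple[PanelData, ArealGraph, TruthRecord]:
    """Named study scenarios.

    * ``tiny`` — 4x4 grid, 6 years, no covariates; unit-test scale.
    * ``standard`` — 10x10 grid, 15 years (the study's span), K=3
      covariates with true effects (0.3, -0.2, 0.1), model-3 truth with
      rho_T=0.7 and tau=4; integration scale.
    * ``sparse_rural`` — like standard but smaller, with a very low
      baseline rate so rural area-years are mostly zero counts.
    """
    rng = np.random.default_rng(seed)
    if name == "tiny":
        graph = grid_graph(4, 4)
        config = ScenarioConfig(n_rows=4, n_cols=4, n_years=6, n_covariates=0)
        spec = ModelSpec(variant="model3")
        data, truth = simulate_panel(
            spec, {"tau": 4.0, "rho_T": 0.7}, graph, config, rng, seed_note=seed
        )
    elif name == "standard":
        graph = grid_graph(10, 10)
        config = ScenarioConfig(n_rows=10, n_cols=10, n_years=15, n_covariates=3)
        spec = ModelSpec(variant="model3", include_covariates=True)
        data, truth = simulate_panel(
            spec,
            {"tau": 4.0, "rho_T": 0.7, "beta": np.array([0.3, -0.2, 0.1])},
            graph, config, rng, seed_note=seed,
        )
    elif name == "sparse_rural":
        graph = grid_graph(8, 8)
        config = ScenarioConfig(
            n_rows=8, n_cols=8, n_years=10, n_covariates=0,
            baseline_rate=12e-5, rural_pop_logmean=6.0, rural_pop_logsd=0.6,
            urban_fraction=0.5,
        )
        spec = ModelSpec(variant="model3")
        data, truth = simulate_panel(
            spec, {"tau": 4.0, "rho_T": 0.7}, graph, config, rng, seed_note=seed
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; options: {FIXTURE_NAMES}")
    return data, graph, truth
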