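"""Markov chain Monte Carlo for the spatiotemporal Poisson models.

The sampler is Metropolis-within-Gibbs with two kinds of moves:

* the whole latent Gaussian block (intercept, regression and trend
  coefficients, area/year effects or the space-time interaction field)
  is updated jointly by a preconditioned Langevin (MALA) proposal whose
  curvature matrix is ``Q_prior(theta) + A' diag(Y + 1/2) A`` — the
  prior precision plus a data-based surrogate for the Poisson curvature
  ``N exp(eta) ~ Y + 1/2``.  The preconditioner depends on the
  hyperparameters but never on the latent block itself, so it is
  refactorized (sparse Cholesky) only periodically while the
  Metropolis-Hastings correction — computed with the exact current
  prior precision — keeps the kernel targeting the posterior exactly.
  Sum-to-zero constraints of intrinsic fields are enforced exactly on
  every proposal by conditioning by kriging, with the matching
  correction to the proposal density.
* each log-precision and each transformed correlation parameter moves
  by adaptive random-walk Metropolis.  Precision moves jointly rescale
  their field (a reparametrized walk on the standardized field), which
  removes the strong posterior coupling between a field and its
  precision.

Step sizes adapt only during burn-in (diminishing adaptation) and are
frozen afterwards.  Everything is driven by one seeded Generator, so
runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import gmrf
from .graph import ArealGraph
from .model import (
    LatentState,
    ModelSpec,
    PanelData,
    covariate_design,
    trend_basis,
)

__all__ = ["McmcConfig", "PosteriorDraws", "fit", "summarize", "summarize_samples", "diagnostics"]


@dataclass
class McmcConfig:
    n_iterations: int = 60_000
    n_burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    latent_step: float = 1.0
    hyper_step: float = 0.5
    adapt: bool = True

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of every model quantity."""

    spec: ModelSpec
    data: PanelData
    graph: ArealGraph
    config: McmcConfig
    scalars: pd.DataFrame                 # one column per scalar quantity
    fields: dict[str, np.ndarray]         # name -> (n_draws, ...) arrays
    acceptance: dict[str, float]

    @property
    def n_draws(self) -> int:
        return len(self.scalars)

    def states(self):
        """Iterate draws as LatentState objects."""
        for d in range(self.n_draws):
            yield self.state(d)

    def state(self, d: int) -> LatentState:
        row = self.scalars.iloc[d]
        st = LatentState(alpha=row["alpha"])
        st.rho_T = row.get("rho_T", 0.0)
        if "rho_S" in row:
            st.rho_S = row["rho_S"]
        for name in ("log_tau", "log_tau_area", "log_tau_eta"):
            if name in row:
                setattr(st, name, row[name])
        for name in ("beta", "trend_coefs", "alpha_area", "eta_t"):
            if name in self.fields:
                setattr(st, name, self.fields[name][d])
        if "omega" in self.fields:
            st.omega = self.fields["omega"][d]
        return st

    def rate_draws(self) -> np.ndarray:
        """Posterior draws of mu_it = exp(eta_it); shape (n_draws, I, T)."""
        from .model import linear_predictor

        out = np.empty((self.n_draws, self.data.n_areas, self.data.n_years))
        for d, st in enumerate(self.states()):
            out[d] = np.exp(linear_predictor(self.spec, st, self.data))
        return out


# ---------------------------------------------------------------------------


# numerical guard keeping tanh/atanh round-trips away from +-1
_RHO_MAX = 1.0 - 1e-9


from functools import lru_cache


@lru_cache(maxsize=512)
def _ar1_dense(T: int, rho: float) -> np.ndarray:
    """Dense unit-marginal AR(1) precision (cached; T is small)."""
    return gmrf.ar1_precision(T, rho).Q.toarray()


@lru_cache(maxsize=512)
def _ar1_chol(T: int, rho: float) -> np.ndarray:
    """Dense lower Cholesky of the unit-marginal AR(1) precision."""
    return np.linalg.cholesky(_ar1_dense(T, rho))


def _ar1_logdet(T: int, rho: float) -> float:
    # |correlation| = (1-rho^2)^(T-1); precision is its inverse
    return -(T - 1) * np.log1p(-rho * rho)


class _LatentStructure:
    """Per-variant bookkeeping: design map, prior blocks, constraints."""

    def __init__(self, spec: ModelSpec, data: PanelData, graph: ArealGraph):
        self.spec, self.data, self.graph = spec, data, graph
        I, T = data.n_areas, data.n_years
        self.I, self.T = I, T
        n = I * T
        B = trend_basis(spec, data.years)            # (T, p)
        X = covariate_design(spec, data)             # (n, nb)
        self.p_trend, self.nb = B.shape[1], X.shape[1]
        cols = [np.ones((n, 1))]
        if self.p_trend:
            cols.append(np.repeat(B, I, axis=0))     # area-fastest
        if self.nb:
            cols.append(X)
        F = np.column_stack(cols)                    # fixed-effect design
        self.n_fixed = F.shape[1]
        if spec.variant == "model1":
            A_area = sp.kron(np.ones((T, 1)), sp.eye(I))
            A_year = sp.kron(sp.eye(T), np.ones((I, 1)))
            self.A = sp.hstack([sp.csc_matrix(F), A_area, A_year], format="csc")
            self.slices = {
                "fixed": slice(0, self.n_fixed),
                "alpha_area": slice(self.n_fixed, self.n_fixed + I),
                "eta_t": slice(self.n_fixed + I, self.n_fixed + I + T),
            }
            self.dim = self.n_fixed + I + T
        else:
            self.A = sp.hstack([sp.csc_matrix(F), sp.eye(n)], format="csc")
            self.slices = {
                "fixed": slice(0, self.n_fixed),
                "omega": slice(self.n_fixed, self.n_fixed + n),
            }
            self.dim = self.n_fixed + n
        self.A = self.A.tocsr()
        self.At = self.A.T.tocsr()
        self.A_blocks = {k: self.A[:, sl].tocsr() for k, sl in self.slices.items()}

        # spatial factor eigen-structure (fixed unless proper CAR)
        if spec.variant == "model3":
            if spec.car_variant == "intrinsic":
                QS = gmrf.icar_precision(graph, island_adjust=True)
                w, V = np.linalg.eigh(QS.Q.toarray())
                w[np.abs(w) < 1e-10] = 0.0
                self.QS = QS
                self.S_eigvals, self.S_eigvecs = w, V
                self.S_def = QS.rank_deficiency
            else:
                d = graph.neighbor_counts.astype(float)
                d[graph.island_mask] = 1.0
                M = sp.diags(1 / np.sqrt(d)) @ graph.adjacency @ sp.diags(1 / np.sqrt(d))
                gam, Vm = np.linalg.eigh(M.toarray())
                self._car_d, self._car_gam, self._car_V = d, gam, Vm
                self.S_def = 0
        elif spec.variant == "model2":
            self.QS = gmrf.iid_precision(I)
            self.S_eigvals = np.ones(I)
            self.S_eigvecs = np.eye(I)
            self.S_def = 0

        # constraints on the latent vector (model 3 intrinsic only)
        if spec.variant == "model3" and spec.car_variant == "intrinsic":
            cs = gmrf.interaction_constraints(graph, T, include_islands=False)
            k = cs.n_constraints
            Acon = np.zeros((k, self.dim))
            Acon[:, self.slices["omega"]] = cs.A
            self.Acon = Acon
        else:
            self.Acon = np.zeros((0, self.dim))

    # ---- spatial factor pieces, possibly rho_S dependent ----

    def spatial_Q(self, st: LatentState) -> sp.csc_matrix:
        if self.spec.variant == "model3" and self.spec.car_variant == "proper":
            return gmrf.proper_car_precision(self.graph, st.rho_S).Q
        return self.QS.Q

    def spatial_sqrt(self, st: LatentState) -> np.ndarray:
        """Dense B with B B' = Q_S (zero modes excluded for intrinsic)."""
        if self.spec.variant == "model3" and self.spec.car_variant == "proper":
            d, gam, V = self._car_d, self._car_gam, self._car_V
            return (np.sqrt(d)[:, None] * V) * np.sqrt(1 - st.rho_S * gam)
        if not hasattr(self, "_BS_fixed"):
            self._BS_fixed = self.S_eigvecs * np.sqrt(self.S_eigvals)
        return self._BS_fixed

    def spatial_logdet(self, st: LatentState) -> float:
        """Generalized log-determinant of Q_S."""
        if self.spec.variant == "model3" and self.spec.car_variant == "proper":
            d, gam = self._car_d, self._car_gam
            return float(np.sum(np.log(d)) + np.sum(np.log1p(-st.rho_S * gam)))
        w = self.S_eigvals
        return float(np.sum(np.log(w[w > 0])))

    # ---- prior precision over the full latent vector ----

    def prior_precision(self, st: LatentState) -> sp.csc_matrix:
        sd = self.spec.priors.fixed_effect_sd
        blocks = [sp.diags(np.full(self.n_fixed, 1.0 / sd**2))]
        if self.spec.variant == "model1":
            blocks.append(np.exp(st.log_tau_area) * sp.eye(self.I))
            QT = sp.csc_matrix(_ar1_dense(self.T, st.rho_T))
            blocks.append(np.exp(st.log_tau_eta) * QT)
        else:
            QT = sp.csc_matrix(_ar1_dense(self.T, st.rho_T))
            blocks.append(np.exp(st.log_tau) * sp.kron(QT, self.spatial_Q(st)))
        return sp.block_diag(blocks, format="csc")

    def sample_prior_noise(self, st: LatentState, rng: np.random.Generator) -> np.ndarray:
        """delta ~ N(0, Q_prior) — *precision as covariance* (for the
        Papandreou-Yuille perturbation used in proposal sampling)."""
        out = np.empty(self.dim)
        sd = self.spec.priors.fixed_effect_sd
        out[self.slices["fixed"]] = rng.standard_normal(self.n_fixed) / sd
        if self.spec.variant == "model1":
            out[self.slices["alpha_area"]] = (
                np.sqrt(np.exp(st.log_tau_area)) * rng.standard_normal(self.I)
            )
            L = _ar1_chol(self.T, st.rho_T)
            out[self.slices["eta_t"]] = (
                np.sqrt(np.exp(st.log_tau_eta)) * (L @ rng.standard_normal(self.T))
            )
        else:
            LT = _ar1_chol(self.T, st.rho_T)           # T x T, Q_T = LT LT'
            BS = self.spatial_sqrt(st)                 # I x I, Q_S = BS BS'
            Z = rng.standard_normal((self.I, self.T))
            M = BS @ Z @ LT.T                          # I x T
            out[self.slices["omega"]] = np.sqrt(np.exp(st.log_tau)) * M.T.ravel()
        return out

    # ---- pack/unpack latent state <-> vector ----

    def pack(self, st: LatentState) -> np.ndarray:
        u = np.empty(self.dim)
        fixed = [st.alpha]
        if self.p_trend:
            fixed += list(st.trend_coefs)
        if self.nb:
            fixed += list(st.beta)
        u[self.slices["fixed"]] = fixed
        if self.spec.variant == "model1":
            u[self.slices["alpha_area"]] = st.alpha_area
            u[self.slices["eta_t"]] = st.eta_t
        else:
            u[self.slices["omega"]] = st.omega.T.ravel()
        return u

    def unpack(self, u: np.ndarray, st: LatentState) -> None:
        fx = u[self.slices["fixed"]]
        st.alpha = float(fx[0])
        pos = 1
        if self.p_trend:
            st.trend_coefs = fx[pos:pos + self.p_trend].copy()
            pos += self.p_trend
        if self.nb:
            st.beta = fx[pos:pos + self.nb].copy()
        if self.spec.variant == "model1":
            st.alpha_area = u[self.slices["alpha_area"]].copy()
            st.eta_t = u[self.slices["eta_t"]].copy()
        else:
            st.omega = u[self.slices["omega"]].reshape(self.T, self.I).T.copy()


class _StepSize:
    """Robbins-Monro step-size adaptation on the log scale."""

    def __init__(self, step: float, target: float):
        self.log_step = np.log(step)
        self.target = target
        self.k = 0
        self.accepted = 0
        self.proposed = 0

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))

    def update(self, accepted: bool, adapting: bool) -> None:
        self.proposed += 1
        self.accepted += int(accepted)
        if adapting:
            self.k += 1
            gamma = self.k ** -0.6
            self.log_step += gamma * (float(accepted) - self.target)

    @property
    def rate(self) -> float:
        return self.accepted / max(self.proposed, 1)


def _initial_state(spec: ModelSpec, lat: _LatentStructure, data: PanelData) -> LatentState:
    total_y, total_n = data.deaths.sum(), data.population.sum()
    st = LatentState(alpha=float(np.log((total_y + 0.5) / total_n)))
    if lat.p_trend:
        st.trend_coefs = np.zeros(lat.p_trend)
    if lat.nb:
        st.beta = np.zeros(lat.nb)
    if spec.variant == "model1":
        st.alpha_area = np.zeros(data.n_areas)
        st.eta_t = np.zeros(data.n_years)
    else:
        st.omega = np.zeros((data.n_areas, data.n_years))
    return st


def fit(
    spec: ModelSpec,
    data: PanelData,
    graph: ArealGraph,
    config: McmcConfig,
) -> PosteriorDraws:
    """Sample the posterior of ``spec`` on ``data``/``graph``."""
    if data.n_areas != graph.n_areas or data.area_ids != graph.area_ids:
        raise ValueError("panel and graph areas do not match")
    rng = np.random.default_rng(config.seed)
    lat = _LatentStructure(spec, data, graph)
    st = _initial_state(spec, lat, data)

    I, T = data.n_areas, data.n_years
    y = data.deaths.T.ravel()            # area-fastest cells
    nvec = data.population.T.ravel()
    mask = nvec > 0
    logn = np.where(mask, np.log(np.where(mask, nvec, 1.0)), 0.0)

    # fixed Poisson-curvature surrogate for the preconditioner
    chat = np.where(mask, y + 0.5, 0.0)
    Ct = (lat.At @ sp.diags(chat) @ lat.A).tocsc()

    u = lat.pack(st)
    k_con = lat.Acon.shape[0]

    def loglik_of(eta_cells: np.ndarray) -> float:
        lam = nvec[mask] * np.exp(eta_cells[mask])
        return float(np.sum(y[mask] * (logn[mask] + eta_cells[mask]) - lam))

    def grad_data(eta_cells: np.ndarray) -> np.ndarray:
        r = np.where(mask, y - nvec * np.exp(eta_cells), 0.0)
        return lat.At @ r

    # --- two theta-dependent objects, with different update cadences ---
    # Qu_cur: the *target* prior precision; must always match the current
    #   hyperparameters (cheap sparse assembly, rebuilt on acceptance).
    # cache:  the proposal preconditioner P = Qu(theta_ref) + C and its
    #   factorization; an *adapted* quantity, refreshed periodically
    #   during burn-in and frozen afterwards (the MH correction uses
    #   Qu_cur, so the kernel stays exact for any reference).
    cache: dict = {}
    Qu_cur = lat.prior_precision(st)

    def refresh(st_ref: LatentState) -> None:
        # Any fixed PD preconditioner keeps the kernel exact, so on
        # numerical failure (e.g. rho_T transiting near +-1 during
        # burn-in) jitter the diagonal, or keep the previous one.
        Qref = lat.prior_precision(st_ref)
        base = (Qref + Ct).tocsc()
        scale = float(np.max(base.diagonal()))
        for jitter in (0.0, 1e-10, 1e-6, 1e-3):
            P = base if jitter == 0.0 else (base + jitter * scale * sp.eye(lat.dim)).tocsc()
            try:
                chol = gmrf.SparseCholesky(P)
            except np.linalg.LinAlgError:
                continue
            cache.update(P=P, chol=chol, ref=st_ref.copy(),
                         jitter_sd=float(np.sqrt(jitter * scale)))
            if k_con:
                V = chol.solve(lat.Acon.T)
                S = lat.Acon @ V
                cache.update(V=V, S=S)
            return
        if "chol" not in cache:
            raise np.linalg.LinAlgError("preconditioner factorization failed")

    refresh(st)
    refresh_every = 20
    qu_stale = False
    eta_cells = lat.A @ u
    ll = loglik_of(eta_cells)
    if not np.isfinite(ll):
        raise RuntimeError(f"non-finite log-likelihood at initialization: state={st}")

    def prior_quad(uvec: np.ndarray) -> float:
        return float(uvec @ (Qu_cur @ uvec))

    steps = {"latent": _StepSize(config.latent_step, 0.574)}
    hyper_names = []
    if spec.variant == "model1":
        hyper_names = ["tau_area", "tau_eta", "rho_T"]
    else:
        hyper_names = ["tau", "rho_T"]
        if spec.variant == "model3" and spec.car_variant == "proper":
            hyper_names.append("rho_S")
    if T == 1:
        hyper_names = [h for h in hyper_names if h != "rho_T"]
    for h in hyper_names:
        steps[h] = _StepSize(config.hyper_step, 0.44)

    pri = spec.priors

    def gamma_term(log_tau: float) -> float:
        tau = np.exp(log_tau)
        return (pri.precision_shape * log_tau - pri.precision_rate * tau)

    def z_prior(zval: float) -> float:
        return -0.5 * (zval / pri.rho_transform_sd) ** 2

    # generalized logdet of the interaction prior, rho-dependent part only
    def interaction_rho_logdet(rho: float) -> float:
        n_pos = I - lat.S_def
        return n_pos * _ar1_logdet(T, rho)

    def interaction_quad(omega_flat: np.ndarray, rho: float, st: LatentState) -> float:
        QT = _ar1_dense(T, rho)
        Om = omega_flat.reshape(T, I).T              # I x T
        return float(np.sum(Om * (lat.spatial_Q(st) @ Om @ QT.T)))

    # --- storage ---
    scalars: list[dict] = []
    fields: dict[str, list] = {}

    adapting = True
    eps = steps["latent"].step

    sqrt_chat = np.sqrt(chat)

    # latent-only warmup: with the fields still at zero the correlation
    # parameters' conditionals are monotone toward |rho| = 1 (the
    # log-determinant grows while the quadratic form is still 0), so let
    # the fields adapt to the data before hyperparameters start moving
    hyper_start = min(50, config.n_burnin // 2)

    for it in range(config.n_iterations):
        adapting = config.adapt and it < config.n_burnin

        # ---------------- latent block: preconditioned MALA ----------------
        # P may depend on the hyperparameters (they are held fixed during
        # this conditional update) but never on u, so a periodic rebuild
        # from the current theta keeps the kernel exact at amortized cost.
        if it and it % refresh_every == 0:
            refresh(st)
        if qu_stale:
            Qu_cur = lat.prior_precision(st)
            qu_stale = False
        eps = steps["latent"].step
        chol = cache["chol"]
        g = grad_data(eta_cells) - Qu_cur @ u
        # noise with covariance exactly P = Qu(ref) + C (+ jitter I)
        delta = lat.sample_prior_noise(cache["ref"], rng) + lat.At @ (
            sqrt_chat * rng.standard_normal(I * T)
        )
        if cache["jitter_sd"]:
            delta = delta + cache["jitter_sd"] * rng.standard_normal(lat.dim)
        h = chol.solve(np.column_stack([g, delta]))
        h, delta_sol = h[:, 0], h[:, 1]
        xi = eps * delta_sol
        u_raw = u + 0.5 * eps * eps * h + xi
        if k_con:
            resid = lat.Acon @ u_raw
            u_raw = u_raw - cache["V"] @ np.linalg.solve(cache["S"], resid)
        u_star = u_raw
        eta_star = lat.A @ u_star
        ll_star = loglik_of(eta_star)

        g_star = grad_data(eta_star) - Qu_cur @ u_star
        h_star = chol.solve(g_star)
        w_f = u_star - u - 0.5 * eps * eps * h
        w_r = u - u_star - 0.5 * eps * eps * h_star
        P = cache["P"]
        qf = float(w_f @ (P @ w_f))
        qr = float(w_r @ (P @ w_r))
        corr = 0.0
        if k_con:
            mA = 0.5 * eps * eps * (lat.Acon @ h)
            mA_star = 0.5 * eps * eps * (lat.Acon @ h_star)
            Sm = cache["S"]
            corr = 0.5 / (eps * eps) * (
                float(mA_star @ np.linalg.solve(Sm, mA_star))
                - float(mA @ np.linalg.solve(Sm, mA))
            )
        log_alpha = (
            (ll_star - 0.5 * prior_quad(u_star))
            - (ll - 0.5 * prior_quad(u))
            + (qf - qr) / (2 * eps * eps)
            + corr
        )
        accept = np.log(rng.uniform()) < log_alpha
        if accept:
            u, eta_cells, ll = u_star, eta_star, ll_star
            lat.unpack(u, st)
        steps["latent"].update(bool(accept), adapting)

        # ---------------- hyperparameter moves ----------------
        for name in hyper_names if it >= hyper_start else []:
            s = steps[name].step
            if name in ("tau", "tau_area", "tau_eta"):
                attr = {"tau": "log_tau", "tau_area": "log_tau_area",
                        "tau_eta": "log_tau_eta"}[name]
                sl = {"tau": "omega", "tau_area": "alpha_area",
                      "tau_eta": "eta_t"}[name]
                phi = getattr(st, attr)
                phi_star = phi + s * rng.standard_normal()
                scale = np.exp(-(phi_star - phi) / 2.0)
                sub = lat.slices[sl]
                u_try = u.copy()
                u_try[sub] = u[sub] * scale
                eta_try = eta_cells + lat.A_blocks[sl] @ (u_try[sub] - u[sub])
                ll_try = loglik_of(eta_try)
                la = (ll_try - ll) + (gamma_term(phi_star) - gamma_term(phi))
                ok = np.log(rng.uniform()) < la
                if ok:
                    u, eta_cells, ll = u_try, eta_try, ll_try
                    setattr(st, attr, float(phi_star))
                    lat.unpack(u, st)
                    qu_stale = True
                steps[name].update(bool(ok), adapting)
            elif name == "rho_T":
                z = np.arctanh(st.rho_T)
                z_star = z + s * rng.standard_normal()
                rho_star = float(np.clip(np.tanh(z_star), -_RHO_MAX, _RHO_MAX))
                if spec.variant == "model1":
                    tau_e = np.exp(st.log_tau_eta)
                    quad_old = float(st.eta_t @ (_ar1_dense(T, st.rho_T) @ st.eta_t))
                    quad_new = float(st.eta_t @ (_ar1_dense(T, rho_star) @ st.eta_t))
                    la = (
                        0.5 * (_ar1_logdet(T, rho_star) - _ar1_logdet(T, st.rho_T))
                        - 0.5 * tau_e * (quad_new - quad_old)
                        + z_prior(z_star) - z_prior(z)
                    )
                else:
                    tau = np.exp(st.log_tau)
                    om = u[lat.slices["omega"]]
                    quad_old = interaction_quad(om, st.rho_T, st)
                    quad_new = interaction_quad(om, rho_star, st)
                    la = (
                        0.5 * (interaction_rho_logdet(rho_star)
                               - interaction_rho_logdet(st.rho_T))
                        - 0.5 * tau * (quad_new - quad_old)
                        + z_prior(z_star) - z_prior(z)
                    )
                ok = np.log(rng.uniform()) < la
                if ok:
                    st.rho_T = float(rho_star)
                    qu_stale = True
                steps[name].update(bool(ok), adapting)
            elif name == "rho_S":
                zs = np.log(st.rho_S / (1 - st.rho_S))
                zs_star = zs + s * rng.standard_normal()
                rs_star = 1.0 / (1.0 + np.exp(-zs_star))
                tau = np.exp(st.log_tau)
                om = u[lat.slices["omega"]]
                st_try = st.copy()
                st_try.rho_S = float(rs_star)
                quad_old = interaction_quad(om, st.rho_T, st)
                quad_new = interaction_quad(om, st.rho_T, st_try)
                la = (
                    0.5 * T * (lat.spatial_logdet(st_try) - lat.spatial_logdet(st))
                    - 0.5 * tau * (quad_new - quad_old)
                    + z_prior(zs_star) - z_prior(zs)
                )
                ok = np.log(rng.uniform()) < la
                if ok:
                    st.rho_S = float(rs_star)
                    qu_stale = True
                steps[name].update(bool(ok), adapting)

        # ---------------- storage ----------------
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            row = {"alpha": st.alpha, "rho_T": st.rho_T}
            if spec.variant == "model1":
                row["log_tau_area"] = st.log_tau_area
                row["log_tau_eta"] = st.log_tau_eta
                row["tau_area"] = np.exp(st.log_tau_area)
                row["tau_eta"] = np.exp(st.log_tau_eta)
            else:
                row["log_tau"] = st.log_tau
                row["tau"] = np.exp(st.log_tau)
                if spec.variant == "model3" and spec.car_variant == "proper":
                    row["rho_S"] = st.rho_S
            scalars.append(row)
            for fname in ("beta", "trend_coefs", "alpha_area", "eta_t", "omega"):
                val = getattr(st, fname)
                if val is not None and np.size(val):
                    fields.setdefault(fname, []).append(np.array(val))

    return PosteriorDraws(
        spec=spec,
        data=data,
        graph=graph,
        config=config,
        scalars=pd.DataFrame(scalars),
        fields={k: np.array(v) for k, v in fields.items()},
        acceptance={k: v.rate for k, v in steps.items()},
    )


# ---------------------------------------------------------------------------
# Summaries and diagnostics


def summarize_samples(x: np.ndarray, level: float = 0.90) -> dict[str, float]:
    """Median and equal-tail interval of a sample vector."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return {
        "median": float(np.median(x)),
        "lo": float(np.quantile(x, lo)),
        "hi": float(np.quantile(x, hi)),
    }


def summarize(draws: PosteriorDraws, level: float = 0.90) -> pd.DataFrame:
    """Posterior median and equal-tail credible interval per scalar.

    Covers the intercept, hyperparameters, and each regression/trend
    coefficient.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws")
    rows = {}
    for col in draws.scalars.columns:
        rows[col] = summarize_samples(draws.scalars[col].to_numpy(), level)
    for fname in ("beta", "trend_coefs"):
        if fname in draws.fields:
            arr = draws.fields[fname]
            for k in range(arr.shape[1]):
                rows[f"{fname}[{k}]"] = summarize_samples(arr[:, k], level)
    return pd.DataFrame(rows).T


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-chain ESS and R-hat for each scalar quantity (via ArviZ)."""
    import warnings

    import arviz as az

    if draws.n_draws < 100:
        raise ValueError("need at least 100 draws for diagnostics")
    rows = {}
    for col in draws.scalars.columns:
        x = draws.scalars[col].to_numpy()
        if np.ptp(x) == 0:
            rows[col] = {"ess": float("nan"), "rhat": float("nan"), "degenerate": True}
            continue
        half = len(x) // 2
        chains = np.stack([x[:half], x[half:2 * half]])  # (chain, draw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(chains)
            ess = float(az.ess(ds)["x"].values.item())
            rhat = float(az.rhat(ds)["x"].values.item())
        rows[col] = {"ess": ess, "rhat": rhat, "degenerate": False}
    out = pd.DataFrame(rows).T
    bad = out[(~out["degenerate"].astype(bool)) & (out["rhat"] > 1.05)]
    if len(bad):
        import logging

        logging.getLogger(__name__).warning(
            "R-hat > 1.05 for: %s", ", ".join(bad.index)
        )
    return out
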