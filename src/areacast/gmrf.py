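"""Sparse Gaussian Markov random field building blocks.

The latent fields of the mortality models are zero-mean Gaussians
specified by sparse precision matrices: a stationary AR(1) in time, an
(intrinsic) conditional autoregressive field in space, and their scaled
Kronecker-product interaction tau * (Q_T (x) Q_S).  Intrinsic fields are
rank deficient; their densities are generalized (product of nonzero
eigenvalues) and their samples are pinned down by sum-to-zero linear
constraints enforced exactly by conditioning by kriging.

Vectorization convention: a space-time field stacks *areas fastest,
years slowest*, i.e. entry ``t * I + i`` is (area i, year t), so the
joint precision is exactly ``Q_T (x) Q_S`` in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .graph import ArealGraph

__all__ = [
    "PrecisionMatrix",
    "ConstraintSet",
    "SparseCholesky",
    "ar1_precision",
    "iid_precision",
    "icar_precision",
    "proper_car_precision",
    "interaction_precision",
    "interaction_constraints",
    "gmrf_logdensity",
    "sample_gmrf",
    "write_precision",
    "read_precision",
]

_PSD_TOL = -1e-8
_EIG_ZERO_TOL = 1e-8


@dataclass
class PrecisionMatrix:
    """Sparse symmetric PSD precision with its known rank deficiency."""

    Q: sp.csc_matrix
    rank_deficiency: int = 0
    scale_note: str = ""

    def __post_init__(self) -> None:
        self.Q = sp.csc_matrix(self.Q)

    @property
    def dim(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.dim - self.rank_deficiency


@dataclass
class ConstraintSet:
    """Linear constraints ``A x = e`` (here always e = 0)."""

    A: np.ndarray
    e: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.e is None:
            self.e = np.zeros(self.A.shape[0])

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]


class SparseCholesky:
    """Cholesky-style factorization of a sparse SPD matrix.

    Backed by SuperLU in symmetric mode (no numerical pivoting, symmetric
    fill-reducing permutation), so that ``P Q P' = L D L'`` with positive
    D; this gives exact log-determinants, solves, and N(0, Q^{-1})
    sampling without a dedicated sparse-Cholesky library.
    """

    def __init__(self, Q: sp.spmatrix):
        Q = sp.csc_matrix(Q)
        self._n = Q.shape[0]
        self._lu = splu(
            Q,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options=dict(SymmetricMode=True),
        )
        self._d = self._lu.U.diagonal()
        if np.any(self._d <= 0):
            raise np.linalg.LinAlgError("matrix is not positive definite")
        self._perm = self._lu.perm_r
        self._L = None

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._d)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._lu.solve(np.asarray(b, dtype=float))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw from N(0, Q^{-1}) via the triangular factor."""
        from scipy.sparse.linalg import spsolve_triangular

        if self._L is None:
            C = self._lu.L @ sp.diags(np.sqrt(self._d))
            self._L = sp.csr_matrix(C.T)
        m = 1 if size is None else size
        z = rng.standard_normal((self._n, m))
        y = spsolve_triangular(self._L, z, lower=False)
        # y lives in permuted coordinates: x = P' y  <=>  x[i] = y[perm[i]]
        x = y[self._perm]
        return x[:, 0] if size is None else x.T


def ar1_precision(T: int, rho: float) -> PrecisionMatrix:
    """Precision of a stationary AR(1) with unit marginal variance.

    The inverse is the correlation matrix with entries ``rho**|i-j|``.
    Tridiagonal; full rank for |rho| < 1.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if abs(rho) >= 1:
        raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
    if T == 1:
        Q = sp.csc_matrix(np.array([[1.0]]))
        return PrecisionMatrix(Q, 0, scale_note="ar1 unit-marginal-variance")
    diag = np.full(T, 1.0 + rho * rho)
    diag[0] = diag[-1] = 1.0
    off = np.full(T - 1, -rho)
    Q = sp.diags([off, diag, off], [-1, 0, 1], format="csc") / (1.0 - rho * rho)
    return PrecisionMatrix(sp.csc_matrix(Q), 0, scale_note="ar1 unit-marginal-variance")


def iid_precision(I: int) -> PrecisionMatrix:
    """Identity precision: exchangeable unit-variance areas."""
    if I < 1:
        raise ValueError("I must be >= 1")
    return PrecisionMatrix(sp.eye(I, format="csc"), 0, scale_note="iid")


def icar_precision(graph: ArealGraph, island_adjust: bool = False) -> PrecisionMatrix:
    """Intrinsic CAR (Besag) precision Q = D - W.

    Rank deficiency equals the number of connected components (islands
    count as singleton components).  With ``island_adjust=True`` islands
    get a unit diagonal entry instead — their block becomes a proper
    standard normal and drops out of the deficiency — the convention the
    model code uses on maps with no-neighbour areas.
    """
    if graph.n_areas == 0:
        raise ValueError("graph is empty")
    W = graph.adjacency
    D = sp.diags(graph.neighbor_counts.astype(float))
    Q = (D - W).tocsc()
    deficiency = graph.n_components
    note = "icar"
    if island_adjust and graph.n_islands:
        fix = np.where(graph.island_mask, 1.0, 0.0)
        Q = (Q + sp.diags(fix)).tocsc()
        deficiency -= graph.n_islands
        note = "icar island-adjusted"
    return PrecisionMatrix(Q, deficiency, scale_note=note)


def proper_car_precision(graph: ArealGraph, rho_s: float) -> PrecisionMatrix:
    """Proper CAR precision Q = D - rho_s W (full rank for rho_s < 1).

    Islands (D_ii = 0) receive a unit diagonal entry.
    """
    if graph.n_areas == 0:
        raise ValueError("graph is empty")
    if not (0.0 <= rho_s < 1.0):
        raise ValueError("rho_s must lie in [0, 1)")
    W = graph.adjacency
    d = graph.neighbor_counts.astype(float)
    d[graph.island_mask] = 1.0
    Q = (sp.diags(d) - rho_s * W).tocsc()
    return PrecisionMatrix(Q, 0, scale_note="proper-car")


def interaction_precision(
    Q_T: PrecisionMatrix, Q_S: PrecisionMatrix, tau: float
) -> PrecisionMatrix:
    """Separable space-time interaction precision tau * (Q_T (x) Q_S).

    With the area-fastest stacking convention the Kronecker order is
    temporal factor first.  Zero eigenvalues multiply, so the deficiency
    is ``T*d_S + d_T*I - d_T*d_S``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    T, I = Q_T.dim, Q_S.dim
    d_T, d_S = Q_T.rank_deficiency, Q_S.rank_deficiency
    Q = (tau * sp.kron(Q_T.Q, Q_S.Q, format="csc")).tocsc()
    deficiency = T * d_S + d_T * I - d_T * d_S
    return PrecisionMatrix(Q, deficiency, scale_note=f"tau*({Q_T.scale_note})x({Q_S.scale_note})")


def interaction_constraints(
    graph: ArealGraph, T: int, include_islands: bool = True
) -> ConstraintSet:
    """Sum-to-zero over areas within each component, at each time point.

    One row per (time, connected component): removes exactly the null
    space of an AR(1) (x) ICAR interaction.  With
    ``include_islands=False`` singleton components are skipped, matching
    the island-adjusted ICAR.
    """
    I = graph.n_areas
    labels = graph.component_labels
    comps = []
    for c in range(graph.n_components):
        members = np.flatnonzero(labels == c)
        if not include_islands and members.size == 1 and graph.island_mask[members[0]]:
            continue
        comps.append(members)
    rows = []
    for t in range(T):
        for members in comps:
            row = np.zeros(T * I)
            row[t * I + members] = 1.0
            rows.append(row)
    A = np.array(rows) if rows else np.zeros((0, T * I))
    return ConstraintSet(A=A)


def _generalized_logdet(Qm: PrecisionMatrix) -> float:
    """Log product of the nonzero eigenvalues (cached on the object)."""
    cached = getattr(Qm, "_gen_logdet", None)
    if cached is not None:
        return cached
    if Qm.rank_deficiency == 0:
        val = SparseCholesky(Qm.Q).logdet
    else:
        w = np.linalg.eigvalsh(Qm.Q.toarray())
        if w.min() < _PSD_TOL * max(1.0, abs(w.max())):
            raise np.linalg.LinAlgError("precision is not positive semidefinite")
        nonzero = np.sort(w)[Qm.rank_deficiency:]
        val = float(np.sum(np.log(nonzero)))
    Qm._gen_logdet = val  # type: ignore[attr-defined]
    return val


def gmrf_logdensity(x: np.ndarray, Qm: PrecisionMatrix) -> float:
    """(Generalized) log-density of a zero-mean GMRF at x.

    ``-r/2 log(2 pi) + 1/2 log|Q|_+ - 1/2 x' Q x`` with r = rank(Q) and
    |Q|_+ the product of nonzero eigenvalues.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (Qm.dim,):
        raise ValueError(f"x has shape {x.shape}, expected ({Qm.dim},)")
    quad = float(x @ (Qm.Q @ x))
    r = Qm.rank
    return -0.5 * r * np.log(2.0 * np.pi) + 0.5 * _generalized_logdet(Qm) - 0.5 * quad


def sample_gmrf(
    Qm: PrecisionMatrix,
    constraints: ConstraintSet | None = None,
    rng: np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw from N(0, Q^{-1}), optionally under exact linear constraints.

    Full-rank Q: sparse Cholesky draw, then (if constraints are given)
    conditioning by kriging.  Rank-deficient Q requires constraints that
    span the null space; the proper completion ``Q + A'A`` is sampled and
    kriging projects onto {A x = 0}, which leaves the distribution on the
    constraint subspace unchanged.
    """
    if rng is None:
        rng = np.random.default_rng()
    Q = Qm.Q
    if Qm.rank_deficiency > 0:
        if constraints is None or constraints.n_constraints < Qm.rank_deficiency:
            raise ValueError(
                "rank-deficient precision needs constraints spanning its null space"
            )
        A = constraints.A
        Q = (Q + sp.csc_matrix(A.T @ A)).tocsc()
    chol = SparseCholesky(Q)
    m = 1 if size is None else size
    x = chol.sample(rng, size=m)  # (m, n)
    if constraints is not None and constraints.n_constraints > 0:
        A = constraints.A
        V = chol.solve(A.T)  # n x k
        S = A @ V
        resid = x @ A.T - constraints.e  # (m, k)
        x = x - resid @ np.linalg.solve(S, V.T)
    return x[0] if size is None else x


# ---------------------------------------------------------------------------
# Serialization: sparse coordinate text with a small header


def write_precision(Qm: PrecisionMatrix, path: str | Path) -> None:
    coo = Qm.Q.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# dim {Qm.dim}\n")
        fh.write(f"# rank_deficiency {Qm.rank_deficiency}\n")
        fh.write(f"# scale_note {Qm.scale_note}\n")
        fh.write("# vectorization area-fastest\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {float(v)!r}\n")


def read_precision(path: str | Path) -> PrecisionMatrix:
    dim = deficiency = None
    note = ""
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["dim"]:
                    dim = int(parts[1])
                elif parts[:1] == ["rank_deficiency"]:
                    deficiency = int(parts[1])
                elif parts[:1] == ["scale_note"]:
                    note = " ".join(parts[1:])
                continue
            i, j, v = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    if dim is None or deficiency is None:
        raise ValueError("missing header in precision file")
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsc()
    return PrecisionMatrix(Q, deficiency, scale_note=note)
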