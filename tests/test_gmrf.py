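"""Precision-matrix constructors, generalized densities, constrained sampling.

Every structure is cross-checked on small instances against dense
linear-algebra oracles (explicit inverses, eigendecompositions,
Cholesky-of-covariance sampling).
"""

import numpy as np
import pytest
import scipy.sparse as sp

from areacast import gmrf
from areacast.graph import build_graph_from_edgelist, grid_graph


def dense_generalized_logpdf(x, Q, deficiency):
    """Oracle: generalized Gaussian log-density via eigendecomposition."""
    w, V = np.linalg.eigh(Q)
    w_pos = np.sort(w)[deficiency:]
    r = len(w_pos)
    quad = x @ Q @ x
    return -0.5 * r * np.log(2 * np.pi) + 0.5 * np.sum(np.log(w_pos)) - 0.5 * quad


class TestAr1:
    def test_rho_zero_is_identity(self):
        Q = gmrf.ar1_precision(3, 0.0)
        assert np.allclose(Q.Q.toarray(), np.eye(3))

    def test_single_time_point(self):
        assert np.allclose(gmrf.ar1_precision(1, 0.9).Q.toarray(), [[1.0]])

    @pytest.mark.parametrize("T,rho", [(3, 0.5), (5, -0.7), (10, 0.9), (7, 0.3)])
    def test_inverse_is_stationary_correlation(self, T, rho):
        Q = gmrf.ar1_precision(T, rho).Q.toarray()
        corr = rho ** np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        assert np.allclose(Q, np.linalg.inv(corr), atol=1e-10)

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            gmrf.ar1_precision(3, 1.0)


class TestIidAndCar:
    def test_iid_identity(self):
        assert np.allclose(gmrf.iid_precision(4).Q.toarray(), np.eye(4))
        assert np.allclose(gmrf.iid_precision(1).Q.toarray(), [[1.0]])
        assert gmrf.iid_precision(7).Q.diagonal().sum() == 7

    def test_icar_path(self, path_graph):
        Q = gmrf.icar_precision(path_graph)
        expected = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        assert np.allclose(Q.Q.toarray(), expected)
        assert Q.rank_deficiency == 1

    def test_icar_disconnected_zero_matrix(self):
        g = build_graph_from_edgelist(["a", "b", "c"], [])
        Q = gmrf.icar_precision(g)
        assert Q.Q.nnz == 0
        assert Q.rank_deficiency == 3

    def test_icar_rows_sum_to_zero(self):
        g = grid_graph(4, 4)
        Q = gmrf.icar_precision(g)
        assert np.allclose(np.asarray(Q.Q.sum(axis=1)).ravel(), 0.0)

    def test_icar_rank_deficiency_matches_components(self):
        # cross-module invariant, checked by dense eigenvalue count
        g = build_graph_from_edgelist(
            ["a", "b", "c", "d", "e"], [("a", "b"), ("c", "d")]
        )
        Q = gmrf.icar_precision(g)
        w = np.linalg.eigvalsh(Q.Q.toarray())
        assert int(np.sum(np.abs(w) < 1e-10)) == g.n_components == Q.rank_deficiency

    def test_icar_island_adjustment(self):
        g = build_graph_from_edgelist(["a", "b", "c"], [("a", "b")])
        Q = gmrf.icar_precision(g, island_adjust=True)
        assert Q.Q.toarray()[2, 2] == 1.0
        assert Q.rank_deficiency == 1  # only the a-b component stays intrinsic

    def test_proper_car_rho_zero_is_degree_diag(self, path_graph):
        Q = gmrf.proper_car_precision(path_graph, 0.0)
        assert np.allclose(Q.Q.toarray(), np.diag([1.0, 2.0, 1.0]))

    def test_proper_car_limit_recovers_icar(self, path_graph):
        Qp = gmrf.proper_car_precision(path_graph, 0.999999).Q.toarray()
        Qi = gmrf.icar_precision(path_graph).Q.toarray()
        assert np.allclose(Qp, Qi, atol=1e-5)

    def test_proper_car_positive_definite(self, path_graph):
        Q = gmrf.proper_car_precision(path_graph, 0.9)
        assert np.linalg.eigvalsh(Q.Q.toarray()).min() > 0

    def test_proper_car_invalid_rho(self, path_graph):
        with pytest.raises(ValueError):
            gmrf.proper_car_precision(path_graph, 1.0)


class TestInteraction:
    def test_identity_kron_identity(self):
        Q = gmrf.interaction_precision(gmrf.iid_precision(3), gmrf.iid_precision(4), 2.0)
        assert np.allclose(Q.Q.toarray(), 2.0 * np.eye(12))
        assert Q.rank_deficiency == 0

    def test_matches_dense_kron_oracle(self, path_graph):
        QT = gmrf.ar1_precision(2, 0.5)
        QS = gmrf.icar_precision(path_graph)
        Q = gmrf.interaction_precision(QT, QS, 1.7)
        dense = 1.7 * np.kron(QT.Q.toarray(), QS.Q.toarray())
        assert np.allclose(Q.Q.toarray(), dense, atol=1e-12)

    def test_rank_deficiency_eigen_count(self, path_graph):
        T = 4
        QT = gmrf.ar1_precision(T, 0.6)
        QS = gmrf.icar_precision(path_graph)
        Q = gmrf.interaction_precision(QT, QS, 1.0)
        w = np.linalg.eigvalsh(Q.Q.toarray())
        assert Q.rank_deficiency == T
        assert int(np.sum(np.abs(w) < 1e-9)) == T

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            gmrf.interaction_precision(gmrf.iid_precision(2), gmrf.iid_precision(2), 0.0)


class TestInteractionConstraints:
    @pytest.mark.parametrize(
        "edges,n_areas,T,expected_rows",
        [
            ([("a", "b"), ("b", "c")], 3, 3, 3),
            ([("a", "b")], 4, 2, 6),  # component {a,b} + 2 islands, per year
        ],
    )
    def test_row_counts(self, edges, n_areas, T, expected_rows):
        ids = [chr(ord("a") + i) for i in range(n_areas)]
        g = build_graph_from_edgelist(ids, edges)
        cs = gmrf.interaction_constraints(g, T)
        assert cs.n_constraints == T * g.n_components == expected_rows

    def test_rows_match_interaction_deficiency(self, path_graph):
        T = 3
        cs = gmrf.interaction_constraints(path_graph, T)
        Q = gmrf.interaction_precision(
            gmrf.ar1_precision(T, 0.5), gmrf.icar_precision(path_graph), 1.0
        )
        assert cs.n_constraints == Q.rank_deficiency


class TestLogDensity:
    def test_standard_bivariate_at_origin(self):
        Q = gmrf.iid_precision(2)
        assert gmrf.gmrf_logdensity(np.zeros(2), Q) == pytest.approx(-np.log(2 * np.pi))

    def test_scalar_closed_form(self):
        Q = gmrf.PrecisionMatrix(sp.csc_matrix(np.array([[2.0]])), 0)
        expected = -0.5 * np.log(2 * np.pi) + 0.5 * np.log(2.0) - 1.0
        assert gmrf.gmrf_logdensity(np.array([1.0]), Q) == pytest.approx(expected)

    def test_icar_generalized_density_oracle(self, path_graph):
        Q = gmrf.icar_precision(path_graph)
        x = np.array([1.0, 0.0, -1.0])
        expected = dense_generalized_logpdf(x, Q.Q.toarray(), 1)
        assert gmrf.gmrf_logdensity(x, Q) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gmrf.gmrf_logdensity(np.zeros(3), gmrf.iid_precision(2))


class TestSampling:
    def test_identity_sample_covariance(self, rng):
        Q = gmrf.iid_precision(4)
        draws = gmrf.sample_gmrf(Q, rng=rng, size=20_000)
        cov = np.cov(draws.T)
        assert np.abs(cov - np.eye(4)).max() < 0.05

    def test_constrained_draws_sum_to_zero(self, path_graph, rng):
        Q = gmrf.icar_precision(path_graph)
        cs = gmrf.ConstraintSet(A=np.ones((1, 3)))
        draws = gmrf.sample_gmrf(Q, cs, rng=rng, size=200)
        assert np.abs(draws.sum(axis=1)).max() < 1e-10

    def test_deterministic_given_seed(self, path_graph):
        Q = gmrf.icar_precision(path_graph)
        cs = gmrf.ConstraintSet(A=np.ones((1, 3)))
        a = gmrf.sample_gmrf(Q, cs, rng=np.random.default_rng(7), size=5)
        b = gmrf.sample_gmrf(Q, cs, rng=np.random.default_rng(7), size=5)
        assert np.array_equal(a, b)

    def test_semidefinite_without_constraints_rejected(self, path_graph):
        Q = gmrf.icar_precision(path_graph)
        with pytest.raises(ValueError):
            gmrf.sample_gmrf(Q, rng=np.random.default_rng(0))

    def test_constrained_covariance_matches_dense_oracle(self, path_graph, rng):
        # oracle: constrained covariance = pseudoinverse restricted to the
        # sum-to-zero subspace of the intrinsic CAR
        Q = gmrf.icar_precision(path_graph)
        cs = gmrf.ConstraintSet(A=np.ones((1, 3)))
        draws = gmrf.sample_gmrf(Q, cs, rng=rng, size=40_000)
        target = np.linalg.pinv(Q.Q.toarray())
        assert np.abs(np.cov(draws.T) - target).max() < 0.05


def test_precision_roundtrip(tmp_path, path_graph):
    Q = gmrf.icar_precision(path_graph)
    path = tmp_path / "q.txt"
    gmrf.write_precision(Q, path)
    Q2 = gmrf.read_precision(path)
    assert Q2.rank_deficiency == Q.rank_deficiency
    assert np.allclose(Q2.Q.toarray(), Q.Q.toarray())
    assert Q2.scale_note == Q.scale_note
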