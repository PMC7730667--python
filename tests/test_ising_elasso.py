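import numpy as np
import pytest

from symptomnet.data_model import SymptomCodebook
from symptomnet.ising_elasso import (
    ElassoConfig,
    EstimationError,
    IsingNetwork,
    NodewiseFit,
    fit_ising_elasso,
    fit_nodewise,
    nodewise_logistic,
    symmetrize,
)
from symptomnet.synthetic_data import (
    IsingModelSpec,
    enumerate_distribution,
    sample,
)

from conftest import make_codebook


def _directed_fit(node: int, p: int, intercept: float, slopes_full) -> NodewiseFit:
    """NodewiseFit with a single path point, for symmetrize unit tests."""
    slopes = np.asarray(slopes_full, dtype=float)
    other = slopes[np.arange(p) != node]
    return NodewiseFit(
        node=node,
        lambda_path=np.array([0.1]),
        intercepts=np.array([intercept]),
        slopes=other[None, :],
        ebic=np.array([0.0]),
        valid=np.array([True]),
        selected=0,
        n=100,
    )


class TestUnpenalizedOracle:
    """The module's primary correctness anchor: on data weighted by the exact
    Ising distribution, P(x_j=1|x_-j) = logistic(tau_j + sum beta_jk x_k), so
    the unpenalized nodewise regression recovers (tau, beta) exactly."""

    @pytest.mark.parametrize("p,seed", [(2, 0), (3, 1), (4, 2)])
    def test_weighted_state_fit_recovers_parameters(self, p, seed):
        rng = np.random.default_rng(seed)
        beta = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        beta[iu] = rng.uniform(-1, 1, size=len(iu[0]))
        beta = beta + beta.T
        tau = rng.uniform(-1.5, 0.5, size=p)
        spec = IsingModelSpec(tau, beta, make_codebook(p))
        dist = enumerate_distribution(spec)
        states = dist.states()
        for j in range(p):
            b0, slopes = nodewise_logistic(
                states, j, sample_weight=dist.probabilities
            )
            assert b0 == pytest.approx(tau[j], abs=1e-4)
            assert slopes == pytest.approx(beta[j], abs=1e-4)

    def test_two_node_model_with_unit_coupling(self):
        spec = IsingModelSpec(
            np.zeros(2), np.array([[0.0, 1.0], [1.0, 0.0]]), make_codebook(2)
        )
        dist = enumerate_distribution(spec)
        b0, slopes = nodewise_logistic(
            dist.states(), 0, sample_weight=dist.probabilities
        )
        assert b0 == pytest.approx(0.0, abs=1e-6)
        assert slopes[1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_statsmodels_glm_on_random_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(800, 5))
        b0, slopes = nodewise_logistic(X, 2)
        Z = np.delete(X, 2, axis=1).astype(float)
        ref = sm.GLM(
            X[:, 2], sm.add_constant(Z), family=sm.families.Binomial()
        ).fit()
        assert b0 == pytest.approx(ref.params[0], abs=1e-7)
        assert np.delete(slopes, 2) == pytest.approx(ref.params[1:], abs=1e-7)


class TestPenalizedPath:
    def test_objective_not_worse_than_sklearn(self):
        """Independent solver cross-check: at several penalties our penalized
        objective is at least as low as liblinear's."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        n = 2000
        Z = rng.integers(0, 2, size=(n, 4))
        logits = -1 + 1.2 * Z[:, 0] - 0.8 * Z[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        X = np.column_stack([y, Z])
        fit = fit_nodewise(X, 0)

        def objective(b0, b, lam):
            eta = b0 + Z @ b
            return np.mean(np.logaddexp(0, eta) - y * eta) + lam * np.abs(b).sum()

        for l in (10, 40, 70):
            lam = fit.lambda_path[l]
            ref = LogisticRegression(
                l1_ratio=1.0, C=1 / (n * lam), solver="liblinear",
                intercept_scaling=1000.0, tol=1e-10, max_iter=10000,
            ).fit(Z, y)
            mine = objective(fit.intercepts[l], fit.slopes[l], lam)
            theirs = objective(ref.intercept_[0], ref.coef_[0], lam)
            assert mine <= theirs + 1e-8

    def test_path_shape_and_invariants(self, chain_sample):
        fit = fit_nodewise(chain_sample.values, 4)
        lam = fit.lambda_path
        assert (lam > 0).all() and (np.diff(lam) < 0).all()
        assert np.isfinite(fit.ebic[fit.valid]).all()
        nnz = (fit.slopes != 0).sum(axis=1)
        assert nnz[0] == 0  # the intercept-only model heads the path
        assert (np.diff(nnz.astype(int)) >= -1).all()  # near-monotone growth
        assert nnz[-1] >= nnz[fit.selected]

    def test_independence_data_select_empty_neighborhoods(self):
        rng = np.random.default_rng(20934)
        X = rng.integers(0, 2, size=(5000, 9))
        for j in range(9):
            fit = fit_nodewise(X, j)
            assert np.count_nonzero(fit.slopes[fit.selected]) == 0

    def test_pure_threshold_model_recovers_intercept(self):
        # all couplings zero, tau_j = -2: fitted intercept within 3 SE
        p = 9
        spec = IsingModelSpec(np.full(p, -2.0), np.zeros((p, p)), make_codebook(p))
        ds = sample(spec, 50_000, seed=3)
        fit = fit_nodewise(ds.values, 0)
        phat = ds.values[:, 0].mean()
        se = np.sqrt(1 / (ds.n * phat * (1 - phat)))
        assert abs(fit.intercepts[fit.selected] - (-2.0)) < 3 * se

    def test_constant_column_raises_naming_the_node(self):
        X = np.ones((50, 3), dtype=int)
        X[:, 0] = np.arange(50) % 2
        X[:, 2] = np.arange(50) % 2
        with pytest.raises(EstimationError, match="node 1"):
            fit_nodewise(X, 1)


class TestSymmetrize:
    def test_all_zero_fits_give_empty_network(self):
        fits = [_directed_fit(j, 3, -1.0, np.zeros(3)) for j in range(3)]
        net = symmetrize(fits, "AND", make_codebook(3))
        assert (net.beta == 0).all()
        assert net.tau == pytest.approx([-1.0, -1.0, -1.0])

    def test_and_vs_or_on_a_disagreeing_edge(self):
        s0 = np.array([0.0, 0.8, 0.0])
        fits = [
            _directed_fit(0, 3, 0.0, s0),
            _directed_fit(1, 3, 0.0, np.zeros(3)),
            _directed_fit(2, 3, 0.0, np.zeros(3)),
        ]
        net_and = symmetrize(fits, "AND", make_codebook(3))
        net_or = symmetrize(fits, "OR", make_codebook(3))
        assert net_and.beta[0, 1] == 0.0
        assert net_or.beta[0, 1] == pytest.approx(0.4)

    def test_agreeing_estimates_pass_through_under_both_rules(self):
        fits = [
            _directed_fit(0, 2, 0.0, [0.0, 0.6]),
            _directed_fit(1, 2, 0.0, [0.6, 0.0]),
        ]
        for rule in ("AND", "OR"):
            net = symmetrize(fits, rule, make_codebook(2))
            assert net.beta[0, 1] == pytest.approx(0.6)


class TestFullEstimator:
    def test_output_is_exactly_symmetric_zero_diagonal(self, chain_sample):
        net = fit_ising_elasso(chain_sample)
        assert np.array_equal(net.beta, net.beta.T)
        assert (np.diag(net.beta) == 0).all()
        assert np.isfinite(net.beta).all() and np.isfinite(net.tau).all()

    def test_estimation_is_deterministic(self, chain_sample):
        a = fit_ising_elasso(chain_sample)
        b = fit_ising_elasso(chain_sample)
        assert np.array_equal(a.beta, b.beta) and np.array_equal(a.tau, b.tau)

    def test_duplicated_rows_preserve_selected_support(self, chain_sample):
        # regression check, not a theorem: doubling every row doubles n in the
        # EBIC but leaves the selected support unchanged on this fixture
        X = chain_sample.values
        a = fit_ising_elasso(X)
        b = fit_ising_elasso(np.vstack([X, X]))
        assert np.array_equal(a.beta != 0, b.beta != 0)

    def test_independence_model_yields_empty_network(self):
        rng = np.random.default_rng(20934)
        X = rng.integers(0, 2, size=(5000, 9))
        net = fit_ising_elasso(X)
        assert (net.beta == 0).all()

    def test_constant_column_policy(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(300, 4))
        X[:, 1] = 1
        with pytest.raises(EstimationError, match="V1"):
            fit_ising_elasso(X)
        with pytest.warns(UserWarning, match="constant"):
            net = fit_ising_elasso(X, ElassoConfig(on_constant="drop"))
        assert (net.beta[1] == 0).all() and (net.beta[:, 1] == 0).all()
        assert net.tau[1] == ElassoConfig().coef_cap  # capped log-odds

    def test_network_exports(self, tmp_path, chain_sample):
        net = fit_ising_elasso(chain_sample)
        edges = net.edge_list()
        assert set(edges.columns) == {"node_a", "node_b", "weight"}
        adj = net.adjacency_frame()
        assert adj.shape == (9, 9)
        gml = tmp_path / "net.graphml"
        net.to_graphml(gml)
        import networkx as nx

        g = nx.read_graphml(gml)
        assert g.number_of_nodes() == 9
        assert g.number_of_edges() == len(edges)


class TestIsingNetworkValidation:
    def test_asymmetric_or_nonzero_diagonal_rejected(self):
        cb = make_codebook(2)
        with pytest.raises(ValueError, match="symmetric"):
            IsingNetwork(np.zeros(2), np.array([[0.0, 1.0], [0.5, 0.0]]), cb)
        with pytest.raises(ValueError, match="diagonal"):
            IsingNetwork(np.zeros(2), np.array([[1.0, 0.0], [0.0, 0.0]]), cb)
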