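"""Sparse Ising network estimation from binary data (the eLasso procedure).

For each node j, the conditional distribution of an Ising model on {0,1}^p is
a logistic regression on the remaining nodes:

    P(x_j = 1 | x_-j) = logistic(tau_j + sum_k beta_jk x_k)

so the network is estimated by p nodewise l1-penalized logistic regressions.
For each node the penalty is chosen along a decreasing path by the extended
Bayesian information criterion,

    EBIC(lambda) = -2 l(lambda) + J log n + 2 gamma J log(p - 1),

where l is the log-likelihood of the penalized fit evaluated without the
penalty term and J counts nonzero slope coefficients (the intercept is always
in the model, never penalized, never counted).  The two directed estimates of
each edge are then combined by the AND rule (edge kept only if both are
nonzero; weight = mean) or the OR rule (either suffices).

The optimizer is a glmnet-style IRLS / coordinate-descent on the penalized
Bernoulli likelihood.  Because all predictors are binary, the n x (p-1)
design collapses exactly to at most 2^(p-1) unique patterns with counts, so
fitting cost is independent of the sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numba
import numpy as np
import pandas as pd

from .data_model import SymptomCodebook, SymptomDataset


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ElassoConfig:
    """Tuning parameters of the eLasso estimator.

    gamma            EBIC sparsity hyperparameter (>= 0); 0.25 is the
                     field-standard default for symptom networks.
    rule             "AND" (conservative default) or "OR" edge retention.
    n_lambda         length of the penalty path.
    lambda_min_ratio smallest penalty as a fraction of lambda_max.
    tol              relative convergence tolerance of the optimizer.
    max_iter         iteration cap of the optimizer.
    coef_cap         |coefficient| bound; a path point that hits it (perfect
                     separation) is excluded from EBIC selection.
    on_constant      what to do with a constant column: "error" (default) or
                     "drop" (zero row/col in the result, threshold capped).
    """

    gamma: float = 0.25
    rule: str = "AND"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-7
    max_iter: int = 10_000
    coef_cap: float = 40.0
    on_constant: str = "error"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.on_constant not in ("error", "drop"):
            raise ValueError("on_constant must be 'error' or 'drop'")


@dataclass
class NodewiseFit:
    """Penalty path of one nodewise regression and its EBIC selection.

    ``slopes[l]`` is in the order of the remaining columns (original order
    with the node's own column removed); ``slopes_full`` re-inserts a zero
    at the node's own position.
    """

    node: int
    lambda_path: np.ndarray          # (L,) strictly decreasing, positive
    intercepts: np.ndarray           # (L,)
    slopes: np.ndarray               # (L, p-1)
    ebic: np.ndarray                 # (L,)
    valid: np.ndarray                # (L,) bool; False where separation hit the cap
    selected: int                    # index into the path minimizing EBIC
    n: int

    @property
    def p(self) -> int:
        return self.slopes.shape[1] + 1

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])

    @property
    def selected_slopes_full(self) -> np.ndarray:
        return self.slopes_full(self.selected)

    def slopes_full(self, l: int) -> np.ndarray:
        out = np.zeros(self.p)
        out[np.arange(self.p) != self.node] = self.slopes[l]
        return out


@dataclass
class IsingNetwork:
    """Estimated Ising model: thresholds tau and symmetric couplings beta."""

    tau: np.ndarray
    beta: np.ndarray
    labels: SymptomCodebook = field(default_factory=SymptomCodebook)
    n_fit: int | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        p = self.tau.shape[0]
        if self.beta.shape != (p, p):
            raise ValueError("beta must be p x p matching tau")
        if not (np.isfinite(self.tau).all() and np.isfinite(self.beta).all()):
            raise ValueError("tau and beta must be finite")
        if not np.array_equal(self.beta, self.beta.T):
            raise ValueError("beta must be exactly symmetric")
        if np.any(np.diag(self.beta) != 0):
            raise ValueError("beta must have a zero diagonal")

    @property
    def p(self) -> int:
        return self.tau.shape[0]

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges (upper triangle) as node_a, node_b, weight."""
        acr = self.labels.acronyms
        rows = [
            (acr[j], acr[k], self.beta[j, k])
            for j in range(self.p)
            for k in range(j + 1, self.p)
            if self.beta[j, k] != 0
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def adjacency_frame(self) -> pd.DataFrame:
        acr = list(self.labels.acronyms)
        return pd.DataFrame(self.beta, index=acr, columns=acr)

    def thresholds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.labels.acronyms), "tau": self.tau}
        )

    def to_graph(self, absolute: bool = False):
        """networkx Graph with 'weight' edge attributes (all nodes present)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels.acronyms)
        acr = self.labels.acronyms
        for j in range(self.p):
            for k in range(j + 1, self.p):
                w = self.beta[j, k]
                if w != 0:
                    g.add_edge(acr[j], acr[k], weight=abs(w) if absolute else w)
        return g

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = self.to_graph()
        for node, t in zip(self.labels.acronyms, self.tau):
            g.nodes[node]["tau"] = float(t)
        nx.write_graphml(g, str(path))


# --------------------------------------------------------------------------
# optimizer kernel

@numba.njit(cache=True)
def _cd_kernel(Z, nz, sz, N, lam, b0, beta, tol, max_iter, cap):
    """Weighted l1 logistic regression by IRLS + coordinate descent.

    Minimizes (1/N) sum_z [nz_z log(1+e^eta) - sz_z eta] + lam ||beta||_1
    over intercept b0 (unpenalized) and slopes beta, where eta = b0 + Z beta,
    nz_z counts observations with predictor pattern z and sz_z those with
    response 1.  Warm-started in place; returns (b0, iterations used).
    """
    m, k = Z.shape
    eta = b0 + Z @ beta
    it = 0
    while it < max_iter:
        it += 1
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.empty(m)
        zeta = np.empty(m)
        for i in range(m):
            wi = nz[i] * mu[i] * (1.0 - mu[i]) / N
            if wi < 1e-12:
                wi = 1e-12
            w[i] = wi
            zeta[i] = eta[i] + (sz[i] - nz[i] * mu[i]) / (N * wi)
        # inner coordinate descent on the quadratic approximation
        r = zeta - eta  # residual of working response at current params
        for _inner in range(1000):
            delta = 0.0
            swr = 0.0
            sw = 0.0
            for i in range(m):
                swr += w[i] * r[i]
                sw += w[i]
            db0 = swr / sw
            b0 += db0
            for i in range(m):
                r[i] -= db0
            if abs(db0) > delta:
                delta = abs(db0)
            for kk in range(k):
                num = 0.0
                den = 0.0
                for i in range(m):
                    num += w[i] * Z[i, kk] * r[i]
                    den += w[i] * Z[i, kk] * Z[i, kk]
                if den <= 0.0:
                    continue
                num += den * beta[kk]
                if num > lam:
                    new = (num - lam) / den
                elif num < -lam:
                    new = (num + lam) / den
                else:
                    new = 0.0
                if new > cap:
                    new = cap
                elif new < -cap:
                    new = -cap
                db = new - beta[kk]
                if db != 0.0:
                    beta[kk] = new
                    for i in range(m):
                        r[i] -= Z[i, kk] * db
                if abs(db) > delta:
                    delta = abs(db)
            if delta < tol:
                break
        new_eta = b0 + Z @ beta
        outer_delta = np.abs(new_eta - eta).max()
        eta = new_eta
        if outer_delta < tol:
            break
    return b0, it


def _collapse(Z: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None):
    """Collapse a binary design to unique rows with (weighted) counts."""
    k = Z.shape[1]
    codes = Z.astype(np.int64) @ (np.int64(1) << np.arange(k, dtype=np.int64))
    uniq, inv = np.unique(codes, return_inverse=True)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    nz = np.bincount(inv, weights=w, minlength=len(uniq))
    sz = np.bincount(inv, weights=w * y, minlength=len(uniq))
    Zu = ((uniq[:, None] >> np.arange(k, dtype=np.int64)) & 1).astype(np.float64)
    return Zu, nz, sz, float(w.sum())


def _log_likelihood(Zu, nz, sz, b0, beta) -> float:
    eta = b0 + Zu @ beta
    return float(np.sum(sz * eta - nz * np.logaddexp(0.0, eta)))


def nodewise_logistic(
    X: np.ndarray,
    j: int,
    sample_weight: np.ndarray | None = None,
    lam: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    cap: float = 200.0,
) -> tuple[float, np.ndarray]:
    """Single (optionally weighted/penalized) logistic fit of node j.

    Regresses column j on all other columns; returns (intercept,
    full-length slope vector with a structural zero at position j).  With
    ``lam=0`` this is the plain maximum-likelihood fit, used e.g. to recover
    (tau, beta) from data weighted by an exact Ising distribution.
    """
    X = np.asarray(X)
    y = X[:, j].astype(float)
    Z = np.delete(X, j, axis=1)
    Zu, nz, sz, N = _collapse(Z, y, sample_weight)
    beta = np.zeros(Z.shape[1])
    b0 = 0.0
    b0, _ = _cd_kernel(Zu, nz, sz, N, lam, b0, beta, tol, max_iter, cap)
    full = np.zeros(X.shape[1])
    full[np.arange(X.shape[1]) != j] = beta
    return float(b0), full


def fit_nodewise(
    X: np.ndarray,
    j: int,
    cfg: ElassoConfig | None = None,
    sample_weight: np.ndarray | None = None,
) -> NodewiseFit:
    """Penalty path + EBIC selection for the regression of node j on the rest."""
    cfg = cfg or ElassoConfig()
    X = np.asarray(X)
    n, p = X.shape
    y = X[:, j].astype(float)
    if y.min() == y.max():
        raise EstimationError(f"node {j} is constant; cannot fit its regression")
    if n < p:
        warnings.warn(f"n={n} < p={p}: nodewise estimates will be unstable")
    Z = np.delete(X, j, axis=1)
    Zu, nz, sz, N = _collapse(Z, y, sample_weight)

    ybar = sz.sum() / N
    lam_max = np.abs(Zu.T @ (sz - nz * ybar)).max() / N
    lam_max = max(lam_max, 1e-4)
    # start a hair above the threshold so the first path point is exactly the
    # intercept-only model (at lam_max itself the KKT boundary is active and
    # round-off can produce a spurious ~1e-15 coefficient, which would remove
    # the J=0 model from the EBIC comparison)
    lam_max *= 1 + 1e-6
    path = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)

    L = cfg.n_lambda
    intercepts = np.empty(L)
    slopes = np.empty((L, p - 1))
    ebic = np.full(L, np.inf)
    valid = np.ones(L, dtype=bool)
    beta = np.zeros(p - 1)
    b0 = float(np.log(ybar / (1 - ybar)))
    log_extra = np.log(p - 1) if p > 1 else 0.0
    for l, lam in enumerate(path):  # warm-started down the path
        b0, _ = _cd_kernel(
            Zu, nz, sz, N, lam, b0, beta, cfg.tol, cfg.max_iter, cfg.coef_cap
        )
        intercepts[l] = b0
        slopes[l] = beta
        if np.abs(beta).max() >= cfg.coef_cap:
            valid[l] = False
            continue
        J = int(np.count_nonzero(beta))
        ll = _log_likelihood(Zu, nz, sz, b0, beta)
        ebic[l] = -2.0 * ll + J * np.log(N) + 2.0 * cfg.gamma * J * log_extra
    if not valid.any():
        raise EstimationError(
            f"node {j}: every path point hit the coefficient cap (separation)"
        )
    if not valid.all():
        warnings.warn(
            f"node {j}: {int((~valid).sum())} path point(s) hit the coefficient "
            "cap and were excluded from EBIC selection"
        )
    masked = np.where(valid, ebic, np.inf)
    selected = int(np.argmin(masked))  # first minimum -> largest lambda on ties
    return NodewiseFit(
        node=j,
        lambda_path=path,
        intercepts=intercepts,
        slopes=slopes,
        ebic=ebic,
        valid=valid,
        selected=selected,
        n=int(round(N)),
    )


def symmetrize(
    fits: Sequence[NodewiseFit],
    rule: str = "AND",
    labels: SymptomCodebook | None = None,
) -> IsingNetwork:
    """Combine p directed nodewise estimates into one undirected network.

    AND: edge (j,k) kept only if both directed coefficients are nonzero;
    OR: either suffices.  A kept edge's weight is the mean of the two
    directed coefficients (a zero counts toward the mean under OR).
    """
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    p = len(fits)
    if sorted(f.node for f in fits) != list(range(p)):
        raise ValueError("need exactly one fit per node 0..p-1")
    directed = np.zeros((p, p))
    tau = np.zeros(p)
    for f in sorted(fits, key=lambda f: f.node):
        directed[f.node] = f.selected_slopes_full
        tau[f.node] = f.selected_intercept
    both = (directed != 0) & (directed.T != 0)
    either = (directed != 0) | (directed.T != 0)
    keep = both if rule == "AND" else either
    beta = np.where(keep, (directed + directed.T) / 2.0, 0.0)
    beta = (beta + beta.T) / 2.0  # exact symmetry
    np.fill_diagonal(beta, 0.0)
    n_fit = fits[0].n
    return IsingNetwork(tau, beta, labels or SymptomCodebook(), n_fit)


def fit_ising_elasso(
    data: SymptomDataset | np.ndarray,
    cfg: ElassoConfig | None = None,
) -> IsingNetwork:
    """Estimate the full symmetric Ising network from a binary dataset."""
    cfg = cfg or ElassoConfig()
    if isinstance(data, SymptomDataset):
        X = data.values
        labels = data.codebook
    else:
        X = np.asarray(data)
        labels = SymptomCodebook(
            tuple((f"V{i}", f"variable {i}") for i in range(X.shape[1]))
        )
    p = X.shape[1]
    col_min, col_max = X.min(axis=0), X.max(axis=0)
    constant = np.flatnonzero(col_min == col_max)
    if constant.size and cfg.on_constant == "error":
        names = [labels.acronyms[j] for j in constant]
        raise EstimationError(f"constant column(s): {names}")
    active = np.setdiff1d(np.arange(p), constant)
    if active.size < 2:
        raise EstimationError("need at least two non-constant columns")
    if constant.size:
        warnings.warn(
            f"dropping constant column(s) {[labels.acronyms[j] for j in constant]} "
            "from estimation; their couplings are set to 0"
        )
    Xa = X[:, active]
    fits = [fit_nodewise(Xa, j, cfg) for j in range(active.size)]
    sub = symmetrize(fits, cfg.rule)
    tau = np.zeros(p)
    beta = np.zeros((p, p))
    tau[active] = sub.tau
    beta[np.ix_(active, active)] = sub.beta
    # a constant column has no finite MLE threshold; cap its log-odds
    for j in constant:
        tau[j] = cfg.coef_cap if col_min[j] == 1 else -cfg.coef_cap
    return IsingNetwork(tau, beta, labels, X.shape[0])
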