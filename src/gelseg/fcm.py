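"""Fuzzy C-Means clustering of pixel intensities.

Minimizes J_m = sum_i sum_j u_ij^m ||x_i - c_j||^2 with alternating
updates of the cluster centers (membership-weighted means) and the
memberships (inverse-distance-ratio rule), stopping when the largest
membership change falls below a tolerance.

All functions accept optional point weights, which makes clustering a
512x512 image on its 256-bin intensity histogram mathematically
identical to per-pixel clustering (the objective and both updates
depend on points only through their value and multiplicity).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger("gelseg")


@dataclass
class FcmParams:
    """Fuzzy C-Means hyperparameters (C clusters, fuzzifier m > 1)."""

    C: int = 2
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol > 0 and max_iter >= 1 required")


@dataclass
class FcmResult:
    """Fitted memberships U (N x C, rows sum to 1), centers, objective
    trace (non-increasing), iteration count and convergence flag."""

    U: np.ndarray
    centers: np.ndarray
    objective_trace: list[float]
    iterations: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps({
            "centers": [float(c) for c in self.centers],
            "iterations": self.iterations,
            "converged": self.converged,
            "objective": self.objective_trace[-1] if self.objective_trace else None,
        })


def init_membership(N: int, C: int, seed: int | None = 0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Random row-normalized membership matrix, reproducible under seed."""
    if N < C:
        raise ValueError(f"need at least as many points ({N}) as clusters ({C})")
    if rng is None:
        rng = np.random.default_rng(seed)
    U = rng.random((N, C))
    return U / U.sum(axis=1, keepdims=True)


def update_centers(U: np.ndarray, data: np.ndarray, m: float,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """Membership-weighted means: c_j = sum u_ij^m x_i / sum u_ij^m."""
    data = np.asarray(data, dtype=np.float64).ravel()
    U = np.asarray(U, dtype=np.float64)
    w = np.ones_like(data) if weights is None else np.asarray(weights, float)
    um = (U**m) * w[:, None]
    mass = um.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("degenerate cluster with zero total membership mass")
    return (um * data[:, None]).sum(axis=0) / mass


def update_membership(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Inverse-distance-ratio membership update.

    u_ij = 1 / sum_k (|x_i - c_j| / |x_i - c_k|)^(2/(m-1)); a point
    coinciding with one or more centers splits full membership equally
    among the coincident centers.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    data = np.asarray(data, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64).ravel()
    if centers.size == 0:
        raise ValueError("centers must be nonempty")
    d = np.abs(data[:, None] - centers[None, :])
    U = np.zeros_like(d)
    on_center = d == 0
    singular = on_center.any(axis=1)
    if np.any(~singular):
        inv = d[~singular] ** (-2.0 / (m - 1.0))
        U[~singular] = inv / inv.sum(axis=1, keepdims=True)
    if np.any(singular):
        z = on_center[singular].astype(np.float64)
        U[singular] = z / z.sum(axis=1, keepdims=True)
    return U


def fcm_objective(data: np.ndarray, U: np.ndarray, centers: np.ndarray,
                  m: float, weights: np.ndarray | None = None) -> float:
    """The weighted FCM cost J_m (>= 0)."""
    data = np.asarray(data, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64).ravel()
    w = np.ones_like(data) if weights is None else np.asarray(weights, float)
    d2 = (data[:, None] - centers[None, :]) ** 2
    return float(np.sum(w[:, None] * (np.asarray(U, float) ** m) * d2))


def fcm_fit(data: np.ndarray, params: FcmParams,
            weights: np.ndarray | None = None,
            init_U: np.ndarray | None = None) -> FcmResult:
    """Run alternating FCM updates from a seeded initialization.

    Stops when the max-abs change of U drops below ``params.tol`` or
    after ``params.max_iter`` cycles.  A cluster column losing all
    membership mass is reinitialized at random (logged).  Constant data
    converges to equal centers and uniform memberships.
    """
    data = np.asarray(data, dtype=np.float64).ravel()
    w = None if weights is None else np.asarray(weights, dtype=np.float64).ravel()
    N, C = data.size, params.C
    if N < C:
        raise ValueError(f"need at least as many points ({N}) as clusters ({C})")
    rng = np.random.default_rng(params.seed)
    U = init_membership(N, C, rng=rng) if init_U is None else np.array(init_U, float)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        um = (U**params.m) * (np.ones(N) if w is None else w)[:, None]
        dead = um.sum(axis=0) <= 0
        if np.any(dead):
            logger.warning("reinitializing %d zero-mass cluster(s)", dead.sum())
            U = U.copy()
            U[:, dead] = rng.random((N, int(dead.sum())))
            U = U / U.sum(axis=1, keepdims=True)
        centers = update_centers(U, data, params.m, weights=w)
        U_new = update_membership(data, centers, params.m)
        trace.append(fcm_objective(data, U_new, centers, params.m, weights=w))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < params.tol:
            converged = True
            break
    return FcmResult(U=U, centers=centers, objective_trace=trace,
                     iterations=it, converged=converged)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Scikit-learn style Fuzzy C-Means for scalar (intensity) data.

    Parameters
    ----------
    n_clusters : int
        Number of clusters C.
    m : float
        Fuzzifier (> 1); 2 is the standard choice.
    tol : float
        Convergence threshold on the max-abs membership change.
    max_iter : int
    random_state : int

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters,)
    membership_ : ndarray of shape (n_samples, n_clusters)
    labels_ : ndarray of shape (n_samples,)
    objective_trace_ : list of float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 100, random_state: int = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("FuzzyCMeans expects scalar samples (n,) or (n, 1)")
        return X

    def fit(self, X, y=None, sample_weight=None) -> "FuzzyCMeans":
        x = self._validate(X)
        params = FcmParams(C=self.n_clusters, m=self.m, tol=self.tol,
                           max_iter=self.max_iter, seed=self.random_state)
        res = fcm_fit(x, params, weights=sample_weight)
        order = np.argsort(res.centers)
        self.cluster_centers_ = res.centers[order]
        self.membership_ = res.U[:, order]
        self.labels_ = hard_labels(x, self.cluster_centers_)
        self.objective_trace_ = res.objective_trace
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        return self

    def soft_predict(self, X) -> np.ndarray:
        return update_membership(self._validate(X), self.cluster_centers_, self.m)

    def predict(self, X) -> np.ndarray:
        return hard_labels(self._validate(X), self.cluster_centers_)


def hard_labels(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Argmax-membership hard assignment, ties toward the larger center.

    For scalar data the membership is a decreasing function of distance
    to the center, so argmax membership equals nearest center; under the
    coincident-center split rule ties go to the larger center.
    """
    data = np.asarray(data, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64).ravel()
    order = np.argsort(centers)[::-1]  # descending: first match = largest center
    d = np.abs(data[:, None] - centers[order][None, :])
    return order[np.argmin(d, axis=1)]
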