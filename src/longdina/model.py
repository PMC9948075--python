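"""Core domain types and probability operations of the Long-DINA model.

The longitudinal higher-order DINA (Long-DINA) model is a three-level
diagnostic classification model for respondents measured repeatedly over
``T`` occasions:

* **First order (measurement):** a conjunctive DINA response model.  Item
  ``i`` at occasion ``t`` is answered correctly with probability
  ``logit^-1(lambda0_it + lambda1_it * eta_nit)`` where the ideal response
  ``eta_nit = prod_k alpha_nkt ** q_ikt`` is 1 only if person ``n`` masters
  every attribute the item requires.
* **Second order (attribute structure):** binary attribute mastery is driven
  by a continuous general ability through a logistic link,
  ``logit P(alpha_nkt = 1) = beta_k * theta_nt - delta_k``, with slopes and
  difficulties invariant over occasions.
* **Third order (growth):** the ability vector ``theta_n = (theta_n1, ...,
  theta_nT)`` follows a T-variate normal with mean ``mu`` and covariance
  ``Sigma``; the first occasion is pinned to a standard normal
  (``mu_1 = 0``, ``Sigma_11 = 1``) to identify the scale.

With ``T = 1`` the model reduces exactly to the cross-sectional higher-order
DINA model.

This module holds the validated array containers plus the pure mathematical
operations; nothing here touches random number generation or MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, log_expit

__all__ = [
    "QMatrixSet",
    "ItemParameters",
    "StructuralParameters",
    "PersonLatent",
    "ResponseData",
    "compute_eta",
    "eta_array",
    "item_response_prob",
    "guessing_from_params",
    "slipping_from_params",
    "attribute_prob",
    "marginal_loglik_bruteforce",
    "attribute_posterior_bruteforce",
]

# Enumeration guard for the brute-force oracle: 2**(K*T) profile sequences.
_MAX_KT = 12


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.size and not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return a.astype(np.int8)


@dataclass
class QMatrixSet:
    """Per-occasion binary item-by-attribute loading structure.

    ``entries`` has shape ``(I, K, T)`` with ``entries[i, k, t] = 1`` iff
    item ``i`` requires attribute ``k`` at occasion ``t``.  ``anchor_items``
    lists 1-based indices of items whose row must be identical at all
    occasions (the internal-anchor linking design).
    """

    entries: np.ndarray
    anchor_items: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.entries = _as_binary(self.entries, "Q-matrix")
        if self.entries.ndim != 3:
            raise ValueError("Q-matrix entries must have shape (I, K, T)")
        self.anchor_items = tuple(int(i) for i in self.anchor_items)
        self.validate()

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attrs(self) -> int:
        return self.entries.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.entries.shape[2]

    def validate(self) -> None:
        if self.n_items and (self.entries.sum(axis=1) == 0).any():
            raise ValueError("every item must require at least one attribute at every occasion")
        for loc in self.anchor_items:
            if not 1 <= loc <= self.n_items:
                raise ValueError(f"anchor item {loc} outside 1..{self.n_items}")
            row = self.entries[loc - 1]
            if not (row == row[:, :1]).all():
                raise ValueError(f"anchor item {loc} has occasion-varying Q rows")


@dataclass
class ItemParameters:
    """DINA intercepts and interactions on the logit scale.

    ``lambda0`` and ``lambda1`` are ``(I, T)`` arrays.  ``lambda1 > 0`` is
    enforced everywhere (mastery never lowers the success probability), and
    anchor items carry one shared parameter pair copied across occasions.
    """

    lambda0: np.ndarray
    lambda1: np.ndarray
    anchor_items: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.lambda0 = np.atleast_2d(np.asarray(self.lambda0, dtype=float))
        self.lambda1 = np.atleast_2d(np.asarray(self.lambda1, dtype=float))
        self.anchor_items = tuple(int(i) for i in self.anchor_items)
        self.validate()

    @property
    def n_items(self) -> int:
        return self.lambda0.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.lambda0.shape[1]

    def validate(self) -> None:
        if self.lambda0.shape != self.lambda1.shape:
            raise ValueError("lambda0 and lambda1 must share shape (I, T)")
        if self.lambda1.size and (self.lambda1 <= 0).any():
            raise ValueError("lambda1 must be strictly positive (monotonicity)")
        for loc in self.anchor_items:
            for arr, name in ((self.lambda0, "lambda0"), (self.lambda1, "lambda1")):
                row = arr[loc - 1]
                if not np.allclose(row, row[0]):
                    raise ValueError(f"anchor item {loc}: {name} varies over occasions")


@dataclass
class StructuralParameters:
    """Higher-order slopes/difficulties and the longitudinal ability law.

    ``beta`` (length K) are logistic slopes of attribute mastery on the
    general ability, ``delta`` (length K) the difficulties; both are
    occasion-invariant.  ``mu`` (length T) and ``sigma_mat`` (T x T) give the
    multivariate-normal growth distribution of abilities, with the
    identification constraints ``mu[0] = 0`` and ``sigma_mat[0, 0] = 1``.
    """

    beta: np.ndarray
    delta: np.ndarray
    mu: np.ndarray
    sigma_mat: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma_mat = np.atleast_2d(np.asarray(self.sigma_mat, dtype=float))
        self.validate()

    @property
    def n_attrs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.mu.shape[0]

    def validate(self) -> None:
        if self.beta.shape != self.delta.shape:
            raise ValueError("beta and delta must have equal length K")
        T = self.mu.shape[0]
        if self.sigma_mat.shape != (T, T):
            raise ValueError("sigma_mat must be T x T")
        if abs(self.mu[0]) > 1e-12 or abs(self.sigma_mat[0, 0] - 1.0) > 1e-12:
            raise ValueError("identification requires mu[0] = 0 and sigma_mat[0, 0] = 1")
        if not np.allclose(self.sigma_mat, self.sigma_mat.T):
            raise ValueError("sigma_mat must be symmetric")
        try:
            np.linalg.cholesky(self.sigma_mat)
        except np.linalg.LinAlgError as err:
            raise ValueError("sigma_mat must be positive definite") from err


@dataclass
class PersonLatent:
    """Continuous abilities and binary attribute profiles (truth or estimate)."""

    theta: np.ndarray  # (N, T)
    alpha: np.ndarray  # (N, K, T)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.alpha = _as_binary(self.alpha, "alpha")
        if self.theta.ndim != 2 or self.alpha.ndim != 3:
            raise ValueError("theta must be (N, T) and alpha (N, K, T)")
        if self.theta.shape[0] != self.alpha.shape[0] or self.theta.shape[1] != self.alpha.shape[2]:
            raise ValueError("theta and alpha dimensions are inconsistent")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_attrs(self) -> int:
        return self.alpha.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.theta.shape[1]


@dataclass
class ResponseData:
    """Complete binary item responses with shape ``(N, I, T)``."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = _as_binary(self.y, "responses")
        if self.y.ndim != 3:
            raise ValueError("responses must have shape (N, I, T)")

    @property
    def n_persons(self) -> int:
        return self.y.shape[0]

    @property
    def n_items(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]


# ---------------------------------------------------------------------------
# Pure operations
# ---------------------------------------------------------------------------

def compute_eta(alpha_profile, q_row) -> int:
    """Conjunctive ideal response: 1 iff every required attribute is mastered.

    Implements ``prod_k alpha_k ** q_k`` with the DINA convention
    ``0 ** 0 = 1`` (items not measuring an attribute ignore it).
    """
    a = _as_binary(alpha_profile, "alpha profile")
    q = _as_binary(q_row, "q row")
    if a.shape != q.shape:
        raise ValueError(f"attribute profile length {a.shape} != q row length {q.shape}")
    return int(np.all(a >= q))


def eta_array(alpha: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorized ideal responses: ``(N, K, T)`` x ``(I, K, T)`` -> ``(N, I, T)``."""
    if alpha.shape[1] != q.shape[1] or alpha.shape[2] != q.shape[2]:
        raise ValueError("alpha and Q disagree on (K, T)")
    return np.all(alpha[:, None, :, :] >= q[None, :, :, :], axis=2).astype(np.int8)


def item_response_prob(eta, lambda0, lambda1):
    """Success probability ``logit^-1(lambda0 + lambda1 * eta)`` (vectorized)."""
    return expit(np.asarray(lambda0, float) + np.asarray(lambda1, float) * np.asarray(eta))


def guessing_from_params(lambda0):
    """Guessing probability implied by the intercept: ``logit^-1(lambda0)``."""
    return expit(np.asarray(lambda0, dtype=float))


def slipping_from_params(lambda0, lambda1):
    """Slipping probability ``1 - logit^-1(lambda0 + lambda1)``."""
    return expit(-(np.asarray(lambda0, dtype=float) + np.asarray(lambda1, dtype=float)))


def attribute_prob(theta, beta_k, delta_k):
    """Higher-order mastery probability ``logit^-1(beta_k * theta - delta_k)``."""
    return expit(np.asarray(beta_k, float) * np.asarray(theta, float) - np.asarray(delta_k, float))


# ---------------------------------------------------------------------------
# Brute-force marginal likelihood oracle (test-grade, tiny problems only)
# ---------------------------------------------------------------------------

def _profile_table(K: int) -> np.ndarray:
    """All 2**K binary attribute profiles, shape (2**K, K)."""
    return np.array(list(_iterproduct((0, 1), repeat=K)), dtype=np.int8) if K else np.zeros((1, 0), np.int8)


def _gh_nodes(struct: StructuralParameters, n_quad: int):
    """Gauss-Hermite product rule for the MVN ability law: nodes (M, T), weights (M,)."""
    x, w = hermgauss(n_quad)
    T = struct.n_occasions
    grids = np.meshgrid(*([x] * T), indexing="ij")
    z = np.stack([g.ravel() for g in grids], axis=1)  # (n_quad**T, T)
    wgrids = np.meshgrid(*([w] * T), indexing="ij")
    wts = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1) / np.pi ** (T / 2)
    L = np.linalg.cholesky(struct.sigma_mat)
    theta = struct.mu[None, :] + (np.sqrt(2.0) * z) @ L.T
    return theta, wts


def _per_node_components(y_person, qmat, items, struct, theta_nodes):
    """For each quadrature/MC node m and occasion t, the weighted profile terms.

    Returns ``c`` with shape (M, T, 2**K): ``c[m, t, a] = P(y_.t | alpha_t = a)
    * P(alpha_t = a | theta_mt)``.  Attribute profiles are independent across
    occasions given theta, so the per-person likelihood at node m is
    ``prod_t sum_a c[m, t, a]``.
    """
    K, T = qmat.n_attrs, qmat.n_occasions
    profiles = _profile_table(K)  # (P, K)
    y = np.asarray(y_person)
    c = np.empty((theta_nodes.shape[0], T, profiles.shape[0]))
    for t in range(T):
        # response log-likelihood per profile: (P,)
        eta_t = np.all(profiles[:, None, :] >= qmat.entries[None, :, :, t], axis=2)  # (P, I)
        z_item = items.lambda0[:, t][None, :] + items.lambda1[:, t][None, :] * eta_t
        ll_resp = (y[None, :, t] * log_expit(z_item) + (1 - y[None, :, t]) * log_expit(-z_item)).sum(axis=1)
        # profile prior per node: (M, P)
        zk = struct.beta[None, :] * theta_nodes[:, t:t + 1] - struct.delta[None, :]  # (M, K)
        lp = profiles[None, :, :] * log_expit(zk)[:, None, :] + (1 - profiles)[None, :, :] * log_expit(-zk)[:, None, :]
        c[:, t, :] = np.exp(lp.sum(axis=2) + ll_resp[None, :])
    return c


def marginal_loglik_bruteforce(
    y_person,
    qmat: QMatrixSet,
    items: ItemParameters,
    struct: StructuralParameters,
    n_quad: int = 21,
    method: str = "quad",
    n_mc: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Log marginal probability of one person's ``(I, T)`` response array.

    Exhaustively sums over all attribute-profile sequences (the sum
    factorizes over occasions given theta) and integrates the ability vector
    either by a tensor-product Gauss-Hermite rule (``method='quad'``) or by
    plain Monte Carlo (``method='mc'``).  Intended as an independent oracle
    for tests; refuses problems with ``K * T > 12``.
    """
    K, T = qmat.n_attrs, qmat.n_occasions
    if K * T > _MAX_KT:
        raise ValueError(f"brute-force enumeration limited to K*T <= {_MAX_KT}")
    if qmat.n_items == 0:
        return 0.0
    if method == "quad":
        if n_quad < 15:
            raise ValueError("n_quad must be >= 15 per dimension")
        theta_nodes, wts = _gh_nodes(struct, n_quad)
    elif method == "mc":
        rng = np.random.default_rng(0) if rng is None else rng
        L = np.linalg.cholesky(struct.sigma_mat)
        theta_nodes = struct.mu[None, :] + rng.standard_normal((n_mc, T)) @ L.T
        wts = np.full(n_mc, 1.0 / n_mc)
    else:
        raise ValueError(f"unknown method {method!r}")
    c = _per_node_components(y_person, qmat, items, struct, theta_nodes)
    lik_nodes = c.sum(axis=2).prod(axis=1)
    return float(np.log(np.dot(wts, lik_nodes)))


def attribute_posterior_bruteforce(
    y_person,
    qmat: QMatrixSet,
    items: ItemParameters,
    struct: StructuralParameters,
    n_quad: int = 21,
) -> np.ndarray:
    """Exact posterior mastery probabilities ``P(alpha_kt = 1 | y)``, shape (K, T).

    Companion oracle to :func:`marginal_loglik_bruteforce`: enumerates
    attribute profiles and integrates theta by quadrature with the model
    parameters held at their supplied values.
    """
    K, T = qmat.n_attrs, qmat.n_occasions
    if K * T > _MAX_KT:
        raise ValueError(f"brute-force enumeration limited to K*T <= {_MAX_KT}")
    theta_nodes, wts = _gh_nodes(struct, n_quad)
    c = _per_node_components(y_person, qmat, items, struct, theta_nodes)  # (M, T, P)
    s = c.sum(axis=2)  # (M, T)
    lik = s.prod(axis=1)  # (M,)
    evidence = np.dot(wts, lik)
    profiles = _profile_table(K)
    post = np.empty((K, T))
    for t in range(T):
        with np.errstate(invalid="ignore", divide="ignore"):
            others = np.where(s[:, t] > 0, lik / s[:, t], 0.0)  # prod over occasions != t
        prof_post = (wts[:, None] * others[:, None] * c[:, t, :]).sum(axis=0) / evidence  # (P,)
        post[:, t] = profiles.T @ prof_post
    return post
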