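"""Fully Bayesian estimation of the Long-DINA model.

A self-contained Metropolis-within-Gibbs sampler over the joint posterior of

* item parameters ``(lambda0_it, lambda1_it)`` — one shared pair per anchor
  item (pooling its likelihood over occasions), a per-occasion pair
  otherwise;
* higher-order slopes and difficulties ``(beta_k, delta_k)``;
* the ability growth law ``mu_t`` (t >= 2), occasion standard deviations
  ``sigma_t`` (t >= 2) and the inter-occasion correlation matrix;
* person latents ``theta_nt`` and ``alpha_nkt``.

Update scheme: attribute indicators by exact Gibbs from their Bernoulli
full conditionals; the free ability means by exact Gibbs from their
conjugate normal full conditional; everything else by random-walk
Metropolis with proposal
scales adapted during burn-in only (frozen afterwards so the retained chain
satisfies detailed balance).  Identification constraints are held exactly:
``mu_1 = 0``, ``sigma_1 = 1``, ``lambda1 > 0``, and the sign of the general
ability is pinned by constraining one slope (the last attribute's, by
default) to be positive; with the identity blocks in the Q-matrix anchoring
each attribute to its own items, no label switching can occur.

Priors (weakly informative, centred on a realistic item-quality regime):
``lambda0 ~ N(-2.197, 1)``; ``lambda1 ~ N(4.394, 1)`` truncated to (0, inf);
``beta_k, delta_k, mu_t ~ N(0, 2^2)`` (``beta`` truncated to (0, inf) for
the sign-pinned attribute only); ``sigma_t ~ half-N(2)``; correlations
uniform over the positive-definite region.

Convergence is assessed with the classic Gelman-Rubin potential scale
reduction factor on all item and structural parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .model import (
    ItemParameters,
    QMatrixSet,
    ResponseData,
    StructuralParameters,
    eta_array,
)

__all__ = [
    "MCMCSettings",
    "MCMCResult",
    "ClassificationResult",
    "run_mcmc",
    "compute_psrf",
    "classify_attributes",
]

_DEFAULT_SCALES = {
    "lambda0": 0.3,
    "lambda1": 0.3,
    "theta": 0.6,
    "beta": 0.3,
    "delta": 0.3,
    "sigma": 0.15,
    "rho": 0.2,
    "translate": 0.15,
    "occ_scale": 0.1,
    "global_scale": 0.05,
}

_PRIOR = {
    "lambda0_mean": -2.197,
    "lambda0_sd": 1.0,
    "lambda1_mean": 4.394,
    "lambda1_sd": 1.0,
    "beta_sd": 2.0,
    "delta_sd": 2.0,
    "mu_sd": 2.0,
    "sigma_sd": 2.0,
}


@dataclass
class MCMCSettings:
    """Run-length, seeding and proposal configuration.

    The defaults mirror the full estimation protocol (two chains of 10,000
    iterations, first 5,000 discarded); :meth:`reduced` gives the desk-scale
    protocol (3,000 / 1,500) used for replication at reduced cost.
    """

    n_chains: int = 2
    n_iterations: int = 10_000
    n_burnin: int = 5_000
    thin: int = 1
    seed: int = 0
    proposal_scales: dict = field(default_factory=lambda: dict(_DEFAULT_SCALES))
    target_accept: float = 0.44
    adapt_rate: float = 0.05
    n_inner_sweeps: int = 3  # (theta, structural) scans per iteration; cheap blocks, mix-limited
    sign_attr: int | None = None  # 1-based attribute whose slope pins the theta sign; None -> last

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        scales = dict(_DEFAULT_SCALES)
        scales.update(self.proposal_scales)
        self.proposal_scales = scales

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "MCMCSettings":
        kw.setdefault("n_iterations", 3_000)
        kw.setdefault("n_burnin", 1_500)
        return cls(seed=seed, **kw)


@dataclass
class ClassificationResult:
    """Posterior attribute classification and ability point estimates."""

    alpha_posterior: np.ndarray  # (N, K, T) posterior mastery probabilities
    alpha_hat: np.ndarray  # (N, K, T) binary, EAP >= 0.5 (ties -> mastery)
    theta_hat: np.ndarray  # (N, T) posterior means


@dataclass
class MCMCResult:
    """Retained draws, convergence diagnostics and posterior summaries."""

    names: list[str]
    draws: np.ndarray  # (n_chains, n_retained, n_monitored)
    alpha_mean: np.ndarray  # (n_chains, N, K, T) per-chain posterior means
    theta_mean: np.ndarray  # (n_chains, N, T)
    accept_rates: dict[str, float]
    settings: MCMCSettings

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def psrf(self) -> pd.Series:
        vals = [compute_psrf(self.draws[:, :, j]) for j in range(self.draws.shape[2])]
        return pd.Series(vals, index=self.names, name="psrf")

    @property
    def posterior_mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=(0, 1)), index=self.names, name="mean")

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        pooled = self.draws.reshape(-1, self.draws.shape[2])
        q = np.quantile(pooled, [lo, hi], axis=0)
        return pd.DataFrame({"lower": q[0], "upper": q[1]}, index=self.names)

    def summary(self) -> pd.DataFrame:
        ci = self.credible_interval()
        return pd.DataFrame(
            {"mean": self.posterior_mean, "lower": ci["lower"], "upper": ci["upper"], "psrf": self.psrf}
        )


def compute_psrf(chains, split: bool = False) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is an ``(m, L)`` array of retained draws of one scalar
    parameter from ``m >= 2`` chains.  Returns
    ``sqrt((((L-1)/L) * W + B/L) / W)`` with the standard between/within
    variance definitions.  ``split=True`` halves each chain first.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2:
        raise ValueError("chains must be a 2-D (m, L) array")
    if split:
        L2 = c.shape[1] // 2
        c = np.concatenate([c[:, :L2], c[:, L2:2 * L2]], axis=0)
    m, L = c.shape
    if m < 2:
        raise ValueError("PSRF needs at least 2 chains (or split=True)")
    if L < 10:
        raise ValueError("PSRF needs chain length >= 10")
    means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean()
    B_over_L = means.var(ddof=1)  # = B / L
    if W == 0.0:
        return 1.0 if B_over_L == 0.0 else float("inf")
    var_plus = (L - 1) / L * W + B_over_L
    return float(np.sqrt(var_plus / W))


def classify_attributes(result: MCMCResult) -> ClassificationResult:
    """EAP attribute classification pooled over chains.

    The posterior mastery probability is the mean of the retained alpha
    draws across chains; mastery is declared at probability >= 0.5 (the tie
    goes to mastery).  Abilities are summarized by their posterior mean.
    """
    alpha_post = result.alpha_mean.mean(axis=0)
    theta_hat = result.theta_mean.mean(axis=0)
    alpha_hat = (alpha_post >= 0.5).astype(np.int8)
    return ClassificationResult(alpha_post, alpha_hat, theta_hat)


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------

def _adapt(log_scale, accept_prob, rate, target):
    """Robbins-Monro style scale adaptation (burn-in only)."""
    return log_scale + rate * (accept_prob - target)


class _Chain:
    """State and update steps for one MCMC chain (vectorized over persons/items)."""

    def __init__(self, y, q, anchors0, settings, rng, fixed_items, fixed_struct):
        self.rng = rng
        self.s = settings
        self.y = y.astype(np.float64)
        self.q = q
        self.N, self.I, self.T = y.shape
        self.K = q.shape[1]
        self.y_sum = self.y.sum(axis=0)  # (I, T)
        self.anchors0 = np.asarray(sorted(anchors0), dtype=int)
        self.fixed_items = fixed_items
        self.fixed_struct = fixed_struct
        sa = settings.sign_attr
        self.sign_attr = (self.K - 1) if sa is None else sa - 1

        # item-parameter blocks: anchors first, then (non-anchor item, occasion)
        non = np.setdiff1d(np.arange(self.I), self.anchors0)
        self.na_items = non
        self.block_names = [f"[{i + 1}]" for i in self.anchors0] + [
            f"[{i + 1},{t + 1}]" for i in non for t in range(self.T)
        ]
        self.n_anchor = len(self.anchors0)
        self.n_blocks = self.n_anchor + non.size * self.T

        # per (k, t): items requiring attribute k, and their q rows with k masked out
        self.req = {}
        for k in range(self.K):
            for t in range(self.T):
                idx = np.flatnonzero(q[:, k, t])
                sub = q[idx, :, t].copy()
                sub[:, k] = 0
                self.req[(k, t)] = (idx, sub)

        self._init_state()
        self._refresh_eta()
        self._refresh_item_logratios()

    # -- initialization (overdispersed) -------------------------------------
    def _init_state(self):
        rng, N, I, T, K = self.rng, self.N, self.I, self.T, self.K
        if self.fixed_items is not None:
            self.lam0 = self.fixed_items.lambda0.copy()
            self.lam1 = self.fixed_items.lambda1.copy()
        else:
            self.lam0 = _PRIOR["lambda0_mean"] + 1.5 * rng.standard_normal((I, T))
            self.lam1 = np.abs(_PRIOR["lambda1_mean"] + 1.5 * rng.standard_normal((I, T)))
            for i in self.anchors0:
                self.lam0[i, :] = self.lam0[i, 0]
                self.lam1[i, :] = self.lam1[i, 0]
        if self.fixed_struct is not None:
            st = self.fixed_struct
            self.beta = st.beta.copy()
            self.delta = st.delta.copy()
            self.mu = st.mu.copy()
            sd = np.sqrt(np.diag(st.sigma_mat))
            self.sd = sd
            self.R = st.sigma_mat / np.outer(sd, sd)
        else:
            self.beta = rng.normal(0.0, 1.0, K)
            self.beta[self.sign_attr] = abs(self.beta[self.sign_attr]) + 0.1
            self.delta = rng.normal(0.0, 1.0, K)
            self.mu = np.concatenate([[0.0], rng.normal(0.0, 1.0, T - 1)])
            self.sd = np.concatenate([[1.0], np.abs(1.0 + 0.5 * rng.standard_normal(T - 1))])
            self.R = np.full((T, T), 0.5)
            np.fill_diagonal(self.R, 1.0)
        self._set_sigma()
        self.theta = self.mu[None, :] + rng.standard_normal((N, T))
        self.alpha = (rng.random((N, K, T)) < 0.5).astype(np.int8)

        sc = self.s.proposal_scales
        self.ls_l0 = np.full(self.n_blocks, math.log(sc["lambda0"]))
        self.ls_l1 = np.full(self.n_blocks, math.log(sc["lambda1"]))
        self.ls_theta = np.full(T, math.log(sc["theta"]))
        self.ls_beta = np.full(K, math.log(sc["beta"]))
        self.ls_delta = np.full(K, math.log(sc["delta"]))
        self.ls_sd = np.full(T, math.log(sc["sigma"]))
        ts = [(a, b) for a in range(T) for b in range(a + 1, T)]
        self.rho_pairs = ts
        self.ls_rho = np.full(len(ts), math.log(sc["rho"]))
        self.ls_tr = np.full(T, math.log(sc["translate"]))
        self.ls_os = np.full(T, math.log(sc["occ_scale"]))
        self.ls_gs = math.log(sc["global_scale"])
        self.acc = {k: [0.0, 0.0] for k in ("lambda0", "lambda1", "theta", "beta", "delta", "mu",
                                            "sigma", "rho", "translate", "occ_scale", "global_scale")}

    def _set_sigma(self) -> bool:
        sigma = self.R * np.outer(self.sd, self.sd)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return False
        self.sigma = sigma
        self.prec = np.linalg.inv(sigma)
        self.logdet = 2.0 * np.log(np.diag(L)).sum()
        return True

    # -- cached quantities ---------------------------------------------------
    def _refresh_eta(self):
        self.eta = np.all(self.alpha[:, None, :, :] >= self.q[None, :, :, :], axis=2)

    def _refresh_item_logratios(self):
        z1 = self.lam0 + self.lam1
        # log p1 - log p0 and log(1-p1) - log(1-p0), per (i, t)
        self.lr_A = log_expit(z1) - log_expit(self.lam0)
        self.lr_B = log_expit(-z1) - log_expit(-self.lam0)

    def _mvn_loglik(self, mu=None, prec=None, logdet=None):
        mu = self.mu if mu is None else mu
        prec = self.prec if prec is None else prec
        logdet = self.logdet if logdet is None else logdet
        d = self.theta - mu[None, :]
        quad = np.einsum("nt,ts,ns->", d, prec, d)
        return -0.5 * quad - 0.5 * self.N * logdet

    def _attr_loglik_kt(self, beta, delta):
        """Sum over persons/occasions of the attribute Bernoulli log-lik for one k."""
        z = beta * self.theta - delta  # (N, T)
        a = self.alpha_k
        return float((a * log_expit(z) + (1.0 - a) * log_expit(-z)).sum())

    # -- update blocks -------------------------------------------------------
    def update_alpha(self):
        """Exact Gibbs scan over (attribute, occasion) cells."""
        y, rng = self.y, self.rng
        for k in range(self.K):
            bk, dk = self.beta[k], self.delta[k]
            for t in range(self.T):
                idx, sub = self.req[(k, t)]
                logodds = bk * self.theta[:, t] - dk
                if idx.size:
                    eta_other = np.all(self.alpha[:, None, :, t] >= sub[None, :, :], axis=2)
                    contrib = y[:, idx, t] * self.lr_A[idx, t][None, :] + (1.0 - y[:, idx, t]) * self.lr_B[idx, t][None, :]
                    logodds = logodds + np.einsum("ni,ni->n", eta_other, contrib)
                self.alpha[:, k, t] = rng.random(self.N) < expit(logodds)
        self._refresh_eta()

    def _block_stats(self):
        n1 = self.eta.sum(axis=0).astype(np.float64)  # (I, T)
        s1 = np.einsum("nit,nit->it", self.eta, self.y)
        s0 = self.y_sum - s1
        n0 = self.N - n1
        if self.n_anchor:
            a = self.anchors0
            n1b = np.concatenate([n1[a].sum(1), n1[self.na_items].ravel()])
            s1b = np.concatenate([s1[a].sum(1), s1[self.na_items].ravel()])
            n0b = np.concatenate([n0[a].sum(1), n0[self.na_items].ravel()])
            s0b = np.concatenate([s0[a].sum(1), s0[self.na_items].ravel()])
        else:
            n1b, s1b, n0b, s0b = (x.ravel() for x in (n1, s1, n0, s0))
        return n1b, s1b, n0b, s0b

    @staticmethod
    def _item_ll(l0, l1, n1, s1, n0, s0):
        z1 = l0 + l1
        return s1 * log_expit(z1) + (n1 - s1) * log_expit(-z1) + s0 * log_expit(l0) + (n0 - s0) * log_expit(-l0)

    def _gather_blocks(self):
        if self.n_anchor:
            a = self.anchors0
            l0 = np.concatenate([self.lam0[a, 0], self.lam0[self.na_items].ravel()])
            l1 = np.concatenate([self.lam1[a, 0], self.lam1[self.na_items].ravel()])
        else:
            l0, l1 = self.lam0.ravel(), self.lam1.ravel()
        return l0, l1

    def _scatter_blocks(self, l0, l1):
        if self.n_anchor:
            a = self.anchors0
            self.lam0[a, :] = l0[: self.n_anchor, None]
            self.lam1[a, :] = l1[: self.n_anchor, None]
            self.lam0[self.na_items] = l0[self.n_anchor:].reshape(-1, self.T)
            self.lam1[self.na_items] = l1[self.n_anchor:].reshape(-1, self.T)
        else:
            self.lam0 = l0.reshape(self.I, self.T)
            self.lam1 = l1.reshape(self.I, self.T)

    def update_items(self, adapting):
        if self.n_blocks == 0:
            return
        rng = self.rng
        n1, s1, n0, s0 = self._block_stats()
        l0, l1 = self._gather_blocks()
        cur = self._item_ll(l0, l1, n1, s1, n0, s0)

        # intercepts
        prop = l0 + np.exp(self.ls_l0) * rng.standard_normal(self.n_blocks)
        new = self._item_ll(prop, l1, n1, s1, n0, s0)
        dprior = (-(prop - _PRIOR["lambda0_mean"]) ** 2 + (l0 - _PRIOR["lambda0_mean"]) ** 2) / (2 * _PRIOR["lambda0_sd"] ** 2)
        logr = new - cur + dprior
        ap = np.exp(np.minimum(0.0, logr))
        take = rng.random(self.n_blocks) < ap
        l0 = np.where(take, prop, l0)
        cur = np.where(take, new, cur)
        self.acc["lambda0"][0] += ap.mean()
        self.acc["lambda0"][1] += 1
        if adapting:
            self.ls_l0 = _adapt(self.ls_l0, ap, self.s.adapt_rate, self.s.target_accept)

        # interactions (positivity-truncated prior: reject non-positive proposals)
        prop = l1 + np.exp(self.ls_l1) * rng.standard_normal(self.n_blocks)
        ok = prop > 0
        propc = np.where(ok, prop, 1.0)
        new = self._item_ll(l0, propc, n1, s1, n0, s0)
        dprior = (-(propc - _PRIOR["lambda1_mean"]) ** 2 + (l1 - _PRIOR["lambda1_mean"]) ** 2) / (2 * _PRIOR["lambda1_sd"] ** 2)
        logr = np.where(ok, new - cur + dprior, -np.inf)
        ap = np.exp(np.minimum(0.0, logr))
        take = rng.random(self.n_blocks) < ap
        l1 = np.where(take, prop, l1)
        self.acc["lambda1"][0] += ap.mean()
        self.acc["lambda1"][1] += 1
        if adapting:
            self.ls_l1 = _adapt(self.ls_l1, ap, self.s.adapt_rate, self.s.target_accept)

        self._scatter_blocks(l0, l1)
        self._refresh_item_logratios()

    def update_theta(self, adapting):
        rng = self.rng
        d = self.theta - self.mu[None, :]
        for t in range(self.T):
            step = np.exp(self.ls_theta[t]) * rng.standard_normal(self.N)
            prop = self.theta[:, t] + step
            z_cur = self.theta[:, t][:, None] * self.beta[None, :] - self.delta[None, :]
            z_new = prop[:, None] * self.beta[None, :] - self.delta[None, :]
            a = self.alpha[:, :, t]
            dll = ((a * (log_expit(z_new) - log_expit(z_cur))
                    + (1 - a) * (log_expit(-z_new) - log_expit(-z_cur))).sum(axis=1))
            cross = d @ self.prec[t] - self.prec[t, t] * d[:, t]
            dc, pc = d[:, t], prop - self.mu[t]
            dprior = -0.5 * self.prec[t, t] * (pc ** 2 - dc ** 2) - (pc - dc) * cross
            ap = np.exp(np.minimum(0.0, dll + dprior))
            take = rng.random(self.N) < ap
            self.theta[take, t] = prop[take]
            d[take, t] = pc[take]
            self.acc["theta"][0] += ap.mean()
            self.acc["theta"][1] += 1
            if adapting:
                self.ls_theta[t] = _adapt(self.ls_theta[t], ap.mean(), self.s.adapt_rate, self.s.target_accept)

    def update_struct_attr(self, adapting):
        """Higher-order slopes and difficulties, one scalar RW step each."""
        rng = self.rng
        for k in range(self.K):
            self.alpha_k = self.alpha[:, k, :].astype(np.float64)
            cur = self._attr_loglik_kt(self.beta[k], self.delta[k])
            # slope
            prop = self.beta[k] + np.exp(self.ls_beta[k]) * rng.standard_normal()
            if k == self.sign_attr and prop <= 0:
                ap = 0.0
            else:
                new = self._attr_loglik_kt(prop, self.delta[k])
                dprior = (-(prop ** 2) + self.beta[k] ** 2) / (2 * _PRIOR["beta_sd"] ** 2)
                ap = math.exp(min(0.0, new - cur + dprior))
                if rng.random() < ap:
                    self.beta[k] = prop
                    cur = new
            self.acc["beta"][0] += ap
            self.acc["beta"][1] += 1
            if adapting:
                self.ls_beta[k] = _adapt(self.ls_beta[k], ap, self.s.adapt_rate, self.s.target_accept)
            # difficulty
            prop = self.delta[k] + np.exp(self.ls_delta[k]) * rng.standard_normal()
            new = self._attr_loglik_kt(self.beta[k], prop)
            dprior = (-(prop ** 2) + self.delta[k] ** 2) / (2 * _PRIOR["delta_sd"] ** 2)
            ap = math.exp(min(0.0, new - cur + dprior))
            if rng.random() < ap:
                self.delta[k] = prop
            self.acc["delta"][0] += ap
            self.acc["delta"][1] += 1
            if adapting:
                self.ls_delta[k] = _adapt(self.ls_delta[k], ap, self.s.adapt_rate, self.s.target_accept)

    def update_struct_growth(self, adapting):
        """Free means, scales and correlations of the ability law."""
        rng = self.rng
        # means (t >= 2): exact Gibbs from the conjugate normal full conditional
        if self.T > 1:
            s = self.theta.sum(axis=0)  # (T,)
            A = self.N * self.prec[1:, 1:] + np.eye(self.T - 1) / _PRIOR["mu_sd"] ** 2
            b = (self.prec @ s)[1:]
            La = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            z = rng.standard_normal(self.T - 1)
            self.mu = np.concatenate([[0.0], mean + np.linalg.solve(La.T, z)])
            self.acc["mu"][0] += 1.0
            self.acc["mu"][1] += 1
        cur = self._mvn_loglik()
        # scales (t >= 2): log-scale random walk (Jacobian log(sd'/sd))
        for t in range(1, self.T):
            prop_sd = self.sd.copy()
            prop_sd[t] = self.sd[t] * math.exp(np.exp(self.ls_sd[t]) * rng.standard_normal())
            dprior = ((-(prop_sd[t] ** 2) + self.sd[t] ** 2) / (2 * _PRIOR["sigma_sd"] ** 2)
                      + math.log(prop_sd[t] / self.sd[t]))
            ap = self._try_sigma(prop_sd, self.R, cur, dprior=dprior)
            if ap < 0:  # rejected inside
                ap = -ap
            else:
                cur = self._mvn_loglik()
            self.acc["sigma"][0] += ap
            self.acc["sigma"][1] += 1
            if adapting:
                self.ls_sd[t] = _adapt(self.ls_sd[t], ap, self.s.adapt_rate, self.s.target_accept)
        # correlations: Fisher-z random walk so steps stay efficient near the
        # boundary (uniform prior on rho -> density 1 - rho^2 on z)
        for j, (a, b) in enumerate(self.rho_pairs):
            prop_R = self.R.copy()
            z = math.atanh(self.R[a, b]) + np.exp(self.ls_rho[j]) * rng.standard_normal()
            r = math.tanh(z)
            prop_R[a, b] = prop_R[b, a] = r
            dprior = math.log((1 - r ** 2) / (1 - self.R[a, b] ** 2))
            ap = self._try_sigma(self.sd, prop_R, cur, dprior=dprior)
            if ap < 0:
                ap = -ap
            else:
                cur = self._mvn_loglik()
            self.acc["rho"][0] += ap
            self.acc["rho"][1] += 1
            if adapting:
                self.ls_rho[j] = _adapt(self.ls_rho[j], ap, self.s.adapt_rate, self.s.target_accept)

    def _try_sigma(self, sd, R, cur_ll, dprior):
        """MH step for a covariance change; returns accept prob (negated if rejected)."""
        sigma = R * np.outer(sd, sd)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return -0.0
        prec = np.linalg.inv(sigma)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        new = self._mvn_loglik(prec=prec, logdet=logdet)
        ap = math.exp(min(0.0, new - cur_ll + dprior))
        if self.rng.random() < ap:
            self.sd = np.asarray(sd, float).copy()
            self.R = R.copy()
            self.sigma, self.prec, self.logdet = sigma, prec, logdet
            return ap
        return -ap

    def _attr_ll_occ(self, theta_t, t):
        z = theta_t[:, None] * self.beta[None, :] - self.delta[None, :]
        a = self.alpha[:, :, t]
        return float((a * log_expit(z) + (1 - a) * log_expit(-z)).sum())

    def update_interweave(self, adapting):
        """Group moves that transform theta jointly with structural parameters.

        The hierarchical posterior has strong ridges: mu_t against the
        location of the theta column, sigma_t against its spread, and the
        overall beta magnitude against the theta scale (whose occasion-1
        scale is pinned only through the prior).  Coordinatewise updates
        cross these ridges slowly, so three Metropolis moves act along them:
        per-occasion translation (theta_.t, mu_t), per-occasion rescale
        (theta_.t, sigma_t) in the non-centred parameterization, and a
        global rescale (beta, theta, mu, sigma).  Each uses the exact
        posterior ratio with the appropriate Jacobian, so detailed balance
        is preserved.
        """
        rng = self.rng
        rate, target = self.s.adapt_rate, self.s.target_accept
        # translation: theta_.t + d, mu_t + d (third-order level invariant)
        for t in range(1, self.T):
            d = np.exp(self.ls_tr[t]) * rng.standard_normal()
            new_col = self.theta[:, t] + d
            dll = self._attr_ll_occ(new_col, t) - self._attr_ll_occ(self.theta[:, t], t)
            dprior = (-(self.mu[t] + d) ** 2 + self.mu[t] ** 2) / (2 * _PRIOR["mu_sd"] ** 2)
            ap = math.exp(min(0.0, dll + dprior))
            if rng.random() < ap:
                self.theta[:, t] = new_col
                self.mu[t] += d
            self.acc["translate"][0] += ap
            self.acc["translate"][1] += 1
            if adapting:
                self.ls_tr[t] = _adapt(self.ls_tr[t], ap, rate, target)
        # per-occasion rescale: residuals fixed, (theta_.t, sigma_t) scaled by c;
        # Jacobian x MVN ratio reduces to a single factor c
        for t in range(1, self.T):
            c = math.exp(np.exp(self.ls_os[t]) * rng.standard_normal())
            new_col = self.mu[t] + c * (self.theta[:, t] - self.mu[t])
            new_sd = c * self.sd[t]
            dll = self._attr_ll_occ(new_col, t) - self._attr_ll_occ(self.theta[:, t], t)
            dprior = (-(new_sd ** 2) + self.sd[t] ** 2) / (2 * _PRIOR["sigma_sd"] ** 2)
            ap = math.exp(min(0.0, dll + dprior + math.log(c)))
            if rng.random() < ap:
                self.theta[:, t] = new_col
                self.sd[t] = new_sd
                self._set_sigma()
            self.acc["occ_scale"][0] += ap
            self.acc["occ_scale"][1] += 1
            if adapting:
                self.ls_os[t] = _adapt(self.ls_os[t], ap, rate, target)
        # global rescale: beta -> c*beta, theta -> theta/c, mu, sigma -> /c
        # (second-order terms beta*theta are exactly invariant)
        c = math.exp(np.exp(self.ls_gs) * rng.standard_normal())
        new_beta = c * self.beta
        new_mu = self.mu / c
        new_sd = self.sd.copy()
        new_sd[1:] /= c
        sigma = self.R * np.outer(new_sd, new_sd)
        sigma[0, 0] = 1.0
        L = np.linalg.cholesky(sigma)
        prec = np.linalg.inv(sigma)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        dd = (self.theta - self.mu[None, :]) / c
        quad = np.einsum("nt,ts,ns->", dd, prec, dd)
        new_mvn = -0.5 * quad - 0.5 * self.N * logdet
        cur_mvn = self._mvn_loglik()
        dprior = ((-(new_beta ** 2) + self.beta ** 2).sum() / (2 * _PRIOR["beta_sd"] ** 2)
                  + (-(new_mu[1:] ** 2) + self.mu[1:] ** 2).sum() / (2 * _PRIOR["mu_sd"] ** 2)
                  + (-(new_sd[1:] ** 2) + self.sd[1:] ** 2).sum() / (2 * _PRIOR["sigma_sd"] ** 2))
        jac = (self.K - self.N * self.T - 2 * (self.T - 1)) * math.log(c)
        ap = math.exp(min(0.0, new_mvn - cur_mvn + dprior + jac))
        if rng.random() < ap:
            self.beta = new_beta
            self.mu = new_mu
            self.theta = self.theta / c
            self.sd = new_sd
            self.sigma, self.prec, self.logdet = sigma, prec, logdet
        self.acc["global_scale"][0] += ap
        self.acc["global_scale"][1] += 1
        if adapting:
            self.ls_gs = _adapt(self.ls_gs, ap, rate, target)
        # reflection mode jump: theta -> -theta, mu -> -mu, beta_k -> -beta_k
        # for every slope except the sign-pinned one.  The model without the
        # sign pin is exactly reflection-symmetric, so a chain started in the
        # mirror basin sits at a trap where the pinned slope is squeezed to
        # 0+; there this involution is nearly free and releases the chain,
        # while in the correct basin it is firmly rejected.  Deterministic
        # involution with unit Jacobian and symmetric priors: only the
        # pinned attribute's second-order likelihood changes.
        sa = self.sign_attr
        z_cur = self.beta[sa] * self.theta - self.delta[sa]
        z_new = -z_cur - 2.0 * self.delta[sa]  # beta_sa * (-theta) - delta_sa
        a = self.alpha[:, sa, :]
        dll = float((a * (log_expit(z_new) - log_expit(z_cur))
                     + (1 - a) * (log_expit(-z_new) - log_expit(-z_cur))).sum())
        ap = math.exp(min(0.0, dll))
        if rng.random() < ap:
            self.theta = -self.theta
            self.mu = -self.mu
            flipped = -self.beta
            flipped[sa] = self.beta[sa]
            self.beta = flipped

    # -- monitoring ----------------------------------------------------------
    def monitored_names(self):
        names = []
        if self.fixed_items is None:
            names += [f"lambda0{b}" for b in self.block_names]
            names += [f"lambda1{b}" for b in self.block_names]
        if self.fixed_struct is None:
            names += [f"beta[{k + 1}]" for k in range(self.K)]
            names += [f"delta[{k + 1}]" for k in range(self.K)]
            names += [f"mu[{t + 1}]" for t in range(1, self.T)]
            names += [f"sigma[{t + 1}]" for t in range(1, self.T)]
            names += [f"rho[{a + 1},{b + 1}]" for a, b in self.rho_pairs]
        return names

    def monitored_values(self):
        vals = []
        if self.fixed_items is None:
            l0, l1 = self._gather_blocks()
            vals += [l0, l1]
        if self.fixed_struct is None:
            vals += [self.beta, self.delta, self.mu[1:], self.sd[1:],
                     np.array([self.R[a, b] for a, b in self.rho_pairs])]
        return np.concatenate(vals) if vals else np.empty(0)


def _run_chain(y, q, anchors0, settings, seed, fixed_items, fixed_struct):
    rng = np.random.default_rng(seed)
    ch = _Chain(y, q, anchors0, settings, rng, fixed_items, fixed_struct)
    n_keep = (settings.n_iterations - settings.n_burnin) // settings.thin
    names = ch.monitored_names()
    draws = np.empty((n_keep, len(names)))
    alpha_sum = np.zeros_like(ch.alpha, dtype=np.float64)
    theta_sum = np.zeros_like(ch.theta)
    kept = 0
    for it in range(settings.n_iterations):
        adapting = it < settings.n_burnin
        ch.update_alpha()
        if fixed_items is None:
            ch.update_items(adapting)
        for _ in range(max(1, settings.n_inner_sweeps)):
            ch.update_theta(adapting)
            if fixed_struct is None:
                ch.update_struct_attr(adapting)
                ch.update_struct_growth(adapting)
                ch.update_interweave(adapting)
        if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thin == 0:
            draws[kept] = ch.monitored_values()
            alpha_sum += ch.alpha
            theta_sum += ch.theta
            kept += 1
    rates = {k: v[0] / v[1] for k, v in ch.acc.items() if v[1]}
    return names, draws[:kept], alpha_sum / kept, theta_sum / kept, rates


def run_mcmc(
    data: ResponseData,
    qmat: QMatrixSet,
    anchor=None,
    settings: MCMCSettings | None = None,
    fixed_items: ItemParameters | None = None,
    fixed_struct: StructuralParameters | None = None,
) -> MCMCResult:
    """Sample the joint Long-DINA posterior with Metropolis-within-Gibbs.

    ``anchor`` may be an :class:`~longdina.simulate.AnchorDesign`, an
    iterable of 1-based anchor item indices, or ``None`` (anchors taken from
    ``qmat.anchor_items``).  Anchor items get a single shared parameter pair
    whose update pools likelihood contributions from all occasions.

    ``fixed_items`` / ``fixed_struct`` clamp those parameter blocks at known
    values and sample only the remaining unknowns — used for oracle
    comparisons on toy problems.
    """
    settings = MCMCSettings() if settings is None else settings
    if data.n_items != qmat.n_items or data.n_occasions != qmat.n_occasions:
        raise ValueError("responses and Q-matrix disagree on (I, T)")
    if anchor is None:
        locs = qmat.anchor_items
    elif hasattr(anchor, "anchor_locations"):
        locs = anchor.anchor_locations
    else:
        locs = tuple(anchor)
    anchors0 = [int(l) - 1 for l in locs]

    ss = np.random.SeedSequence(settings.seed)
    child = ss.spawn(settings.n_chains)
    out = [
        _run_chain(data.y, qmat.entries, anchors0, settings, child[c], fixed_items, fixed_struct)
        for c in range(settings.n_chains)
    ]
    names = out[0][0]
    draws = np.stack([o[1] for o in out])
    alpha_mean = np.stack([o[2] for o in out])
    theta_mean = np.stack([o[3] for o in out])
    rates = {k: float(np.mean([o[4][k] for o in out])) for k in out[0][4]}
    return MCMCResult(names, draws, alpha_mean, theta_mean, rates, settings)
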