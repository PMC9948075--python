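"""Classification-accuracy and recovery statistics.

Three rates summarize how well binary attribute profiles are recovered:

* **ACCR** — attribute correct classification rate: the fraction of
  person-replication cells where one attribute's estimated status equals the
  truth at one occasion, ``sum_r sum_n I(alpha_hat = alpha) / (N * Re)``.
* **PCCR** — pattern correct classification rate at one occasion: the
  fraction of persons whose entire K-attribute profile is correct there.
* **LPCCR** — longitudinal PCCR: the fraction of persons whose full
  ``K x T`` attribute array is correct at every occasion (with K=4, T=3 this
  spans 12 attribute statuses per person).

By construction ``pccr(t) <= min_k accr(k, t)`` and
``lpccr <= min_t pccr(t)``.  Replication indicators are pooled before
dividing (denominator ``N * Re``).  Continuous ability recovery is
summarized by bias and root-mean-square error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccuracyReport",
    "accr",
    "pccr",
    "lpccr",
    "theta_rmse",
    "theta_bias",
    "param_recovery",
]


def _check(a, b, name):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"{name}: shapes {a.shape} and {b.shape} differ")
    return a, b


def accr(alpha_true, alpha_hat, k: int | None = None, t: int | None = None):
    """Attribute correct classification rate.

    Arrays have shape ``(..., K, T)`` with leading person/replication axes
    pooled.  ``k`` and ``t`` are 0-based; omit both for the full ``(K, T)``
    table.
    """
    at, ah = _check(alpha_true, alpha_hat, "accr")
    match = (at == ah)
    lead = tuple(range(match.ndim - 2))
    table = match.mean(axis=lead)
    if k is None and t is None:
        return table
    if k is None or t is None:
        return table[:, t] if k is None else table[k, :]
    return float(table[k, t])


def pccr(alpha_true, alpha_hat, t: int | None = None):
    """Per-occasion pattern correct classification rate (whole K-profile)."""
    at, ah = _check(alpha_true, alpha_hat, "pccr")
    ok = (at == ah).all(axis=-2)  # (..., T)
    lead = tuple(range(ok.ndim - 1))
    rates = ok.mean(axis=lead)
    return rates if t is None else float(rates[t])


def lpccr(alpha_true, alpha_hat) -> float:
    """Longitudinal PCCR: all ``K x T`` attribute statuses correct per person."""
    at, ah = _check(alpha_true, alpha_hat, "lpccr")
    ok = (at == ah).all(axis=(-2, -1))
    return float(ok.mean())


def theta_rmse(theta_true, theta_hat, t: int | None = None):
    """Root-mean-square error of ability estimates, per occasion or at ``t``."""
    tt, th = _check(theta_true, theta_hat, "theta_rmse")
    sq = (th - tt) ** 2
    lead = tuple(range(sq.ndim - 1))
    out = np.sqrt(sq.mean(axis=lead))
    return out if t is None else float(out[t])


def theta_bias(theta_true, theta_hat, t: int | None = None):
    """Mean signed error of ability estimates."""
    tt, th = _check(theta_true, theta_hat, "theta_bias")
    err = th - tt
    lead = tuple(range(err.ndim - 1))
    out = err.mean(axis=lead)
    return out if t is None else float(out[t])


def param_recovery(truth: dict, estimates: dict) -> dict[str, tuple[float, float]]:
    """Bias and RMSE per parameter block.

    ``truth`` and ``estimates`` map block names (e.g. ``"lambda0"``,
    ``"beta"``, ``"mu"``) to arrays of equal shape; entries are pooled
    within each block.
    """
    out = {}
    for name, tv in truth.items():
        tv, ev = _check(tv, estimates[name], name)
        err = np.asarray(ev, float) - np.asarray(tv, float)
        out[name] = (float(err.mean()), float(np.sqrt((err ** 2).mean())))
    return out


@dataclass
class AccuracyReport:
    """Aggregated recovery summary for one simulation condition."""

    accr: np.ndarray  # (K, T)
    pccr: np.ndarray  # (T,)
    lpccr: float
    theta_rmse: np.ndarray  # (T,)
    param_bias: dict[str, float] = field(default_factory=dict)
    param_rmse: dict[str, float] = field(default_factory=dict)
    n_replications: int = 1
    n_persons: int = 0
    n_flagged: int = 0  # replications with any monitored PSRF > 1.2

    def __post_init__(self) -> None:
        self.accr = np.asarray(self.accr, float)
        self.pccr = np.asarray(self.pccr, float)
        self.theta_rmse = np.asarray(self.theta_rmse, float)
        for arr in (self.accr, self.pccr):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("classification rates must lie in [0, 1]")

    @property
    def accr_pooled(self) -> float:
        """Equal-weight mean of the per-attribute, per-occasion ACCR cells."""
        return float(self.accr.mean())

    def to_dict(self) -> dict:
        return {
            "accr": self.accr.tolist(),
            "accr_pooled": self.accr_pooled,
            "pccr": self.pccr.tolist(),
            "lpccr": self.lpccr,
            "theta_rmse": self.theta_rmse.tolist(),
            "param_bias": dict(self.param_bias),
            "param_rmse": dict(self.param_rmse),
            "n_replications": self.n_replications,
            "n_persons": self.n_persons,
            "n_flagged": self.n_flagged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AccuracyReport":
        return cls(
            accr=np.asarray(d["accr"]),
            pccr=np.asarray(d["pccr"]),
            lpccr=float(d["lpccr"]),
            theta_rmse=np.asarray(d["theta_rmse"]),
            param_bias=dict(d.get("param_bias", {})),
            param_rmse=dict(d.get("param_rmse", {})),
            n_replications=int(d.get("n_replications", 1)),
            n_persons=int(d.get("n_persons", 0)),
            n_flagged=int(d.get("n_flagged", 0)),
        )
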