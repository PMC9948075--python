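"""Synthetic data generation for Long-DINA anchor-item simulation studies.

Generates complete datasets for a longitudinal learning diagnostic
assessment: per-occasion Q-matrices built as ``(R, R, Q*)`` with two leading
4x4 identity blocks for identifiability, item parameters from a bivariate
normal on the logit scale, abilities from a multivariate-normal growth law,
attributes from the higher-order logistic model, and Bernoulli responses
from the DINA measurement model.

Anchor items — items administered identically at every occasion — keep both
their Q-matrix row and their ``(lambda0, lambda1)`` pair fixed across
occasions; everything else is redrawn per occasion (different test forms
share only the anchors) and regenerated per replication.

Study 1 varies which items are anchors (inside or outside the identity
blocks); Study 2 varies the anchor ratio from 0% to 80%.  The tabulated
designs below are exposed through :func:`build_anchor_design`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np

from .model import (
    ItemParameters,
    PersonLatent,
    QMatrixSet,
    ResponseData,
    StructuralParameters,
    attribute_prob,
    eta_array,
    item_response_prob,
)

__all__ = [
    "AnchorDesign",
    "SimulationConfig",
    "SimulatedDataset",
    "multi_attribute_patterns",
    "build_anchor_design",
    "generate_qmatrix",
    "generate_item_params",
    "build_ability_covariance",
    "generate_persons",
    "generate_responses",
    "simulate_dataset",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class AnchorDesign:
    """One anchor-item condition of Study 1 or Study 2.

    ``anchor_locations`` are 1-based item indices, matching the tabulated
    designs; ``n_unit_blocks_in_anchors`` counts how many of the leading
    identity (unit Q-matrix) blocks fall inside the anchor set.
    """

    study: int
    condition_id: int
    n_items: int
    anchor_locations: tuple[int, ...]
    n_unit_blocks_in_anchors: int
    anchor_ratio: float

    def __post_init__(self) -> None:
        locs = self.anchor_locations
        if len(set(locs)) != len(locs):
            raise ValueError("duplicate anchor locations")
        if locs and (min(locs) < 1 or max(locs) > self.n_items):
            raise ValueError("anchor locations out of range")

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_locations)


def _span(a: int, b: int) -> tuple[int, ...]:
    return tuple(range(a, b + 1))


# Study 1: condition -> (anchor count, unit blocks among anchors, locations).
# Locations are the same for 20- and 30-item forms.
_STUDY1 = {
    1: (4, 0, _span(9, 12)),
    2: (4, 1, _span(1, 4)),
    3: (8, 0, _span(9, 16)),
    4: (8, 1, _span(1, 4) + _span(9, 12)),
    5: (8, 2, _span(1, 8)),
}

# Study 2: (n_items, condition) -> (ratio %, locations).  All nonzero
# conditions anchor exactly one identity block (items 1-4) plus items
# outside the blocks.
_STUDY2 = {
    (20, 1): (0, ()),
    (20, 2): (20, _span(1, 4)),
    (20, 3): (40, _span(1, 4) + _span(9, 12)),
    (20, 4): (60, _span(1, 4) + _span(9, 16)),
    (20, 5): (80, _span(1, 4) + _span(9, 20)),
    (30, 1): (0, ()),
    (30, 2): (20, _span(1, 4) + _span(9, 10)),
    (30, 3): (40, _span(1, 4) + _span(9, 16)),
    (30, 4): (60, _span(1, 4) + _span(9, 22)),
    (30, 5): (80, _span(1, 4) + _span(9, 28)),
}


def build_anchor_design(study: int, condition_id: int, n_items: int) -> AnchorDesign:
    """Look up one tabulated anchor-item condition.

    Study 1 conditions differ in whether anchors sit inside the identity
    blocks; Study 2 conditions differ in the anchor ratio (0-80%).
    """
    if study == 1:
        try:
            count, blocks, locs = _STUDY1[condition_id]
        except KeyError as err:
            raise ValueError(f"unknown Study 1 condition {condition_id}") from err
        if n_items not in (20, 30):
            raise ValueError("Study 1 is defined for 20- or 30-item forms")
        return AnchorDesign(1, condition_id, n_items, locs, blocks, count / n_items)
    if study == 2:
        try:
            ratio, locs = _STUDY2[(n_items, condition_id)]
        except KeyError as err:
            raise ValueError(f"unknown Study 2 condition (I={n_items}, C{condition_id})") from err
        blocks = 1 if locs else 0
        return AnchorDesign(2, condition_id, n_items, locs, blocks, ratio / 100)
    raise ValueError(f"unknown study {study}")


@dataclass
class SimulationConfig:
    """Generating configuration; defaults reproduce the study conditions.

    Item parameters ``(lambda0, lambda1)`` are bivariate normal with means
    ``(-2.197, 4.394)`` (average guessing and slipping near 0.1), unit
    variances and correlation -0.6.  The higher-order structure uses
    ``delta_k = 1.5`` and ``beta = (-1, -0.5, 0.5, 1)``.  Abilities over
    occasions share correlation 0.9, grow by 0.5 per interval in mean and
    inflate their standard deviation by a factor 1.25 per interval.
    """

    n_persons: int = 100
    n_items: int = 20
    n_attrs: int = 4
    n_occasions: int = 3
    design: AnchorDesign | None = None
    n_replications: int = 1
    seed: int = 0
    item_param_mean: tuple[float, float] = (-2.197, 4.394)
    item_param_corr: float = -0.6
    delta_value: float = 1.5
    beta_values: tuple[float, ...] = (-1.0, -0.5, 0.5, 1.0)
    ability_corr: float = 0.9
    mean_growth: float = 0.5
    scale_change: float = 1.25

    def __post_init__(self) -> None:
        if self.n_persons < 0 or self.n_items < 0:
            raise ValueError("n_persons and n_items must be non-negative")
        if len(self.beta_values) != self.n_attrs:
            raise ValueError("beta_values must have length n_attrs")
        if self.design is None:
            self.design = build_anchor_design(1, 2, self.n_items) if self.n_items in (20, 30) else AnchorDesign(1, 0, self.n_items, (), 0, 0.0)


@dataclass
class SimulatedDataset:
    """One replication: generating truth plus the observed responses."""

    config: SimulationConfig
    qmat: QMatrixSet
    items: ItemParameters
    struct: StructuralParameters
    persons: PersonLatent
    responses: ResponseData


def multi_attribute_patterns(n_attrs: int) -> np.ndarray:
    """All binary attribute patterns requiring more than one attribute.

    For K attributes there are ``2**K - 1 - K`` such patterns (11 for K=4);
    these form the candidate pool for the randomly combined Q* rows.
    """
    pats = [p for p in _iterproduct((0, 1), repeat=n_attrs) if sum(p) >= 2]
    return np.array(pats, dtype=np.int8)


def generate_qmatrix(config: SimulationConfig, rng) -> QMatrixSet:
    """Draw one per-occasion Q-matrix set ``Q = (R, R, Q*)``.

    Rows 1..K and K+1..2K at every occasion are identity blocks; the
    remaining Q* rows are i.i.d. uniform draws from the multi-attribute
    pattern pool, redrawn per occasion except for anchor items, whose
    first-occasion row is copied to later occasions.
    """
    rng = _rng(rng)
    I, K, T = config.n_items, config.n_attrs, config.n_occasions
    if I < 2 * K:
        raise ValueError(f"need at least {2 * K} items for the two identity blocks")
    pool = multi_attribute_patterns(K)
    q = np.zeros((I, K, T), dtype=np.int8)
    eye = np.eye(K, dtype=np.int8)
    for t in range(T):
        q[:K, :, t] = eye
        q[K:2 * K, :, t] = eye
        idx = rng.integers(0, len(pool), size=I - 2 * K)
        q[2 * K:, :, t] = pool[idx]
    anchors = config.design.anchor_locations
    for loc in anchors:
        q[loc - 1, :, 1:] = q[loc - 1, :, :1]
    return QMatrixSet(q, anchor_items=anchors)


def generate_item_params(qmat: QMatrixSet, design: AnchorDesign, config: SimulationConfig, rng) -> ItemParameters:
    """Draw ``(lambda0, lambda1)`` pairs from the generating bivariate normal.

    Draws with ``lambda1 <= 0`` (probability ~6e-6 under the defaults) are
    rejection-resampled to preserve monotonicity.  Anchor items are drawn
    once at the first occasion and copied forward.
    """
    rng = _rng(rng)
    I, T = qmat.n_items, qmat.n_occasions
    mean = np.asarray(config.item_param_mean)
    cov = np.array([[1.0, config.item_param_corr], [config.item_param_corr, 1.0]])
    L = np.linalg.cholesky(cov)
    draws = mean + rng.standard_normal((I, T, 2)) @ L.T
    bad = draws[..., 1] <= 0
    while bad.any():
        redraw = mean + rng.standard_normal((int(bad.sum()), 2)) @ L.T
        draws[bad] = redraw
        bad = draws[..., 1] <= 0
    lam0, lam1 = draws[..., 0], draws[..., 1]
    for loc in design.anchor_locations:
        lam0[loc - 1, 1:] = lam0[loc - 1, 0]
        lam1[loc - 1, 1:] = lam1[loc - 1, 0]
    return ItemParameters(lam0, lam1, anchor_items=design.anchor_locations)


def build_ability_covariance(config: SimulationConfig) -> StructuralParameters:
    """Assemble the generating structural parameters.

    Means grow cumulatively by ``mean_growth`` per interval starting at 0;
    standard deviations compound by ``scale_change`` starting at 1; all
    pairwise ability correlations equal ``ability_corr``.
    """
    T = config.n_occasions
    mu = config.mean_growth * np.arange(T, dtype=float)
    sd = config.scale_change ** np.arange(T, dtype=float)
    sigma = config.ability_corr * np.outer(sd, sd)
    np.fill_diagonal(sigma, sd ** 2)
    return StructuralParameters(
        beta=np.asarray(config.beta_values, dtype=float),
        delta=np.full(config.n_attrs, config.delta_value, dtype=float),
        mu=mu,
        sigma_mat=sigma,
    )


def generate_persons(struct: StructuralParameters, config: SimulationConfig, rng) -> PersonLatent:
    """Draw abilities from the T-variate normal and attributes from the logistic link."""
    rng = _rng(rng)
    N, K, T = config.n_persons, config.n_attrs, config.n_occasions
    L = np.linalg.cholesky(struct.sigma_mat)
    theta = struct.mu[None, :] + rng.standard_normal((N, T)) @ L.T
    p = attribute_prob(theta[:, None, :], struct.beta[None, :, None], struct.delta[None, :, None])
    alpha = (rng.random((N, K, T)) < p).astype(np.int8)
    return PersonLatent(theta, alpha)


def generate_responses(persons: PersonLatent, qmat: QMatrixSet, items: ItemParameters, rng) -> ResponseData:
    """Bernoulli responses from the DINA model given latents and item parameters."""
    rng = _rng(rng)
    eta = eta_array(persons.alpha, qmat.entries)
    p = item_response_prob(eta, items.lambda0[None], items.lambda1[None])
    y = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseData(y)


def simulate_dataset(config: SimulationConfig, rng=None) -> SimulatedDataset:
    """Generate one complete replication under ``config``.

    Uses a single seeded generator so a fixed ``config.seed`` yields a
    bit-identical dataset.
    """
    rng = _rng(config.seed if rng is None else rng)
    qmat = generate_qmatrix(config, rng)
    items = generate_item_params(qmat, config.design, config, rng)
    struct = build_ability_covariance(config)
    persons = generate_persons(struct, config, rng)
    responses = generate_responses(persons, qmat, items, rng)
    return SimulatedDataset(config, qmat, items, struct, persons, responses)
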