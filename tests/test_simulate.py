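"""Tests of the synthetic-data generator: designs, moments, invariants."""

import numpy as np
import pytest

from longdina import (
    SimulationConfig,
    attribute_prob,
    build_ability_covariance,
    build_anchor_design,
    generate_item_params,
    generate_persons,
    generate_qmatrix,
    generate_responses,
    guessing_from_params,
    multi_attribute_patterns,
    simulate_dataset,
    slipping_from_params,
)


class TestAnchorDesigns:
    @pytest.mark.parametrize(
        "cond, count, blocks, locs",
        [
            (1, 4, 0, tuple(range(9, 13))),
            (2, 4, 1, tuple(range(1, 5))),
            (3, 8, 0, tuple(range(9, 17))),
            (4, 8, 1, tuple(range(1, 5)) + tuple(range(9, 13))),
            (5, 8, 2, tuple(range(1, 9))),
        ],
    )
    def test_study1_table(self, cond, count, blocks, locs):
        for I in (20, 30):
            d = build_anchor_design(1, cond, I)
            assert (d.n_anchors, d.n_unit_blocks_in_anchors, d.anchor_locations) == (count, blocks, locs)

    @pytest.mark.parametrize(
        "I, cond, ratio, count",
        [(20, 1, 0.0, 0), (20, 2, 0.2, 4), (20, 3, 0.4, 8), (20, 4, 0.6, 12), (20, 5, 0.8, 16),
         (30, 1, 0.0, 0), (30, 2, 0.2, 6), (30, 3, 0.4, 12), (30, 4, 0.6, 18), (30, 5, 0.8, 24)],
    )
    def test_study2_ratios(self, I, cond, ratio, count):
        d = build_anchor_design(2, cond, I)
        assert d.n_anchors == count
        assert d.anchor_ratio == pytest.approx(ratio)
        assert len(set(d.anchor_locations)) == count

    def test_study2_locations_include_one_unit_block(self):
        d20 = build_anchor_design(2, 5, 20)
        assert d20.anchor_locations == tuple(range(1, 5)) + tuple(range(9, 21))
        d30 = build_anchor_design(2, 2, 30)
        assert d30.anchor_locations == (1, 2, 3, 4, 9, 10)

    def test_unknown_combination_raises(self):
        with pytest.raises(ValueError):
            build_anchor_design(2, 6, 20)
        with pytest.raises(ValueError):
            build_anchor_design(3, 1, 20)


def test_pattern_pool_counts():
    """K attributes give 2^K - 1 - K multi-attribute patterns (11 at K=4)."""
    assert len(multi_attribute_patterns(4)) == 11
    assert len(multi_attribute_patterns(3)) == 4
    pool = multi_attribute_patterns(4)
    assert (pool.sum(axis=1) >= 2).all()
    assert len({tuple(p) for p in pool}) == 11


class TestQMatrixGeneration:
    def test_identity_blocks_and_anchor_copies(self):
        cfg = SimulationConfig(n_items=20, seed=1, design=build_anchor_design(1, 2, 20))
        q = generate_qmatrix(cfg, np.random.default_rng(1))
        for t in range(3):
            assert (q.entries[:4, :, t] == np.eye(4)).all()
            assert (q.entries[4:8, :, t] == np.eye(4)).all()
            assert (q.entries[8:, :, t].sum(axis=1) >= 2).all()
        for loc in (1, 2, 3, 4):
            row = q.entries[loc - 1]
            assert (row == row[:, :1]).all()

    def test_non_anchor_qstar_rows_vary_across_occasions(self):
        cfg = SimulationConfig(n_items=20, seed=3, design=build_anchor_design(1, 2, 20))
        q = generate_qmatrix(cfg, np.random.default_rng(3))
        varying = sum(not (q.entries[i] == q.entries[i, :, :1]).all() for i in range(8, 20))
        assert varying > 0  # different test forms share only the anchors

    def test_outside_anchor_rows_fixed_across_occasions(self):
        cfg = SimulationConfig(n_items=20, seed=5, design=build_anchor_design(1, 1, 20))
        q = generate_qmatrix(cfg, np.random.default_rng(5))
        for loc in range(9, 13):
            row = q.entries[loc - 1]
            assert (row == row[:, :1]).all()

    def test_replications_regenerate_qstar(self):
        cfg = SimulationConfig(n_items=20, design=build_anchor_design(1, 2, 20))
        qs = [generate_qmatrix(cfg, np.random.default_rng(s)).entries[8:] for s in range(20)]
        distinct = {q.tobytes() for q in qs}
        assert len(distinct) == 20

    def test_too_few_items_raises(self):
        cfg = SimulationConfig.__new__(SimulationConfig)  # bypass validation
        cfg.n_items, cfg.n_attrs, cfg.n_occasions = 6, 4, 3
        cfg.design = build_anchor_design(1, 1, 20)
        with pytest.raises(ValueError):
            generate_qmatrix(cfg, np.random.default_rng(0))


class TestItemParameters:
    def test_moments_and_anchor_sharing(self):
        cfg = SimulationConfig(n_persons=10, n_items=30, seed=0, design=build_anchor_design(1, 2, 30))
        rng = np.random.default_rng(0)
        q = generate_qmatrix(cfg, rng)
        draws0, draws1 = [], []
        for _ in range(60):
            p = generate_item_params(q, cfg.design, cfg, rng)
            # non-anchor draws only, to avoid double counting shared pairs
            draws0.append(p.lambda0[4:].ravel())
            draws1.append(p.lambda1[4:].ravel())
            for loc in cfg.design.anchor_locations:
                assert (p.lambda0[loc - 1] == p.lambda0[loc - 1, 0]).all()
                assert (p.lambda1[loc - 1] == p.lambda1[loc - 1, 0]).all()
            assert (p.lambda1 > 0).all()
        l0, l1 = np.concatenate(draws0), np.concatenate(draws1)
        n = l0.size  # ~4700 draws: MC error on the mean ~ 1/sqrt(n) ~ 0.015
        assert l0.mean() == pytest.approx(-2.197, abs=4 / np.sqrt(n))
        assert l1.mean() == pytest.approx(4.394, abs=4 / np.sqrt(n))
        assert np.corrcoef(l0, l1)[0, 1] == pytest.approx(-0.6, abs=0.05)

    def test_guessing_slipping_distribution_shape(self):
        """Implied guessing/slipping: mean near 0.1, positively skewed."""
        rng = np.random.default_rng(12)
        cov = np.array([[1.0, -0.6], [-0.6, 1.0]])
        d = np.array([-2.197, 4.394]) + rng.standard_normal((100_000, 2)) @ np.linalg.cholesky(cov).T
        g = guessing_from_params(d[:, 0])
        s = slipping_from_params(d[:, 0], np.abs(d[:, 1]))
        for x in (g, s):
            assert abs(x.mean() - 0.1) < 0.05
            assert np.median(x) < x.mean()  # positive skew
            assert x.min() > 0 and x.max() < 1


class TestAbilityGrowth:
    def test_covariance_construction(self):
        cfg = SimulationConfig(n_occasions=3)
        st = build_ability_covariance(cfg)
        assert np.allclose(st.mu, [0.0, 0.5, 1.0])
        assert np.allclose(np.diag(st.sigma_mat), [1.0, 1.5625, 2.44140625])
        assert st.sigma_mat[0, 1] == pytest.approx(0.9 * 1.25)
        np.linalg.cholesky(st.sigma_mat)

    def test_t1_degenerates_to_standard_normal(self):
        cfg = SimulationConfig(n_occasions=1)
        st = build_ability_covariance(cfg)
        assert st.mu.tolist() == [0.0] and st.sigma_mat.tolist() == [[1.0]]

    def test_theta_moments_large_sample(self):
        cfg = SimulationConfig(n_persons=100_000, seed=9)
        st = build_ability_covariance(cfg)
        p = generate_persons(st, cfg, np.random.default_rng(9))
        se = 1 / np.sqrt(cfg.n_persons)
        assert p.theta[:, 0].mean() == pytest.approx(0.0, abs=4 * se)
        assert p.theta[:, 0].var() == pytest.approx(1.0, abs=6 * se)
        assert np.corrcoef(p.theta[:, 0], p.theta[:, 1])[0, 1] == pytest.approx(0.9, abs=0.01)
        assert p.theta[:, 1].mean() == pytest.approx(0.5, abs=4 * 1.25 * se)

    def test_mastery_rate_matches_quadrature(self):
        """Occasion-1 mastery rates match the integral of the higher-order
        link over the standard-normal ability law."""
        from numpy.polynomial.hermite import hermgauss
        cfg = SimulationConfig(n_persons=100_000, seed=13)
        st = build_ability_covariance(cfg)
        p = generate_persons(st, cfg, np.random.default_rng(13))
        x, w = hermgauss(61)
        theta = np.sqrt(2) * x
        for k in range(4):
            expected = np.dot(w, attribute_prob(theta, st.beta[k], st.delta[k])) / np.sqrt(np.pi)
            observed = p.alpha[:, k, 0].mean()
            assert observed == pytest.approx(expected, abs=4 * np.sqrt(expected * (1 - expected) / cfg.n_persons))

    def test_zero_slope_isolates_difficulty(self):
        cfg = SimulationConfig(n_persons=50_000, seed=4, beta_values=(0.0, 0.0, 0.0, 0.0))
        st = build_ability_covariance(cfg)
        p = generate_persons(st, cfg, np.random.default_rng(4))
        from scipy.special import expit
        assert p.alpha[:, 0, 0].mean() == pytest.approx(expit(-1.5), abs=0.01)


class TestResponses:
    def test_conditional_response_rate(self, small_dataset):
        d = small_dataset
        cfg = SimulationConfig(n_persons=200_000, n_items=20, seed=21, design=d.config.design)
        st = build_ability_covariance(cfg)
        rng = np.random.default_rng(21)
        persons = generate_persons(st, cfg, rng)
        y = generate_responses(persons, d.qmat, d.items, rng)
        from longdina import eta_array, item_response_prob
        eta = eta_array(persons.alpha, d.qmat.entries)
        i, t = 10, 1
        mask = eta[:, i, t] == 1
        expected = item_response_prob(1, d.items.lambda0[i, t], d.items.lambda1[i, t])
        assert y.y[mask, i, t].mean() == pytest.approx(expected, abs=4 * np.sqrt(expected * (1 - expected) / mask.sum()))

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_persons=30, n_items=20, seed=77, design=build_anchor_design(1, 3, 20))
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert (a.responses.y == b.responses.y).all()
        assert (a.qmat.entries == b.qmat.entries).all()
        assert np.array_equal(a.persons.theta, b.persons.theta)


def test_dataset_invariants(small_dataset):
    d = small_dataset
    d.qmat.validate()
    d.items.validate()
    d.struct.validate()
    assert d.responses.y.shape == (50, 20, 3)
    assert set(np.unique(d.responses.y)) <= {0, 1}
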