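"""Sampler tests: PSRF diagnostic, classification rules, oracle agreement,
constraint preservation, and prior recovery (a no-data detailed-balance
check)."""

import numpy as np
import pandas as pd
import pytest

from longdina import (
    ItemParameters,
    MCMCResult,
    MCMCSettings,
    QMatrixSet,
    ResponseData,
    SimulationConfig,
    StructuralParameters,
    attribute_posterior_bruteforce,
    build_anchor_design,
    classify_attributes,
    compute_psrf,
    run_mcmc,
    simulate_dataset,
)


class TestPSRF:
    def test_identical_chains(self):
        """Zero between-chain variance gives sqrt((L-1)/L), reported as-is."""
        chain = np.random.default_rng(0).normal(size=1000)
        val = compute_psrf(np.stack([chain, chain]))
        assert val == pytest.approx(np.sqrt(999 / 1000))

    def test_separated_chains_blow_up(self):
        r = np.random.default_rng(1)
        chains = np.stack([r.normal(0, 1, 1000), r.normal(10, 1, 1000)])
        assert compute_psrf(chains) > 5.0

    def test_same_target_approaches_one(self):
        r = np.random.default_rng(2)
        chains = r.normal(size=(4, 20_000))
        assert compute_psrf(chains) == pytest.approx(1.0, abs=0.005)

    def test_constant_chains(self):
        assert compute_psrf(np.ones((2, 50))) == 1.0

    def test_single_chain_requires_split(self):
        c = np.random.default_rng(3).normal(size=(1, 100))
        with pytest.raises(ValueError):
            compute_psrf(c)
        assert compute_psrf(c, split=True) < 1.1

    def test_short_chains_rejected(self):
        with pytest.raises(ValueError):
            compute_psrf(np.zeros((2, 5)))


class TestClassification:
    def _result(self, alpha_mean):
        am = np.asarray(alpha_mean, float)
        return MCMCResult(names=[], draws=np.zeros((am.shape[0], 10, 0)),
                          alpha_mean=am, theta_mean=np.zeros((am.shape[0], am.shape[1], am.shape[3])),
                          accept_rates={}, settings=MCMCSettings())

    def test_unanimous_and_tie(self):
        # one chain, 1 person, 3 attributes, 1 occasion
        res = self._result(np.array([[[[1.0], [0.5], [0.2]]]]))
        cls = classify_attributes(res)
        assert cls.alpha_posterior[0, 0, 0] == 1.0
        assert cls.alpha_hat[0, :, 0].tolist() == [1, 1, 0]  # tie at 0.5 -> mastery

    def test_chain_pooling(self):
        res = self._result(np.stack([np.full((1, 1, 1), 0.2), np.full((1, 1, 1), 0.9)]))
        cls = classify_attributes(res)
        assert cls.alpha_posterior[0, 0, 0] == pytest.approx(0.55)
        assert cls.alpha_hat[0, 0, 0] == 1


class TestSamplerOracle:
    def test_alpha_posterior_matches_enumeration(self, toy_single):
        """On a K=1, T=1 toy with known parameters, MCMC mastery posteriors
        agree with exhaustive enumeration + quadrature for every person."""
        qmat, items, struct = toy_single
        rng = np.random.default_rng(5)
        # a spread of response patterns, including all-right and all-wrong
        y = np.array([[1, 1, 1, 1], [0, 0, 0, 0], [1, 0, 1, 0], [1, 1, 0, 1],
                      [0, 1, 0, 0], [1, 1, 1, 0]], np.int8)[:, :, None]
        data = ResponseData(y)
        s = MCMCSettings(n_chains=2, n_iterations=4000, n_burnin=500, seed=3)
        res = run_mcmc(data, qmat, (), s, fixed_items=items, fixed_struct=struct)
        cls = classify_attributes(res)
        for n in range(y.shape[0]):
            exact = attribute_posterior_bruteforce(y[n], qmat, items, struct, n_quad=41)
            assert cls.alpha_posterior[n, 0, 0] == pytest.approx(exact[0, 0], abs=0.02)

    def test_two_person_toy(self, toy_single):
        qmat, items, struct = toy_single
        y = np.array([[1, 1, 1, 1], [0, 0, 0, 1]], np.int8)[:, :, None]
        res = run_mcmc(ResponseData(y), qmat, (), MCMCSettings(n_chains=2, n_iterations=4000, n_burnin=500, seed=8),
                       fixed_items=items, fixed_struct=struct)
        cls = classify_attributes(res)
        for n in range(2):
            exact = attribute_posterior_bruteforce(y[n], qmat, items, struct, n_quad=41)
            assert cls.alpha_posterior[n, 0, 0] == pytest.approx(exact[0, 0], abs=0.02)


@pytest.fixture(scope="module")
def short_fit():
    cfg = SimulationConfig(n_persons=60, n_items=20, seed=19, design=build_anchor_design(1, 2, 20))
    d = simulate_dataset(cfg)
    s = MCMCSettings(n_chains=2, n_iterations=400, n_burnin=200, seed=4)
    return d, run_mcmc(d.responses, d.qmat, d.config.design, s)


class TestConstraintPreservation:

    def test_lambda1_positive_in_every_draw(self, short_fit):
        _, res = short_fit
        idx = [j for j, n in enumerate(res.names) if n.startswith("lambda1")]
        assert (res.draws[:, :, idx] > 0).all()

    def test_sigma_positive_and_sign_constraint(self, short_fit):
        _, res = short_fit
        sig = [j for j, n in enumerate(res.names) if n.startswith("sigma")]
        assert (res.draws[:, :, sig] > 0).all()
        last_beta = res.names.index("beta[4]")
        assert (res.draws[:, :, last_beta] > 0).all()

    def test_anchor_items_have_single_shared_block(self, short_fit):
        d, res = short_fit
        # anchors are monitored once, without an occasion index
        for loc in d.config.design.anchor_locations:
            assert f"lambda0[{loc}]" in res.names
            assert f"lambda0[{loc},1]" not in res.names

    def test_rho_draws_in_open_interval(self, short_fit):
        _, res = short_fit
        rho = [j for j, n in enumerate(res.names) if n.startswith("rho")]
        assert (np.abs(res.draws[:, :, rho]) < 1).all()

    def test_rejects_non_binary_data(self, short_fit):
        d, _ = short_fit
        with pytest.raises(ValueError):
            ResponseData(d.responses.y.astype(float) + 0.5)

    def test_dimension_mismatch(self, short_fit):
        d, _ = short_fit
        bad = ResponseData(d.responses.y[:, :-1, :])
        with pytest.raises(ValueError):
            run_mcmc(bad, d.qmat, d.config.design, MCMCSettings(n_iterations=20, n_burnin=10))


class TestPriorRecovery:
    def test_no_data_posterior_is_prior(self):
        """With zero items the posterior equals the prior; the sampled
        structural marginals must match the prior moments.  This exercises
        detailed balance of every structural update, including the
        translation/rescale group moves."""
        N, K, T = 30, 4, 3
        qmat = QMatrixSet(np.zeros((0, K, T), np.int8))
        data = ResponseData(np.zeros((N, 0, T), np.int8))
        s = MCMCSettings(n_chains=2, n_iterations=6000, n_burnin=1000, seed=9, n_inner_sweeps=1)
        res = run_mcmc(data, qmat, (), s)
        pooled = pd.DataFrame(res.draws.reshape(-1, res.draws.shape[2]), columns=res.names)
        # delta_k ~ N(0, 2); loose bands: chains in prior space mix slowly
        for k in range(1, K + 1):
            assert abs(pooled[f"delta[{k}]"].mean()) < 1.0
            assert pooled[f"delta[{k}]"].std() == pytest.approx(2.0, abs=0.6)
        # sigma_t ~ half-normal(2): mean 2*sqrt(2/pi) ~ 1.596, sd ~ 1.206
        for t in (2, 3):
            assert pooled[f"sigma[{t}]"].mean() == pytest.approx(1.596, abs=0.5)
        # sign-pinned slope is half-normal, the rest are centred
        assert (pooled["beta[4]"] > 0).all()
        assert abs(pooled["beta[2]"].mean()) < 1.2


class TestRecoverySmoke:
    def test_item_parameter_recovery_small(self):
        """Posterior means of lambda0 track the generating values on a
        moderate dataset (correlation well above chance)."""
        cfg = SimulationConfig(n_persons=300, n_items=20, seed=23, design=build_anchor_design(1, 2, 20))
        d = simulate_dataset(cfg)
        s = MCMCSettings(n_chains=2, n_iterations=1500, n_burnin=750, seed=6)
        res = run_mcmc(d.responses, d.qmat, d.config.design, s)
        pm = res.posterior_mean
        est, truth = [], []
        for loc in d.config.design.anchor_locations:
            est.append(pm[f"lambda0[{loc}]"])
            truth.append(d.items.lambda0[loc - 1, 0])
        for i in set(range(1, 21)) - set(d.config.design.anchor_locations):
            for t in range(1, 4):
                est.append(pm[f"lambda0[{i},{t}]"])
                truth.append(d.items.lambda0[i - 1, t - 1])
        assert np.corrcoef(est, truth)[0, 1] > 0.85

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_persons=40, n_items=20, seed=31, design=build_anchor_design(1, 2, 20))
        d = simulate_dataset(cfg)
        s = MCMCSettings(n_chains=2, n_iterations=120, n_burnin=60, seed=17)
        a = run_mcmc(d.responses, d.qmat, d.config.design, s)
        b = run_mcmc(d.responses, d.qmat, d.config.design, s)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.alpha_mean, b.alpha_mean)
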