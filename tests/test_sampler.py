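import numpy as np
import pandas as pd
import pytest

from tigerocc.model import (
    GatingMode, LatentState, ModelArrays, ModelParameters,
    enumerate_latent_posterior,
)
from tigerocc.sampler import (
    PosteriorDraws, SamplerConfig, full_conditional_Z, full_conditional_use,
    gelman_rubin, metropolis_update, run_mcmc,
)

from conftest import make_dataset


class TestFullConditionals:
    def test_hand_bayes_for_grid_occupancy(self, zero_params):
        # psi=0.5, one subgrid with z_y=1, p=0.5, n=2, y=0:
        # P(Z=1|...) = 0.5*0.25 / (0.5*0.25 + 0.5*1) = 0.2
        ds = make_dataset({"g1": (0.0,)},
                          {"s1": {"grid_id": "g1", "effort": 2}})
        lat = LatentState(np.array([1]), np.array([1]), np.array([1]))
        prob = full_conditional_Z(zero_params, lat, ds)
        assert prob[0] == pytest.approx(0.2, abs=1e-12)

    def test_detection_forces_occupancy(self, one_cell_dataset, zero_params,
                                        all_ones_latent):
        prob = full_conditional_Z(zero_params, all_ones_latent(1, 1),
                                  one_cell_dataset)
        assert prob[0] == 1.0

    def test_no_effort_returns_prior(self, zero_params):
        p = ModelParameters.zeros()
        p.b[0] = 1.3
        ds = make_dataset({"g1": (0.0,)},
                          {"s1": {"grid_id": "g1", "effort": 0}})
        lat = LatentState(np.array([1]), np.array([1]), np.array([1]))
        from tigerocc.model import inv_logit
        assert full_conditional_Z(p, lat, ds)[0] == pytest.approx(
            inv_logit(1.3), abs=1e-12)

    def test_use_conditional_matches_enumeration(self, small_dataset):
        """Gibbs conditional for each use bit agrees with the conditional
        computed from the enumeration oracle."""
        rng = np.random.default_rng(3)
        params = ModelParameters.from_vector(rng.normal(scale=0.7, size=20))
        arrays = ModelArrays.from_dataset(small_dataset)
        lat = LatentState(np.ones(2, np.int8),
                          np.array([1, 0, 1, 1], np.int8),
                          np.array([1, 0, 0, 1], np.int8))
        from tigerocc.model import complete_data_loglik
        for species, bits in (("prey", "z_x"), ("tiger", "z_y")):
            got = full_conditional_use(params, lat, arrays, species)
            for j in range(arrays.n_subgrids):
                lls = {}
                for v in (0, 1):
                    l2 = LatentState(lat.Z.copy(), lat.z_x.copy(),
                                     lat.z_y.copy())
                    getattr(l2, bits)[j] = v
                    lls[v] = complete_data_loglik(params, l2, arrays)
                if np.isinf(lls[0]) and np.isinf(lls[1]):
                    continue
                expected = 1.0 / (1.0 + np.exp(lls[0] - lls[1]))
                assert got[j] == pytest.approx(expected, abs=1e-10), \
                    (species, j)


class TestMetropolis:
    def _setup(self, seed=0):
        ds = make_dataset(
            {"g1": (0.3,), "g2": (-0.3,)},
            {"s1": {"grid_id": "g1", "effort": 5, "tiger_det": 2,
                    "prey_det": 3},
             "s2": {"grid_id": "g2", "effort": 4}})
        arrays = ModelArrays.from_dataset(ds)
        lat = LatentState(np.ones(2, np.int8), np.ones(2, np.int8),
                          np.ones(2, np.int8))
        return arrays, lat, np.random.default_rng(seed)

    def test_out_of_bounds_proposal_rejected(self):
        arrays, lat, rng = self._setup()
        theta = np.zeros(20)
        theta[0] = 9.99  # near the prior bound; a huge step must reject
        new, accepted = metropolis_update(
            "grid_occupancy", theta, arrays, lat, GatingMode.TIGER_GATED,
            scale=100.0, prior_bound=10.0, rng=rng)
        assert not accepted
        np.testing.assert_array_equal(new, theta)

    def test_zero_delta_always_accepted(self):
        # a zero-scale step proposes the current point: ratio 1, accept
        arrays, lat, rng = self._setup()
        theta = np.zeros(20)
        accepted_any = [metropolis_update(
            "tiger_detection", theta, arrays, lat, GatingMode.TIGER_GATED,
            scale=1e-300, prior_bound=10.0, rng=rng)[1] for _ in range(20)]
        assert all(accepted_any)

    def test_acceptance_rate_lands_in_adaptation_band(self):
        """After burn-in adaptation the per-block acceptance stays in the
        0.2-0.5 target band on a small fixture."""
        ds = make_dataset(
            {f"g{i}": ((-1) ** i * 0.5,) for i in range(8)},
            {f"s{i}": {"grid_id": f"g{i % 8}", "effort": 6,
                       "tiger_det": (i % 3 == 0) * 2,
                       "prey_det": (i % 2) * 3,
                       "ndvi": (-1) ** i * 0.7} for i in range(24)})
        cfg = SamplerConfig(iterations=1500, burn_in=700, thin=2, chains=1,
                            seed=11)
        draws = run_mcmc(ds, cfg)
        rates = [v for v in draws.accept_rates["chain_0"].values()]
        assert all(0.15 < r < 0.6 for r in rates), rates


class TestRunMcmc:
    def test_retention_arithmetic(self, small_dataset):
        cfg = SamplerConfig(iterations=300, burn_in=100, thin=10, chains=2,
                            seed=5)
        draws = run_mcmc(small_dataset, cfg)
        assert draws.draws.shape == (2, 20, 20)
        assert np.all(np.abs(draws.draws) <= cfg.prior_bound)

    def test_default_config_keeps_750_per_chain(self):
        cfg = SamplerConfig()
        assert cfg.draws_per_chain == 750
        assert cfg.chains == 3

    def test_same_seed_reproduces_exactly(self, small_dataset):
        cfg = SamplerConfig(iterations=200, burn_in=50, thin=5, chains=2,
                            seed=42)
        d1 = run_mcmc(small_dataset, cfg)
        d2 = run_mcmc(small_dataset, cfg)
        np.testing.assert_array_equal(d1.draws, d2.draws)
        np.testing.assert_array_equal(d1.p_tiger_use, d2.p_tiger_use)

    def test_different_seeds_differ(self, small_dataset):
        cfg = SamplerConfig(iterations=200, burn_in=50, thin=5, chains=1,
                            seed=1)
        d1 = run_mcmc(small_dataset, cfg)
        d2 = run_mcmc(small_dataset, SamplerConfig(
            iterations=200, burn_in=50, thin=5, chains=1, seed=2))
        assert not np.array_equal(d1.draws, d2.draws)

    def test_unstandardized_data_refused(self, small_dataset):
        ds = small_dataset.copy()
        ds.scaling = None
        with pytest.raises(ValueError, match="standardize"):
            run_mcmc(ds, SamplerConfig(iterations=20, burn_in=10, chains=2,
                                       thin=1))

    def test_gibbs_marginal_matches_enumeration_small(self, small_dataset):
        """At fixed true coefficients, the Gibbs-sampled P(Z=1|data) agrees
        with the enumeration oracle (quick single-seed version)."""
        rng = np.random.default_rng(8)
        params = ModelParameters.from_vector(rng.normal(scale=0.5, size=20))
        oracle = enumerate_latent_posterior(params, small_dataset)
        cfg = SamplerConfig(iterations=4000, burn_in=500, thin=1, chains=2,
                            seed=99)
        draws = run_mcmc(small_dataset, cfg, fixed_params=params)
        np.testing.assert_allclose(draws.p_occupancy, oracle["Z"], atol=0.05)
        np.testing.assert_allclose(draws.p_prey_use, oracle["z_x"], atol=0.05)

    def test_draws_round_trip_via_csv(self, small_dataset, tmp_path):
        cfg = SamplerConfig(iterations=120, burn_in=20, thin=5, chains=2,
                            seed=3)
        draws = run_mcmc(small_dataset, cfg)
        draws.save(tmp_path)
        back = PosteriorDraws.load(tmp_path)
        np.testing.assert_allclose(back.draws, draws.draws, atol=1e-12)
        assert back.param_names == draws.param_names
        np.testing.assert_allclose(back.p_occupancy, draws.p_occupancy,
                                   atol=1e-12)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((1, 200, 3))
        arr = np.concatenate([chain, chain], axis=0)
        rep = gelman_rubin(arr)
        assert (rep.r_hat <= 1.01).all()

    def test_disjoint_constant_chains_diverge(self):
        arr = np.stack([np.zeros((100, 1)), np.ones((100, 1))])
        rep = gelman_rubin(arr)
        assert rep.r_hat.iloc[0] > 1.1
        assert not rep.converged

    def test_iid_normal_draws_converge(self):
        rng = np.random.default_rng(123)
        arr = rng.standard_normal((3, 750, 4))
        rep = gelman_rubin(arr)
        assert (rep.r_hat < 1.05).all()
        assert rep.converged

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.zeros((1, 100, 2)))

    def test_matches_arviz_on_random_draws(self):
        """Cross-check the split-R-hat against arviz's classic (non
        rank-normalized) implementation."""
        import arviz as az
        rng = np.random.default_rng(7)
        arr = rng.standard_normal((3, 200, 2)) + \
            0.3 * rng.standard_normal((3, 1, 2))
        rep = gelman_rubin(arr)
        ref = az.rhat(az.convert_to_dataset(arr), method="split")
        ours = rep.r_hat.to_numpy()
        theirs = ref.to_array().to_numpy().ravel()
        np.testing.assert_allclose(ours, theirs, atol=0.01)
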