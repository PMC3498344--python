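"""Joint posterior assembly, sampler contracts, diagnostics, derived
quantities and projection."""

import warnings

import numpy as np
import pytest

from kiteipm.inference import (
    McmcConfig,
    PosteriorChains,
    component_logliks,
    derived_quantities,
    gelman_rubin,
    log_joint,
    project,
    run_mcmc,
)
from kiteipm.inference import _ChEvaluator
from kiteipm.multistate import ch_loglik
from kiteipm.simulate import ScenarioConfig, generate


def _truth_state(cfg: ScenarioConfig, truth):
    names = ("phi", "m_juv", "m_1y", "m_2my", "rho1", "rho2", "rho3",
             "p", "pA", "rP", "rO", "gamma")
    s = {k: getattr(cfg, k) for k in names}
    s["mu"] = np.log(cfg.mean_f)
    s["sigma"] = np.sqrt(cfg.sigma2_f)
    s["logf"] = np.log(np.array(truth.f))
    s["N"] = np.array(truth.trajectory)
    s["x"] = np.column_stack([truth.xP, truth.xO])
    return s


@pytest.fixture(scope="module")
def bundle_truth():
    cfg = ScenarioConfig()
    bundle, truth = generate(cfg, seed=42)
    return cfg, bundle, truth


class TestLogJoint:
    def test_ms_variant_is_ch_loglik(self, bundle_truth):
        """Under flat priors the MS joint density is exactly the
        multistate likelihood."""
        cfg, bundle, truth = bundle_truth
        s = _truth_state(cfg, truth)
        got = log_joint(s, bundle, "MS")
        assert got == pytest.approx(ch_loglik(bundle.histories, cfg.ms_params()))

    def test_variant_nesting_difference_is_recovery_component(self, bundle_truth):
        cfg, bundle, truth = bundle_truth
        s = _truth_state(cfg, truth)
        comp2 = component_logliks(s, bundle, "IPM2")
        comp1 = component_logliks(s, bundle, "IPM1")
        assert set(comp2) - set(comp1) == {"recov"}
        assert log_joint(s, bundle, "IPM2") - log_joint(s, bundle, "IPM1") == (
            pytest.approx(comp2["recov"])
        )

    def test_joint_is_sum_of_components(self, bundle_truth):
        cfg, bundle, truth = bundle_truth
        s = _truth_state(cfg, truth)
        comps = component_logliks(s, bundle, "IPM2")
        assert log_joint(s, bundle, "IPM2") == pytest.approx(sum(comps.values()))

    def test_finite_at_generating_truth(self, bundle_truth):
        cfg, bundle, truth = bundle_truth
        s = _truth_state(cfg, truth)
        for variant in ("MS", "IPM1", "IPM2"):
            assert np.isfinite(log_joint(s, bundle, variant))

    def test_gamma_prior_sensitivity_options(self, bundle_truth):
        """The two truncated-normal gamma priors shift the joint density
        relative to the flat default by exactly the prior log-density."""
        cfg, bundle, truth = bundle_truth
        s = _truth_state(cfg, truth)
        base = log_joint(s, bundle, "IPM1", McmcConfig(gamma_prior="uniform"))
        wide = log_joint(s, bundle, "IPM1", McmcConfig(gamma_prior="tnorm_wide"))
        tight = log_joint(
            s, bundle, "IPM1", McmcConfig(gamma_prior="tnorm_informative")
        )
        from scipy import stats

        assert wide - base == pytest.approx(
            stats.norm.logpdf(s["gamma"], 0.75, np.sqrt(1000.0)), abs=1e-8
        )
        assert tight - base == pytest.approx(
            stats.norm.logpdf(s["gamma"], 0.5, 0.5), abs=1e-8
        )
        with pytest.raises(ValueError):
            McmcConfig(gamma_prior="bogus")

    def test_fast_evaluator_matches_reference_likelihood(self, bundle_truth):
        cfg, bundle, _ = bundle_truth
        ev = _ChEvaluator(bundle.histories)
        for seed in range(3):
            r = np.random.default_rng(seed)
            from conftest import random_ms_params

            p = random_ms_params(r)
            assert ev(p) == pytest.approx(
                ch_loglik(bundle.histories, p), rel=1e-12
            )


class TestRunMcmc:
    def test_same_seed_bit_identical(self, bundle_truth):
        _, bundle, _ = bundle_truth
        cfgm = McmcConfig(chains=2, iterations=60, burn_in=30, thin=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_mcmc(bundle, "MS", cfgm)
            b = run_mcmc(bundle, "MS", cfgm)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_nonconvergence_reported(self, bundle_truth):
        _, bundle, _ = bundle_truth
        cfgm = McmcConfig(chains=2, iterations=40, burn_in=10, thin=1, seed=1)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            chains = run_mcmc(bundle, "MS", cfgm)
        assert "not_converged" in chains.meta
        if chains.meta["not_converged"]:
            assert any("R-hat" in str(w.message) for w in caught)

    def test_ipm2_requires_recoveries(self, bundle_truth):
        _, bundle, _ = bundle_truth
        import dataclasses

        stripped = dataclasses.replace(bundle, recoveries=None)
        with pytest.raises(ValueError, match="recover"):
            run_mcmc(stripped, "IPM2", McmcConfig(chains=1, iterations=10, burn_in=1))

    def test_summary_schema(self, bundle_truth):
        _, bundle, _ = bundle_truth
        cfgm = McmcConfig(chains=2, iterations=60, burn_in=30, thin=2, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chains = run_mcmc(bundle, "IPM2", cfgm)
        df = chains.summary()
        assert {"parameter", "mean", "sd", "q2.5", "q97.5", "rhat"} <= set(df.columns)
        assert {"phi", "gamma", "sigma2", "mean_f"} <= set(df["parameter"])


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rng):
        # constant chains: degenerate case, defined as exactly 1
        const = np.ones((3, 100))
        assert gelman_rubin({"a": const})["a"] == 1.0
        # identical stationary chains: no between-chain component
        x = np.tile(rng.normal(size=200), (3, 1))
        assert gelman_rubin({"a": x})["a"] == pytest.approx(1.0, abs=0.05)

    def test_shifted_chains_flagged(self, rng):
        x = rng.normal(0, 1, size=(3, 200))
        x[0] += 5.0
        assert gelman_rubin({"a": x})["a"] > 1.1

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.normal(0, 1, size=(4, 500)) + rng.normal(0, 0.3, size=(4, 1))
        got = gelman_rubin({"a": x})["a"]
        want = az.rhat(
            az.convert_to_dataset(x[..., None]), method="split"
        )["x"].values.item()
        assert got == pytest.approx(want, abs=1e-6)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin({"a": rng.normal(size=(1, 50))})


def _constant_chains(n=2000, N_last=(40, 30, 100)):
    """Degenerate posterior: every draw identical — isolates the
    stochastic projection machinery."""
    T = 3
    params = {
        "phi": np.full((1, n), 0.808),
        "m_juv": np.full((1, n), 0.428),
        "m_1y": np.full((1, n), 0.764),
        "m_2my": np.full((1, n), 0.764),
        "gamma": np.full((1, n), 0.631),
        "mu": np.full((1, n), np.log(1.825)),
        "sigma": np.full((1, n), 1e-6),
    }
    latent = np.tile(np.array(N_last, dtype=float), (1, n, T, 1))
    return PosteriorChains(params=params, latent_N=latent, f=None)


class TestDerivedQuantities:
    def test_poison_free_survival_row(self, bundle_truth):
        chains = _constant_chains(n=10)
        dq = derived_quantities(chains)
        assert dq["draws"]["phi_star_juv"][0] == pytest.approx(0.890, abs=5e-4)
        assert dq["draws"]["phi_star_2my"][0] == pytest.approx(0.955, abs=5e-4)

    def test_delta_algebraic_inverse(self, rng):
        n = 200
        phi = rng.uniform(0.3, 0.95, n)
        m = rng.uniform(0, 1, n)
        chains = PosteriorChains(
            params={
                "phi": phi[None], "m_juv": m[None], "m_1y": m[None],
                "m_2my": m[None],
            },
            latent_N=None, f=None,
        )
        dq = derived_quantities(chains)
        star = dq["draws"]["phi_star_juv"]
        delta = dq["draws"]["delta_juv"]
        np.testing.assert_allclose(star * (1 - delta), phi, atol=1e-12)

    def test_zero_poison_fraction_leaves_survival(self):
        chains = PosteriorChains(
            params={
                "phi": np.full((1, 5), 0.808),
                "m_juv": np.zeros((1, 5)),
                "m_1y": np.zeros((1, 5)),
                "m_2my": np.zeros((1, 5)),
            },
            latent_N=None, f=None,
        )
        dq = derived_quantities(chains)
        np.testing.assert_allclose(dq["draws"]["phi_star_juv"], 0.808)

    def test_lambda_geometric_mean(self):
        latent = np.zeros((1, 1, 3, 3))
        latent[0, 0, :, 2] = [100, 110, 121]
        chains = PosteriorChains(
            params={"phi": np.full((1, 1), 0.8), "m_juv": np.zeros((1, 1)),
                    "m_1y": np.zeros((1, 1)), "m_2my": np.zeros((1, 1))},
            latent_N=latent, f=None,
        )
        dq = derived_quantities(chains)
        assert dq["draws"]["lambda_bar"][0] == pytest.approx(1.1, rel=1e-10)

    def test_zero_population_recorded_as_undefined(self):
        latent = np.zeros((1, 1, 3, 3))
        chains = PosteriorChains(
            params={"phi": np.full((1, 1), 0.8), "m_juv": np.zeros((1, 1)),
                    "m_1y": np.zeros((1, 1)), "m_2my": np.zeros((1, 1))},
            latent_N=latent, f=None,
        )
        dq = derived_quantities(chains)
        summ = dq["summary"].set_index("quantity")
        assert summ.loc["lambda_bar", "n_undefined"] == 1


class TestProject:
    def test_zero_horizon_returns_filtered_state(self):
        chains = _constant_chains(n=50)
        proj = project(chains, horizon_years=0, seed=0)
        np.testing.assert_allclose(proj["Ntot"][:, 0], 170.0)

    def test_interval_widens_with_horizon(self):
        chains = _constant_chains(n=4000)
        proj = project(chains, horizon_years=4, seed=1)
        width = proj["summary"]["Ntot_hi"] - proj["summary"]["Ntot_lo"]
        assert (np.diff(width) >= -1e-9).all()
        assert width.iloc[-1] > width.iloc[1]

    def test_mean_tracks_matrix_power(self):
        """With degenerate parameter draws the projection mean follows the
        deterministic Leslie iterate A^h @ N."""
        from kiteipm.leslie import VitalRates, build_matrix

        chains = _constant_chains(n=20000)
        proj = project(chains, horizon_years=3, seed=2)
        v = VitalRates(0.808, 0.808, 0.808, f=1.825, gamma=0.631, beta2=0.1)
        A = build_matrix(v)
        N = np.array([40.0, 30.0, 100.0])
        for h in range(4):
            want = (np.linalg.matrix_power(A, h) @ N).sum()
            got = proj["Ntot"][:, h].mean()
            assert got == pytest.approx(want, rel=0.02), h

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            project(_constant_chains(n=5), horizon_years=-1)
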