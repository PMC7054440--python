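import itertools

import numpy as np
import pytest
from scipy.special import expit

from rotdiag.data_model import QMatrix, ResponseDataset
from rotdiag.joint_model import (
    MCMCConfig,
    PosteriorDraws,
    SpeedCoefficients,
    TransitionCoefficients,
    estimate_trajectories,
    joint_log_likelihood,
    max_psrf,
    posterior_summary,
    psrf,
    rt_log_density,
    run_mcmc,
    transition_probability,
)


class TestTransitionProbability:
    def test_zero_coefficients_give_half(self):
        lam = TransitionCoefficients(np.zeros(12))
        assert transition_probability((0, 0, 0, 0), 0, 0.0, np.zeros(5), lam) == 0.5

    def test_worked_logistic_example(self):
        lam = TransitionCoefficients.from_dict(
            {"lambda_0": -1.0, "lambda_theta": 2.821, "lambda_alpha": 0.471})
        p = transition_probability((1, 1, 0, 0), 2, 0.5, np.zeros(5), lam)
        assert p == pytest.approx(0.7945, abs=5e-5)

    def test_mastery_is_absorbing(self):
        lam = TransitionCoefficients(np.full(12, -50.0))
        assert transition_probability((1, 0, 0, 0), 0, 0.0, np.zeros(5), lam) == 1.0

    def test_covariate_main_effects_enter_linearly(self):
        lam = TransitionCoefficients.from_dict({"lambda_gender": 1.0})
        p = transition_probability((0, 0, 0, 0), 0, 0.0, np.array([1, 0, 0, 0, 0]), lam)
        assert p == pytest.approx(expit(1.0))


class TestRTLogDensity:
    def test_density_peaks_at_exp_gamma(self):
        phi = SpeedCoefficients(np.zeros(10))
        args = dict(alpha_t=(0, 0, 0, 0), q_row=(1, 0, 0, 0), gamma=3.0, a=2.0,
                    tau=0.0, cov5=np.zeros(5), phi=phi)
        at_mode = rt_log_density(np.exp(3.0), **args)
        for ell in (np.exp(2.5), np.exp(3.5)):
            assert rt_log_density(ell, **args) < at_mode

    def test_worked_moment_example(self):
        # gamma=3.288, a=1.657, tau=0.2, phi_alpha=-0.327, G=1:
        # mean log L = 3.415, var = 0.6035
        phi = SpeedCoefficients.from_dict({"phi_alpha": -0.327})
        dens = rt_log_density(np.exp(3.415), (1, 1, 1, 1), (1, 0, 0, 0),
                              gamma=3.288, a=1.657, tau=0.2, cov5=np.zeros(5), phi=phi)
        # normal logpdf at its mean with variance 1/1.657
        assert dens == pytest.approx(-0.5 * np.log(2 * np.pi / 1.657), abs=1e-10)

    def test_mastery_slows_responses_with_negative_phi_alpha(self):
        # phi_alpha = -0.327 means G: 0 -> 1 raises mean log-time by 0.327
        phi = SpeedCoefficients.from_dict({"phi_alpha": -0.327})
        base = dict(q_row=(1, 0, 0, 0), gamma=3.0, a=1.0, tau=0.0,
                    cov5=np.zeros(5), phi=phi)
        slow = np.exp(3.0 + 0.327)
        assert (rt_log_density(slow, (1, 1, 1, 1), **base)
                > rt_log_density(slow, (0, 0, 0, 0), **base))

    def test_nonpositive_time_rejected(self):
        phi = SpeedCoefficients(np.zeros(10))
        with pytest.raises(ValueError):
            rt_log_density(0.0, (1, 0, 0, 0), (1, 0, 0, 0), 3.0, 1.0, 0.0,
                           np.zeros(5), phi)


def _toy_problem():
    """1-person, K=2-style toy embedded in the K=4 machinery: 2 modules."""
    rng = np.random.default_rng(0)
    q = QMatrix(entries=np.array([[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0]]),
                module_of_item=np.array([1, 1, 2]))
    n, j = 2, 3
    ds = ResponseDataset(Y=rng.integers(0, 2, (n, j)),
                         L=np.exp(rng.normal(3, 0.5, (n, j))),
                         module_of_item=q.module_of_item)
    params = {
        "s": np.array([0.2, 0.15, 0.25]),
        "g": np.array([0.3, 0.35, 0.2]),
        "gamma": np.array([3.1, 2.9, 3.3]),
        "a": np.array([1.5, 2.0, 1.2]),
        "theta": np.array([0.4, -0.6]),
        "tau": np.array([0.1, -0.2]),
        "lam": TransitionCoefficients.from_dict(
            {"lambda_0": -0.5, "lambda_theta": 1.2, "lambda_alpha": 0.4,
             "lambda_gender": 0.3}),
        "phi": SpeedCoefficients.from_dict(
            {"phi_alpha": -0.3, "phi_gender": -0.1, "phi_country": 0.1}),
        "beta0": np.array([0.2, -0.1, 0.0, 0.3]),
        "beta_theta": np.array([1.0, 1.5, 0.8, 1.2]),
    }
    cov5 = np.array([[1, 0, 1, 0, 0], [0, 1, 0, 1, 0]], dtype=float)
    return ds, q, params, cov5


class TestJointLogLikelihood:
    def test_components_sum_to_total(self):
        ds, q, params, cov5 = _toy_problem()
        alpha = np.zeros((2, 4, 2), dtype=np.int8)
        alpha[:, :, 1] = 1
        comp = joint_log_likelihood(ds, q, alpha, params, cov5)
        parts = comp["accuracy"] + comp["response_time"] + comp["transition"] + comp["initial"]
        assert comp["total"] == pytest.approx(parts, abs=1e-12)

    def test_coin_flip_items_contribute_log_half(self):
        ds, q, params, cov5 = _toy_problem()
        params = dict(params)
        params["s"] = np.full(3, 0.5)
        params["g"] = np.full(3, 0.5)
        alpha = np.zeros((2, 4, 2), dtype=np.int8)
        comp = joint_log_likelihood(ds, q, alpha, params, cov5)
        assert comp["accuracy"] == pytest.approx(2 * 3 * np.log(0.5), abs=1e-10)

    def test_marginal_matches_enumeration_oracle(self):
        # sum of exp(joint loglik) over all monotone trajectories must
        # equal an independently coded brute-force marginal
        ds, q, params, cov5 = _toy_problem()

        def oracle_marginal(person):
            from scipy import stats as st

            total = 0.0
            for bits1 in itertools.product((0, 1), repeat=4):
                for bits2 in itertools.product((0, 1), repeat=4):
                    if any(b1 > b2 for b1, b2 in zip(bits1, bits2)):
                        continue
                    prob = 1.0
                    th = params["theta"][person]
                    # initial law
                    for k in range(4):
                        pk = expit(params["beta0"][k] + params["beta_theta"][k] * th)
                        prob *= pk if bits1[k] else 1 - pk
                    # transition law
                    x9 = np.array([cov5[person, 0], cov5[person, 1], cov5[person, 2],
                                   cov5[person, 3], cov5[person, 4],
                                   cov5[person, 0] * cov5[person, 2],
                                   cov5[person, 1] * cov5[person, 2],
                                   cov5[person, 2] * cov5[person, 3],
                                   cov5[person, 2] * cov5[person, 4]])
                    v = params["lam"].values
                    for k in range(4):
                        if bits1[k] == 1:
                            continue
                        pt = expit(v[0] + v[1] * th + v[2] * sum(bits1) + x9 @ v[3:])
                        prob *= pt if bits2[k] else 1 - pt
                    # observations
                    for t, bits in enumerate((bits1, bits2)):
                        for j in np.flatnonzero(q.module_of_item == t + 1):
                            dom = all(b >= qq for b, qq in zip(bits, q.entries[j]))
                            pj = 1 - params["s"][j] if dom else params["g"][j]
                            yij = ds.Y[person, j]
                            prob *= pj if yij else 1 - pj
                            mean = params["gamma"][j] - (
                                params["tau"][person]
                                + params["phi"].values[0] * dom
                                + x9 @ params["phi"].values[1:])
                            prob *= st.norm.pdf(np.log(ds.L[person, j]), mean,
                                                np.sqrt(1 / params["a"][j]))
                    total += prob
            return np.log(total)

        # marginal via the package: logsumexp over enumerated trajectories
        from scipy.special import logsumexp

        for person in range(2):
            sub = ResponseDataset(Y=ds.Y[[person]], L=ds.L[[person]],
                                  module_of_item=ds.module_of_item)
            vals = []
            pp = dict(params)
            pp["theta"] = params["theta"][[person]]
            pp["tau"] = params["tau"][[person]]
            for bits1 in itertools.product((0, 1), repeat=4):
                for bits2 in itertools.product((0, 1), repeat=4):
                    if any(b1 > b2 for b1, b2 in zip(bits1, bits2)):
                        continue
                    alpha = np.zeros((1, 4, 2), dtype=np.int8)
                    alpha[0, :, 0] = bits1
                    alpha[0, :, 1] = bits2
                    vals.append(joint_log_likelihood(sub, q, alpha, pp,
                                                     cov5[[person]])["total"])
            assert logsumexp(vals) == pytest.approx(oracle_marginal(person), abs=1e-8)


class TestPSRF:
    def test_identical_chains_shrink_below_one(self):
        assert psrf([[1, 2, 3], [1, 2, 3]]) == pytest.approx(np.sqrt(2 / 3))

    def test_hand_computed_example(self):
        # chains [1,2] and [2,3]: B=1, W=0.5, var+=0.75 -> sqrt(1.5)
        assert psrf([[1, 2], [2, 3]]) == pytest.approx(np.sqrt(1.5), abs=1e-12)

    def test_zero_within_variance_reports_infinity(self):
        assert psrf([[1, 1], [2, 2]]) == np.inf

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            psrf([[1, 2, 3]])


class TestPosteriorSummary:
    def _draws_from(self, arr):
        cfg = MCMCConfig(n_chains=2, n_iter=4, burn_in=2, seeds=(1, 2))
        params = {"lambda_theta": np.asarray(arr)}
        return PosteriorDraws(params=params, alpha=np.zeros((2, 2, 1, 4, 4), dtype=np.int8),
                              theta=np.zeros((2, 2, 1)), tau=np.zeros((2, 2, 1)),
                              config=cfg, monitored=("lambda_theta",))

    def test_constant_chain(self):
        s = posterior_summary(self._draws_from([[3.0, 3.0], [3.0, 3.0]]))
        row = s.loc["lambda_theta"]
        assert row["mean"] == 3.0 and row["sd"] == 0.0
        assert row["lower_95"] == row["upper_95"] == 3.0

    def test_standard_normal_interval(self, rng):
        z = rng.standard_normal((2, 100_000))
        s = posterior_summary(self._draws_from(z))
        row = s.loc["lambda_theta"]
        assert row["lower_95"] == pytest.approx(-1.96, abs=0.03)
        assert row["upper_95"] == pytest.approx(1.96, abs=0.03)
        assert not row["significant"]


@pytest.fixture(scope="module")
def tiny_fit(default_cohort):
    co = default_cohort
    sub = ResponseDataset(Y=co.dataset.Y[:80], L=co.dataset.L[:80],
                          module_of_item=co.dataset.module_of_item)
    cfg = MCMCConfig(n_chains=2, n_iter=120, burn_in=60, seeds=(5, 6))
    return sub, co.covariates.iloc[:80], co.q, cfg


class TestMCMCMechanics:
    def test_zero_iteration_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=2, n_iter=0)

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=2, n_iter=10, seeds=(1, 1))

    def test_determinism_and_constraints(self, tiny_fit):
        ds, cov, q, cfg = tiny_fit
        d1 = run_mcmc(ds, cov, q, cfg)
        d2 = run_mcmc(ds, cov, q, cfg)
        np.testing.assert_array_equal(d1.params["lam"], d2.params["lam"])
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        # constraints on every draw
        assert (1 - d1.params["s"] - d1.params["g"] > 0).all()
        assert (d1.params["a"] > 0).all()
        assert (np.diff(d1.alpha, axis=4) >= 0).all()

    def test_trajectory_estimates_are_monotone(self, tiny_fit):
        ds, cov, q, cfg = tiny_fit
        draws = run_mcmc(ds, cov, q, cfg)
        est = estimate_trajectories(draws)
        assert (np.diff(est["map"], axis=2) >= 0).all()
        rates = est["mastery_rates"]
        assert (np.diff(rates, axis=1) >= -1e-12).all()
        dist = est["skill_count_distribution"]
        np.testing.assert_allclose(dist.sum(axis=1), 1.0)

    def test_noiseless_items_identify_true_trajectories(self, small_cohort):
        from rotdiag.synthetic_data import ItemBank, simulate_responses_and_times

        co = small_cohort
        items = ItemBank(q=co.q, s=np.full(40, 1e-4), g=np.full(40, 1e-4),
                         gamma=co.items.gamma, a=co.items.a)
        ds = simulate_responses_and_times(co.alpha, items, co.covariates,
                                          co.tau, co.config.phi, seed=9)
        cfg = MCMCConfig(n_chains=2, n_iter=150, burn_in=100, seeds=(3, 4))
        draws = run_mcmc(ds, co.covariates, co.q, cfg)
        est = estimate_trajectories(draws)
        agree = (est["map"] == co.alpha).mean()
        assert agree > 0.99
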