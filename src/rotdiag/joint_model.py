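"""Joint dynamic model of response accuracy and response times.

The model has three linked parts, all defined on the 4-skill, 4-time-point
rotation assessment:

* a DINA measurement model for correct/incorrect responses: a person whose
  profile dominates an item's Q-row answers correctly with probability
  1 - s_j (slipping), otherwise with probability g_j (guessing);
* a higher-order hidden-Markov transition model: mastery is absorbing, and
  an unlearned skill transitions 0 -> 1 between consecutive modules with a
  logistic probability driven by a general learning ability theta_i, the
  number of already-mastered skills, and observed covariates (gender,
  country, intervention, strategy, and intervention interactions);
* a lognormal response-time model: log L_ij ~ N(gamma_j - (tau_i +
  sum_h phi_h Cov_h), 1 / a_j), where gamma_j is the item time intensity,
  a_j the time discrimination (precision), tau_i a latent speed, and the
  covariates include the latent mastery indicator G(alpha_i(t), q_j).

Estimation is Metropolis-Hastings within Gibbs: exact forward-backward
sampling of monotone skill trajectories over the 16 profiles, conjugate
updates for (s, g), (gamma, a), tau, phi and the unstructured
initial-profile mixture, and random-walk MH for theta and the transition
coefficients lambda (with lambda_theta >= 0 as the loading sign
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy import stats

from .data_model import (
    K,
    N_MODULES,
    QMatrix,
    ResponseDataset,
    all_profiles,
    ideal_response_table,
)

__all__ = [
    "TransitionCoefficients",
    "SpeedCoefficients",
    "MCMCConfig",
    "PosteriorDraws",
    "LAMBDA_NAMES",
    "PHI_NAMES",
    "interaction_design",
    "transition_probability",
    "rt_log_density",
    "joint_log_likelihood",
    "run_mcmc",
    "psrf",
    "max_psrf",
    "posterior_summary",
    "estimate_trajectories",
]

#: coefficient order of the transition model (intercept + 11 reported slopes)
LAMBDA_NAMES = (
    "lambda_0",
    "lambda_theta",
    "lambda_alpha",
    "lambda_gender",
    "lambda_country",
    "lambda_iv",
    "lambda_st1",
    "lambda_st2",
    "lambda_gender_iv",
    "lambda_country_iv",
    "lambda_iv_st1",
    "lambda_iv_st2",
)

#: coefficient order of the response-time covariate model
PHI_NAMES = (
    "phi_alpha",
    "phi_gender",
    "phi_country",
    "phi_iv",
    "phi_st1",
    "phi_st2",
    "phi_gender_iv",
    "phi_country_iv",
    "phi_iv_st1",
    "phi_iv_st2",
)


@dataclass(frozen=True)
class TransitionCoefficients:
    """Transition-model coefficient vector, Eq.-style order (see LAMBDA_NAMES)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (12,):
            raise ValueError("transition coefficient vector must have length 12")
        if not np.isfinite(v).all():
            raise ValueError("transition coefficients must be finite")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionCoefficients":
        return cls(np.array([d.get(n, 0.0) for n in LAMBDA_NAMES]))

    def as_dict(self) -> dict:
        return dict(zip(LAMBDA_NAMES, self.values))


@dataclass(frozen=True)
class SpeedCoefficients:
    """Response-time covariate coefficients phi (see PHI_NAMES)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (10,):
            raise ValueError("speed coefficient vector must have length 10")
        if not np.isfinite(v).all():
            raise ValueError("speed coefficients must be finite")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_dict(cls, d: dict) -> "SpeedCoefficients":
        return cls(np.array([d.get(n, 0.0) for n in PHI_NAMES]))

    def as_dict(self) -> dict:
        return dict(zip(PHI_NAMES, self.values))


def interaction_design(cov5: np.ndarray) -> np.ndarray:
    """Expand the 5 dummy covariates into the 9-column design block.

    Input columns: gender, country, intervention, strategy1, strategy2.
    Output adds gender*IV, country*IV, IV*strategy1, IV*strategy2.
    """
    cov5 = np.asarray(cov5, dtype=float)
    g, c, iv, s1, s2 = (cov5[:, i] for i in range(5))
    return np.column_stack([g, c, iv, s1, s2, g * iv, c * iv, iv * s1, iv * s2])


def transition_probability(alpha_t, k, theta, cov5, lam: TransitionCoefficients) -> float:
    """Probability that skill k is mastered at t+1 given the state at t.

    Mastery is absorbing: returns 1.0 when alpha_t[k] = 1.  Otherwise the
    inverse-logit of the linear predictor with the number of *other*
    mastered skills and the covariate main effects and interactions.
    """
    alpha_t = np.asarray(alpha_t)
    if alpha_t[k] == 1:
        return 1.0
    x = interaction_design(np.asarray(cov5, dtype=float)[None, :])[0]
    n_mastered = float(alpha_t.sum() - alpha_t[k])
    v = lam.values
    eta = v[0] + v[1] * float(theta) + v[2] * n_mastered + x @ v[3:]
    return float(expit(eta))


def rt_log_density(L, alpha_t, q_row, gamma, a, tau, cov5, phi: SpeedCoefficients) -> float:
    """Lognormal response-time log-density for one observation.

    The mean of log L is gamma - (tau + phi_alpha * G + covariate terms),
    with G = 1 iff the profile dominates the item's Q-row; the variance is
    1 / a (a is a precision-like time discrimination, a > 0).
    """
    if L <= 0:
        raise ValueError("response time must be positive")
    if a <= 0:
        raise ValueError("time discrimination a must be positive")
    g_ind = float(np.all(np.asarray(alpha_t) >= np.asarray(q_row)))
    x = interaction_design(np.asarray(cov5, dtype=float)[None, :])[0]
    v = phi.values
    mean = gamma - (tau + v[0] * g_ind + x @ v[1:])
    return float(stats.norm.logpdf(np.log(L), loc=mean, scale=np.sqrt(1.0 / a)))


@dataclass
class MCMCConfig:
    """Sampler settings: chain count, iteration budget, burn-in, seeds.

    burn_in defaults to the first half of each chain.  seeds must be
    distinct, one per chain.
    """

    n_chains: int = 2
    n_iter: int = 5000
    burn_in: int = None
    thin: int = 1
    seeds: tuple = None
    proposal_scale_theta: float = 0.6
    prior_sd_coef: float = 2.0
    prior_sd_intercept: float = 5.0   # weaker prior on lambda_0 only
    prior_gamma_mean: float = 3.0
    prior_gamma_sd: float = 10.0
    prior_a_shape: float = 1.0
    prior_a_rate: float = 1.0

    def __post_init__(self):
        if self.burn_in is None:
            self.burn_in = self.n_iter // 2
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.seeds is None:
            self.seeds = tuple(range(1, self.n_chains + 1))
        if len(set(self.seeds)) != self.n_chains:
            raise ValueError("chain seeds must be distinct, one per chain")


@dataclass
class PosteriorDraws:
    """Multi-chain MCMC output.

    ``params`` maps a parameter name to an array of shape (n_chains,
    n_kept, ...); scalar structural parameters have trailing shape ().
    ``alpha`` holds trajectory draws as (n_chains, n_kept, N, K, T) int8,
    ``theta``/``tau`` person draws as (n_chains, n_kept, N).
    """

    params: dict
    alpha: np.ndarray
    theta: np.ndarray
    tau: np.ndarray
    config: MCMCConfig
    monitored: tuple = ()

    def stacked(self, name: str) -> np.ndarray:
        """Pool post-burn-in draws of one parameter across chains."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])


# ---------------------------------------------------------------------------
# internal sampler machinery
# ---------------------------------------------------------------------------


def _monotone_structure(k: int = K):
    """Dominance mask and acquisition/non-acquisition counts for 2^k profiles."""
    prof = all_profiles(k)
    sup = (prof[None, :, :] >= prof[:, None, :]).all(axis=2)  # sup[c, c'] : c' >= c
    pop = prof.sum(axis=1)
    d = pop[None, :] - pop[:, None]          # newly acquired skills
    z = (k - pop[:, None]) - d               # skills staying unmastered
    return prof, sup, d, z, pop


def _emission_loglik(Y, L, mask, eta, s, g, gamma, a, tau, rt_shift, phi_alpha, module_items):
    """Log P(Y_i(t), L_i(t) | profile c) for every person, time and profile.

    Returns an (N, T, C) array.  ``rt_shift`` is the person-level observed
    covariate contribution x_i' phi_cov (without the latent G term).
    """
    n = Y.shape[0]
    c = eta.shape[0]
    t_len = len(module_items)
    out = np.empty((n, t_len, c))
    log_p1 = np.log(1.0 - s)
    log_p0 = np.log(g)
    log_q1 = np.log(s)
    log_q0 = np.log(1.0 - g)
    for t, items in enumerate(module_items):
        yt = Y[:, items] * mask[:, items]
        mt = mask[:, items].astype(float)
        e = eta[:, items].astype(float)  # (C, nj)
        # accuracy: sum_j [ y log p + (1-y) log(1-p) ]; p switches with eta
        a0 = yt @ log_p0[items] + (mt - yt) @ log_q0[items]
        acc = a0[:, None] + (
            yt * (log_p1[items] - log_p0[items])[None, :]
            + (mt - yt) * (log_q1[items] - log_q0[items])[None, :]
        ) @ e.T
        # response time: r = log L - gamma + tau + rt_shift; mean resid = -phi_alpha*G
        r = (np.log(L[:, items]) - gamma[items][None, :] + tau[:, None] + rt_shift[:, None]) * mt
        aj = a[items]
        base = (-0.5 * aj * r**2 + 0.5 * mt * (np.log(aj) - np.log(2 * np.pi))).sum(axis=1)
        cross = (r * aj[None, :]) @ e.T * (-phi_alpha)
        quad = -0.5 * phi_alpha**2 * ((mt * aj[None, :]) @ e.T)
        out[:, t, :] = acc + base[:, None] + cross + quad
    return out


def _person_transition_matrices(theta, base_cov, lam, sup, d, z, pop):
    """(N, C, C) monotone transition matrices; homogeneous across the 3 gaps.

    Because covariates and theta are constant in time and the per-skill
    transition probability depends on the current profile only through its
    popcount, P(c -> c') = p^(new) (1-p)^(still zero) with a person-by-
    profile probability p[i, c].
    """
    eta = (lam[0] + lam[1] * theta + base_cov)[:, None] + lam[2] * pop[None, :]
    p = expit(eta)  # (N, C)
    logp = np.log(np.clip(p, 1e-300, None))
    log1m = np.log(np.clip(1 - p, 1e-300, None))
    logt = logp[:, :, None] * d[None, :, :] + log1m[:, :, None] * z[None, :, :]
    t_mat = np.exp(np.where(sup[None, :, :], logt, -np.inf))
    return t_mat, p


def _ffbs(init, t_mat, emis, rng):
    """Forward filtering, backward sampling of profile paths.

    init: (N, C); t_mat: (N, C, C); emis: (N, T, C) log-emissions.
    Returns sampled state indices (N, T) and the per-person log marginal
    likelihood of (Y, L) with the trajectory integrated out.
    """
    n, t_len, c = emis.shape
    shift = emis.max(axis=2, keepdims=True)
    e = np.exp(emis - shift)
    f = np.empty((n, t_len, c))
    loglik = shift[:, :, 0].sum(axis=1)
    cur = init * e[:, 0, :]
    norm = cur.sum(axis=1)
    loglik += np.log(norm)
    cur /= norm[:, None]
    f[:, 0, :] = cur
    for t in range(1, t_len):
        cur = np.einsum("nc,ncd->nd", cur, t_mat) * e[:, t, :]
        norm = cur.sum(axis=1)
        loglik += np.log(norm)
        cur /= norm[:, None]
        f[:, t, :] = cur
    states = np.empty((n, t_len), dtype=np.int64)
    u = rng.random((n, t_len))
    cdf = np.cumsum(f[:, -1, :], axis=1)
    states[:, -1] = (u[:, -1, None] * cdf[:, -1, None] < cdf).argmax(axis=1)
    for t in range(t_len - 2, -1, -1):
        w = f[:, t, :] * t_mat[np.arange(n), :, states[:, t + 1]]
        cdf = np.cumsum(w, axis=1)
        states[:, t] = (u[:, t, None] * cdf[:, -1, None] < cdf).argmax(axis=1)
    return states, loglik


def _transition_loglik_per_person(states, p_trans, pop, k_total=K):
    """Log-likelihood of the sampled monotone path's transitions per person.

    Uses the popcount factorization: at each gap, d new skills are acquired
    out of the (k - popcount) eligible ones, each independently with the
    same person-by-profile probability.
    """
    n, t_len = states.shape
    ll = np.zeros(n)
    for t in range(t_len - 1):
        c = states[:, t]
        d = pop[states[:, t + 1]] - pop[c]
        z = (k_total - pop[c]) - d
        p = p_trans[np.arange(n), c]
        ll += d * np.log(np.clip(p, 1e-300, None)) + z * np.log(np.clip(1 - p, 1e-300, None))
    return ll


def _initial_loglik_per_person(states0, theta, beta0, beta_theta, prof):
    alpha1 = prof[states0]  # (N, K)
    eta = beta0[None, :] + beta_theta[None, :] * theta[:, None]
    return (alpha1 * eta - np.logaddexp(0.0, eta)).sum(axis=1)


def joint_log_likelihood(ds: ResponseDataset, q: QMatrix, trajectory, params: dict, cov5):
    """Complete-data log-likelihood given a full trajectory and parameter set.

    ``trajectory`` is an (N, K, T) binary array; ``params`` holds s, g,
    gamma, a, theta, tau, lam (TransitionCoefficients), phi
    (SpeedCoefficients), and an initial law: either ``pi_init`` (a shared
    mixing vector over the 2^K profiles) or the higher-order logistic
    coefficients ``beta0``/``beta_theta``.  Returns a dict with the four
    additive components (accuracy, response_time, transition, initial) and
    their total.
    """
    alpha = np.asarray(trajectory)
    n, k, t_len = alpha.shape
    prof, sup, d, z, pop = _monotone_structure(k)
    states = (alpha * (1 << np.arange(k))[None, :, None]).sum(axis=1)  # (N, T)
    eta = ideal_response_table(q.entries, k)
    s, g = np.asarray(params["s"]), np.asarray(params["g"])
    gamma, a = np.asarray(params["gamma"]), np.asarray(params["a"])
    theta, tau = np.asarray(params["theta"]), np.asarray(params["tau"])
    lam = params["lam"].values
    phi = params["phi"].values
    x9 = interaction_design(cov5)
    rt_shift = x9 @ phi[1:]
    module_items = [q.items_in_module(m) for m in range(1, t_len + 1)]

    acc = rt = 0.0
    for t, items in enumerate(module_items):
        e = eta[states[:, t]][:, items]
        mt = ds.mask[:, items]
        p = np.where(e == 1, 1 - s[items][None, :], g[items][None, :])
        yt = ds.Y[:, items]
        acc += float((mt * (yt * np.log(p) + (1 - yt) * np.log(1 - p))).sum())
        mean = gamma[items][None, :] - (tau[:, None] + phi[0] * e + rt_shift[:, None])
        resid = np.log(ds.L[:, items]) - mean
        rt += float((mt * (0.5 * np.log(a[items] / (2 * np.pi))[None, :]
                           - 0.5 * a[items][None, :] * resid**2)).sum())

    base_cov = x9 @ lam[3:]
    _, p_trans = _person_transition_matrices(theta, base_cov, lam, sup, d, z, pop)
    trans = float(_transition_loglik_per_person(states, p_trans, pop, k).sum())
    if "pi_init" in params:
        pi0 = np.asarray(params["pi_init"], dtype=float)
        init = float(np.log(np.clip(pi0[states[:, 0]], 1e-300, None)).sum())
    else:
        init = float(_initial_loglik_per_person(
            states[:, 0], theta, np.asarray(params["beta0"], dtype=float),
            np.asarray(params["beta_theta"], dtype=float), prof).sum())
    total = acc + rt + trans + init
    return {
        "accuracy": acc,
        "response_time": rt,
        "transition": trans,
        "initial": init,
        "total": total,
    }


def _truncated_beta(rng, a_par, b_par, hi):
    """Draw Beta(a, b) truncated to (0, hi), vectorized via inverse CDF."""
    u = rng.random(np.shape(a_par))
    c_hi = stats.beta.cdf(hi, a_par, b_par)
    draw = stats.beta.ppf(u * c_hi, a_par, b_par)
    return np.clip(draw, 1e-6, hi - 1e-6)


def _run_single_chain(ds, cov5, q, cfg: MCMCConfig, seed, sigma_theta_fixed=1.0):
    rng = np.random.default_rng(seed)
    n, j = ds.Y.shape
    t_len = int(ds.module_of_item.max())
    prof, sup, d, z, pop = _monotone_structure(K)
    eta = ideal_response_table(q.entries, K)
    module_items = [q.items_in_module(m) for m in range(1, t_len + 1)]
    x9 = interaction_design(cov5)
    logL = np.log(ds.L)
    mask = ds.mask.astype(float)
    y = ds.Y * ds.mask

    # --- empirical initial values, jittered across chains ----------------
    # theta from standardized total scores anchors the latent-ability
    # alignment from the first sweep; with neutral starts the chains can
    # settle into a misaligned mode that local MH moves never escape
    total = (y * mask).sum(axis=1) / np.maximum(mask.sum(axis=1), 1)
    theta = (total - total.mean()) / max(total.std(), 1e-6)
    theta = np.clip(theta, -3, 3) + 0.3 * rng.standard_normal(n)
    low = total <= np.median(total)
    g = np.array([
        (y[low, jj] * mask[low, jj]).sum() / max(mask[low, jj].sum(), 1.0)
        for jj in range(j)
    ])
    s = 1.0 - np.array([
        (y[~low, jj] * mask[~low, jj]).sum() / max(mask[~low, jj].sum(), 1.0)
        for jj in range(j)
    ])
    g = np.clip(g + 0.03 * rng.standard_normal(j), 0.03, 0.9)
    s = np.clip(s + 0.03 * rng.standard_normal(j), 0.03, 0.9)
    over = s + g > 0.95
    s[over] = 0.95 - g[over]
    s = np.clip(s, 0.03, None)
    gamma = np.array([logL[:, jj][ds.mask[:, jj]].mean() for jj in range(j)])
    a_emp = np.array([1.0 / max(np.var(logL[:, jj][ds.mask[:, jj]]), 0.05)
                      for jj in range(j)])
    a = np.clip(a_emp * np.exp(0.1 * rng.standard_normal(j)), 0.2, 10.0)
    tau = np.zeros(n)
    lam = np.zeros(12)
    lam[0] = -1.5 + 0.5 * rng.standard_normal()
    lam[1] = 1.0 + 0.5 * np.abs(rng.standard_normal())
    phi = np.zeros(10)
    # unstructured initial-profile mixture (theta-independent): a
    # theta-driven initial law lets the model reclassify able
    # transitioners as initial masters and cripples the transition block
    pi_init = rng.dirichlet(np.full(2**K, 20.0))
    kappa = 0.0          # regression of tau on theta (= rho * sigma_tau)
    sig2_tau = 0.1       # residual variance of tau given theta

    prior_prec = 1.0 / cfg.prior_sd_coef**2
    # slope coefficients get the N(0, sd_coef^2) prior; the transition
    # intercept a flatter one -- shrinking lambda_0 toward zero leaks into
    # the correlated slope block (popcount absorbs the compensation)
    lam_prior_prec = np.full(12, prior_prec)
    lam_prior_prec[0] = 1.0 / cfg.prior_sd_intercept**2
    lam_scale = np.full(12, 0.3)
    th_scale = cfg.proposal_scale_theta
    # adaptive joint proposal for lambda: empirical covariance from burn-in
    lam_hist = []
    lam_chol = None
    lam_joint_scale = 2.38 / np.sqrt(12)

    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    store = {
        "s": np.empty((n_keep, j)), "g": np.empty((n_keep, j)),
        "gamma": np.empty((n_keep, j)), "a": np.empty((n_keep, j)),
        "lam": np.empty((n_keep, 12)), "phi": np.empty((n_keep, 10)),
        "pi_init": np.empty((n_keep, 2**K)),
        "kappa": np.empty(n_keep), "sig2_tau": np.empty(n_keep),
    }
    alpha_store = np.empty((n_keep, n, K, t_len), dtype=np.int8)
    theta_store = np.empty((n_keep, n))
    tau_store = np.empty((n_keep, n))
    kept = 0

    states = None
    for it in range(cfg.n_iter):
        adapting = it < cfg.burn_in

        # --- trajectories: exact FFBS over the 16-profile monotone chain --
        rt_shift = x9 @ phi[1:]
        base_cov = x9 @ lam[3:]
        emis = _emission_loglik(y, ds.L, ds.mask, eta, s, g, gamma, a, tau,
                                rt_shift, phi[0], module_items)
        t_mat, p_trans = _person_transition_matrices(theta, base_cov, lam, sup, d, z, pop)
        init = np.broadcast_to(pi_init, (n, 2**K))
        states, _ = _ffbs(init, t_mat, emis, rng)
        if not np.isfinite(emis).all():
            raise FloatingPointError("non-finite likelihood; sampler diverged")
        # mastery indicator for each (person, item) at the item's module
        g_pi = np.empty((n, j))
        for t, items in enumerate(module_items):
            g_pi[:, items] = eta[states[:, t]][:, items]

        # --- item accuracy parameters: truncated-Beta Gibbs ---------------
        m1 = (g_pi * mask)
        m0 = ((1 - g_pi) * mask)
        s1 = (m1 * y).sum(axis=0)          # correct among dominating persons
        n1 = m1.sum(axis=0)
        s0 = (m0 * y).sum(axis=0)
        n0 = m0.sum(axis=0)
        s = _truncated_beta(rng, n1 - s1 + 1.0, s1 + 1.0, 1.0 - g)
        g = _truncated_beta(rng, s0 + 1.0, n0 - s0 + 1.0, 1.0 - s)

        # --- response-time block ------------------------------------------
        rt_shift = x9 @ phi[1:]
        delta = tau[:, None] + phi[0] * g_pi + rt_shift[:, None]  # (N, J)
        # gamma_j | . conjugate normal
        prec_g = a * mask.sum(axis=0) + 1.0 / cfg.prior_gamma_sd**2
        mean_g = (a * (mask * (logL + delta)).sum(axis=0)
                  + cfg.prior_gamma_mean / cfg.prior_gamma_sd**2) / prec_g
        gamma = mean_g + rng.standard_normal(j) / np.sqrt(prec_g)
        # a_j | . conjugate gamma on the precision
        resid = (logL - gamma[None, :] + delta) * mask
        sse = (resid**2).sum(axis=0)
        a = rng.gamma(cfg.prior_a_shape + 0.5 * mask.sum(axis=0),
                      1.0 / (cfg.prior_a_rate + 0.5 * sse))
        a = np.clip(a, 1e-6, None)

        # --- phi | . collapsed conjugate normal (tau integrated out) -------
        # y_i = Z_i phi + u_i 1 + noise, u_i ~ N(0, sig2_tau): marginalizing
        # the latent speed decouples phi from tau (person-level covariate
        # columns are otherwise absorbed by tau and mix glacially).
        # y = gamma_j - kappa*theta - logL; Sigma_i^-1 via Woodbury.
        y_t = gamma[None, :] - kappa * theta[:, None] - logL   # (N, J)
        w = a[None, :] * mask
        zw_g = w * g_pi
        s_i = w.sum(axis=1)                                    # 1' A_i 1
        c_i = sig2_tau / (1.0 + sig2_tau * s_i)                # (N,)
        w_g = zw_g.sum(axis=1)                                 # 1' A_i G_i
        w_y = (w * y_t).sum(axis=1)                            # 1' A_i y_i
        A_mat = np.empty((10, 10))
        b_vec = np.empty(10)
        A_mat[0, 0] = (w * g_pi * g_pi).sum() - (c_i * w_g**2).sum()
        A_mat[0, 1:] = A_mat[1:, 0] = x9.T @ (w_g - c_i * w_g * s_i)
        A_mat[1:, 1:] = (x9 * (s_i - c_i * s_i**2)[:, None]).T @ x9
        b_vec[0] = (zw_g * y_t).sum() - (c_i * w_g * w_y).sum()
        b_vec[1:] = x9.T @ ((w * y_t).sum(axis=1) - c_i * s_i * w_y)
        A_mat = A_mat + prior_prec * np.eye(10)
        chol = np.linalg.cholesky(A_mat)
        mean_phi = np.linalg.solve(A_mat, b_vec)
        phi = mean_phi + np.linalg.solve(chol.T, rng.standard_normal(10))

        # --- tau | . conjugate normal --------------------------------------
        rt_shift = x9 @ phi[1:]
        prec_tau = (a[None, :] * mask).sum(axis=1) + 1.0 / sig2_tau
        num = ((a[None, :] * mask) * (gamma[None, :] - phi[0] * g_pi
                                      - rt_shift[:, None] - logL)).sum(axis=1)
        mean_tau = (num + kappa * theta / sig2_tau) / prec_tau
        tau = mean_tau + rng.standard_normal(n) / np.sqrt(prec_tau)

        # --- tau hyperparameters (kappa, sig2_tau) -------------------------
        sxx = float(theta @ theta) + prior_prec
        sxy = float(theta @ tau)
        kappa = sxy / sxx + rng.standard_normal() / np.sqrt(sxx / sig2_tau)
        res_t = tau - kappa * theta
        sig2_tau = 1.0 / rng.gamma(1.0 + 0.5 * n, 1.0 / (0.05 + 0.5 * float(res_t @ res_t)))

        # --- theta | . random-walk MH --------------------------------------
        def person_theta_loglik(th):
            p_tr = expit((lam[0] + lam[1] * th + base_cov)[:, None]
                         + lam[2] * pop[None, :])
            ll = _transition_loglik_per_person(states, p_tr, pop, K)
            ll += -0.5 * th**2 / sigma_theta_fixed**2
            ll += -0.5 * (tau - kappa * th) ** 2 / sig2_tau
            return ll

        base_cov = x9 @ lam[3:]
        cur_ll = person_theta_loglik(theta)
        prop = theta + th_scale * rng.standard_normal(n)
        new_ll = person_theta_loglik(prop)
        accept = np.log(rng.random(n)) < (new_ll - cur_ll)
        theta = np.where(accept, prop, theta)

        # --- lambda | . componentwise random-walk MH -----------------------
        elig = prof[states[:, :-1]] == 0                       # (N, T-1, K)
        nxt = prof[states[:, 1:]]                              # (N, T-1, K)
        i_idx, t_idx, k_idx = np.nonzero(elig)
        y_tr = nxt[i_idx, t_idx, k_idx].astype(float)
        x_tr = np.column_stack([
            np.ones_like(y_tr),
            theta[i_idx],
            pop[states[i_idx, t_idx]].astype(float),
            x9[i_idx],
        ])

        eta_tr = x_tr @ lam

        def lam_logpost(eta_lin, vec):
            return float(y_tr @ eta_lin - np.logaddexp(0.0, eta_lin).sum()
                         - 0.5 * float(lam_prior_prec @ vec**2))

        # componentwise scan (always; keeps moves alive early on);
        # lambda_theta >= 0 is the loading sign convention that pins the
        # (theta, lambda_theta, kappa) reflection
        for c_i in range(12):
            step = lam_scale[c_i] * rng.standard_normal()
            prop_vec = lam.copy()
            prop_vec[c_i] += step
            if c_i == 1 and prop_vec[1] < 0:
                if adapting:
                    lam_scale[c_i] *= 0.985
                continue
            eta_new = eta_tr + x_tr[:, c_i] * step
            if np.log(rng.random()) < lam_logpost(eta_new, prop_vec) - lam_logpost(eta_tr, lam):
                lam = prop_vec
                eta_tr = eta_new
                if adapting:
                    lam_scale[c_i] *= 1.03
            elif adapting:
                lam_scale[c_i] *= 0.985
        # joint move along the empirical posterior covariance: the
        # coefficients ride a correlated ridge that axis moves cross slowly
        if adapting:
            lam_hist.append(lam.copy())
            if it % 200 == 199 and len(lam_hist) > 300:
                h = np.asarray(lam_hist[len(lam_hist) // 3:])
                cov = np.cov(h.T) + 1e-8 * np.eye(12)
                lam_chol = np.linalg.cholesky(cov)
        if lam_chol is not None:
            step = lam_joint_scale * (lam_chol @ rng.standard_normal(12))
            prop_vec = lam + step
            if prop_vec[1] >= 0:
                eta_new = x_tr @ prop_vec
                if np.log(rng.random()) < lam_logpost(eta_new, prop_vec) - lam_logpost(eta_tr, lam):
                    lam = prop_vec
                    eta_tr = eta_new
                    if adapting:
                        lam_joint_scale *= 1.05
                elif adapting:
                    lam_joint_scale *= 0.975

        # --- initial-profile mixture: conjugate Dirichlet ------------------
        counts = np.bincount(states[:, 0], minlength=2**K)
        pi_init = rng.dirichlet(1.0 + counts)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            store["s"][kept] = s
            store["g"][kept] = g
            store["gamma"][kept] = gamma
            store["a"][kept] = a
            store["lam"][kept] = lam
            store["phi"][kept] = phi
            store["pi_init"][kept] = pi_init
            store["kappa"][kept] = kappa
            store["sig2_tau"][kept] = sig2_tau
            alpha_store[kept] = np.transpose(prof[states], (0, 2, 1))
            theta_store[kept] = theta
            tau_store[kept] = tau
            kept += 1

    return store, alpha_store, theta_store, tau_store


def run_mcmc(ds: ResponseDataset, covariates, q: QMatrix, cfg: MCMCConfig) -> PosteriorDraws:
    """Fit the joint model by Metropolis-Hastings within Gibbs.

    ``covariates`` is either an (N, 5) dummy-coded array or a DataFrame
    accepted by :func:`rotdiag.data_model.encode_covariates`.  Returns
    multi-chain :class:`PosteriorDraws`; identical data, config and seeds
    give bit-identical output.
    """
    import pandas as pd

    from .data_model import encode_covariates

    if isinstance(covariates, pd.DataFrame):
        cov5 = encode_covariates(covariates)
    else:
        cov5 = np.asarray(covariates, dtype=float)
    chains = [
        _run_single_chain(ds, cov5, q, cfg, seed)
        for seed in cfg.seeds
    ]
    params = {}
    for name in chains[0][0]:
        params[name] = np.stack([c[0][name] for c in chains])
    alpha = np.stack([c[1] for c in chains])
    theta = np.stack([c[2] for c in chains])
    tau = np.stack([c[3] for c in chains])
    # flat per-coefficient views for summaries and diagnostics
    for i, nm in enumerate(LAMBDA_NAMES):
        params[nm] = params["lam"][:, :, i]
    for i, nm in enumerate(PHI_NAMES):
        params[nm] = params["phi"][:, :, i]
    monitored = tuple(
        [*LAMBDA_NAMES, *PHI_NAMES, "s", "g", "gamma", "a", "pi_init",
         "kappa", "sig2_tau"]
    )
    draws = PosteriorDraws(params=params, alpha=alpha, theta=theta, tau=tau,
                           config=cfg, monitored=monitored)
    _check_constraints(draws)
    return draws


def _check_constraints(draws: PosteriorDraws) -> None:
    s, g, a = draws.params["s"], draws.params["g"], draws.params["a"]
    if not ((s > 0).all() and (g > 0).all() and (1 - s - g > 0).all()):
        raise AssertionError("accuracy parameter draws violate 1 - s - g > 0")
    if not (a > 0).all():
        raise AssertionError("time-discrimination draws must be positive")
    if (np.diff(draws.alpha, axis=4) < 0).any():
        raise AssertionError("trajectory draws must be monotone non-decreasing")


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin proportional scale reduction factor for one parameter.

    ``chains`` is (m, n) with m >= 2 chains of n post-burn-in draws.
    R-hat = sqrt(var+ / W) with var+ = ((n-1)/n) W + B/n, B the between-
    chain and W the mean within-chain variance.  W = 0 with B > 0 is
    reported as +inf.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    m, n = c.shape
    means = c.mean(axis=1)
    w = c.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if w == 0:
        return float("inf") if b > 0 else np.sqrt((n - 1) / n)
    return float(np.sqrt(var_plus / w))


def _monitored_chain_arrays(draws: PosteriorDraws):
    out = {}
    for name in draws.monitored:
        arr = draws.params[name]
        if arr.ndim == 2:   # scalar parameter: (chains, n)
            out[name] = arr
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for idx in range(flat.shape[2]):
                out[f"{name}[{idx}]"] = flat[:, :, idx]
    return out


def max_psrf(draws: PosteriorDraws) -> float:
    """Maximum R-hat over all monitored structural parameters."""
    vals = [psrf(c) for c in _monitored_chain_arrays(draws).values()]
    return float(np.max(vals))


def psrf_trace(draws: PosteriorDraws, n_points: int = 20):
    """Max-R-hat as a function of the number of kept iterations used.

    Mirrors convergence monitoring that plots the running maximum PSRF
    against iteration count; returns (iteration counts, max R-hat values).
    """
    arrays = _monitored_chain_arrays(draws)
    n = next(iter(arrays.values())).shape[1]
    pts = np.unique(np.linspace(max(4, n // n_points), n, n_points).astype(int))
    out = []
    for upto in pts:
        out.append(max(psrf(c[:, :upto]) for c in arrays.values()))
    return pts, np.array(out)


def posterior_summary(draws: PosteriorDraws, names=None):
    """Posterior mean, SD and central 95% interval per monitored parameter.

    A coefficient is flagged ``significant`` when its 95% credible interval
    excludes zero.
    """
    import pandas as pd

    arrays = _monitored_chain_arrays(draws)
    if names is not None:
        arrays = {k: v for k, v in arrays.items() if k in names or k.split("[")[0] in names}
    rows = []
    for name, c in arrays.items():
        pooled = c.reshape(-1)
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        rows.append({
            "parameter": name,
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1) if pooled.size > 1 else 0.0,
            "lower_95": lo,
            "upper_95": hi,
            "significant": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows).set_index("parameter")


def estimate_trajectories(draws: PosteriorDraws, threshold: float = 0.5):
    """Posterior mastery probabilities and MAP trajectories.

    Returns a dict with ``prob`` (N, K, T) marginal posterior mastery
    probabilities, ``map`` (N, K, T) thresholded profiles re-monotonized
    in t, per-skill-by-time mastery rates, and the distribution of the
    number of mastered skills at each time point.
    """
    flat = draws.alpha.reshape(-1, *draws.alpha.shape[2:])  # (draws, N, K, T)
    prob = flat.mean(axis=0)
    map_alpha = (prob >= threshold).astype(np.int8)
    map_alpha = np.maximum.accumulate(map_alpha, axis=2)
    rates = map_alpha.mean(axis=0)  # (K, T)
    counts = map_alpha.sum(axis=1)  # (N, T)
    t_len = map_alpha.shape[2]
    dist = np.stack([
        np.bincount(counts[:, t], minlength=K + 1) / counts.shape[0]
        for t in range(t_len)
    ])
    return {"prob": prob, "map": map_alpha, "mastery_rates": rates,
            "skill_count_distribution": dist}
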