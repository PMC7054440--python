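"""Synthetic cohorts with the statistical structure of the rotation study.

The real cohort is not public, so every downstream stage is exercised on
generated data that emulates the study design: 548 undergraduates, a
4-module program (10 items each), K = 4 binary rotation skills, covariate
margins matching the reported sample composition, DINA item parameters
drawn around the reported per-module means, transition coefficients equal
to the reported posterior means (non-significant coefficients zero), and
lognormal response times with the reported speed coefficients.

The generator defaults *are* the study conditions; they are not tuning
knobs.  Values the study does not report (the transition intercept, the
initial-profile model, the latent speed scale) are fixed once and
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    K,
    N_MODULES,
    QMatrix,
    ResponseDataset,
    blueprint_q_matrix,
    encode_covariates,
)
from .joint_model import (
    SpeedCoefficients,
    TransitionCoefficients,
    interaction_design,
)

__all__ = [
    "GeneratorConfig",
    "ItemBank",
    "SimulatedCohort",
    "simulate_covariates",
    "simulate_latents",
    "simulate_item_bank",
    "simulate_trajectories",
    "simulate_responses_and_times",
    "simulate_cohort",
]

#: reported per-module mean accuracy and response-time item parameters
#: (slipping, guessing, time discrimination, time intensity)
MODULE_ITEM_MEANS = {
    1: {"s": 0.182, "g": 0.560, "a": 1.657, "gamma": 3.288},
    2: {"s": 0.065, "g": 0.757, "a": 1.978, "gamma": 2.680},
    3: {"s": 0.272, "g": 0.418, "a": 1.757, "gamma": 3.093},
    4: {"s": 0.193, "g": 0.514, "a": 1.560, "gamma": 2.970},
}

#: transition-model generating values: reported posterior means for the two
#: significant coefficients, zero elsewhere; the intercept (unreported) is
#: fixed at -2.0
DEFAULT_LAMBDA = {
    "lambda_0": -2.0,
    "lambda_theta": 2.821,
    "lambda_alpha": 0.471,
}

#: speed-model generating values: reported posterior means for the six
#: significant coefficients, zero for the interactions
DEFAULT_PHI = {
    "phi_alpha": -0.327,
    "phi_gender": -0.081,
    "phi_country": 0.084,
    "phi_iv": 0.072,
    "phi_st1": 0.034,
    "phi_st2": -0.093,
}

#: initial-profile intercept, calibrated so that with beta_theta = 1.5 the
#: expected fraction of persons starting as full masters of all four skills
#: is 0.595 (the study's estimated initial full-mastery rate)
DEFAULT_BETA0 = 2.2379
DEFAULT_BETA_THETA = 1.5


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort generator."""

    n_persons: int = 548
    seed: int = 0
    # covariate margins (counts); each pair must sum to n_persons
    n_male: int = 147
    n_china: int = 325
    n_color: int = 264
    n_analytic: int = 62
    n_holistic: int = 63
    lam: TransitionCoefficients = field(
        default_factory=lambda: TransitionCoefficients.from_dict(DEFAULT_LAMBDA)
    )
    phi: SpeedCoefficients = field(
        default_factory=lambda: SpeedCoefficients.from_dict(DEFAULT_PHI)
    )
    beta0: tuple = (DEFAULT_BETA0,) * K
    beta_theta: tuple = (DEFAULT_BETA_THETA,) * K
    rho: float = 0.3          # correlation between theta and tau
    sigma_tau: float = 0.25   # SD of the latent speed
    item_jitter_sg: float = 0.04   # SD of the jitter around module mean s, g
    item_jitter_a: float = 0.15
    item_jitter_gamma: float = 0.15
    # within-module complexity contrasts: single-skill (simple) items guess
    # high / slip low and are answered faster than two-skill (complex)
    # items, as in the reported item-parameter pattern; ratios/offsets are
    # balanced so module means stay at the reported values
    guess_ratio_simple: float = 2.0      # g_simple / g_complex
    slip_ratio_complex: float = 2.5      # s_complex / s_simple
    gamma_contrast: float = 0.25         # log-seconds shift, complex slower
    a_contrast: float = 0.1              # precision shift, simple more precise

    def __post_init__(self):
        if not -1 < self.rho < 1:
            raise ValueError("latent correlation rho must lie in (-1, 1)")
        for n_level in (self.n_male, self.n_china, self.n_color):
            if not 0 <= n_level <= self.n_persons:
                raise ValueError("covariate margin exceeds n_persons")
        if self.n_analytic + self.n_holistic > self.n_persons:
            raise ValueError("strategy margins exceed n_persons")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class ItemBank:
    """Generated item parameters aligned with a Q-matrix."""

    q: QMatrix
    s: np.ndarray
    g: np.ndarray
    gamma: np.ndarray
    a: np.ndarray

    def __post_init__(self):
        if not ((self.s > 0).all() and (self.g > 0).all()
                and (1 - self.s - self.g > 0).all()):
            raise ValueError("item parameters must satisfy 1 - s - g > 0")
        if not (self.a > 0).all():
            raise ValueError("time discrimination a must be positive")


@dataclass
class SimulatedCohort:
    """A full synthetic cohort plus its generating ground truth."""

    dataset: ResponseDataset
    covariates: pd.DataFrame
    q: QMatrix
    items: ItemBank
    theta: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray          # (N, K, T) ground-truth trajectories
    config: GeneratorConfig

    def ground_truth(self) -> dict:
        return {
            "lambda": self.config.lam.as_dict(),
            "phi": self.config.phi.as_dict(),
            "beta0": list(self.config.beta0),
            "beta_theta": list(self.config.beta_theta),
            "theta": self.theta.tolist(),
            "tau": self.tau.tolist(),
            "alpha": self.alpha.tolist(),
            "s": self.items.s.tolist(),
            "g": self.items.g.tolist(),
            "gamma": self.items.gamma.tolist(),
            "a": self.items.a.tolist(),
        }


def _exact_margin(rng, n, n_ones):
    v = np.zeros(n, dtype=int)
    v[:n_ones] = 1
    rng.shuffle(v)
    return v


def simulate_covariates(cfg: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Covariate table with exact margin counts, columns independently shuffled."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    if n == 0:
        return pd.DataFrame(columns=["person_id", "gender", "country",
                                     "intervention", "strategy"])
    gender = np.where(_exact_margin(rng, n, cfg.n_male) == 1, "male", "female")
    country = np.where(_exact_margin(rng, n, cfg.n_china) == 1, "china", "us")
    iv = np.where(_exact_margin(rng, n, cfg.n_color) == 1, "color", "non-color")
    strat = np.array(["Combined"] * n, dtype=object)
    lab = np.zeros(n, dtype=int)
    lab[: cfg.n_analytic] = 1
    lab[cfg.n_analytic: cfg.n_analytic + cfg.n_holistic] = 2
    rng.shuffle(lab)
    strat[lab == 1] = "Analytic"
    strat[lab == 2] = "Holistic"
    return pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "gender": gender,
        "country": country,
        "intervention": iv,
        "strategy": strat,
    })


def simulate_latents(cfg: GeneratorConfig, rng=None):
    """Draw (theta, tau) from a zero-mean bivariate normal.

    Var(theta) = 1, Var(tau) = sigma_tau^2, Corr = rho.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    z = rng.standard_normal((n, 2))
    theta = z[:, 0]
    tau = cfg.sigma_tau * (cfg.rho * z[:, 0] + np.sqrt(1 - cfg.rho**2) * z[:, 1])
    return theta, tau


def simulate_item_bank(cfg: GeneratorConfig, rng=None, q: QMatrix = None) -> ItemBank:
    """Item parameters jittered around the per-module reported means.

    Within each module, single-skill (simple) and two-skill (complex)
    items are contrasted — simple items guess high / slip low and are
    answered faster, complex items the opposite — with offsets balanced so
    the module means stay at the reported values.  Truncation keeps
    s, g > 0.01 and discrimination 1 - s - g > 0.02.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    q = q or blueprint_q_matrix()
    j = q.n_items
    s = np.empty(j)
    g = np.empty(j)
    a = np.empty(j)
    gamma = np.empty(j)
    n_skills = q.entries.sum(axis=1)
    for m in range(1, N_MODULES + 1):
        idx = q.items_in_module(m)
        simple = n_skills[idx] == 1
        n_tot, n1 = idx.size, int(simple.sum())
        n2 = n_tot - n1
        mm = MODULE_ITEM_MEANS[m]
        if n1 and n2:
            # class levels with exact module means:
            # mean = (n1 * level_simple + n2 * level_complex) / n
            g_complex = mm["g"] * n_tot / (n1 * cfg.guess_ratio_simple + n2)
            g_level = np.where(simple, cfg.guess_ratio_simple * g_complex, g_complex)
            s_simple = mm["s"] * n_tot / (n1 + cfg.slip_ratio_complex * n2)
            s_level = np.where(simple, s_simple, cfg.slip_ratio_complex * s_simple)
            gam_level = mm["gamma"] + np.where(
                simple, -2 * cfg.gamma_contrast * n2 / n_tot,
                2 * cfg.gamma_contrast * n1 / n_tot)
            a_level = mm["a"] + np.where(
                simple, 2 * cfg.a_contrast * n2 / n_tot,
                -2 * cfg.a_contrast * n1 / n_tot)
        else:
            g_level = np.full(n_tot, mm["g"])
            s_level = np.full(n_tot, mm["s"])
            gam_level = np.full(n_tot, mm["gamma"])
            a_level = np.full(n_tot, mm["a"])
        for _ in range(200):
            s_m = s_level + cfg.item_jitter_sg * rng.standard_normal(idx.size)
            g_m = g_level + cfg.item_jitter_sg * rng.standard_normal(idx.size)
            ok = (s_m > 0.01) & (g_m > 0.01) & (1 - s_m - g_m > 0.02)
            if ok.all():
                break
        s_m = np.clip(s_m, 0.01, None)
        g_m = np.clip(g_m, 0.01, 0.97 - s_m)
        s[idx], g[idx] = s_m, g_m
        a[idx] = np.clip(a_level + cfg.item_jitter_a * rng.standard_normal(idx.size), 0.2, None)
        gamma[idx] = gam_level + cfg.item_jitter_gamma * rng.standard_normal(idx.size)
    return ItemBank(q=q, s=s, g=g, gamma=gamma, a=a)


def simulate_trajectories(covariates, theta, lam: TransitionCoefficients,
                          beta0, beta_theta, seed, t_len: int = N_MODULES) -> np.ndarray:
    """Monotone (N, K, T) skill trajectories.

    The initial profile is drawn skill-wise from the higher-order logistic
    logit P(alpha_k(1) = 1) = beta0_k + beta_theta_k * theta; each later
    0 -> 1 transition occurs with the covariate logistic probability, and
    mastery is absorbing.
    """
    rng = np.random.default_rng(seed)
    cov5 = covariates if isinstance(covariates, np.ndarray) else encode_covariates(covariates)
    n = cov5.shape[0]
    x9 = interaction_design(cov5)
    v = lam.values
    beta0 = np.asarray(beta0, dtype=float)
    beta_theta = np.asarray(beta_theta, dtype=float)
    alpha = np.zeros((n, K, t_len), dtype=np.int8)
    p_init = expit(beta0[None, :] + beta_theta[None, :] * theta[:, None])
    alpha[:, :, 0] = rng.random((n, K)) < p_init
    base = v[0] + v[1] * theta + x9 @ v[3:]
    for t in range(t_len - 1):
        cur = alpha[:, :, t]
        n_other = cur.sum(axis=1, keepdims=True) - cur  # equals popcount when cur==0
        p = expit(base[:, None] + v[2] * n_other)
        new = (rng.random((n, K)) < p) & (cur == 0)
        alpha[:, :, t + 1] = cur | new
    return alpha


def simulate_responses_and_times(alpha, items: ItemBank, covariates, tau,
                                 phi: SpeedCoefficients, seed) -> ResponseDataset:
    """Draw DINA responses and lognormal response times given trajectories.

    The mastery covariate G(alpha_i(t), q_j) is recomputed per item at the
    item's own module; log L has mean gamma_j - (tau_i + phi'Cov) and
    variance 1 / a_j.
    """
    rng = np.random.default_rng(seed)
    cov5 = covariates if isinstance(covariates, np.ndarray) else encode_covariates(covariates)
    x9 = interaction_design(cov5)
    v = phi.values
    q = items.q
    tau = np.asarray(tau, dtype=float)
    n = alpha.shape[0]
    j = q.n_items
    y = np.zeros((n, j), dtype=np.int8)
    ell = np.zeros((n, j))
    rt_shift = x9 @ v[1:]
    for m in range(1, int(q.module_of_item.max()) + 1):
        idx = q.items_in_module(m)
        prof_t = alpha[:, :, m - 1]
        dom = (prof_t[:, None, :] >= q.entries[idx][None, :, :]).all(axis=2)
        p = np.where(dom, 1 - items.s[idx][None, :], items.g[idx][None, :])
        y[:, idx] = rng.random((n, idx.size)) < p
        mean = items.gamma[idx][None, :] - (
            tau[:, None] + v[0] * dom + rt_shift[:, None]
        )
        sd = 1.0 / np.sqrt(items.a[idx])
        ell[:, idx] = np.exp(mean + sd[None, :] * rng.standard_normal((n, idx.size)))
    return ResponseDataset(Y=y, L=ell, module_of_item=q.module_of_item)


def simulate_cohort(cfg: GeneratorConfig) -> SimulatedCohort:
    """Generate a complete cohort: covariates, latents, items, trajectories, data."""
    rng = np.random.default_rng(cfg.seed)
    cov = simulate_covariates(cfg, rng)
    theta, tau = simulate_latents(cfg, rng)
    items = simulate_item_bank(cfg, rng)
    alpha = simulate_trajectories(cov, theta, cfg.lam, cfg.beta0, cfg.beta_theta,
                                  seed=int(rng.integers(2**31)))
    ds = simulate_responses_and_times(alpha, items, encode_covariates(cov), tau,
                                      cfg.phi, seed=int(rng.integers(2**31)))
    return SimulatedCohort(dataset=ds, covariates=cov, q=items.q, items=items,
                           theta=theta, tau=tau, alpha=alpha, config=cfg)
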