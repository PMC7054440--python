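"""Cross-sectional measurement-model selection for the 10-item modules.

Each module is treated as a mini-test and fitted by marginal maximum
likelihood EM under six diagnostic classification models: DINA, DINO, the
additive CDM (ACDM, identity link), the linear logistic model (LLM, logit
link), the reduced reparameterized unified model (RRUM, log link) and the
saturated GDINA.  Test-level selection uses AIC/BIC; item-level selection
uses Wald tests of each reduced model against the saturated item.

For an item requiring a single attribute all six models coincide with
DINA, so only two-attribute items ever discriminate between them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .data_model import K, QMatrix, all_profiles

__all__ = [
    "MODELS",
    "EMFit",
    "dina_response_prob",
    "gdina_item_prob",
    "fit_dcm_em",
    "information_criteria",
    "wald_item_test",
    "select_measurement_model",
]

MODELS = ("DINA", "DINO", "ACDM", "LLM", "RRUM", "GDINA")

_EPS = 1e-9
_PCLIP = 1e-6


def dina_response_prob(alpha, q, s: float, g: float) -> float:
    """DINA correct-response probability: 1 - s for dominating profiles, g else."""
    alpha = np.asarray(alpha)
    q = np.asarray(q)
    return 1.0 - s if np.all(alpha >= q) else g


def _factorial_design(k_star: int) -> np.ndarray:
    """Full-factorial design over the 2^k* reduced profiles.

    Column order: intercept, main effects, then interactions by increasing
    order (for k* = 2: [1, a1, a2, a1*a2]).
    """
    red = all_profiles(k_star)
    cols = [np.ones(red.shape[0])]
    for order in range(1, k_star + 1):
        for combo in itertools.combinations(range(k_star), order):
            cols.append(np.prod(red[:, combo], axis=1))
    return np.column_stack(cols)


def gdina_item_prob(alpha, q, delta, link: str = "identity") -> float:
    """GDINA-family correct-response probability for one profile and item.

    ``delta`` holds effect coefficients over the factorial design columns
    (intercept, main effects, interactions); shorter vectors use the
    leading columns, which encodes the reduced (additive) models.  The
    link is identity (ACDM/GDINA), logit (LLM) or log (RRUM).
    """
    alpha = np.asarray(alpha)
    q = np.asarray(q)
    req = np.flatnonzero(q)
    red = alpha[req]
    design = _factorial_design(req.size)
    row = design[int((red << np.arange(req.size)).sum())]
    delta = np.asarray(delta, dtype=float)
    lin = float(row[: delta.size] @ delta)
    if link == "identity":
        if not 0.0 <= lin <= 1.0:
            raise ValueError(f"identity-link probability {lin:.4f} outside [0, 1]")
        return lin
    if link == "logit":
        return float(expit(lin))
    if link == "log":
        p = float(np.exp(lin))
        if p > 1.0:
            raise ValueError("log-link probability exceeds 1")
        return p
    raise ValueError(f"unknown link {link!r}")


@dataclass
class EMFit:
    """Converged (or flagged) EM fit of one module under one model."""

    model: str
    pi: np.ndarray                  # mixing proportions over 2^K profiles
    item_probs: np.ndarray          # (J, 2^K) correct-response probabilities
    item_params: list               # per-item parameter dicts
    loglik: float
    n_params: int
    n_persons: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)
    q: QMatrix = field(repr=False, default=None)
    posterior: np.ndarray = field(repr=False, default=None)


def _reduced_index(q_row: np.ndarray) -> np.ndarray:
    """Map each of the 2^K profiles to its reduced-profile index for one item."""
    req = np.flatnonzero(q_row)
    prof = all_profiles(K)
    return (prof[:, req] << np.arange(req.size)).sum(axis=1)


def _mstep_item(model, r_w, n_w, k_star, p_cur):
    """Maximize the expected item log-likelihood over reduced-profile groups.

    r_w, n_w: expected corrects and totals per reduced profile (length 2^k*).
    Returns the new reduced-profile probability vector.
    """
    red = all_profiles(k_star)
    if model == "GDINA" or k_star == 1:
        return np.clip(r_w / np.maximum(n_w, _EPS), _PCLIP, 1 - _PCLIP)
    if model == "DINA":
        conj = red.prod(axis=1).astype(bool)
        p = np.empty(red.shape[0])
        for grp in (conj, ~conj):
            p[grp] = np.clip(r_w[grp].sum() / max(n_w[grp].sum(), _EPS), _PCLIP, 1 - _PCLIP)
        return p
    if model == "DINO":
        disj = red.any(axis=1)
        p = np.empty(red.shape[0])
        for grp in (disj, ~disj):
            p[grp] = np.clip(r_w[grp].sum() / max(n_w[grp].sum(), _EPS), _PCLIP, 1 - _PCLIP)
        return p
    design = _factorial_design(k_star)[:, : 1 + k_star]  # additive part

    def nll_from_p(p):
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        return -(r_w @ np.log(p) + (n_w - r_w) @ np.log(1 - p))

    to_p = {
        "ACDM": lambda d: design @ d,
        "LLM": lambda d: expit(design @ d),
        "RRUM": lambda d: np.exp(np.minimum(design @ d, 0.0)),
    }.get(model)
    if to_p is None:
        raise ValueError(f"unknown model {model!r}")
    target = np.clip(p_cur, 0.01, 0.99)
    link = {"ACDM": lambda p: p, "LLM": logit, "RRUM": np.log}[model]
    x0 = np.linalg.lstsq(design, link(target), rcond=None)[0]
    res = optimize.minimize(lambda d: nll_from_p(to_p(d)), x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    p_new = np.clip(to_p(res.x), _PCLIP, 1 - _PCLIP)
    # generalized-EM guard: keep the current point unless the expected
    # complete-data log-likelihood actually improved
    return p_new if nll_from_p(p_new) <= nll_from_p(p_cur) else np.asarray(p_cur)


def _init_p(model: str, k_star: int, lo: float, hi: float) -> np.ndarray:
    """Starting reduced-profile probabilities *inside* the model's space.

    Anchors: lo for the no-required-skill profile, hi for the full one.
    """
    red = all_profiles(k_star)
    if model == "DINA" or k_star == 1:
        return lo + (hi - lo) * red.prod(axis=1).astype(float)
    if model == "DINO":
        return lo + (hi - lo) * red.any(axis=1).astype(float)
    frac = red.mean(axis=1)  # fraction of required skills mastered
    if model in ("GDINA", "ACDM"):
        return lo + (hi - lo) * frac
    if model == "LLM":
        return expit(logit(lo) + (logit(hi) - logit(lo)) * frac)
    if model == "RRUM":
        return np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * frac)
    raise ValueError(f"unknown model {model!r}")


def _item_param_count(model: str, k_star: int) -> int:
    if k_star == 1:
        return 2
    if model in ("DINA", "DINO"):
        return 2
    if model == "GDINA":
        return 2**k_star
    return 1 + k_star  # additive models


def _marginal_loglik(y, mask, probs, pi):
    """Log marginal likelihood and posterior over the 2^K classes."""
    logp = np.log(probs)
    log1m = np.log(1 - probs)
    ll = (y * mask) @ logp + ((1 - y) * mask) @ log1m  # (N, C)
    ll = ll + np.log(pi)[None, :]
    mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    tot = w.sum(axis=1)
    return float((mx[:, 0] + np.log(tot)).sum()), w / tot[:, None]


def fit_dcm_em(y_module, q_module: QMatrix, model: str, tol: float = 1e-7,
               max_iter: int = 1000, n_restarts: int = 5, seed: int = 0,
               mask=None) -> EMFit:
    """Marginal maximum-likelihood EM fit of one module under one model.

    An unstructured mixing vector over the 2^K attribute profiles is
    estimated alongside the item parameters.  EM stops when the relative
    log-likelihood change falls below ``tol``; non-convergence within
    ``max_iter`` sets ``converged = False`` instead of raising.  The best
    of ``n_restarts`` jittered starts is returned.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    y = np.asarray(y_module, dtype=float)
    n, j = y.shape
    mask = np.ones_like(y) if mask is None else np.asarray(mask, dtype=float)
    q_rows = q_module.entries if isinstance(q_module, QMatrix) else np.asarray(q_module)
    red_idx = [_reduced_index(q_rows[jj]) for jj in range(j)]
    k_stars = [int(q_rows[jj].sum()) for jj in range(j)]
    rng = np.random.default_rng(seed)
    c = 2**K

    best = None
    for restart in range(n_restarts):
        pi = np.full(c, 1.0 / c)
        if restart:
            pi = rng.dirichlet(np.full(c, 5.0))
        p_red = []
        for jj in range(j):
            lo, hi = 0.2, 0.8
            if restart:  # jittered anchors keep the start inside the model space
                lo = float(np.clip(0.2 + 0.1 * rng.standard_normal(), 0.05, 0.45))
                hi = float(np.clip(0.8 + 0.1 * rng.standard_normal(), 0.55, 0.95))
            p_red.append(_init_p(model, k_stars[jj], lo, hi))

        prev = -np.inf
        path = []
        converged = False
        for _ in range(max_iter):
            probs = np.vstack([p_red[jj][red_idx[jj]] for jj in range(j)])  # (J, C)
            ll, post = _marginal_loglik(y, mask, probs, pi)
            path.append(ll)
            if prev > -np.inf and ll - prev < tol * abs(prev):
                converged = True
                break
            prev = ll
            pi = np.clip(post.mean(axis=0), 1e-10, None)
            pi = pi / pi.sum()
            for jj in range(j):
                w = post * mask[:, jj][:, None]
                n_c = w.sum(axis=0)
                r_c = (w * y[:, jj][:, None]).sum(axis=0)
                n_w = np.bincount(red_idx[jj], weights=n_c, minlength=2 ** k_stars[jj])
                r_w = np.bincount(red_idx[jj], weights=r_c, minlength=2 ** k_stars[jj])
                p_red[jj] = _mstep_item(model, r_w, n_w, k_stars[jj], p_red[jj])
        if best is None or ll > best[0]:
            best = (ll, pi, [p.copy() for p in p_red], converged, np.array(path))

    ll, pi, p_red, converged, path = best
    probs = np.vstack([p_red[jj][red_idx[jj]] for jj in range(j)])  # (J, C)
    _, post = _marginal_loglik(y, mask, probs, pi)
    item_params = []
    for jj in range(j):
        red = all_profiles(k_stars[jj])
        conj = red.prod(axis=1).astype(bool)
        item_params.append({
            "p_reduced": p_red[jj],
            "k_star": k_stars[jj],
            "slipping": float(1 - p_red[jj][conj].mean()),
            "guessing": float(p_red[jj][~conj].mean()) if (~conj).any() else float("nan"),
        })
    n_params = sum(_item_param_count(model, ks) for ks in k_stars) + (c - 1)
    qm = q_module if isinstance(q_module, QMatrix) else None
    return EMFit(model=model, pi=pi, item_probs=probs, item_params=item_params,
                 loglik=ll, n_params=n_params, n_persons=n, converged=converged,
                 loglik_path=path, q=qm, posterior=post)


def information_criteria(loglik: float, p: int, n: int):
    """AIC = -2 l + 2p and BIC = -2 l + p ln n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * loglik + 2.0 * p, -2.0 * loglik + p * np.log(n)


# Wald restrictions on the reduced-probability vector of a saturated item.
# Each entry: (contrast builder, transform, df).
def _wald_restriction(reduced_model: str, k_star: int):
    m = 2**k_star
    red = all_profiles(k_star)
    conj = red.prod(axis=1).astype(bool)
    disj = red.any(axis=1)
    if reduced_model == "DINA":
        # all non-conjunctive cells equal
        rows = []
        base = np.flatnonzero(~conj)[0]
        for r in np.flatnonzero(~conj)[1:]:
            v = np.zeros(m)
            v[base], v[r] = -1.0, 1.0
            rows.append(v)
        return np.array(rows), "identity"
    if reduced_model == "DINO":
        rows = []
        base = np.flatnonzero(disj)[0]
        for r in np.flatnonzero(disj)[1:]:
            v = np.zeros(m)
            v[base], v[r] = -1.0, 1.0
            rows.append(v)
        return np.array(rows), "identity"
    if reduced_model in ("ACDM", "LLM", "RRUM"):
        # zero interaction contrasts in the link scale
        design = _factorial_design(k_star)
        # contrasts: rows of inv(design) corresponding to interaction terms
        inv = np.linalg.inv(design)
        rows = inv[1 + k_star:, :]
        link = {"ACDM": "identity", "LLM": "logit", "RRUM": "log"}[reduced_model]
        return np.array(rows), link
    raise ValueError(f"unknown reduced model {reduced_model!r}")


def _item_scores(fit: EMFit, item: int, y_item: np.ndarray) -> np.ndarray:
    """Per-person score contributions wrt one item's reduced probabilities."""
    par = fit.item_params[item]
    m = 2 ** par["k_star"]
    p_r = par["p_reduced"]
    red_idx = _reduced_index(fit.q.entries[item])
    grp = np.zeros((fit.posterior.shape[1], m))
    grp[np.arange(fit.posterior.shape[1]), red_idx] = 1.0
    w_pc = fit.posterior @ grp            # (N, m) posterior mass per group
    return w_pc * ((y_item[:, None] - p_r[None, :])
                   / (p_r * (1 - p_r))[None, :])


def saturated_covariance(fit: EMFit, y_module: np.ndarray) -> list:
    """Per-item covariance blocks of the saturated reduced probabilities.

    The full outer-product-of-gradients information over *all* item cells
    plus the free mixing weights is inverted and the item-diagonal blocks
    extracted; inverting an item's block alone ignores cross-parameter
    correlation and badly understates the variance.
    """
    y_module = np.asarray(y_module, dtype=float)
    blocks = []
    offsets = []
    cols = []
    for jj in range(len(fit.item_params)):
        offsets.append(sum(b.shape[1] for b in cols))
        cols.append(_item_scores(fit, jj, y_module[:, jj]))
    # free mixing weights: first class is the reference
    pi = fit.pi
    cols.append(fit.posterior[:, 1:] / pi[None, 1:]
                - (fit.posterior[:, [0]] / pi[0]))
    scores = np.hstack(cols)
    opg = scores.T @ scores
    try:
        v_full = np.linalg.inv(opg + 1e-10 * np.eye(opg.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular full information matrix") from exc
    for jj, off in enumerate(offsets):
        m = 2 ** fit.item_params[jj]["k_star"]
        blocks.append(v_full[off:off + m, off:off + m])
    return blocks


def wald_item_test(saturated_fit: EMFit, item: int, reduced_model: str,
                   alpha_level: float = 0.05, y_module=None):
    """Wald test of a reduced item model against the saturated GDINA item.

    The covariance of the saturated reduced-profile probabilities comes
    from the full-model outer-product-of-gradients (see
    :func:`saturated_covariance`); restrictions are linear contrasts on
    the identity, logit or log scale.  Returns (W, df, p_value, retained).
    """
    if saturated_fit.model != "GDINA":
        raise ValueError("Wald tests require the saturated GDINA fit")
    par = saturated_fit.item_params[item]
    k_star = par["k_star"]
    if k_star < 2:
        raise ValueError("single-attribute items are exempt from Wald testing")
    p_r = par["p_reduced"]
    if y_module is None:
        raise ValueError("the module's response matrix is required")
    if getattr(saturated_fit, "_vcov_blocks", None) is None:
        saturated_fit._vcov_blocks = saturated_covariance(saturated_fit, y_module)
    v_p = saturated_fit._vcov_blocks[item]
    r_mat, link = _wald_restriction(reduced_model, k_star)
    if r_mat.size == 0:
        raise ValueError("restriction matrix has no rows")
    if link == "identity":
        h = r_mat @ p_r
        jac = r_mat
    elif link == "logit":
        h = r_mat @ logit(p_r)
        jac = r_mat / (p_r * (1 - p_r))[None, :]
    else:
        h = r_mat @ np.log(p_r)
        jac = r_mat / p_r[None, :]
    cov_h = jac @ v_p @ jac.T
    try:
        w_stat = float(h @ np.linalg.solve(cov_h, h))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"unstable item {item}: singular restriction covariance") from exc
    df = r_mat.shape[0]
    p_val = float(stats.chi2.sf(max(w_stat, 0.0), df))
    return w_stat, df, p_val, p_val >= alpha_level


def _item_decisions(sat_fit: EMFit, y_module, alpha_level: float):
    rows = []
    for jj, par in enumerate(sat_fit.item_params):
        if par["k_star"] < 2:
            rows.append({"item": jj, "decision": "DINA", "note": "single-attribute"})
            continue
        retained = {}
        for model in ("DINA", "DINO", "ACDM", "LLM", "RRUM"):
            try:
                w, df, p, keep = wald_item_test(sat_fit, jj, model, alpha_level,
                                                y_module=y_module)
            except np.linalg.LinAlgError:
                continue
            if keep:
                retained[model] = p
        if not retained:
            decision = "GDINA"
        elif "DINA" in retained:
            decision = "DINA"
        elif "DINO" in retained:
            decision = "DINO"
        else:
            decision = max(retained, key=retained.get)
        rows.append({"item": jj, "decision": decision,
                     "note": ";".join(f"{m}:p={p:.3f}" for m, p in retained.items())})
    return pd.DataFrame(rows)


def select_measurement_model(y_by_module: dict, q: QMatrix, alpha_level: float = 0.05,
                             seed: int = 0, n_restarts: int = 3):
    """Test-level (AIC/BIC) and item-level (Wald) measurement-model selection.

    ``y_by_module`` maps module number (1..4) to its (N, 10) response block.
    Returns a dict with the fit-index table (6 models x modules x AIC/BIC),
    per-item Wald decisions, and an overall recommendation by majority with
    parsimony (ties fall to DINA).
    """
    fit_rows = []
    decisions = []
    votes = []
    for m, y_m in sorted(y_by_module.items()):
        items = q.items_in_module(m)
        q_m = QMatrix(entries=q.entries[items], module_of_item=np.full(items.size, m))
        fits = {}
        for model in MODELS:
            fit = fit_dcm_em(y_m, q_m.entries, model, seed=seed, n_restarts=n_restarts)
            fit.q = q_m
            fits[model] = fit
            aic, bic = information_criteria(fit.loglik, fit.n_params, fit.n_persons)
            fit_rows.append({"module": m, "model": model, "loglik": fit.loglik,
                             "n_params": fit.n_params, "AIC": aic, "BIC": bic})
        sub = [r for r in fit_rows if r["module"] == m]
        votes.append(min(sub, key=lambda r: r["AIC"])["model"])
        votes.append(min(sub, key=lambda r: r["BIC"])["model"])
        dec = _item_decisions(fits["GDINA"], y_m, alpha_level)
        dec.insert(0, "module", m)
        decisions.append(dec)
    table = pd.DataFrame(fit_rows)
    decisions = pd.concat(decisions, ignore_index=True)
    item_votes = decisions["decision"].tolist()
    counts = pd.Series(votes + item_votes).value_counts()
    top = counts[counts == counts.max()].index.tolist()
    recommendation = "DINA" if "DINA" in top else top[0]
    return {"fit_table": table, "item_decisions": decisions,
            "recommendation": recommendation}
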