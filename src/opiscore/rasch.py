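"""Dichotomous Rasch model: MML-EM estimation, EAP/WLE person scores,
reliability coefficients, and infit/outfit item fit statistics.

Estimation is marginal maximum likelihood over a normal latent distribution
with mean fixed at 0 (identification) and variance estimated, using
Gauss–Hermite quadrature. The E-step/M-step cycle is exact in the item
difficulties (per-item Newton to convergence) while the latent SD is
updated by direct maximization of the true marginal likelihood, so the
marginal log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit, logsumexp

from .errors import (
    DegenerateDataError,
    InvalidArgumentError,
    UndefinedStatisticError,
)
from .scoring import ItemResponseMatrix

_W_FLOOR = 1e-10


@dataclass
class RaschFit:
    """Fitted model state plus derived person/item statistics.

    ``delta`` holds +inf for all-zero items and -inf for all-one items;
    ``item_mask`` marks the items with mixed responses that entered the
    likelihood.
    """

    delta: np.ndarray
    delta_se: np.ndarray
    item_mask: np.ndarray
    latent_mean: float
    latent_sd: float
    log_likelihood: float
    converged: bool
    n_iter: int
    nodes: np.ndarray = field(repr=False, default=None)
    node_weights: np.ndarray = field(repr=False, default=None)
    theta_eap: np.ndarray | None = None
    psd_eap: np.ndarray | None = None
    theta_wle: np.ndarray | None = None
    se_wle: np.ndarray | None = None
    eap_reliability: float | None = None
    wle_reliability: float | None = None
    infit_mnsq: np.ndarray | None = None
    outfit_mnsq: np.ndarray | None = None


def _as_scores(matrix: ItemResponseMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ItemResponseMatrix):
        return np.asarray(matrix.scores, dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or not np.isin(x, (0, 1)).all():
        raise InvalidArgumentError("matrix must be 2-D binary")
    return x


def _log_lik_nq(x: np.ndarray, theta_q: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Per-person, per-node conditional log-likelihood (N, Q)."""
    logits = theta_q[None, :, None] - delta[None, None, :]  # (1, Q, I)
    # log sigmoid(±logits), numerically stable
    log_p = -np.logaddexp(0.0, -logits)
    log_q = -np.logaddexp(0.0, logits)
    return np.einsum("ni,qi->nq", x, log_p[0]) + np.einsum("ni,qi->nq", 1.0 - x, log_q[0])


def marginal_log_likelihood(
    x: np.ndarray, delta: np.ndarray, sigma: float, z: np.ndarray, logw: np.ndarray
) -> float:
    theta_q = np.sqrt(2.0) * sigma * z
    ll = _log_lik_nq(x, theta_q, delta)
    return float(logsumexp(ll + logw[None, :], axis=1).sum())


def fit_rasch_mml(
    matrix: ItemResponseMatrix | np.ndarray,
    n_quadrature: int = 41,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> RaschFit:
    """Fit the Rasch model by MML-EM with Gauss–Hermite quadrature.

    All-zero/all-one items are excluded from the likelihood and reported
    with ±inf difficulty. Raises ``DegenerateDataError`` when no item has
    mixed responses; a non-converged fit is returned with a warning and
    ``converged=False``.
    """
    x_full = _as_scores(matrix)
    n, n_items = x_full.shape
    if n < 2 or n_items < 2:
        raise InvalidArgumentError("need at least 2 persons and 2 items")
    col = x_full.sum(axis=0)
    mask = (col > 0) & (col < n)
    if not mask.any():
        raise DegenerateDataError("no item has mixed responses")
    x = x_full[:, mask]

    z, w = np.polynomial.hermite.hermgauss(n_quadrature)
    logw = np.log(w) - 0.5 * np.log(np.pi)

    # Start from logit-transformed proportions; latent SD 1.
    p = x.mean(axis=0)
    delta = -np.log(p / (1.0 - p))
    sigma = 1.0
    ll_old = marginal_log_likelihood(x, delta, sigma, z, logw)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_q = np.sqrt(2.0) * sigma * z
        ll_nq = _log_lik_nq(x, theta_q, delta)
        post = ll_nq + logw[None, :]
        post -= logsumexp(post, axis=1, keepdims=True)
        wq = np.exp(post)  # (N, Q)
        n_q = wq.sum(axis=0)  # (Q,)
        r_qi = wq.T @ x  # (Q, I) expected successes at each node

        # Exact M-step for difficulties: per-item 1-D Newton.
        delta_new = delta.copy()
        for _ in range(50):
            p_qi = expit(theta_q[:, None] - delta_new[None, :])
            f = r_qi.sum(axis=0) - (n_q[:, None] * p_qi).sum(axis=0)
            fp = (n_q[:, None] * p_qi * (1.0 - p_qi)).sum(axis=0)
            step = f / np.maximum(fp, _W_FLOOR)
            delta_new = delta_new - np.clip(step, -2.0, 2.0)
            if np.max(np.abs(step)) < 0.1 * tol:
                break

        # Latent SD: direct line search on the true marginal likelihood.
        def neg_ll(log_s: float) -> float:
            return -marginal_log_likelihood(x, delta_new, np.exp(log_s), z, logw)

        res = minimize_scalar(
            neg_ll, bounds=(np.log(0.05), np.log(10.0)), method="bounded",
            options={"xatol": 1e-6},
        )
        sigma_new = float(np.exp(res.x))
        if -res.fun < marginal_log_likelihood(x, delta_new, sigma, z, logw):
            sigma_new = sigma  # guard: never decrease the objective

        ll_new = marginal_log_likelihood(x, delta_new, sigma_new, z, logw)
        shift = max(np.max(np.abs(delta_new - delta)), abs(sigma_new - sigma))
        delta, sigma, ll_old = delta_new, sigma_new, ll_new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Rasch MML-EM did not converge", RuntimeWarning)

    # Wald SEs from expected complete-data information at the solution.
    theta_q = np.sqrt(2.0) * sigma * z
    ll_nq = _log_lik_nq(x, theta_q, delta)
    post = ll_nq + logw[None, :]
    post -= logsumexp(post, axis=1, keepdims=True)
    wq = np.exp(post)
    p_qi = expit(theta_q[:, None] - delta[None, :])
    info = (wq.sum(axis=0)[:, None] * p_qi * (1.0 - p_qi)).sum(axis=0)
    se = 1.0 / np.sqrt(np.maximum(info, _W_FLOOR))

    delta_full = np.full(n_items, np.inf)
    delta_full[col == n] = -np.inf
    delta_full[mask] = delta
    se_full = np.full(n_items, np.nan)
    se_full[mask] = se
    return RaschFit(
        delta=delta_full,
        delta_se=se_full,
        item_mask=mask,
        latent_mean=0.0,
        latent_sd=sigma,
        log_likelihood=ll_old,
        converged=converged,
        n_iter=it,
        nodes=z,
        node_weights=logw,
    )


def eap_scores(
    fit: RaschFit, matrix: ItemResponseMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD of ability per person on the quadrature grid."""
    x = _as_scores(matrix)[:, fit.item_mask]
    theta_q = np.sqrt(2.0) * fit.latent_sd * fit.nodes
    post = _log_lik_nq(x, theta_q, fit.delta[fit.item_mask]) + fit.node_weights[None, :]
    post -= logsumexp(post, axis=1, keepdims=True)
    wq = np.exp(post)
    mean = wq @ theta_q
    var = wq @ theta_q**2 - mean**2
    fit.theta_eap = mean
    fit.psd_eap = np.sqrt(np.maximum(var, 0.0))
    return fit.theta_eap, fit.psd_eap


def _wle_solve(r: float, delta: np.ndarray) -> float:
    """Warm's weighted-likelihood ability for raw score r on items delta."""

    def g(theta: float) -> float:
        p = expit(theta - delta)
        i = np.sum(p * (1.0 - p))
        j = np.sum(p * (1.0 - p) * (1.0 - 2.0 * p))
        return r - p.sum() + j / (2.0 * max(i, _W_FLOOR))

    lo, hi = -15.0, 15.0
    if g(lo) <= 0:
        return lo
    if g(hi) >= 0:
        return hi
    return float(brentq(g, lo, hi, xtol=1e-10))


def wle_scores(
    fit: RaschFit, matrix: ItemResponseMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Warm's bias-corrected ML ability and SE = 1/sqrt(information).

    Finite at perfect and zero raw scores; by Rasch sufficiency the
    estimate depends on the response pattern only through the raw score.
    """
    x = _as_scores(matrix)[:, fit.item_mask]
    delta = fit.delta[fit.item_mask]
    raw = x.sum(axis=1)
    theta = np.empty(x.shape[0])
    se = np.empty(x.shape[0])
    cache: dict[float, tuple[float, float]] = {}
    for n, r in enumerate(raw):
        if r not in cache:
            th = _wle_solve(float(r), delta)
            p = expit(th - delta)
            info = float(np.sum(p * (1.0 - p)))
            cache[r] = (th, 1.0 / np.sqrt(max(info, _W_FLOOR)))
        theta[n], se[n] = cache[r]
    fit.theta_wle = theta
    fit.se_wle = se
    return theta, se


def eap_reliability(theta_eap: np.ndarray, psd_eap: np.ndarray) -> float:
    """var(EAP) / (var(EAP) + mean(PSD²)), clipped to [0, 1]."""
    theta_eap = np.asarray(theta_eap, dtype=float)
    if theta_eap.size < 2:
        raise InvalidArgumentError("need at least 2 persons")
    v = float(np.var(theta_eap, ddof=1))
    denom = v + float(np.mean(np.asarray(psd_eap) ** 2))
    if denom <= 0:
        raise UndefinedStatisticError("zero total variance")
    return float(np.clip(v / denom, 0.0, 1.0))


def wle_reliability(theta_wle: np.ndarray, se_wle: np.ndarray) -> float:
    """1 − mean(SE²) / var(WLE), clipped to [0, 1]."""
    theta_wle = np.asarray(theta_wle, dtype=float)
    if theta_wle.size < 2:
        raise InvalidArgumentError("need at least 2 persons")
    v = float(np.var(theta_wle, ddof=1))
    if v <= 0:
        raise UndefinedStatisticError("zero observed-score variance")
    return float(np.clip(1.0 - float(np.mean(np.asarray(se_wle) ** 2)) / v, 0.0, 1.0))


def infit_outfit(
    fit: RaschFit,
    matrix: ItemResponseMatrix | np.ndarray,
    person_estimates: str = "posterior",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-item mean-square fit statistics; 1.0 is model-conforming.

    The default ``'posterior'`` mode scores each item against its
    leave-one-out posterior-predictive probability (posterior over ability
    computed from the *other* items), under which the standardized
    mean-square has expectation exactly 1 for a model-conforming item —
    plugging point abilities into the classic formula deflates the null
    mean-square by roughly (I−1)/I because each person's ability is fitted
    to their own responses. ``'wle'``/``'eap'`` select the classic plug-in
    statistics. Items without mixed responses get NaN.
    """
    x_full = _as_scores(matrix)
    n_items = x_full.shape[1]
    infit = np.full(n_items, np.nan)
    outfit = np.full(n_items, np.nan)
    if person_estimates == "posterior":
        x = x_full[:, fit.item_mask]
        delta = fit.delta[fit.item_mask]
        theta_q = np.sqrt(2.0) * fit.latent_sd * fit.nodes
        log_post = _log_lik_nq(x, theta_q, delta) + fit.node_weights[None, :]
        logits = theta_q[:, None] - delta[None, :]
        p_qi = expit(logits)
        log_p = -np.logaddexp(0.0, -logits)
        log_q = -np.logaddexp(0.0, logits)
        for j, i in enumerate(np.flatnonzero(fit.item_mask)):
            item_ll = np.where(x[:, [j]] > 0, log_p[None, :, j], log_q[None, :, j])
            lp = log_post - item_ll
            lp -= logsumexp(lp, axis=1, keepdims=True)
            p_tilde = np.exp(lp) @ p_qi[:, j]
            w = p_tilde * (1.0 - p_tilde)
            keep = w > _W_FLOOR
            if not keep.any():
                warnings.warn(f"item {i}: all residual variances below floor", RuntimeWarning)
                continue
            resid2 = (x[keep, j] - p_tilde[keep]) ** 2
            outfit[i] = float(np.mean(resid2 / w[keep]))
            infit[i] = float(resid2.sum() / w[keep].sum())
    elif person_estimates in ("wle", "eap"):
        if person_estimates == "wle":
            if fit.theta_wle is None:
                wle_scores(fit, matrix)
            theta = fit.theta_wle
        else:
            if fit.theta_eap is None:
                eap_scores(fit, matrix)
            theta = fit.theta_eap
        for i in np.flatnonzero(fit.item_mask):
            e = expit(theta - fit.delta[i])
            w = e * (1.0 - e)
            keep = w > _W_FLOOR
            if not keep.any():
                warnings.warn(f"item {i}: all residual variances below floor", RuntimeWarning)
                continue
            resid2 = (x_full[keep, i] - e[keep]) ** 2
            outfit[i] = float(np.mean(resid2 / w[keep]))
            infit[i] = float(resid2.sum() / w[keep].sum())
    else:
        raise InvalidArgumentError(
            "person_estimates must be 'posterior', 'wle' or 'eap'"
        )
    fit.infit_mnsq = infit
    fit.outfit_mnsq = outfit
    return infit, outfit


def flag_fit(
    infit_mnsq: np.ndarray, lower: float = 0.7, upper: float = 1.3
) -> list[str]:
    """'ok' / 'low' / 'high' per item against the chosen infit bounds."""
    if lower >= upper:
        raise InvalidArgumentError("lower bound must be below upper bound")
    flags = []
    for v in np.asarray(infit_mnsq, dtype=float):
        if np.isnan(v):
            flags.append("undefined")
        elif v < lower:
            flags.append("low")
        elif v > upper:
            flags.append("high")
        else:
            flags.append("ok")
    return flags


def calibrate(
    matrix: ItemResponseMatrix | np.ndarray,
    n_quadrature: int = 41,
    tol: float = 1e-5,
    max_iter: int = 500,
    fit_person_estimates: str = "posterior",
) -> RaschFit:
    """Full calibration: fit, person scores, reliabilities, item fit."""
    fit = fit_rasch_mml(matrix, n_quadrature=n_quadrature, tol=tol, max_iter=max_iter)
    eap_scores(fit, matrix)
    wle_scores(fit, matrix)
    fit.eap_reliability = eap_reliability(fit.theta_eap, fit.psd_eap)
    fit.wle_reliability = wle_reliability(fit.theta_wle, fit.se_wle)
    infit_outfit(fit, matrix, person_estimates=fit_person_estimates)
    return fit
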