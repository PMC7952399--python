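"""EM deconvolution of bulk methylation with aberrant-CpG down-weighting.

The model: the observed beta-value z_ki of CpG k in bulk sample i is a
two-component scale mixture around the deconvolution mean

    mu_ki = eta_i nu_0k + sum_q rho_qi nu_qk,

with a "consistent" component N(mu, sigma_c^2 w_ki) and an "aberrant"
component N(mu, sigma_a^2 w_ki), sigma_a >= sigma_c.  The per-sample
mixing weight pi_ai is the prior probability that a CpG is aberrant in
sample i.  Proportions rho_i live on the simplex {rho >= 0,
sum_q rho_qi = 1 - eta_i} and carry a ridge penalty to stabilise the fit
when reference profiles are collinear (e.g. CD4T vs CD8T).  Parameters
are estimated by an EM algorithm whose M-step for rho is a small convex
quadratic program per sample.

A Laplace error family is available as a robust variant: densities are
Laplace with the same second moments, and the proportion update becomes
a ridge-penalised weighted least-absolute-deviations problem solved by
iteratively reweighted QP.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import (BulkBetaMatrix, EMethFit, EmethError, FitOptions,
                 ReferenceMatrix, SampleInfo, align_by_cpg)
from .nu0 import estimate_nu0

logger = logging.getLogger("emeth")

_WEIGHT_FLOOR = 1e-6       # floor for binomial variance multipliers
_VAR_FLOOR = 1e-12         # floor for sigma_a^2 / sigma_c^2
_LAD_EPS = 1e-6            # |e| smoothing for the Laplace IRLS rho update
_ABERRANT_MAJORITY_WARNING = (
    "more than half of the CpG-sample entries are flagged aberrant; "
    "the cell type-specific reference may be inappropriate for these samples"
)

__all__ = [
    "WeightMatrix", "e_step_posterior", "m_step_proportions",
    "m_step_variances_and_pi", "penalized_loglik", "select_ridge",
    "fit_emeth",
]


# ---------------------------------------------------------------------------
# Variance multipliers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightMatrix:
    """Positive variance multipliers w_ki (K x I)."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if (vals <= 0).any():
            raise EmethError("weight matrix entries must be > 0")
        object.__setattr__(self, "values", vals)

    @classmethod
    def ones(cls, K: int, I: int) -> "WeightMatrix":
        return cls(np.ones((K, I)))

    @classmethod
    def binomial(cls, ref_values: np.ndarray, rho: np.ndarray,
                 eta: np.ndarray, nu0: np.ndarray | None) -> "WeightMatrix":
        """w_ki = sum_q rho_qi nu_qk (1-nu_qk) + eta_i nu_0k (1-nu_0k)."""
        w = (ref_values * (1.0 - ref_values)) @ rho
        if nu0 is not None:
            w = w + np.outer(nu0 * (1.0 - nu0), eta)
        return cls(np.maximum(w, _WEIGHT_FLOOR))


# ---------------------------------------------------------------------------
# Component log-densities, E-step and observed-data likelihood
# ---------------------------------------------------------------------------

def _log_densities(residuals, weights, sigma_a2, sigma_c2, family):
    """Return (log f_a, log f_c) elementwise for the two components."""
    if sigma_c2 <= 0 or sigma_a2 <= 0:
        raise EmethError("component variances must be positive")
    if family == "normal":
        qa = residuals * residuals / weights
        la = -0.5 * (np.log(2.0 * np.pi * sigma_a2 * weights) + qa / sigma_a2)
        lc = -0.5 * (np.log(2.0 * np.pi * sigma_c2 * weights) + qa / sigma_c2)
        return la, lc
    if family == "laplace":
        # Laplace(0, b) with 2 b^2 = sigma^2 w  (matched second moments)
        babs = np.abs(residuals) / np.sqrt(0.5 * weights)
        sa, sc = np.sqrt(sigma_a2), np.sqrt(sigma_c2)
        la = -np.log(2.0 * np.sqrt(0.5 * weights) * sa) - babs / sa
        lc = -np.log(2.0 * np.sqrt(0.5 * weights) * sc) - babs / sc
        return la, lc
    raise EmethError(f"unknown error family {family!r}")


def e_step_posterior(residuals, weights, sigma_a2, sigma_c2, pi_a,
                     family: str = "normal"):
    """Posterior probability gamma_ki that entry (k, i) is aberrant.

    Bayes' rule on the two component densities, evaluated in log space:
    gamma = expit(log f_a - log f_c + logit(pi_a)).
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    w = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    w = np.broadcast_to(np.atleast_2d(w), residuals.shape)
    pi_a = np.atleast_1d(np.asarray(pi_a, dtype=float))
    if (pi_a < 0).any() or (pi_a > 1).any():
        raise EmethError("pi_a entries must lie in [0, 1]")
    if sigma_c2 > sigma_a2:
        raise EmethError("need sigma_a2 >= sigma_c2")
    la, lc = _log_densities(residuals, w, sigma_a2, sigma_c2, family)
    with np.errstate(divide="ignore"):
        logit_pi = np.log(pi_a) - np.log1p(-pi_a)
    x = (la - lc) + logit_pi[np.newaxis, :]
    gamma = np.empty_like(x)
    pos = x >= 0
    gamma[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    gamma[~pos] = ex / (1.0 + ex)
    # degenerate priors are exactly degenerate posteriors
    gamma[:, pi_a == 0.0] = 0.0
    gamma[:, pi_a == 1.0] = 1.0
    return gamma


def penalized_loglik(residuals, weights, sigma_a2, sigma_c2, pi_a, rho,
                     ridge: float, family: str = "normal") -> float:
    """Observed-data penalized log-likelihood.

    sum_ki log[pi_ai f_a(e_ki) + (1 - pi_ai) f_c(e_ki)] - ridge * sum rho^2.
    This is the quantity the EM iterations monotonically increase while
    ridge and nu0 are held fixed.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    w = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    w = np.broadcast_to(np.atleast_2d(w), residuals.shape)
    pi_a = np.atleast_1d(np.asarray(pi_a, dtype=float))
    la, lc = _log_densities(residuals, w, sigma_a2, sigma_c2, family)
    with np.errstate(divide="ignore"):
        ll = np.logaddexp(np.log(pi_a)[None, :] + la,
                          np.log1p(-pi_a)[None, :] + lc)
    total = float(ll.sum() - ridge * np.sum(np.square(rho)))
    if not np.isfinite(total):
        k, i = np.argwhere(~np.isfinite(ll))[0]
        raise EmethError(f"non-finite log-likelihood at CpG row {k}, sample {i}")
    return total


# ---------------------------------------------------------------------------
# Simplex-constrained quadratic programming (batched active set)
# ---------------------------------------------------------------------------

def _solve_simplex_qp(H, b, s, free0=None):
    """Minimise 0.5 rho' H rho - b' rho  s.t.  sum rho = s, rho >= 0.

    H : (I, Q, Q) positive definite, b : (I, Q), s : (I,).
    Primal active-set method run batched over samples: active bounds are
    written into the KKT system as identity rows and all systems are
    solved with one batched ``np.linalg.solve`` per sweep.
    """
    H = np.asarray(H, float)
    b = np.asarray(b, float)
    I, Q = b.shape
    s = np.broadcast_to(np.asarray(s, float), (I,))
    if (s < 0).any():
        raise EmethError("infeasible simplex constraint: negative target mass")
    # relative jitter keeps the batched solves non-singular under exact
    # reference collinearity with zero ridge
    diag_scale = np.einsum("iqq->i", H) / Q
    H = H + (1e-10 * np.maximum(diag_scale, 1e-30))[:, None, None] * np.eye(Q)

    free = np.ones((I, Q), bool) if free0 is None else free0.copy()
    free[~np.any(free, axis=1)] = True
    rho = np.zeros((I, Q))
    active_samples = s > 0
    done = ~active_samples
    kkt = np.zeros((I, Q + 1, Q + 1))
    rhs = np.zeros((I, Q + 1, 1))
    tol = 1e-9 * max(1.0, float(np.abs(b).max(initial=0.0)))

    for _ in range(3 * Q + 10):
        todo = ~done
        if not todo.any():
            break
        idx = np.where(todo)[0]
        kkt[idx, :Q, :Q] = H[idx]
        kkt[idx, Q, :Q] = 1.0
        kkt[idx, :Q, Q] = 1.0
        kkt[idx, Q, Q] = 0.0
        rhs[idx, :Q, 0] = b[idx]
        rhs[idx, Q, 0] = s[idx]
        # clamp active coordinates: identity row, zero rhs
        rows = np.where(todo[:, None] & ~free)
        kkt[rows[0], rows[1], :] = 0.0
        kkt[rows[0], rows[1], rows[1]] = 1.0
        rhs[rows[0], rows[1], 0] = 0.0
        try:
            sol = np.linalg.solve(kkt[idx], rhs[idx])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise EmethError(f"QP solver failed: singular KKT system ({exc})")
        rho_t, mu_t = sol[:, :Q], sol[:, Q]
        neg = (rho_t < -1e-12) & free[idx]
        has_neg = neg.any(axis=1)
        # samples with a negative free coordinate: clamp the most negative
        if has_neg.any():
            sub = idx[has_neg]
            jneg = np.argmin(np.where(neg[has_neg], rho_t[has_neg], np.inf),
                             axis=1)
            free[sub, jneg] = False
        # feasible samples: release the most binding bound or finish
        ok = ~has_neg
        if ok.any():
            sub = idx[ok]
            rho_ok = np.maximum(rho_t[ok], 0.0)
            rho[sub] = rho_ok
            grad = np.einsum("iqp,ip->iq", H[sub], rho_ok) - b[sub] \
                + mu_t[ok][:, None]
            lam = np.where(~free[sub], grad, np.inf)
            jmin = np.argmin(lam, axis=1)
            release = lam[np.arange(len(sub)), jmin] < -tol
            free[sub[release], jmin[release]] = True
            done[sub[~release]] = True
    else:
        bad = int(np.where(~done)[0][0])
        raise EmethError(f"QP active-set did not converge for sample index {bad}")
    # re-impose the equality exactly after clipping round-off negatives
    gap = s - rho.sum(axis=1)
    rho[np.arange(I), np.argmax(rho, axis=1)] += gap
    return rho, free


def _gram_factor(nu):
    """Per-CpG outer products nu_k nu_k', flattened for fast H assembly."""
    Q = nu.shape[1]
    return (nu[:, :, None] * nu[:, None, :]).reshape(nu.shape[0], Q * Q)


def _rho_qp_batch(y, nu, u, s, ridge, free0=None, P=None):
    """Ridge-penalised gamma-weighted LS proportions for all samples.

    Minimises 0.5 sum_k u_ki (y_ki - sum_q rho_qi nu_qk)^2 + ridge sum_q rho_qi^2
    per sample on the simplex sum rho = s_i, rho >= 0.
    """
    Q = nu.shape[1]
    if P is None:
        P = _gram_factor(nu)
    H = (u.T @ P).reshape(-1, Q, Q) + 2.0 * ridge * np.eye(Q)
    b = (nu.T @ (u * y)).T
    return _solve_simplex_qp(H, b, s, free0=free0)


def m_step_proportions(z_i, ref: ReferenceMatrix, eta_i: float, nu0,
                       gamma_i, sigma_a2: float, sigma_c2: float,
                       weights_i=None, ridge: float = 0.0):
    """Single-sample M-step update of the proportions rho_i.

    Minimises the gamma-weighted penalised residual criterion
    0.5 sum_k u_ki e_ki^2 + ridge sum_q rho_qi^2 with
    u_ki = gamma_ki / (sigma_a^2 w_ki) + (1 - gamma_ki) / (sigma_c^2 w_ki),
    subject to rho >= 0 and sum rho = 1 - eta_i (convex QP).
    """
    nu = ref.values if isinstance(ref, ReferenceMatrix) else np.asarray(ref, float)
    z_i = np.asarray(z_i, float)
    gamma_i = np.asarray(gamma_i, float)
    K = nu.shape[0]
    if eta_i > 1.0:
        raise EmethError(f"infeasible constraint: eta = {eta_i} > 1")
    if ridge < 0:
        raise EmethError("ridge penalty must be >= 0")
    w = np.ones(K) if weights_i is None else np.asarray(weights_i, float)
    u = gamma_i / (sigma_a2 * w) + (1.0 - gamma_i) / (sigma_c2 * w)
    y = z_i - eta_i * (np.zeros(K) if nu0 is None else np.asarray(nu0, float))
    rho, _ = _rho_qp_batch(y[:, None], nu, u[:, None],
                           np.array([1.0 - eta_i]), ridge)
    return rho[0]


def m_step_variances_and_pi(residuals, gamma, weights, prev=None):
    """Closed-form M-step for the global variances and per-sample priors.

    sigma_a^2 and sigma_c^2 are gamma-weighted means of e^2 / w pooled over
    all CpGs and samples; pi_ai is the per-sample mean of gamma.  If the
    raw estimates violate sigma_a^2 >= sigma_c^2 the component labels are
    swapped (gamma -> 1 - gamma, pi_a -> 1 - pi_a).  An empty component
    keeps its previous variance and a warning is recorded.

    Returns (sigma_a2, sigma_c2, pi_a, gamma, warnings).
    """
    residuals = np.atleast_2d(np.asarray(residuals, float))
    gamma = np.atleast_2d(np.asarray(gamma, float))
    w = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    w = np.broadcast_to(np.atleast_2d(w), residuals.shape)
    warns = []
    q2 = residuals * residuals / w
    wa, wc = gamma.sum(), (1.0 - gamma).sum()
    prev_a, prev_c = prev if prev is not None else (None, None)
    if wa <= 0:
        sigma_a2 = prev_a if prev_a is not None else _VAR_FLOOR
        warns.append("aberrant component empty; sigma_a2 kept at previous value")
    else:
        sigma_a2 = float((gamma * q2).sum() / wa)
    if wc <= 0:
        sigma_c2 = prev_c if prev_c is not None else _VAR_FLOOR
        warns.append("consistent component empty; sigma_c2 kept at previous value")
    else:
        sigma_c2 = float(((1.0 - gamma) * q2).sum() / wc)
    sigma_a2 = max(sigma_a2, _VAR_FLOOR)
    sigma_c2 = max(sigma_c2, _VAR_FLOOR)
    if sigma_a2 < sigma_c2:
        sigma_a2, sigma_c2 = sigma_c2, sigma_a2
        gamma = 1.0 - gamma
    pi_a = gamma.mean(axis=0)
    return sigma_a2, sigma_c2, pi_a, gamma, warns


def _laplace_scale_update(residuals, gamma, w, prev):
    """Laplace analogue of the variance M-step (scale via weighted |e|)."""
    ab = np.abs(residuals) / np.sqrt(0.5 * w)
    warns = []
    wa, wc = gamma.sum(), (1.0 - gamma).sum()
    prev_a, prev_c = prev
    sa = float((gamma * ab).sum() / wa) if wa > 0 else np.sqrt(prev_a)
    sc = float(((1.0 - gamma) * ab).sum() / wc) if wc > 0 else np.sqrt(prev_c)
    if wa <= 0:
        warns.append("aberrant component empty; sigma_a2 kept at previous value")
    if wc <= 0:
        warns.append("consistent component empty; sigma_c2 kept at previous value")
    sigma_a2 = max(sa * sa, _VAR_FLOOR)
    sigma_c2 = max(sc * sc, _VAR_FLOOR)
    if sigma_a2 < sigma_c2:
        sigma_a2, sigma_c2 = sigma_c2, sigma_a2
        gamma = 1.0 - gamma
    pi_a = gamma.mean(axis=0)
    return sigma_a2, sigma_c2, pi_a, gamma, warns


# ---------------------------------------------------------------------------
# Inner EM loop (ridge and weights fixed; nu0 updated as a CM step)
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


def _estep_and_loglik(e, w, logw, sigma_a2, sigma_c2, pi_a, family):
    """One fused pass: posterior gamma and the mixture log-likelihood.

    The component log-densities are computed once and shared between the
    E-step (via a stable logistic) and the observed-data log-likelihood
    (via logaddexp).  ``logw`` is None when all weights are 1.
    """
    if family == "normal":
        q2 = e * e if w is None else e * e / w
        la = q2 * (-0.5 / sigma_a2) - 0.5 * (_LOG2PI + np.log(sigma_a2))
        lc = q2 * (-0.5 / sigma_c2) - 0.5 * (_LOG2PI + np.log(sigma_c2))
    else:
        ab = np.abs(e) * np.sqrt(2.0) if w is None else np.abs(e) * np.sqrt(2.0 / w)
        sa, sc = np.sqrt(sigma_a2), np.sqrt(sigma_c2)
        la = ab * (-1.0 / sa) - np.log(np.sqrt(2.0) * sa) - np.log(2.0)
        lc = ab * (-1.0 / sc) - np.log(np.sqrt(2.0) * sc) - np.log(2.0)
    if logw is not None:
        la = la - 0.5 * logw
        lc = lc - 0.5 * logw
    with np.errstate(divide="ignore"):
        logit_pi = np.log(pi_a) - np.log1p(-pi_a)
        lpa, lpc = np.log(pi_a), np.log1p(-pi_a)
    x = (la - lc) + logit_pi[None, :]
    gamma = _stable_expit(x)
    gamma[:, pi_a == 0.0] = 0.0
    gamma[:, pi_a == 1.0] = 1.0
    ll = float(np.logaddexp(lpa[None, :] + la, lpc[None, :] + lc).sum())
    return gamma, ll


def _stable_expit(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# Numba-compiled fused passes for the normal family.  They evaluate the
# same expressions as _estep_and_loglik / m_step_variances_and_pi in one
# sweep over the K x I grid; a unit test pins the two routes together.
try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _normal_pass(e, w, has_w, sigma_a2, sigma_c2, pi_a):
        K, I = e.shape
        gamma = np.empty((K, I))
        u = np.empty((K, I))
        ll = 0.0
        inv_a, inv_c = 1.0 / sigma_a2, 1.0 / sigma_c2
        c_d = 0.5 * (inv_c - inv_a)
        c_log = 0.5 * np.log(sigma_c2 / sigma_a2)
        lc_const = -0.5 * (_LOG2PI + np.log(sigma_c2))
        for i in range(I):
            p = pi_a[i]
            degenerate = p <= 0.0 or p >= 1.0
            lp = 0.0
            lpc = 0.0
            if not degenerate:
                lp = np.log(p) - np.log1p(-p)
                lpc = np.log1p(-p)
            for k in range(K):
                ww = w[k, i] if has_w else 1.0
                q2w = e[k, i] * e[k, i] / ww
                lc = lc_const - 0.5 * q2w * inv_c
                if has_w:
                    lc -= 0.5 * np.log(ww)
                if degenerate:
                    if p <= 0.0:
                        g = 0.0
                        ll += lc
                    else:
                        g = 1.0
                        ll += lc + q2w * c_d + c_log
                else:
                    x = q2w * c_d + c_log + lp
                    if x >= 0.0:
                        t = np.exp(-x)
                        g = 1.0 / (1.0 + t)
                        ll += lpc + lc + x + np.log1p(t)
                    else:
                        t = np.exp(x)
                        g = t / (1.0 + t)
                        ll += lpc + lc + np.log1p(t)
                gamma[k, i] = g
                u[k, i] = (g * inv_a + (1.0 - g) * inv_c) / ww
        return gamma, u, ll

    @_njit(cache=True, fastmath=True)
    def _variance_pass(e, gamma, w, has_w):
        K, I = e.shape
        sa_num = 0.0
        sa_den = 0.0
        sc_num = 0.0
        sc_den = 0.0
        colmean = np.zeros(I)
        for i in range(I):
            acc = 0.0
            for k in range(K):
                g = gamma[k, i]
                q2w = e[k, i] * e[k, i] / (w[k, i] if has_w else 1.0)
                sa_num += g * q2w
                sa_den += g
                sc_num += (1.0 - g) * q2w
                sc_den += 1.0 - g
                acc += g
            colmean[i] = acc / K
        return sa_num, sa_den, sc_num, sc_den, colmean

    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False


def _nu0_cm_update(e, nu0_old, eta, u):
    """Exact CM maximizer of the Q-function in nu0 (weighted slope).

    Per CpG the Q-function is quadratic in nu_0k, so the u-weighted
    no-intercept regression slope, clipped to [0, 1], is the constrained
    conditional maximizer; the EM objective cannot decrease.  The
    partial residual is recovered from the current full residual as
    r = e + eta * nu0_old, avoiding a matrix product.
    """
    r = e + np.outer(nu0_old, eta)
    denom = u @ (eta * eta)
    nu0 = (u * r) @ eta / denom
    return np.clip(nu0, 0.0, 1.0)


def _em_inner(z, nu, eta, s, w, ridge, family, state, nu0, max_iter, tol,
              update_nu0):
    """Run EM to convergence with the variance multipliers w fixed.

    Each iteration: fused E-step / likelihood evaluation, a CM update of
    nu0 (when a no-reference cell type is present), the simplex QP for
    the proportions, then closed-form variance and prior updates.
    ``state`` carries rho (Q, I), sigma_a2, sigma_c2, pi_a (I,) and the
    warm-start QP free mask.
    """
    rho = state["rho"]
    sigma_a2, sigma_c2 = state["sigma_a2"], state["sigma_c2"]
    pi_a = np.asarray(state["pi_a"], float)
    free = state.get("free")
    warns = list(state.get("warnings", []))
    w_is_one = w is None or bool(np.all(w == 1.0))
    wv = None if w_is_one else w
    logw = None if w_is_one else np.log(w)
    w_arr = np.ones((1, 1)) if w_is_one else w     # numba-typed placeholder
    use_fast = _HAVE_NUMBA and family == "normal"
    P = _gram_factor(nu)
    trace = []
    converged = False
    y = z if nu0 is None else z - np.outer(nu0, eta)
    e = y - nu @ rho
    ll_prev = None
    for _ in range(max_iter + 1):
        if use_fast:
            gamma, u, ll = _normal_pass(e, w_arr, not w_is_one,
                                        sigma_a2, sigma_c2, pi_a)
        else:
            gamma, ll = _estep_and_loglik(e, wv, logw, sigma_a2, sigma_c2,
                                          pi_a, family)
            u = None
        ll -= ridge * float(np.sum(rho * rho))
        if not np.isfinite(ll):
            raise EmethError("non-finite log-likelihood during EM")
        trace.append(ll)
        if ll_prev is not None and abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            converged = True
            break
        if len(trace) == max_iter + 1:
            break
        ll_prev = ll
        # CM steps, each a conditional maximizer of the Q-function
        if family == "normal":
            if u is None:
                u = gamma / sigma_a2 + (1.0 - gamma) / sigma_c2
                if not w_is_one:
                    u = u / w
            if update_nu0:
                nu0 = _nu0_cm_update(e, nu0, eta, u)
                y = z - np.outer(nu0, eta)
            rho_new, free = _rho_qp_batch(y, nu, u, s, ridge, free0=free, P=P)
            rho = rho_new.T
            e = y - nu @ rho
            if use_fast:
                sa_num, sa_den, sc_num, sc_den, colmean = _variance_pass(
                    e, gamma, w_arr, not w_is_one)
                if sa_den <= 0:
                    vw = ["aberrant component empty; sigma_a2 kept at previous value"]
                else:
                    sigma_a2, vw = max(sa_num / sa_den, _VAR_FLOOR), []
                if sc_den <= 0:
                    vw.append("consistent component empty; sigma_c2 kept at previous value")
                else:
                    sigma_c2 = max(sc_num / sc_den, _VAR_FLOOR)
                if sigma_a2 < sigma_c2:
                    sigma_a2, sigma_c2 = sigma_c2, sigma_a2
                    colmean = 1.0 - colmean
                pi_a = colmean
            else:
                sigma_a2, sigma_c2, pi_a, gamma, vw = m_step_variances_and_pi(
                    e, gamma, w if w is not None else 1.0,
                    prev=(sigma_a2, sigma_c2))
        else:
            c = (gamma / np.sqrt(sigma_a2) + (1.0 - gamma) / np.sqrt(sigma_c2))
            c = c * np.sqrt(2.0) if w_is_one else c * np.sqrt(2.0 / w)
            for _irls in range(8):
                u = c / np.sqrt(e * e + _LAD_EPS * _LAD_EPS)
                if update_nu0:
                    nu0 = _nu0_cm_update(e, nu0, eta, u)
                    y = z - np.outer(nu0, eta)
                rho_new, free = _rho_qp_batch(y, nu, u, s, ridge, free0=free, P=P)
                moved = np.abs(rho_new.T - rho).max()
                rho = rho_new.T
                e = y - nu @ rho
                if moved < 1e-9:
                    break
            sigma_a2, sigma_c2, pi_a, gamma, vw = _laplace_scale_update(
                e, gamma, np.ones_like(e) if w_is_one else w,
                (sigma_a2, sigma_c2))
        warns.extend(x for x in vw if x not in warns)
    gamma, _ = _estep_and_loglik(e, wv, logw, sigma_a2, sigma_c2, pi_a, family)
    return {
        "rho": rho, "sigma_a2": sigma_a2, "sigma_c2": sigma_c2,
        "pi_a": pi_a, "gamma": gamma, "residuals": e, "free": free,
        "nu0": nu0, "trace": np.asarray(trace), "converged": converged,
        "loglik": trace[-1], "warnings": warns,
    }


# ---------------------------------------------------------------------------
# Full pipeline at a fixed ridge
# ---------------------------------------------------------------------------

#: Extra rounds are only needed to refresh binomial variance multipliers,
#: which stay fixed inside each EM run so monotonicity is preserved.
_BINOM_REFRESH_ROUNDS = 5


def _init_state(z, nu, eta, special):
    """QP-baseline initialisation of rho, variances and priors."""
    K, I = z.shape
    u = np.ones((K, I))
    rho, free = _rho_qp_batch(z, nu, u, 1.0 - eta, 0.0)
    rho = rho.T
    nu0 = None
    if special:
        nu0 = estimate_nu0(z, eta, rho, nu)
    y = z if nu0 is None else z - np.outer(nu0, eta)
    e = y - nu @ rho
    sigma_c2 = max(float(np.mean(e * e)), _VAR_FLOOR)
    return {
        "rho": rho, "sigma_a2": 10.0 * sigma_c2, "sigma_c2": sigma_c2,
        "pi_a": np.full(I, 0.1), "free": free,
    }, nu0


def _fit_at_ridge(z, nu, eta, options: FitOptions, ridge: float,
                  warm=None):
    """Fit all parameters at one fixed ridge penalty.

    With unit weights this is a single EM run (nu0, when present, is
    updated inside the loop as a CM step).  With binomial weights the
    run is repeated a few times, recomputing the multipliers from the
    current (rho, nu0) between runs.  ``warm`` optionally supplies a
    (state, nu0) pair to start from, e.g. the previous candidate during
    ridge selection.
    """
    K, I = z.shape
    special = bool((eta > 0).any())
    if warm is None:
        state, nu0 = _init_state(z, nu, eta, special)
    else:
        state, nu0 = warm
    s = 1.0 - eta
    rounds = _BINOM_REFRESH_ROUNDS if options.variance_weights == "binom" else 1
    prev_obj = -np.inf
    result = None
    for _ in range(rounds):
        if options.variance_weights == "binom":
            w = WeightMatrix.binomial(nu, state["rho"], eta, nu0).values
        else:
            w = None
        result = _em_inner(z, nu, eta, s, w, ridge, options.error_family,
                           state, nu0, options.max_iter, options.tol,
                           update_nu0=special)
        state = {k: result[k] for k in
                 ("rho", "sigma_a2", "sigma_c2", "pi_a", "free", "warnings")}
        nu0 = result["nu0"]
        obj = result["loglik"]
        if abs(obj - prev_obj) < options.tol * (1.0 + abs(obj)):
            break
        prev_obj = obj
    return result


# ---------------------------------------------------------------------------
# Ridge selection by CpG-fold cross-validation
# ---------------------------------------------------------------------------

def _cv_folds(K, n_folds, seed):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(K)
    return np.array_split(perm, n_folds)


def select_ridge(bulk: BulkBetaMatrix, ref: ReferenceMatrix,
                 eta, options: FitOptions) -> float:
    """Choose the ridge penalty by cross-validation over CpG folds.

    For each candidate, the model is fitted on the training CpGs and
    scored by the mean squared prediction error of held-out beta-values
    (predicted as eta_i nu0_k + sum_q rho_qi nu_qk, with nu0 on held-out
    CpGs re-estimated from the training-fold proportions).  Ties break
    toward the larger (more stable) penalty.
    """
    z = bulk.values if isinstance(bulk, BulkBetaMatrix) else np.asarray(bulk, float)
    nu = ref.values if isinstance(ref, ReferenceMatrix) else np.asarray(ref, float)
    eta = np.asarray(getattr(eta, "eta", eta), float)
    K = z.shape[0]
    grid = sorted(options.resolved_grid(K))
    if len(grid) == 1:
        return float(grid[0])
    if K < options.cv_folds:
        raise EmethError(f"cannot make {options.cv_folds} CV folds from {K} CpGs")
    folds = _cv_folds(K, options.cv_folds, options.seed)
    special = bool((eta > 0).any())
    # exploration fits: the CV score (a held-out MSE ~1e-3) is insensitive
    # to the last digits of the parameters, so a looser EM tolerance is
    # used here; the final fit runs at full precision
    explore = replace(options, tol=max(options.tol, 1e-5),
                      max_iter=min(options.max_iter, 150))
    scores = np.zeros(len(grid))
    for test_idx in folds:
        mask = np.zeros(K, bool)
        mask[test_idx] = True
        z_tr, nu_tr = z[~mask], nu[~mask]
        z_te, nu_te = z[mask], nu[mask]
        warm = None
        for gi, ridge in enumerate(grid):
            res = _fit_at_ridge(z_tr, nu_tr, eta, explore, ridge, warm=warm)
            # successive candidates start from the previous optimum
            warm = ({k: res[k] for k in ("rho", "sigma_a2", "sigma_c2",
                                         "pi_a", "free", "warnings")},
                    res["nu0"])
            pred = nu_te @ res["rho"]
            if special:
                nu0_te = estimate_nu0(z_te, eta, res["rho"], nu_te)
                pred = pred + np.outer(nu0_te, eta)
            scores[gi] += float(np.mean((z_te - pred) ** 2))
    scores /= len(folds)
    # argmin with ties toward the larger ridge (grid is sorted ascending)
    best = len(grid) - 1 - int(np.argmin(scores[::-1]))
    logger.debug("select_ridge: grid=%s scores=%s chosen=%g",
                 grid, scores, grid[best])
    return float(grid[best])


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def fit_emeth(bulk: BulkBetaMatrix, ref: ReferenceMatrix,
              info: SampleInfo | None = None,
              options: FitOptions | None = None) -> EMethFit:
    """Fit the EM deconvolution model to aligned bulk and reference data.

    Orchestrates ridge selection (cross-validated over CpG folds),
    QP-baseline initialisation, the alternation between estimating the
    no-reference profile nu0 (when any eta_i > 0) and the EM loop, and
    invariant checks on the returned fit.
    """
    options = options or FitOptions()
    if tuple(bulk.cpg_ids) != tuple(ref.cpg_ids):
        bulk, ref = align_by_cpg(bulk, ref)
    if info is None:
        info = SampleInfo.zeros(bulk.sample_ids)
    if tuple(info.sample_ids) != tuple(bulk.sample_ids):
        raise EmethError("sample ids of bulk matrix and sample info disagree")
    z, nu, eta = bulk.values, ref.values, info.eta
    K = z.shape[0]
    grid = options.resolved_grid(K)
    chosen = select_ridge(bulk, ref, eta, options) if len(grid) > 1 else float(grid[0])
    res = _fit_at_ridge(z, nu, eta, options, chosen)
    warnings_list = list(res["warnings"])
    if not res["converged"]:
        warnings_list.append(
            f"EM did not converge within {options.max_iter} iterations")
    if float(res["gamma"].mean()) > 0.5:
        warnings_list.append(_ABERRANT_MAJORITY_WARNING)
        logger.warning(_ABERRANT_MAJORITY_WARNING)
    fit = EMethFit(
        cell_types=ref.cell_types,
        sample_ids=bulk.sample_ids,
        cpg_ids=bulk.cpg_ids,
        proportions=res["rho"],
        pi_a=res["pi_a"],
        sigma_a2=res["sigma_a2"],
        sigma_c2=res["sigma_c2"],
        gamma=res["gamma"],
        nu0=res["nu0"],
        residuals=res["residuals"],
        chosen_ridge=chosen,
        loglik_trace=res["trace"],
        converged=res["converged"],
        eta=eta,
        warnings=warnings_list,
    )
    fit.validate()
    return fit
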