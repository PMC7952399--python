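"""Competitor deconvolution methods: LS, RLS (Huber), SVR and QP.

Each method regresses a bulk sample's beta-values on the Q reference
columns; the regression coefficients are the cell-type proportion
estimates.  LS/RLS/SVR coefficients are post-processed by truncating
negatives at zero and renormalising to the target mass; QP is solved
under non-negativity directly and only renormalised.  None of these
methods model a no-reference cell type: when one is present (eta > 0)
its signal is simply unexplained noise to them, and the target mass
defaults to 1 - eta so the estimates remain comparable to the truth.
"""
from __future__ import annotations

import logging
import warnings as _pywarnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import nnls
from sklearn.svm import LinearSVR

from .core import _solve_simplex_qp
from .io import (BulkBetaMatrix, EmethError, ReferenceMatrix, SampleInfo,
                 align_by_cpg)

logger = logging.getLogger("emeth")

METHODS = ("LS", "RLS", "SVR", "QP")

#: SVR cost grid {2^-5, ..., 2^5} and the Huber tuning constant.
SVR_COST_GRID = tuple(2.0 ** p for p in range(-5, 6))
HUBER_T = 1.345

__all__ = ["BaselineResult", "deconvolve_baseline", "truncate_and_renormalize",
           "METHODS"]


@dataclass
class BaselineResult:
    method: str
    cell_types: tuple
    sample_ids: tuple
    proportions: np.ndarray        # (Q, I), post-processed
    raw_coefficients: np.ndarray   # (Q, I), pre-normalisation
    target_mass: np.ndarray        # (I,)
    target_mass_mode: str
    tuning: dict = field(default_factory=dict)

    def validate(self, tol: float = 1e-6) -> None:
        if (self.proportions < -tol).any():
            raise EmethError("baseline invariant violated: negative proportion")
        err = np.abs(self.proportions.sum(axis=0) - self.target_mass).max()
        if err > tol:
            raise EmethError("baseline invariant violated: column mass mismatch")


def truncate_and_renormalize(raw, target_mass: float) -> np.ndarray:
    """Zero out negative coefficients and rescale to the target mass.

    An all-non-positive vector degenerates to the uniform vector at the
    target mass (with a warning), since no direction of the simplex is
    preferred by the raw fit.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise EmethError("truncate_and_renormalize: non-finite coefficient")
    if not 0.0 < target_mass <= 1.0:
        raise EmethError(f"target mass must lie in (0, 1], got {target_mass}")
    clipped = np.maximum(raw, 0.0)
    total = clipped.sum()
    if total <= 0.0:
        _pywarnings.warn(
            "all coefficients non-positive; returning the uniform vector",
            RuntimeWarning, stacklevel=2)
        return np.full(raw.shape, target_mass / raw.size)
    return clipped * (target_mass / total)


def _fit_ls(z, nu):
    if np.linalg.cond(nu) > 1e10:
        raise EmethError(
            "singular reference design for least squares; use the QP method "
            "or a ridge-penalised fit instead")
    coef, *_ = np.linalg.lstsq(nu, z, rcond=None)
    return coef


def _fit_rls(z, nu, maxiter: int = 50):
    """Huber M-estimation, iteratively reweighted, batched over samples.

    Same estimator as MASS::rlm / statsmodels RLM with HuberT(1.345) and
    MAD-about-zero scale (a unit test pins this against statsmodels);
    batching the weighted solves over samples keeps it fast.
    """
    K, Q = nu.shape
    I = z.shape[1]
    B = np.linalg.lstsq(nu, z, rcond=None)[0]
    P = (nu[:, :, None] * nu[:, None, :]).reshape(K, Q * Q)
    for _ in range(maxiter):
        r = z - nu @ B
        s = np.median(np.abs(r), axis=0) / 0.6744897501960817
        if (s < 1e-12).all():
            break
        wgt = np.minimum(1.0, HUBER_T * np.maximum(s, 1e-12)
                         / np.maximum(np.abs(r), 1e-12))
        H = (wgt.T @ P).reshape(I, Q, Q)
        b = (nu.T @ (wgt * z)).T[..., None]
        B_new = np.linalg.solve(H, b)[..., 0].T
        if np.abs(B_new - B).max() < 1e-8:
            B = B_new
            break
        B = B_new
    return B


def _svr_epsilon(z, nu):
    """Per-sample tube width: 0.1 x the residual sd of a plain LS fit.

    Scaling the tube to the residual noise (rather than the raw beta sd)
    keeps the epsilon-insensitive loss robust under noise while letting
    a noise-free mixture be recovered exactly.
    """
    coef, *_ = np.linalg.lstsq(nu, z, rcond=None)
    return 0.1 * np.std(z - nu @ coef, axis=0)


def _select_svr_cost(z, nu, eps, seed):
    """Pick the SVR cost by 5-fold CV over CpGs, MSE-scored.

    Scoring averages over a seeded subset of samples; the cost is shared
    by all samples of the dataset.  Ties break toward the smaller (more
    regularised) cost.
    """
    K, I = z.shape
    rng = np.random.default_rng(seed)
    sample_subset = np.sort(rng.choice(I, size=min(I, 5), replace=False))
    perm = rng.permutation(K)
    folds = np.array_split(perm, 5)
    if min(len(f) for f in folds) < 2:
        raise EmethError("too few CpGs for the SVR cost cross-validation")
    errors = np.zeros(len(SVR_COST_GRID))
    for test_idx in folds:
        mask = np.zeros(K, bool)
        mask[test_idx] = True
        for ci, cost in enumerate(SVR_COST_GRID):
            for i in sample_subset:
                # exploration fits use a loose tolerance; held-out MSE is
                # insensitive to the last digits of the coefficients
                svr = LinearSVR(C=cost, epsilon=float(eps[i]),
                                fit_intercept=False,
                                tol=1e-2, max_iter=500, random_state=0)
                with _pywarnings.catch_warnings():
                    _pywarnings.simplefilter("ignore")
                    svr.fit(nu[~mask], z[~mask, i])
                pred = nu[mask] @ svr.coef_
                errors[ci] += float(np.mean((z[mask, i] - pred) ** 2))
    if not np.isfinite(errors).all():
        raise EmethError("SVR cross-validation produced non-finite errors")
    return float(SVR_COST_GRID[int(np.argmin(errors))])


def _fit_svr(z, nu, cost, eps):
    coefs = np.empty((nu.shape[1], z.shape[1]))
    for i in range(z.shape[1]):
        svr = LinearSVR(C=cost, epsilon=float(eps[i]), fit_intercept=False,
                        tol=3e-3, max_iter=1500, random_state=0)
        with _pywarnings.catch_warnings():
            _pywarnings.simplefilter("ignore")
            svr.fit(nu, z[:, i])
        coefs[:, i] = svr.coef_
    return coefs


def _fit_qp(z, nu, target_mass):
    """Non-negative LS with sum rho <= target mass, exact QP solution."""
    Q, I = nu.shape[1], z.shape[1]
    coefs = np.empty((Q, I))
    H = nu.T @ nu
    need_eq = []
    for i in range(I):
        rho, _ = nnls(nu, z[:, i])
        if rho.sum() <= target_mass[i] + 1e-12:
            coefs[:, i] = rho
        else:
            need_eq.append(i)
    if need_eq:
        idx = np.array(need_eq)
        Hb = np.broadcast_to(H, (len(idx), Q, Q))
        b = (nu.T @ z[:, idx]).T
        rho_eq, _ = _solve_simplex_qp(Hb.copy(), b, target_mass[idx])
        coefs[:, idx] = rho_eq.T
    return coefs


def deconvolve_baseline(bulk: BulkBetaMatrix, ref: ReferenceMatrix,
                        info: SampleInfo | None = None, method: str = "QP",
                        target_mass_mode: str = "auto",
                        seed: int = 0) -> BaselineResult:
    """Run one competitor method on aligned bulk and reference data.

    method : one of "LS", "RLS", "SVR", "QP" (case-insensitive).
    target_mass_mode : "one", "one_minus_eta", or "auto" (1 - eta when a
        no-reference cell type is present, 1 otherwise).
    """
    method = method.upper()
    if method not in METHODS:
        raise EmethError(f"unknown baseline method {method!r}; choose from {METHODS}")
    if tuple(bulk.cpg_ids) != tuple(ref.cpg_ids):
        bulk, ref = align_by_cpg(bulk, ref)
    if info is None:
        info = SampleInfo.zeros(bulk.sample_ids)
    z, nu, eta = bulk.values, ref.values, info.eta
    if target_mass_mode == "auto":
        target_mass_mode = "one_minus_eta" if info.has_special else "one"
    if target_mass_mode == "one":
        target = np.ones(z.shape[1])
    elif target_mass_mode == "one_minus_eta":
        target = 1.0 - eta
    else:
        raise EmethError(f"unknown target_mass_mode {target_mass_mode!r}")
    tuning = {}
    if method == "LS":
        raw = _fit_ls(z, nu)
    elif method == "RLS":
        raw = _fit_rls(z, nu)
    elif method == "SVR":
        eps = _svr_epsilon(z, nu)
        cost = _select_svr_cost(z, nu, eps, seed)
        tuning["cost"] = cost
        raw = _fit_svr(z, nu, cost, eps)
    else:
        raw = _fit_qp(z, nu, target)
    if method == "QP":
        # already non-negative: rescale columns to the target mass only
        sums = raw.sum(axis=0)
        props = np.where(sums > 0, raw * (target / np.where(sums > 0, sums, 1.0)),
                         (target / nu.shape[1])[None, :])
    else:
        props = np.column_stack([
            truncate_and_renormalize(raw[:, i], target[i])
            for i in range(z.shape[1])
        ])
    result = BaselineResult(
        method=method, cell_types=ref.cell_types, sample_ids=bulk.sample_ids,
        proportions=props, raw_coefficients=raw, target_mass=target,
        target_mass_mode=target_mass_mode, tuning=tuning)
    result.validate()
    return result
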