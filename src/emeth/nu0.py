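"""Estimate the methylation profile of the no-reference cell type.

When one cell type (typically tumor cells) has known proportions eta_i
but no reference profile, its per-CpG methylation nu_0k is identifiable
from variation of eta across samples: after removing the referenced
cell types' contribution, the leftover methylation at CpG k is
proportional to eta_i with slope nu_0k.  Each CpG is therefore a
no-intercept regression of the partial residual on eta, optionally
precision-weighted so that entries flagged aberrant by the E-step count
less.
"""
from __future__ import annotations

import logging

import numpy as np

from .io import BulkBetaMatrix, EmethError, ReferenceMatrix

logger = logging.getLogger("emeth")

__all__ = ["estimate_nu0"]


def estimate_nu0(bulk, eta, rho, ref, precision_weights=None) -> np.ndarray:
    """Per-CpG no-intercept regression slope of z - nu rho on eta.

    Parameters
    ----------
    bulk : BulkBetaMatrix or (K, I) array of beta-values.
    eta : (I,) known proportions of the no-reference cell type.
    rho : (Q, I) current proportion estimates of the referenced types.
    ref : ReferenceMatrix or (K, Q) array of reference means.
    precision_weights : optional (K, I) positive weights u_ki (for
        example gamma/(sigma_a^2 w) + (1-gamma)/(sigma_c^2 w) from the
        E-step); plain least squares when omitted.

    Returns
    -------
    (K,) estimated profile, clipped to [0, 1]; the number of clipped
    CpGs is logged.
    """
    z = bulk.values if isinstance(bulk, BulkBetaMatrix) else np.asarray(bulk, float)
    nu = ref.values if isinstance(ref, ReferenceMatrix) else np.asarray(ref, float)
    eta = np.asarray(getattr(eta, "eta", eta), float)
    rho = np.asarray(rho, float)
    if z.shape != (nu.shape[0], eta.shape[0]) or rho.shape != (nu.shape[1], eta.shape[0]):
        raise EmethError("estimate_nu0: inconsistent input shapes")
    if not (eta > 0).any():
        raise EmethError("estimate_nu0: all eta are zero; nothing to estimate")
    positive = np.unique(eta[eta > 0])
    if positive.size < 2:
        logger.warning(
            "estimate_nu0: eta takes %d distinct positive value(s); more "
            "variation across samples gives a better-determined profile",
            positive.size)
    r = z - nu @ rho
    if precision_weights is None:
        u = np.ones_like(z)
    else:
        u = np.asarray(precision_weights, float)
        if u.shape != z.shape or (u <= 0).any():
            raise EmethError("estimate_nu0: precision weights must be positive, K x I")
    denom = u @ (eta * eta)
    if (denom <= 0).any():
        raise EmethError("estimate_nu0: zero denominator in the slope estimate")
    nu0 = (u * r) @ eta / denom
    n_clip = int(((nu0 < 0) | (nu0 > 1)).sum())
    if n_clip:
        logger.debug("estimate_nu0: clipped %d of %d CpGs into [0, 1]",
                     n_clip, nu0.size)
    return np.clip(nu0, 0.0, 1.0)
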