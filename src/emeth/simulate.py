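"""Synthetic 450k-style data generation for benchmarking deconvolution.

Three generators cover the study designs the estimators are evaluated
on:

* ``make_synthetic_reference`` draws a bimodal, 450k-like reference of
  cell type-specific mean beta-values, with one designated pair of cell
  types (CD4T/CD8T by default) forced to a target Pearson correlation to
  emulate the strong collinearity of closely related immune cells, plus
  replicate-level noisy observations of each profile.
* ``simulate_mixtures`` builds bulk samples from Dirichlet-distributed
  proportions, a Uniform(0,1) profile for the no-reference cell type,
  binomial mean-variance noise, and per-sample aberrant CpG subsets with
  inflated variance.
* ``mix_profiles`` linearly combines individual-level cell type-specific
  profiles and perturbs them with Gaussian noise on the M-value scale
  (in-silico mixing).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import BulkBetaMatrix, EmethError, ReferenceMatrix, SimulationTruth

logger = logging.getLogger("emeth")

#: Default immune cell panel used when Q == 7.
IMMUNE_CELL_TYPES = ("CD4T", "CD8T", "Bcell", "NK", "Neutrophil",
                     "Monocyte", "Treg")

#: Beta-mixture for 450k-like CpG means: mostly unmethylated, a large
#: methylated mode, and a small intermediate mode.
_BIMODAL_COMPONENTS = ((0.5, 8.0), (8.0, 0.5), (5.0, 5.0))
_BIMODAL_PROBS = (0.55, 0.35, 0.10)
_REPLICATE_PRECISION = 200.0

__all__ = ["SimulationConfig", "make_synthetic_reference", "select_cpgs",
           "simulate_mixtures", "mix_profiles", "IMMUNE_CELL_TYPES"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated bulk methylation study.

    Defaults follow the benchmark design: 946 CpGs, 100 samples, seven
    immune cell types, consistent-CpG noise sigma_c2, an aberrant/
    consistent variance ratio lambda_ratio, 5-15% aberrant CpGs per
    sample, and a no-reference cell type with proportion eta drawn
    uniformly from (0.3, 0.7).
    """

    K: int = 946
    I: int = 100
    Q: int = 7
    sigma_c2: float = 0.00221
    lambda_ratio: float = 10.0
    aberrant_range: tuple = (0.05, 0.15)
    eta_range: tuple = (0.3, 0.7)
    include_special: bool = True
    proportion_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.I < 1 or self.Q < 2:
            raise EmethError("simulation needs K >= 1, I >= 1, Q >= 2")
        if not self.sigma_c2 > 0:
            raise EmethError("sigma_c2 must be > 0")
        if self.lambda_ratio < 1:
            raise EmethError("lambda_ratio must be >= 1")
        for name, (lo, hi) in (("aberrant_range", self.aberrant_range),
                               ("eta_range", self.eta_range)):
            if not (0.0 <= lo < hi <= 1.0):
                raise EmethError(f"{name} must satisfy 0 <= low < high <= 1")
        if not self.proportion_concentration > 0:
            raise EmethError("proportion_concentration must be > 0")


def _default_cell_types(Q: int) -> tuple:
    if Q == len(IMMUNE_CELL_TYPES):
        return IMMUNE_CELL_TYPES
    return tuple(f"celltype{q + 1}" for q in range(Q))


def _draw_bimodal(rng, size):
    comp = rng.choice(len(_BIMODAL_PROBS), size=size, p=_BIMODAL_PROBS)
    draws = np.stack([rng.beta(a, b, size=size) for a, b in _BIMODAL_COMPONENTS])
    return np.take_along_axis(draws, comp[None, ...], axis=0)[0]


def make_synthetic_reference(K_pool: int = 2000, Q: int = 7,
                             replicates: int = 6,
                             collinear_pair_rho: float = 0.96,
                             seed: int = 0):
    """Draw a bimodal synthetic reference with one collinear pair.

    Returns (ReferenceMatrix of per-CpG, per-cell-type mean beta-values;
    replicate-level beta array of shape (K_pool, Q, replicates)).  The
    first two cell types are made collinear at ``collinear_pair_rho``
    (+- 0.01) by copying one profile and re-randomising a fraction of
    its CpGs, the fraction found by bisection.
    """
    if Q < 2:
        raise EmethError("need at least two cell types")
    if K_pool < Q:
        raise EmethError("need at least as many CpGs as cell types")
    rng = np.random.default_rng(seed)
    means = _draw_bimodal(rng, (K_pool, Q))
    if collinear_pair_rho is not None:
        means[:, 1] = _collinearize(rng, means[:, 0], collinear_pair_rho)
    means = np.clip(means, 0.0, 1.0)
    m = np.clip(means, 5e-3, 1.0 - 5e-3)
    reps = rng.beta(m[..., None] * _REPLICATE_PRECISION,
                    (1.0 - m[..., None]) * _REPLICATE_PRECISION,
                    size=(K_pool, Q, replicates))
    cpg_ids = tuple(f"cg{k:06d}" for k in range(K_pool))
    ref = ReferenceMatrix(cpg_ids, _default_cell_types(Q), means)
    return ref, reps


def _collinearize(rng, base, target, tol=0.01, max_rounds=200):
    """Copy ``base`` then re-randomise a fraction of CpGs by bisection
    until the Pearson correlation with ``base`` is within +-tol of
    ``target``."""
    K = base.shape[0]
    lo_frac, hi_frac = 0.0, 1.0
    for _ in range(max_rounds):
        frac = 0.5 * (lo_frac + hi_frac)
        col = base.copy()
        n_new = int(round(frac * K))
        if n_new:
            idx = rng.choice(K, size=n_new, replace=False)
            col[idx] = _draw_bimodal(rng, (n_new,))
        r = np.corrcoef(base, col)[0, 1]
        if abs(r - target) <= tol:
            return col
        if r > target:
            lo_frac = frac    # too correlated: re-randomise more
        else:
            hi_frac = frac
    raise EmethError(
        f"could not reach pairwise correlation {target} +- {tol} "
        f"after {max_rounds} rounds")


def select_cpgs(replicate_ref: np.ndarray, n_target: int) -> np.ndarray:
    """Pick the most cell type-discriminating CpGs.

    One-vs-rest Welch t-statistics are computed per cell type on the
    replicate-level beta-values; the top ceil(n_target / Q) CpGs per
    cell type by |t| are pooled, de-duplicated and truncated to
    ``n_target`` (the per-type depth grows if de-duplication leaves too
    few).  Returns sorted CpG indices; deterministic given the input.
    """
    reps = np.asarray(replicate_ref, float)
    if reps.ndim != 3:
        raise EmethError("replicate reference must have shape (K, Q, replicates)")
    K, Q, R = reps.shape
    if n_target > K:
        raise EmethError(f"cannot select {n_target} CpGs from a pool of {K}")
    tstats = np.empty((K, Q))
    for q in range(Q):
        grp1 = reps[:, q, :]
        grp0 = reps[:, np.arange(Q) != q, :].reshape(K, -1)
        m1, m0 = grp1.mean(axis=1), grp0.mean(axis=1)
        v1 = grp1.var(axis=1, ddof=1) / grp1.shape[1]
        v0 = grp0.var(axis=1, ddof=1) / grp0.shape[1]
        tstats[:, q] = (m1 - m0) / np.sqrt(np.maximum(v1 + v0, 1e-30))
    order = np.argsort(-np.abs(tstats), axis=0, kind="stable")
    depth = int(np.ceil(n_target / Q))
    while True:
        chosen = []
        seen = set()
        for rank in range(depth):
            for q in range(Q):
                k = int(order[rank, q])
                if k not in seen:
                    seen.add(k)
                    chosen.append(k)
        if len(chosen) >= n_target or depth >= K:
            break
        depth = min(K, depth + max(1, (n_target - len(chosen)) // Q + 1))
    if len(chosen) < n_target:
        logger.warning("select_cpgs: only %d informative CpGs available "
                       "(requested %d)", len(chosen), n_target)
    return np.sort(np.asarray(chosen[:n_target], dtype=int))


def simulate_mixtures(ref_means: ReferenceMatrix, config: SimulationConfig):
    """Simulate bulk beta-values and ground truth from a reference.

    Per sample: eta ~ U(eta_range) (zero when no special cell type),
    rho = (1 - eta) * Dirichlet(concentration); the no-reference profile
    nu0 ~ U(0,1) per CpG once per run; means mu = eta nu0 + nu rho;
    binomial mean-variance multipliers w; an exact round(p_i K)-sized
    aberrant CpG subset per sample with p_i ~ U(aberrant_range); then
    z ~ N(mu, sigma^2 w) with sigma^2 = sigma_c2 or
    lambda_ratio * sigma_c2, clipped to [0, 1] (clip rate logged).
    """
    nu = ref_means.values
    K, Q = nu.shape
    if K != config.K or Q != config.Q:
        raise EmethError(
            f"reference shape {(K, Q)} does not match config "
            f"(K={config.K}, Q={config.Q})")
    I = config.I
    rng = np.random.default_rng(config.seed)
    if config.include_special:
        eta = rng.uniform(*config.eta_range, size=I)
    else:
        eta = np.zeros(I)
    rho = (1.0 - eta) * rng.dirichlet(
        np.full(Q, config.proportion_concentration), size=I).T
    nu0 = rng.uniform(0.0, 1.0, size=K)
    mu = nu @ rho + np.outer(nu0, eta)
    w = np.maximum((nu * (1.0 - nu)) @ rho + np.outer(nu0 * (1.0 - nu0), eta),
                   1e-6)
    # exact aberrant counts so every sample's fraction sits in the range
    p_ab = rng.uniform(*config.aberrant_range, size=I)
    mask = np.zeros((K, I), dtype=bool)
    lo = int(np.ceil(config.aberrant_range[0] * K - 1e-9))
    hi = int(np.floor(config.aberrant_range[1] * K + 1e-9))
    for i in range(I):
        n_ab = min(max(int(round(p_ab[i] * K)), lo), hi)
        mask[rng.choice(K, size=n_ab, replace=False), i] = True
    var = config.sigma_c2 * np.where(mask, config.lambda_ratio, 1.0) * w
    z_raw = rng.normal(mu, np.sqrt(var))
    z = np.clip(z_raw, 0.0, 1.0)
    clip_rate = float((z != z_raw).mean())
    if clip_rate:
        logger.info("simulate_mixtures: clipped %.3f%% of beta-values into "
                    "[0, 1]", 100 * clip_rate)
    sample_ids = tuple(f"sample{i + 1:03d}" for i in range(I))
    bulk = BulkBetaMatrix(ref_means.cpg_ids, sample_ids, z)
    truth = SimulationTruth(
        cell_types=ref_means.cell_types, sample_ids=sample_ids,
        cpg_ids=ref_means.cpg_ids, true_proportions=rho, true_eta=eta,
        true_nu0=nu0, aberrant_mask=mask,
        config_echo=replace(config),
    )
    return bulk, truth


def beta_to_m(beta: np.ndarray) -> np.ndarray:
    """M = log2(beta / (1 - beta)), the Illumina logit transform."""
    beta = np.asarray(beta, float)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, float)
    return 1.0 / (1.0 + np.exp2(-m))


#: noise_c is relative: an in-silico noise level c maps to an M-value
#: standard deviation of 0.01 * c.
M_NOISE_PER_UNIT = 0.01
_MIX_CLIP = 1e-6


def mix_profiles(profiles: np.ndarray, proportions: np.ndarray,
                 noise_c: float = 0.0, scale: str = "beta_via_m",
                 seed: int = 0, sample_ids=None, cpg_ids=None) -> BulkBetaMatrix:
    """In-silico mixing of individual-level cell type-specific profiles.

    profiles : (K, Q, N) beta-values per CpG, cell type and individual.
    proportions : (Q, N) mixing weights; each column must sum to 1.
    noise_c : relative Gaussian noise level; with scale="beta_via_m" the
        mixture is mapped to M-values, perturbed with sd 0.01 * noise_c,
        and mapped back; "linear" perturbs on the beta scale directly.
    """
    profiles = np.asarray(profiles, float)
    proportions = np.asarray(proportions, float)
    if profiles.ndim != 3 or proportions.ndim != 2 \
            or profiles.shape[1:] != proportions.shape:
        raise EmethError("mix_profiles: profiles must be (K, Q, N) and "
                         "proportions (Q, N)")
    if np.abs(proportions.sum(axis=0) - 1.0).max() > 1e-6:
        raise EmethError("mix_profiles: proportion columns must sum to 1")
    if scale not in ("beta_via_m", "linear"):
        raise EmethError(f"unknown mixing scale {scale!r}")
    K, Q, N = profiles.shape
    bulk = np.einsum("kqn,qn->kn", profiles, proportions)
    rng = np.random.default_rng(seed)
    sd = M_NOISE_PER_UNIT * float(noise_c)
    if sd > 0:
        if scale == "beta_via_m":
            m = beta_to_m(np.clip(bulk, _MIX_CLIP, 1.0 - _MIX_CLIP))
            bulk = m_to_beta(m + rng.normal(0.0, sd, size=m.shape))
        else:
            bulk = bulk + rng.normal(0.0, sd, size=bulk.shape)
    bulk = np.clip(bulk, _MIX_CLIP, 1.0 - _MIX_CLIP)
    if sample_ids is None:
        sample_ids = tuple(f"mixture{n + 1:03d}" for n in range(N))
    if cpg_ids is None:
        cpg_ids = tuple(f"cg{k:06d}" for k in range(K))
    return BulkBetaMatrix(cpg_ids, sample_ids, bulk)
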