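"""Domain types and TSV readers/writers for methylation deconvolution.

Matrices follow the Illumina processing convention: CpGs in rows,
samples or cell types in columns.  Beta-values are unitless fractions in
[0, 1].  All other modules consume and produce these types; no module
other than this one (and the CLI) touches the filesystem.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("emeth")

#: Values may stray outside [0, 1] by at most this much before erroring;
#: smaller violations (float round-off in upstream pipelines) are clipped.
RANGE_SLACK = 1e-6

#: Decimal places used when serialising matrices.  Beta-values carry at
#: most three meaningful digits, so six decimals are lossless in practice.
WRITE_DECIMALS = 6


class EmethError(ValueError):
    """Raised for invalid inputs or infeasible model configurations."""


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------

def _check_beta_matrix(values: np.ndarray, row_ids, col_ids, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise EmethError(f"{what}: expected a 2-D matrix, got shape {values.shape}")
    if values.shape != (len(row_ids), len(col_ids)):
        raise EmethError(
            f"{what}: shape {values.shape} does not match "
            f"{len(row_ids)} row ids x {len(col_ids)} column ids"
        )
    if not np.isfinite(values).all():
        k, i = np.argwhere(~np.isfinite(values))[0]
        raise EmethError(
            f"{what}: non-finite value at row {row_ids[k]!r}, column {col_ids[i]!r}"
        )
    low, high = values.min(initial=0.0), values.max(initial=1.0)
    if low < -RANGE_SLACK or high > 1.0 + RANGE_SLACK:
        k, i = np.argwhere((values < -RANGE_SLACK) | (values > 1 + RANGE_SLACK))[0]
        raise EmethError(
            f"{what}: beta-value {values[k, i]:.6g} out of [0, 1] at "
            f"row {row_ids[k]!r}, column {col_ids[i]!r}"
        )
    if len(set(row_ids)) != len(row_ids):
        raise EmethError(f"{what}: duplicated row (CpG) identifiers")
    if len(set(col_ids)) != len(col_ids):
        raise EmethError(f"{what}: duplicated column identifiers")
    return np.clip(values, 0.0, 1.0)


@dataclass(frozen=True)
class ReferenceMatrix:
    """Cell type-specific mean beta-values, CpGs (K) x cell types (Q)."""

    cpg_ids: tuple
    cell_types: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        vals = _check_beta_matrix(self.values, self.cpg_ids, self.cell_types,
                                  "reference matrix")
        if vals.shape[0] < vals.shape[1]:
            logger.warning(
                "reference matrix has fewer CpGs (%d) than cell types (%d); "
                "it may be transposed", vals.shape[0], vals.shape[1])
        object.__setattr__(self, "values", vals)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cpg_ids),
                            columns=list(self.cell_types))


@dataclass(frozen=True)
class BulkBetaMatrix:
    """Observed bulk beta-values, CpGs (K) x samples (I)."""

    cpg_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = _check_beta_matrix(self.values, self.cpg_ids, self.sample_ids,
                                  "bulk matrix")
        object.__setattr__(self, "values", vals)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cpg_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample proportion eta of the no-reference cell type.

    For tumor samples eta is the tumor purity; when no such special cell
    type exists eta is identically zero.
    """

    sample_ids: tuple
    eta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        eta = np.asarray(self.eta, dtype=float)
        if eta.shape != (len(self.sample_ids),):
            raise EmethError("sample info: eta length does not match sample ids")
        if not np.isfinite(eta).all():
            raise EmethError("sample info: non-finite eta")
        if (eta < 0).any() or (eta >= 1).any():
            i = int(np.argwhere((eta < 0) | (eta >= 1))[0][0])
            raise EmethError(
                f"sample info: eta must lie in [0, 1); sample "
                f"{self.sample_ids[i]!r} has eta = {eta[i]:.6g}")
        object.__setattr__(self, "eta", eta)

    @classmethod
    def zeros(cls, sample_ids: Sequence[str]) -> "SampleInfo":
        return cls(tuple(sample_ids), np.zeros(len(sample_ids)))

    @property
    def has_special(self) -> bool:
        return bool((self.eta > 0).any())


@dataclass
class FitOptions:
    """Knobs for the EM deconvolution fit.

    variance_weights : "ones" (default) or "binom".  Binomial weights use
        w_ki = sum_q rho_qi nu_qk (1 - nu_qk) + eta_i nu_0k (1 - nu_0k),
        the mean-variance relation of a binomial read-out.
    error_family : "normal" (default) or "laplace".
    ridge_grid : candidate ridge penalties for the proportion estimates;
        ``None`` selects {0, 1e-3, 1e-2, 1e-1} * K at fit time.
    cv_folds : CpG folds used for the ridge cross-validation.
    """

    variance_weights: str = "ones"
    error_family: str = "normal"
    ridge_grid: Sequence[float] | None = None
    cv_folds: int = 5
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.variance_weights not in ("ones", "binom"):
            raise EmethError(f"unknown variance_weights {self.variance_weights!r}")
        if self.error_family not in ("normal", "laplace"):
            raise EmethError(f"unknown error_family {self.error_family!r}")
        if self.ridge_grid is not None:
            grid = [float(g) for g in self.ridge_grid]
            if not grid:
                raise EmethError("ridge_grid must be non-empty")
            if any(g < 0 for g in grid):
                raise EmethError("ridge penalties must be >= 0")
            self.ridge_grid = grid
        if self.cv_folds < 2:
            raise EmethError("cv_folds must be >= 2")
        if self.max_iter < 1:
            raise EmethError("max_iter must be >= 1")
        if not self.tol > 0:
            raise EmethError("tol must be > 0")

    def resolved_grid(self, n_cpgs: int) -> list:
        if self.ridge_grid is not None:
            return list(self.ridge_grid)
        return [0.0, 1e-3 * n_cpgs, 1e-2 * n_cpgs, 1e-1 * n_cpgs]


@dataclass
class EMethFit:
    """Everything estimated by one EM deconvolution run.

    proportions : (Q, I) cell-type proportions rho.
    pi_a        : (I,) per-sample prior probability of a CpG being aberrant.
    sigma_a2 / sigma_c2 : global aberrant / consistent variance scales.
    gamma       : (K, I) posterior probability each CpG-sample entry is aberrant.
    nu0         : (K,) methylation of the no-reference cell type, or None.
    residuals   : (K, I) z - eta nu0 - nu rho.
    loglik_trace: observed-data penalized log-likelihood per EM iteration of
                  the final inner run (ridge and nu0 fixed).
    """

    cell_types: tuple
    sample_ids: tuple
    cpg_ids: tuple
    proportions: np.ndarray
    pi_a: np.ndarray
    sigma_a2: float
    sigma_c2: float
    gamma: np.ndarray
    nu0: np.ndarray | None
    residuals: np.ndarray
    chosen_ridge: float
    loglik_trace: np.ndarray
    converged: bool
    eta: np.ndarray = None
    warnings: list = field(default_factory=list)

    def validate(self, tol: float = 1e-6) -> None:
        rho, eta = self.proportions, self.eta
        if (rho < -tol).any():
            raise EmethError("fit invariant violated: negative proportion")
        colsum = rho.sum(axis=0)
        if np.abs(colsum - (1.0 - eta)).max() > tol:
            raise EmethError("fit invariant violated: proportions do not sum to 1 - eta")
        if (self.gamma < -tol).any() or (self.gamma > 1 + tol).any():
            raise EmethError("fit invariant violated: gamma outside [0, 1]")
        if (self.pi_a < -tol).any() or (self.pi_a > 1 + tol).any():
            raise EmethError("fit invariant violated: pi_a outside [0, 1]")
        if not (self.sigma_a2 >= self.sigma_c2 > 0):
            raise EmethError("fit invariant violated: need sigma_a2 >= sigma_c2 > 0")
        if self.nu0 is not None and ((self.nu0 < 0).any() or (self.nu0 > 1).any()):
            raise EmethError("fit invariant violated: nu0 outside [0, 1]")
        trace = np.asarray(self.loglik_trace)
        # Laplace uses an epsilon-smoothed L1 proportion update, so its
        # trace is monotone only up to the smoothing scale.
        mono_tol = 1e-8 * max(1.0, np.abs(trace).max(initial=1.0))
        if trace.size > 1 and np.diff(trace).min() < -mono_tol:
            raise EmethError("fit invariant violated: log-likelihood decreased")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded by the simulator for benchmarking."""

    cell_types: tuple
    sample_ids: tuple
    cpg_ids: tuple
    true_proportions: np.ndarray   # (Q, I)
    true_eta: np.ndarray           # (I,)
    true_nu0: np.ndarray           # (K,)
    aberrant_mask: np.ndarray      # (K, I) bool
    config_echo: object = None

    def __post_init__(self):
        total = self.true_proportions.sum(axis=0) + self.true_eta
        if np.abs(total - 1.0).max() > 1e-10:
            raise EmethError("simulation truth: proportions + eta must sum to 1")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, kind: str):
    """Read a CpGs x columns TSV into a ReferenceMatrix or BulkBetaMatrix.

    The first row holds column names (cell types or samples), the first
    column CpG identifiers.  Values must be beta-values in [0, 1]; values
    outside by more than 1e-6 are an error naming the offending cell.
    """
    if kind not in ("reference", "bulk"):
        raise EmethError(f"read_matrix: unknown kind {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / not a table
        raise EmethError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise EmethError(f"{path}: no data columns found (malformed header?)")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise EmethError(f"{path}: non-numeric value at CpG {row!r}, column {col!r}")
    ids = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if kind == "reference":
        return ReferenceMatrix(ids, cols, df.to_numpy(dtype=float))
    return BulkBetaMatrix(ids, cols, df.to_numpy(dtype=float))


def read_sample_info(path, sample_ids: Sequence[str] | None = None) -> SampleInfo:
    """Read a two-column (sample_id, eta) TSV; order follows the file."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=None,
                     names=["sample_id", "eta"], skiprows=_header_rows(path))
    info = SampleInfo(tuple(str(s) for s in df.index),
                      df["eta"].to_numpy(dtype=float))
    if sample_ids is not None:
        lookup = dict(zip(info.sample_ids, info.eta))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise EmethError(f"{path}: no eta for samples {missing[:5]}")
        info = SampleInfo(tuple(sample_ids),
                          np.array([lookup[s] for s in sample_ids]))
    return info


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline().split("\t")
    try:
        float(first[1])
        return 0
    except (ValueError, IndexError):
        return 1


def align_by_cpg(bulk: BulkBetaMatrix, ref: ReferenceMatrix):
    """Restrict both matrices to their shared CpGs, in reference order.

    Idempotent; errors if the identifier sets are disjoint.
    """
    bulk_pos = {c: i for i, c in enumerate(bulk.cpg_ids)}
    keep = [c for c in ref.cpg_ids if c in bulk_pos]
    if not keep:
        raise EmethError("bulk and reference share no CpG identifiers")
    dropped = (len(ref.cpg_ids) - len(keep)) + (len(bulk.cpg_ids) - len(keep))
    if dropped:
        logger.info("align_by_cpg: dropped %d non-shared CpG rows", dropped)
    ref_pos = {c: i for i, c in enumerate(ref.cpg_ids)}
    ref_idx = [ref_pos[c] for c in keep]
    bulk_idx = [bulk_pos[c] for c in keep]
    return (
        BulkBetaMatrix(keep, bulk.sample_ids, bulk.values[bulk_idx]),
        ReferenceMatrix(keep, ref.cell_types, ref.values[ref_idx]),
    )


def write_fit(fit: EMethFit, out_dir, options: "FitOptions | None" = None) -> None:
    """Write proportions, nu0, gamma and run metadata as TSV/flat text."""
    fit.validate()
    os.makedirs(out_dir, exist_ok=True)
    fmt = f"%.{WRITE_DECIMALS}f"
    pd.DataFrame(fit.proportions, index=list(fit.cell_types),
                 columns=list(fit.sample_ids)).to_csv(
        os.path.join(out_dir, "proportions.tsv"), sep="\t", float_format=fmt)
    pd.DataFrame(fit.gamma, index=list(fit.cpg_ids),
                 columns=list(fit.sample_ids)).to_csv(
        os.path.join(out_dir, "gamma.tsv"), sep="\t", float_format=fmt)
    meta = {
        "sigma_a2": f"{fit.sigma_a2:.10g}",
        "sigma_c2": f"{fit.sigma_c2:.10g}",
        "chosen_ridge": f"{fit.chosen_ridge:.10g}",
        "converged": str(fit.converged).lower(),
        "n_iterations": str(len(fit.loglik_trace)),
        "special_cell_type": "present" if fit.nu0 is not None else "absent",
    }
    if options is not None:
        meta.update({
            "variance_weights": options.variance_weights,
            "error_family": options.error_family,
            "cv_folds": str(options.cv_folds),
            "max_iter": str(options.max_iter),
            "tol": f"{options.tol:g}",
            "seed": str(options.seed),
        })
    if fit.nu0 is not None:
        pd.Series(fit.nu0, index=list(fit.cpg_ids), name="beta").to_csv(
            os.path.join(out_dir, "nu0.tsv"), sep="\t", header=False,
            float_format=fmt)
    with open(os.path.join(out_dir, "metadata.txt"), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")
        for w in fit.warnings:
            fh.write(f"warning={w}\n")


def write_matrix(mat, path) -> None:
    """Write a ReferenceMatrix or BulkBetaMatrix as TSV (6 decimals)."""
    mat.to_frame().to_csv(path, sep="\t", float_format=f"%.{WRITE_DECIMALS}f")
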