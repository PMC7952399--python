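"""RMSE metrics and the benchmark grid over noise settings and methods.

The grid mirrors the simulation study design: for every combination of
consistent-CpG noise sigma_c2 and aberrant/consistent variance ratio
lambda_ratio, datasets are simulated and every method is run on the
identical data (paired comparison, which sharply reduces the
Monte-Carlo variance of method orderings).  Accuracy is the root mean
squared error between estimated and true proportions, pooled over cell
types and samples and also reported per cell type.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baselines import METHODS, deconvolve_baseline
from .core import fit_emeth
from .io import EmethError, FitOptions, ReferenceMatrix, SampleInfo
from .simulate import SimulationConfig, simulate_mixtures

logger = logging.getLogger("emeth")

ALL_METHODS = ("EMeth",) + METHODS

__all__ = ["BenchmarkTable", "compute_rmse", "run_benchmark_grid",
           "ALL_METHODS"]


def compute_rmse(estimated, truth, per_celltype: bool = False):
    """Root mean squared error of proportion estimates.

    Overall: sqrt of the mean squared difference pooled over all Q x I
    entries.  Per cell type: the same restricted to each row, returned
    as a length-Q vector.  Note overall^2 equals the mean of the
    per-cell-type squared values.
    """
    estimated = np.asarray(estimated, float)
    truth = np.asarray(truth, float)
    if estimated.shape != truth.shape:
        raise EmethError(
            f"shape mismatch: estimated {estimated.shape} vs truth {truth.shape}")
    sq = (estimated - truth) ** 2
    if per_celltype:
        return np.sqrt(sq.mean(axis=1))
    return float(np.sqrt(sq.mean()))


@dataclass
class BenchmarkTable:
    """Long-format benchmark results plus a pivoted summary."""

    rows: pd.DataFrame
    cell_types: tuple

    def summary(self) -> pd.DataFrame:
        """Mean overall RMSE per (sigma_c2, lambda_ratio) x method."""
        ok = self.rows.dropna(subset=["overall_rmse"])
        pivot = ok.pivot_table(index=["sigma_c2", "lambda_ratio"],
                               columns="method", values="overall_rmse",
                               aggfunc="mean")
        order = [m for m in ALL_METHODS if m in pivot.columns]
        return pivot[order]

    def write(self, long_path, pivot_path=None) -> None:
        self.rows.to_csv(long_path, sep="\t", index=False,
                         float_format="%.6g")
        if pivot_path is not None:
            self.summary().to_csv(pivot_path, sep="\t", float_format="%.6g")


def _run_one_method(method, bulk, ref, info, seed, fit_options):
    if method.lower() == "emeth":
        opts = replace(fit_options, seed=seed)
        fit = fit_emeth(bulk, ref, info, opts)
        return fit.proportions, fit.nu0
    res = deconvolve_baseline(bulk, ref, info, method=method, seed=seed)
    return res.proportions, None


def run_benchmark_grid(ref_means: ReferenceMatrix, settings,
                       methods=ALL_METHODS, repetitions: int = 10,
                       seed: int = 0,
                       fit_options: FitOptions | None = None) -> BenchmarkTable:
    """Simulate and score every method on every setting x repetition.

    Per cell of the grid, one dataset is simulated per repetition (with
    a child seed derived from ``seed``) and consumed by all methods.
    A failing method is recorded as a NaN row and the grid continues.
    """
    settings = list(settings)
    if not settings:
        raise EmethError("benchmark needs at least one simulation setting")
    if not methods:
        raise EmethError("benchmark needs at least one method")
    if repetitions < 1:
        raise EmethError("repetitions must be >= 1")
    fit_options = fit_options or FitOptions()
    cell_types = ref_means.cell_types
    records = []
    for si, cfg in enumerate(settings):
        if not isinstance(cfg, SimulationConfig):
            raise EmethError("settings must be SimulationConfig instances")
        for rep in range(repetitions):
            # child seed keyed by repetition only: the same repetition in
            # different grid cells shares the underlying draws, so
            # cross-setting comparisons are paired too
            child = int(np.random.SeedSequence([seed, rep])
                        .generate_state(1)[0] % (2 ** 31))
            bulk, truth = simulate_mixtures(ref_means, replace(cfg, seed=child))
            info = SampleInfo(truth.sample_ids, truth.true_eta)
            for method in methods:
                t0 = time.perf_counter()
                row = {
                    "sigma_c2": cfg.sigma_c2,
                    "lambda_ratio": cfg.lambda_ratio,
                    "method": "EMeth" if method.lower() == "emeth" else method.upper(),
                    "repetition": rep,
                }
                try:
                    props, nu0 = _run_one_method(method, bulk, ref_means,
                                                 info, child, fit_options)
                    row["overall_rmse"] = compute_rmse(props, truth.true_proportions)
                    per_ct = compute_rmse(props, truth.true_proportions,
                                          per_celltype=True)
                    for q, ct in enumerate(cell_types):
                        row[f"rmse_{ct}"] = per_ct[q]
                    if nu0 is not None and truth.true_eta.max() > 0:
                        row["nu0_correlation"] = float(
                            np.corrcoef(nu0, truth.true_nu0)[0, 1])
                    else:
                        row["nu0_correlation"] = np.nan
                except Exception as exc:   # record failure, keep the grid going
                    logger.warning("benchmark: %s failed on setting %d rep %d: %s",
                                   method, si, rep, exc)
                    row["overall_rmse"] = np.nan
                    row["nu0_correlation"] = np.nan
                row["runtime_s"] = time.perf_counter() - t0
                records.append(row)
    rows = pd.DataFrame.from_records(records)
    return BenchmarkTable(rows=rows, cell_types=cell_types)
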