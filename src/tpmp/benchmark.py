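"""Benchmark harness: sweep the measurement count and compare solvers.

Mirrors the standard compressed-sensing ECG evaluation protocol at a
configurable scale: for each number of measurements M (equivalently each
compression ratio) draw a window, sparsify it to K DCT coefficients, draw a
fresh Bernoulli sensing matrix, compress (optionally at a nominal SNR), run
every configured solver, and tabulate the exact-recovery ratio (ERR) and the
percentage root-mean-square difference (PRD) per (solver, M).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, fields
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .metrics import cr, prd, prd_lower_bound
from .sensing import (
    Dictionary,
    make_bernoulli_sensing,
    make_dct_basis,
    read_ecg_window,
    sparsify,
    synthesize_sparse_ecg,
)
from .solvers import SolverConfig, run_solver

__all__ = ["TrialRecord", "BenchmarkConfig", "run_benchmark", "summarize"]


@dataclass(frozen=True)
class TrialRecord:
    """One (solver, trial) outcome."""

    solver: str
    n: int
    m: int
    k: int
    snr_db: float | None
    seed: int
    support_exact: bool
    prd: float
    prd_bound: float
    residual_norm: float
    runtime: float
    candidates: int = 0
    error: str | None = None


@dataclass(frozen=True)
class BenchmarkConfig:
    """Sweep definition.

    ``m_grid`` must be strictly increasing; ``snr_db=None`` means noiseless
    measurements.  ``data_source`` is "synthetic" (exactly K-sparse DCT
    windows) or "csv" (real windows read from ``csv_path`` and sparsified to
    K, so the K-term approximation error enters the PRD floor).
    """

    n: int = 128
    k: int = 8
    m_grid: tuple = (24, 32, 40, 48, 56, 64)
    trials: int = 200
    solvers: tuple = ("omp", "sp", "tpmp")
    snr_db: float | None = None
    seed: int = 0
    data_source: str = "synthetic"
    csv_path: str | None = None
    channel: int = 0
    window_length: int | None = None
    amplitude_range: tuple = (0.5, 2.0)
    low_freq_bias: bool = True
    tpmp_c: float = 0.0
    tpmp_theta_size: int | None = None
    tpmp_inner: str = "sp"
    tpmp_stop_multiplier: str = "n"
    mmp_L: int = 2
    max_nodes: int = 1000

    def __post_init__(self):
        if self.trials < 1:
            raise ValueError("need at least one trial per grid point")
        if any(b <= a for a, b in zip(self.m_grid, self.m_grid[1:])):
            raise ValueError("m_grid must be strictly increasing")
        if self.data_source not in {"synthetic", "csv"}:
            raise ValueError(f"unknown data source {self.data_source!r}")

    @classmethod
    def from_dict(cls, mapping: dict) -> "BenchmarkConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown benchmark config keys: {sorted(unknown)}")
        mapping = dict(mapping)
        for key in ("m_grid", "solvers", "amplitude_range"):
            if key in mapping:
                mapping[key] = tuple(mapping[key])
        return cls(**mapping)


def _draw_window(config: BenchmarkConfig, rng: np.random.Generator, basis):
    """Return (x_tilde, sparse, x) for one trial."""
    if config.data_source == "csv":
        full = read_ecg_window(config.csv_path, channel=config.channel)
        length = config.window_length or config.n
        if length != config.n:
            raise ValueError("window_length must equal n")
        start = int(rng.integers(0, full.size - length + 1))
        x_tilde = full[start : start + length]
    else:
        x_tilde, _ = synthesize_sparse_ecg(
            config.n,
            config.k,
            amplitude_range=config.amplitude_range,
            seed=rng,
            low_freq_bias=config.low_freq_bias,
            basis=basis,
        )
    sparse, x = sparsify(x_tilde, config.k, basis=basis)
    return x_tilde, sparse, x


def run_benchmark(config: BenchmarkConfig):
    """Execute the sweep; returns ``(records, summary_dataframe)``.

    Fully reproducible: trial randomness is derived from
    ``(config.seed, m_index, trial_index)`` so runs are independent of solver
    list order and identical across repeats.
    """
    basis = make_dct_basis(config.n)
    records: list[TrialRecord] = []
    for mi, m in enumerate(config.m_grid):
        for t in range(config.trials):
            rng = np.random.default_rng([config.seed, mi, t])
            trial_seed = int(rng.integers(0, 2**31 - 1))
            x_tilde, sparse, _x = _draw_window(config, rng, basis)
            sensing = make_bernoulli_sensing(
                m, config.n, seed=int(rng.integers(0, 2**31 - 1))
            )
            D = Dictionary(sensing, basis)
            clean = D.product @ sparse.coefficients
            if config.snr_db is None:
                sigma2 = 0.0
                y = clean
            else:
                sigma2 = float(clean @ clean) * 10 ** (-config.snr_db / 10) / m
                y = clean + rng.normal(0.0, np.sqrt(sigma2), size=m)
            bound = prd_lower_bound(x_tilde, config.k, basis=basis)
            nz = sparse.coefficients[list(sparse.support)]
            prior_var = float(np.mean(nz**2))
            scfg = SolverConfig(
                k=config.k,
                L=config.mmp_L,
                max_nodes=config.max_nodes,
                sigma2=sigma2,
                prior_variance=prior_var,
            )

            meas = SimpleNamespace(y=y, noise_sigma2=sigma2)
            for name in config.solvers:
                extra = {}
                if name == "oracle":
                    extra["support"] = sparse.support
                if name == "tpmp":
                    extra.update(
                        c=config.tpmp_c,
                        theta_size=config.tpmp_theta_size,
                        inner_solver=config.tpmp_inner,
                        stop_multiplier=config.tpmp_stop_multiplier,
                    )
                tic = time.perf_counter()
                try:
                    result = run_solver(name, D, meas, scfg, **extra)
                except Exception as exc:  # surfaced per trial, counted, not fatal
                    records.append(
                        TrialRecord(
                            solver=name, n=config.n, m=m, k=config.k,
                            snr_db=config.snr_db, seed=trial_seed,
                            support_exact=False, prd=float("nan"),
                            prd_bound=bound, residual_norm=float("nan"),
                            runtime=time.perf_counter() - tic,
                            error=f"{type(exc).__name__}: {exc}",
                        )
                    )
                    continue
                elapsed = time.perf_counter() - tic
                x_hat = basis.synthesize(result.coefficients)
                records.append(
                    TrialRecord(
                        solver=name, n=config.n, m=m, k=config.k,
                        snr_db=config.snr_db, seed=trial_seed,
                        support_exact=set(result.support) == set(sparse.support),
                        prd=prd(x_tilde, x_hat),
                        prd_bound=bound,
                        residual_norm=result.residual_norm,
                        runtime=elapsed,
                        candidates=int(result.diagnostics.get("candidates", 0)),
                    )
                )
    return records, summarize(records)


def summarize(records) -> pd.DataFrame:
    """Per-(solver, M) table: ERR, mean/sd PRD, mean candidate count, CR."""
    frame = pd.DataFrame([r.__dict__ for r in records])
    if frame.empty:
        raise ValueError("no trial records to summarize")
    grouped = (
        frame.groupby(["solver", "n", "m", "k"], as_index=False)
        .agg(
            trials=("support_exact", "size"),
            err=("support_exact", "mean"),
            mean_prd=("prd", "mean"),
            sd_prd=("prd", "std"),
            mean_candidates=("candidates", "mean"),
            mean_runtime=("runtime", "mean"),
            failures=("error", lambda s: int(s.notna().sum())),
        )
        .sort_values(["solver", "m"])
        .reset_index(drop=True)
    )
    grouped["cr"] = [cr(m, n) for m, n in zip(grouped["m"], grouped["n"])]
    return grouped
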