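"""Model-style front end: a recovery problem object and its fitted results.

``SparseRecovery`` bundles a measurement with its dictionary the way a
statistical model bundles data with its design; ``fit()`` runs a solver and
returns a ``RecoveryResults`` carrying the coefficient estimates, support,
residual diagnostics and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import prd
from .pursuit import TPMPConfig, reconstruct, tpmp
from .sensing import (
    Dictionary,
    Measurement,
    SparseSignal,
    compress,
    make_bernoulli_sensing,
    make_dct_basis,
    sparsify,
)
from .solvers import SolverConfig, run_solver

__all__ = ["SparseRecovery", "RecoveryResults"]


class SparseRecovery:
    """A compressed-sensing recovery problem y = A s + v with sparsity K."""

    def __init__(self, y, dictionary: Dictionary, k: int, sigma2: float = 0.0):
        self.y = np.asarray(y, dtype=float)
        self.dictionary = dictionary
        self.k = int(k)
        self.sigma2 = float(sigma2)
        if self.y.size != dictionary.m:
            raise ValueError(
                f"measurement length {self.y.size} != dictionary rows {dictionary.m}"
            )
        if not 1 <= self.k <= dictionary.m:
            raise ValueError(f"need 1 <= k <= m, got k={k}, m={dictionary.m}")

    @classmethod
    def from_signal(
        cls,
        x_tilde,
        m: int,
        k: int,
        seed=None,
        snr_db: float | None = None,
    ) -> "SparseRecovery":
        """Build the full pipeline from a raw window: sparsify, sense, compress."""
        x_tilde = np.asarray(x_tilde, dtype=float)
        n = x_tilde.size
        basis = make_dct_basis(n)
        sparse, _ = sparsify(x_tilde, k, basis=basis)
        D = Dictionary(make_bernoulli_sensing(m, n, seed=seed), basis)
        meas = compress(D, sparse, snr_db=snr_db, seed=None if seed is None else seed + 1)
        model = cls(meas.y, D, k, sigma2=meas.noise_sigma2)
        model._truth = sparse
        model._x_tilde = x_tilde
        return model

    def fit(self, method: str = "tpmp", **options) -> "RecoveryResults":
        """Solve the recovery problem; ``method`` is any registry solver name."""
        state = None
        if method == "tpmp":
            cfg = TPMPConfig(k=self.k, **options)
            result, state = tpmp(self.dictionary, self.y, cfg, sigma2=self.sigma2)
        else:
            known = {f for f in ("L", "mode", "max_nodes", "tol", "prior_variance")}
            cfg = SolverConfig(
                k=self.k,
                sigma2=self.sigma2,
                **{k: v for k, v in options.items() if k in known},
            )
            extra = {k: v for k, v in options.items() if k not in known}
            meas = Measurement(self.y, self.sigma2, None, self.y.size)
            result = run_solver(method, self.dictionary, meas, cfg, **extra)
        return RecoveryResults(self, method, result, state)


@dataclass
class RecoveryResults:
    """Fitted sparse estimate with diagnostics."""

    model: SparseRecovery
    method: str
    solver_result: object
    search_state: object = None

    @property
    def coefficients(self) -> np.ndarray:
        return self.solver_result.coefficients

    @property
    def support(self) -> tuple:
        return self.solver_result.support

    @property
    def residual_norm(self) -> float:
        return self.solver_result.residual_norm

    def reconstruct(self) -> np.ndarray:
        """Time-domain reconstruction x_hat = Psi s_hat."""
        return reconstruct(self.model.dictionary.basis, self.solver_result)

    def prd(self, x_ref=None) -> float:
        """PRD (%) against a reference window (defaults to the build signal)."""
        if x_ref is None:
            x_ref = getattr(self.model, "_x_tilde", None)
        if x_ref is None:
            raise ValueError("no reference signal available; pass x_ref")
        return prd(x_ref, self.reconstruct())

    def support_exact(self, truth: SparseSignal | None = None) -> bool:
        truth = truth or getattr(self.model, "_truth", None)
        if truth is None:
            raise ValueError("no ground-truth support available; pass truth")
        return set(self.support) == set(truth.support)

    def summary(self) -> str:
        D = self.model.dictionary
        lines = [
            "Sparse recovery results",
            "=" * 47,
            f"{'method':<24}{self.method}",
            f"{'N (signal dim)':<24}{D.n}",
            f"{'M (measurements)':<24}{D.m}",
            f"{'K (sparsity)':<24}{self.model.k}",
            f"{'noise sigma^2':<24}{self.model.sigma2:.3e}",
            f"{'support':<24}{list(self.support)}",
            f"{'residual norm':<24}{self.residual_norm:.6e}",
        ]
        diag = getattr(self.solver_result, "diagnostics", {})
        for key in ("candidates", "nodes", "pruning_events", "termination"):
            if key in diag:
                lines.append(f"{key:<24}{diag[key]}")
        truth = getattr(self.model, "_truth", None)
        if truth is not None:
            lines.append(f"{'support exact':<24}{self.support_exact(truth)}")
        if getattr(self.model, "_x_tilde", None) is not None:
            lines.append(f"{'PRD (%)':<24}{self.prd():.6f}")
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot(self, x_ref=None, ax=None):
        """Overlay the reconstruction on the reference window (needs matplotlib)."""
        import matplotlib.pyplot as plt  # noqa: PLC0415 -- optional extra

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        if x_ref is None:
            x_ref = getattr(self.model, "_x_tilde", None)
        if x_ref is not None:
            ax.plot(x_ref, "k-", lw=0.8, label="original")
        ax.plot(self.reconstruct(), "r--", lw=0.8, label="reconstructed")
        ax.set_xlabel("sample")
        ax.legend(frameon=False)
        return ax
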