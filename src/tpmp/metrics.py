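"""Reconstruction-quality metrics: PRD, exact-recovery ratio, compression ratio."""

from __future__ import annotations

import numpy as np

from .sensing import BasisMatrix, sparsify

__all__ = ["prd", "err", "cr", "prd_lower_bound"]


def prd(x_ref, x_hat, percentage: bool = True) -> float:
    """Percentage root-mean-square difference.

    PRD = ||x_ref - x_hat||_2 / ||x_ref - mean(x_ref)||_2, reported as a
    percentage by default.  Scale-invariant; undefined (raises) when the
    reference is constant.
    """
    x_ref = np.asarray(x_ref, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x_ref.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x_ref.shape} vs {x_hat.shape}")
    denom = float(np.linalg.norm(x_ref - x_ref.mean()))
    if denom == 0.0:
        raise ValueError("PRD undefined for a constant reference signal")
    ratio = float(np.linalg.norm(x_ref - x_hat)) / denom
    return 100.0 * ratio if percentage else ratio


def err(records) -> float:
    """Exact recovery ratio: the fraction of trials with the true support.

    Accepts an iterable of booleans or of objects with a ``support_exact``
    attribute (e.g. benchmark trial records).
    """
    flags = [
        bool(getattr(rec, "support_exact", rec)) for rec in records
    ]
    if not flags:
        raise ValueError("ERR needs at least one trial record")
    return sum(flags) / len(flags)


def cr(m: int, n: int) -> float:
    """Compression ratio (N - M)/N x 100 (%)."""
    if not 0 < m <= n:
        raise ValueError(f"need 0 < m <= n, got m={m}, n={n}")
    return (n - m) / n * 100.0


def prd_lower_bound(
    x_tilde, k: int, basis: BasisMatrix | None = None, percentage: bool = True
) -> float:
    """PRD of the best K-term transform approximation of ``x_tilde``.

    No estimator reconstructing a K-sparse coefficient vector can beat this:
    under an orthonormal basis the K-term truncation minimizes the
    reconstruction error over every size-K coefficient subset.
    """
    _, x = sparsify(x_tilde, k, basis=basis)
    return prd(x_tilde, x, percentage=percentage)
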