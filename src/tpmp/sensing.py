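"""Compression front end: DCT sparsification and random Bernoulli sensing.

A digitized single-channel ECG window ``x_tilde`` of length ``N`` is first
approximated by its best K-term representation in an orthonormal DCT basis,

    x_tilde = Psi @ s_tilde  ~=  x = Psi @ s,      ||s||_0 = K,

and then compressed to ``M << N`` linear measurements

    y = Phi @ x + v = Phi @ Psi @ s + v = A @ s + v,

where ``Phi`` is an M x N random Bernoulli matrix with entries +-1/sqrt(M)
(unit-norm columns) and ``v`` is optional white Gaussian measurement noise.
This module builds the operators, performs the sparsification/compression,
and synthesizes ECG-like sparse test signals; recovery lives elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.fft import dct, idct

__all__ = [
    "BasisMatrix",
    "SensingMatrix",
    "Dictionary",
    "SparseSignal",
    "Measurement",
    "make_dct_basis",
    "sparsify",
    "make_bernoulli_sensing",
    "compress",
    "synthesize_sparse_ecg",
    "read_ecg_window",
    "top_k_indices",
]


def top_k_indices(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` largest-magnitude entries, lowest index on ties.

    A stable descending sort on magnitude guarantees the deterministic
    lowest-index tie-break used throughout the package.
    """
    values = np.asarray(values)
    order = np.argsort(-np.abs(values), kind="stable")
    return np.sort(order[:k])


@dataclass(frozen=True)
class BasisMatrix:
    """Orthonormal synthesis basis ``Psi`` (time samples = Psi @ coefficients)."""

    n: int
    entries: np.ndarray

    def synthesize(self, coefficients: np.ndarray) -> np.ndarray:
        return self.entries @ np.asarray(coefficients, dtype=float)

    def analyze(self, signal: np.ndarray) -> np.ndarray:
        """Transform coefficients of a time-domain signal (Psi^T x)."""
        return self.entries.T @ np.asarray(signal, dtype=float)


@dataclass(frozen=True)
class SensingMatrix:
    """Random Bernoulli compression operator with entries +-1/sqrt(M)."""

    m: int
    n: int
    entries: np.ndarray
    seed: int | None = None


@dataclass(frozen=True)
class Dictionary:
    """Sensing/basis pair and their product ``A = Phi @ Psi``.

    Columns of ``A`` are the atoms the recovery algorithms correlate with;
    ``column(j)`` uses 0-based indexing into the universe ``{0..N-1}``.
    """

    sensing: SensingMatrix
    basis: BasisMatrix
    product: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.product is None:
            object.__setattr__(
                self, "product", self.sensing.entries @ self.basis.entries
            )

    @property
    def m(self) -> int:
        return self.sensing.m

    @property
    def n(self) -> int:
        return self.basis.n

    def column(self, j: int) -> np.ndarray:
        return self.product[:, j]

    @classmethod
    def bernoulli_dct(cls, m: int, n: int, seed=None) -> "Dictionary":
        """Convenience constructor for the standard Bernoulli/DCT pair."""
        return cls(make_bernoulli_sensing(m, n, seed), make_dct_basis(n))


@dataclass(frozen=True)
class SparseSignal:
    """A K-sparse coefficient vector with its support."""

    n: int
    coefficients: np.ndarray
    support: tuple
    k: int

    def __post_init__(self):
        if len(self.support) != self.k:
            raise ValueError("support size must equal sparsity k")

    @classmethod
    def from_dense(cls, coefficients: np.ndarray) -> "SparseSignal":
        coefficients = np.asarray(coefficients, dtype=float)
        support = tuple(int(j) for j in np.flatnonzero(coefficients))
        return cls(coefficients.size, coefficients, support, len(support))

    def min_nonzero(self) -> float:
        return float(np.min(np.abs(self.coefficients[list(self.support)])))


@dataclass(frozen=True)
class Measurement:
    """Compressed observation ``y`` with its noise bookkeeping."""

    y: np.ndarray
    noise_sigma2: float
    snr_db: float | None
    m: int

    @property
    def noiseless(self) -> bool:
        return self.noise_sigma2 == 0.0


def make_dct_basis(n: int) -> BasisMatrix:
    """Orthonormal DCT synthesis matrix ``Psi`` of size n x n.

    Convention: ``Psi`` inverts the orthonormal DCT-II analysis transform, so
    ``x = Psi @ s`` with ``s = dct(x, norm="ortho")``; the first atom is the
    constant vector 1/sqrt(n).
    """
    if n < 1:
        raise ValueError(f"basis dimension must be positive, got {n}")
    psi = idct(np.eye(n), type=2, norm="ortho", axis=0)
    return BasisMatrix(n=n, entries=psi)


def sparsify(x_tilde: np.ndarray, k: int, basis: BasisMatrix | None = None):
    """Best K-term DCT approximation of a signal.

    Keeps the ``k`` largest-magnitude transform coefficients of
    ``Psi^-1 x_tilde`` and zeroes the rest. Returns ``(sparse, x)`` where
    ``x = Psi @ s`` is the approximated time-domain signal. By Parseval the
    approximation error equals the energy of the discarded coefficients, and
    no other k-subset of coefficients does better.
    """
    x_tilde = np.asarray(x_tilde, dtype=float)
    n = x_tilde.size
    if not 1 <= k <= n:
        raise ValueError(f"sparsity k={k} must satisfy 1 <= k <= n={n}")
    if basis is None:
        basis = make_dct_basis(n)
    s_full = basis.analyze(x_tilde)
    keep = top_k_indices(s_full, k)
    s = np.zeros(n)
    s[keep] = s_full[keep]
    sparse = SparseSignal(n=n, coefficients=s, support=tuple(int(j) for j in keep), k=k)
    return sparse, basis.synthesize(s)


def make_bernoulli_sensing(m: int, n: int, seed=None) -> SensingMatrix:
    """I.i.d. equiprobable +-1/sqrt(m) sensing matrix; reproducible from seed."""
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(m, n)) * 2 - 1
    return SensingMatrix(m=m, n=n, entries=signs / math.sqrt(m), seed=seed)


def compress(
    dictionary: Dictionary,
    sparse_signal: SparseSignal,
    snr_db: float | None = None,
    sigma2: float | None = None,
    seed=None,
) -> Measurement:
    """Compress ``y = A s + v``.

    With neither ``snr_db`` nor ``sigma2`` the measurement is noiseless.  A
    given ``snr_db`` sets the per-sample noise variance from the realized
    signal power, ``sigma2 = ||A s||^2 * 10**(-snr_db/10) / M``, so that
    10*log10(||As||^2 / (M sigma2)) equals the nominal SNR.
    """
    if sparse_signal.n != dictionary.n:
        raise ValueError(
            f"dimension mismatch: signal n={sparse_signal.n}, dictionary n={dictionary.n}"
        )
    clean = dictionary.product @ sparse_signal.coefficients
    m = dictionary.m
    if sigma2 is None:
        if snr_db is None:
            sigma2 = 0.0
        else:
            sigma2 = float(clean @ clean) * 10.0 ** (-snr_db / 10.0) / m
    if sigma2 < 0:
        raise ValueError("noise variance must be non-negative")
    if sigma2 == 0.0:
        y = clean
    else:
        rng = np.random.default_rng(seed)
        y = clean + rng.normal(0.0, math.sqrt(sigma2), size=m)
    return Measurement(y=y, noise_sigma2=float(sigma2), snr_db=snr_db, m=m)


def synthesize_sparse_ecg(
    n: int,
    k: int,
    amplitude_range: tuple[float, float] = (0.5, 2.0),
    seed=None,
    low_freq_bias: bool = True,
    basis: BasisMatrix | None = None,
):
    """Draw an ECG-like K-sparse DCT coefficient vector and its signal.

    Real ECG windows concentrate most of their DCT energy at low frequencies;
    with ``low_freq_bias`` the support is drawn without replacement with
    probability proportional to exp(-4 j / n) over coefficient index j, which
    mimics that compaction.  Nonzero amplitudes are uniform in magnitude over
    ``amplitude_range`` with equiprobable random sign.  Returns ``(x, sparse)``
    with ``x = Psi @ s`` exactly.
    """
    if not 1 <= k <= n:
        raise ValueError(f"sparsity k={k} must satisfy 1 <= k <= n={n}")
    a_min, a_max = amplitude_range
    if not (0 < a_min <= a_max):
        raise ValueError(f"empty amplitude range {amplitude_range}")
    rng = np.random.default_rng(seed)
    if low_freq_bias:
        weights = np.exp(-4.0 * np.arange(n) / n)
        weights /= weights.sum()
        support = rng.choice(n, size=k, replace=False, p=weights)
    else:
        support = rng.choice(n, size=k, replace=False)
    support = np.sort(support)
    magnitudes = rng.uniform(a_min, a_max, size=k)
    signs = rng.integers(0, 2, size=k) * 2 - 1
    s = np.zeros(n)
    s[support] = magnitudes * signs
    if basis is None:
        basis = make_dct_basis(n)
    sparse = SparseSignal(
        n=n, coefficients=s, support=tuple(int(j) for j in support), k=k
    )
    return basis.synthesize(s), sparse


def read_ecg_window(
    source,
    channel: int = 0,
    start: int = 0,
    length: int | None = None,
) -> np.ndarray:
    """Read a contiguous window of samples from a CSV file or WFDB record.

    CSV dialect: one sample per row (multi-column files are indexed by
    ``channel``); a single non-numeric leading row is treated as a header.
    WFDB records (PhysioNet) are read through the optional ``wfdb`` package.
    """
    path = Path(source)
    if path.suffix.lower() in {".csv", ".txt", ""} and path.exists():
        samples = _read_csv_samples(path, channel)
    else:
        try:
            import wfdb  # noqa: PLC0415 -- optional, only needed for PhysioNet records
        except ImportError as exc:  # pragma: no cover - absent in minimal installs
            raise OSError(
                f"cannot read {source!r}: not a readable CSV file and the "
                "optional 'wfdb' package is not installed"
            ) from exc
        record = wfdb.rdrecord(str(source))  # pragma: no cover
        samples = np.asarray(record.p_signal)[:, channel]  # pragma: no cover
    total = samples.size
    if length is None:
        length = total - start
    if start < 0 or length < 1 or start + length > total:
        raise IndexError(
            f"window [{start}, {start + length}) out of range for record of "
            f"{total} samples"
        )
    return samples[start : start + length].astype(float)


def _read_csv_samples(path: Path, channel: int) -> np.ndarray:
    rows: list[Sequence[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(line.split(","))
    if not rows:
        raise OSError(f"{path}: empty file")
    first = 0
    try:
        float(rows[0][min(channel, len(rows[0]) - 1)])
    except ValueError:
        first = 1  # header row
    try:
        return np.array([float(r[channel]) for r in rows[first:]])
    except (ValueError, IndexError) as exc:
        raise OSError(f"{path}: cannot parse channel {channel}") from exc
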