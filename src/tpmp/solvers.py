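"""Baseline sparse-recovery solvers and the uniform solver registry.

These are the comparison estimators used in the benchmarks and the inner
engines available to the tree search's posterior-completion step: orthogonal
matching pursuit (OMP), subspace pursuit (SP), multipath matching pursuit
(MMP, breadth- and depth-first), basis pursuit (BP, as a linear program),
the oracle least-squares estimator, a linear MMSE estimator, and an
exhaustive l0 oracle for tiny instances.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .sensing import Dictionary, top_k_indices

__all__ = [
    "SolverResult",
    "SolverConfig",
    "least_squares_on",
    "omp",
    "sp",
    "mmp",
    "bp",
    "oracle_ls",
    "lmmse",
    "l0_oracle",
    "SOLVERS",
    "run_solver",
]


@dataclass(frozen=True)
class SolverResult:
    """Outcome of a sparse recovery attempt.

    ``coefficients`` is the length-N estimate (zero off ``support``);
    ``residual_norm`` is ||y - A_supp s_supp||_2 recomputed from the fit.
    """

    coefficients: np.ndarray
    support: tuple
    residual_norm: float
    iterations: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def support_set(self) -> frozenset:
        return frozenset(self.support)


@dataclass(frozen=True)
class SolverConfig:
    """Shared knobs for the registry interface."""

    k: int = 1
    L: int = 2
    mode: str = "breadth"
    max_nodes: int = 1000
    tol: float = 1e-10
    sigma2: float = 0.0
    prior_variance: float | None = None

    def __post_init__(self):
        if self.k < 1 or self.L < 1 or self.max_nodes < 1:
            raise ValueError("k, L and max_nodes must be positive")


def _as_matrix(dictionary) -> np.ndarray:
    if isinstance(dictionary, Dictionary):
        return dictionary.product
    return np.asarray(dictionary, dtype=float)


def least_squares_on(A: np.ndarray, y: np.ndarray, support) -> tuple:
    """LS fit of ``y`` on the columns ``support`` of ``A``.

    Returns ``(coeffs_on_support, residual_vector, rank_deficient)``; the
    min-norm solution is used when the submatrix is rank deficient.  An empty
    support yields the zero fit with residual ``y``.
    """
    support = list(support)
    if not support:
        return np.zeros(0), np.asarray(y, dtype=float).copy(), False
    sub = A[:, support]
    coef, _, rank, _ = np.linalg.lstsq(sub, y, rcond=None)
    return coef, y - sub @ coef, rank < len(support)


def _embed(n: int, support, coef) -> np.ndarray:
    s = np.zeros(n)
    if len(support):
        s[list(support)] = coef
    return s


def _result(A, y, support, iterations=0, **diag) -> SolverResult:
    support = tuple(sorted(int(j) for j in support))
    coef, r, deficient = least_squares_on(A, y, support)
    if deficient:
        diag["rank_deficient"] = True
    return SolverResult(
        coefficients=_embed(A.shape[1], support, coef),
        support=support,
        residual_norm=float(np.linalg.norm(r)),
        iterations=iterations,
        diagnostics=diag,
    )


def omp(dictionary, y, k: int, tol: float = 1e-10) -> SolverResult:
    """Orthogonal matching pursuit.

    Per iteration: pick the column most correlated in magnitude with the
    current residual (lowest index on ties), refit by least squares on the
    enlarged support, update the residual; stop at ``k`` atoms or when the
    residual is numerically zero.
    """
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    ynorm = float(np.linalg.norm(y))
    support: list[int] = []
    r = y.copy()
    it = 0
    while it < k and np.linalg.norm(r) > tol * max(ynorm, 1.0):
        corr = np.abs(A.T @ r)
        corr[support] = -1.0
        j = int(np.argmax(corr))
        support.append(j)
        _, r, _ = least_squares_on(A, y, support)
        it += 1
    return _result(A, y, support, iterations=it)


def sp(dictionary, y, k: int, tol: float = 1e-10) -> SolverResult:
    """Subspace pursuit.

    Initialize with the k most correlated columns; then iterate {merge in the
    k columns most correlated with the residual, least-squares on the union,
    keep the k largest coefficients, refit} until the residual norm stops
    decreasing.  The returned support is the best one seen, so the reported
    residual is never worse than any intermediate iterate's.
    """
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    k = min(k, n)
    if np.linalg.norm(y) == 0.0:
        return _result(A, y, ())

    def refit(sup):
        coef, r, _ = least_squares_on(A, y, sup)
        return coef, float(np.linalg.norm(r))

    support = [int(j) for j in top_k_indices(A.T @ y, k)]
    coef, res = refit(support)
    best_support, best_res = list(support), res
    for it in range(1, 2 * k + 1):
        _, r, _ = least_squares_on(A, y, best_support)
        corr = np.abs(A.T @ r)
        corr[best_support] = -1.0
        extra = [int(j) for j in np.argsort(-corr, kind="stable")[:k]]
        union = sorted(best_support + extra)
        coef_u, _, _ = least_squares_on(A, y, union)
        keep = top_k_indices(_embed(n, union, coef_u), k)
        support = [int(j) for j in keep]
        coef, res = refit(support)
        if res < best_res * (1.0 - tol) or (res < best_res and best_res == 0.0):
            best_support, best_res = support, res
        else:
            break
        if best_res <= tol * max(float(np.linalg.norm(y)), 1.0):
            break
    return _result(A, y, best_support, iterations=it)


def mmp(
    dictionary,
    y,
    k: int,
    L: int = 2,
    mode: str = "breadth",
    max_nodes: int = 1000,
) -> SolverResult:
    """Multipath matching pursuit.

    Like OMP but each path spreads ``L`` branches per layer, chosen as the L
    columns most correlated in magnitude with that path's residual; paths are
    deduplicated as unordered index sets, and the full-size candidate of
    minimum residual norm wins.  ``mode="depth"`` explores depth-first under
    a candidate budget (the reduced-complexity variant); ``L=1`` reduces to
    OMP.
    """
    if mode not in {"breadth", "depth"}:
        raise ValueError(f"unknown mode {mode!r}")
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    if np.linalg.norm(y) == 0.0:
        return _result(A, y, ())

    best_key, best_res = None, math.inf
    nodes = 0
    truncated = False
    seen: set = set()

    def children(path_key):
        _, r, _ = least_squares_on(A, y, path_key)
        corr = np.abs(A.T @ r)
        corr[list(path_key)] = -1.0
        order = np.argsort(-corr, kind="stable")
        return [int(j) for j in order[:L] if corr[j] >= 0.0]

    frontier: deque = deque([()])
    pop = frontier.popleft if mode == "breadth" else frontier.pop
    full_candidates = 0
    while frontier:
        path = pop()
        for j in children(path):
            key = tuple(sorted(path + (j,)))
            if key in seen:
                continue
            seen.add(key)
            nodes += 1
            if len(key) == k:
                full_candidates += 1
                _, r, _ = least_squares_on(A, y, key)
                res = float(np.linalg.norm(r))
                if res < best_res:
                    best_key, best_res = key, res
            else:
                frontier.append(key)
            if nodes >= max_nodes:
                truncated = True
                break
        if truncated:
            break
    if best_key is None:
        # budget exhausted before any full candidate: fall back to the greedy path
        best_key = omp(A, y, k).support
        truncated = True
    return _result(
        A, y, best_key, iterations=nodes,
        nodes=nodes, candidates=full_candidates, truncated=truncated,
    )


def bp(dictionary, y, support_rtol: float = 1e-6) -> SolverResult:
    """Basis pursuit: min ||s||_1 subject to A s = y, as a linear program.

    The signed variable is split into positive and negative parts
    (s = u - w, u, w >= 0) and solved with the HiGHS simplex/IPM; the support
    is read off by a relative magnitude threshold to shed numerical dust.
    """
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    m, n = A.shape
    if np.linalg.norm(y) == 0.0:
        return _result(A, y, ())
    res = linprog(
        c=np.ones(2 * n),
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"basis pursuit LP failed: {res.status} {res.message}")
    s = res.x[:n] - res.x[n:]
    support = tuple(
        int(j) for j in np.flatnonzero(np.abs(s) > support_rtol * np.abs(s).max())
    )
    out = _result(A, y, support, iterations=int(res.nit), objective=float(res.fun))
    return out


def oracle_ls(dictionary, y, support) -> SolverResult:
    """Least squares on a given (true) support: the genie-aided lower bound."""
    A = _as_matrix(dictionary)
    return _result(A, np.asarray(y, dtype=float), tuple(support))


def lmmse(
    dictionary,
    y,
    sigma2: float,
    prior_variance: float,
    k: int | None = None,
) -> SolverResult:
    """Linear MMSE estimate under an i.i.d. zero-mean coefficient prior.

    s_hat = sv * A^T (sv * A A^T + sigma2 * I)^-1 y with sv the prior
    variance.  The estimate is dense; for support-recovery metrics the
    reported support is its top-K magnitudes (all entries if k is None).
    A tiny ridge keeps the normal matrix invertible when sigma2 = 0.
    """
    if sigma2 < 0 or prior_variance <= 0:
        raise ValueError("need sigma2 >= 0 and prior_variance > 0")
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    m, n = A.shape
    gram = prior_variance * (A @ A.T) + sigma2 * np.eye(m)
    ridged = False
    try:
        w = np.linalg.solve(gram, y)
    except np.linalg.LinAlgError:
        w = np.linalg.solve(gram + 1e-12 * np.eye(m), y)
        ridged = True
    s = prior_variance * (A.T @ w)
    support = tuple(int(j) for j in top_k_indices(s, k if k is not None else n))
    r = y - A @ s
    return SolverResult(
        coefficients=s,
        support=tuple(sorted(support)),
        residual_norm=float(np.linalg.norm(r)),
        diagnostics={"ridged": ridged, "dense": True},
    )


def l0_oracle(dictionary, y, k: int, max_subsets: int = 100_000) -> SolverResult:
    """Exhaustive l0 minimizer over all C(N, k) supports (tiny N only).

    Ties in residual norm break toward the lexicographically smallest
    support.  Refuses instances whose enumeration exceeds ``max_subsets``.
    """
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    total = math.comb(n, k)
    if total > max_subsets:
        raise ValueError(
            f"C({n},{k}) = {total} exceeds the enumeration cap {max_subsets}"
        )
    best_support, best_res = None, math.inf
    for support in itertools.combinations(range(n), k):
        _, r, _ = least_squares_on(A, y, support)
        res = float(np.linalg.norm(r))
        if res < best_res:
            best_support, best_res = support, res
    return _result(A, y, best_support, iterations=total)


def run_solver(name: str, dictionary, measurement, config: SolverConfig, **extra):
    """Dispatch a solver by registry name with a uniform signature."""
    A = _as_matrix(dictionary)
    y = measurement.y if hasattr(measurement, "y") else np.asarray(measurement)
    sigma2 = getattr(measurement, "noise_sigma2", config.sigma2)
    if name == "omp":
        return omp(A, y, config.k, tol=config.tol)
    if name == "sp":
        return sp(A, y, config.k, tol=config.tol)
    if name == "mmp":
        return mmp(A, y, config.k, L=config.L, mode="breadth", max_nodes=config.max_nodes)
    if name == "mmp-df":
        return mmp(A, y, config.k, L=config.L, mode="depth", max_nodes=config.max_nodes)
    if name == "bp":
        return bp(A, y)
    if name == "oracle":
        return oracle_ls(A, y, extra["support"])
    if name == "lmmse":
        pv = config.prior_variance
        if pv is None:
            pv = max((float(y @ y) - A.shape[0] * sigma2), 1e-12) / config.k
        return lmmse(A, y, sigma2, pv, k=config.k)
    if name == "l0":
        return l0_oracle(A, y, config.k)
    if name == "tpmp":
        from .pursuit import TPMPConfig, tpmp  # local import avoids a cycle

        cfg = TPMPConfig(k=config.k, c=extra.pop("c", 0.0), **extra)
        result, _ = tpmp(A, y, cfg, sigma2=sigma2)
        return result
    raise KeyError(f"unknown solver {name!r}")


#: registry used by the CLI, benchmarks and the tree search's inner hook
SOLVERS = ("omp", "sp", "mmp", "mmp-df", "bp", "oracle", "lmmse", "l0", "tpmp")
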