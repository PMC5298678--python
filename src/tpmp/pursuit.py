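"""Tree-pruning matching pursuit (TPMP).

The search identifies the support of a K-sparse coefficient vector from
``y = A s + v`` in two stages:

1. *Pre-scanning*: keep the ``|Theta|`` dictionary columns most correlated in
   magnitude with ``y`` (``Theta = argmax_{|I|=K} ||A_I^T y||_2`` for the
   default ``|Theta| = K``; the objective is separable so the top-K
   correlations solve it exactly).

2. *Pruned tree search*: grow partial supports ("paths") layer by layer with
   branches drawn from Theta.  Each new path ``Lambda_i`` is judged by the
   cost of a *full-size* candidate: a greedy inner solver (subspace pursuit
   by default) completes the path with ``K - i`` posterior indices from the
   remaining dictionary, and the cost ``J = ||y - A_Lk (A_Lk^+ y)||_2`` is the
   least-squares residual of the completed set.  Paths whose completed cost
   exceeds the pruning threshold ``eps`` are discarded; ``eps`` for the next
   layer is the running minimum candidate cost.  The search stops early once
   the incumbent's squared residual drops below ``c * N * sigma^2`` (a
   fraction of the expected noise energy; with ``c = 0`` on noiseless data
   this fires at the first zero-residual candidate).

The final estimate is the least-squares fit on the incumbent support,
``s_hat = A_I*^+ y``, synthesized back to the time domain by ``x = Psi s``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import solvers as _solvers
from .sensing import BasisMatrix, Dictionary, SparseSignal
from .solvers import SolverResult, least_squares_on

__all__ = [
    "PreScanSet",
    "Candidate",
    "SearchState",
    "TPMPConfig",
    "pre_scan",
    "residual",
    "posterior_indices",
    "evaluate_candidate",
    "tpmp",
    "reconstruct",
]


@dataclass(frozen=True)
class PreScanSet:
    """Pre-scanned column set Theta, ordered by descending |a_j^T y|."""

    indices: tuple
    correlations: np.ndarray


@dataclass(frozen=True)
class Candidate:
    """A full-size (cardinality-K) support hypothesis and its cost."""

    full_set: tuple
    posterior: tuple
    residual_norm: float
    coefficients: np.ndarray


@dataclass
class SearchState:
    """Diagnostics and intermediate structure of one TPMP run."""

    layers: list = field(default_factory=list)
    epsilons: list = field(default_factory=list)
    best: Candidate | None = None
    nodes_expanded: int = 0
    candidates_evaluated: int = 0
    pruning_events: int = 0
    termination: str = "exhausted"
    noise_sigma2: float = 0.0
    stop_constant: float = 0.0


@dataclass(frozen=True)
class TPMPConfig:
    """Search configuration.

    ``theta_size`` defaults to ``k`` (the minimal pre-scan).  The posterior
    completion runs the ``inner_solver`` over the full remaining dictionary
    (``posterior_domain="full"``) or, optionally, only over the pre-scanned
    set.  ``c`` scales the early-stopping bound ``c * N * sigma^2``
    (``stop_multiplier="m"`` switches the multiplier to M, the actual noise
    dimension).  ``epsilon_update="frozen"`` prunes layer ``i`` against the
    threshold fixed at layer entry while the running minimum feeds layer
    ``i+1``; ``"running"`` lets mid-layer improvements prune immediately.
    """

    k: int
    theta_size: int | None = None
    inner_solver: str = "sp"
    posterior_domain: str = "full"  # "full" (Omega \ path) or "theta"
    c: float = 0.0
    stop_multiplier: str = "n"  # "n" per the stated bound c*N*sigma^2, or "m"
    epsilon_update: str = "frozen"
    literal_incumbent: bool = False
    max_candidates: int = 100_000
    zero_tol: float = 1e-9
    inner_L: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.theta_size is not None and self.theta_size < self.k:
            raise ValueError("theta_size must be >= k")
        if self.c < 0:
            raise ValueError("stopping constant c must be non-negative")
        if self.posterior_domain not in {"full", "theta"}:
            raise ValueError(f"unknown posterior_domain {self.posterior_domain!r}")
        if self.stop_multiplier not in {"n", "m"}:
            raise ValueError(f"unknown stop_multiplier {self.stop_multiplier!r}")
        if self.epsilon_update not in {"frozen", "running"}:
            raise ValueError(f"unknown epsilon_update {self.epsilon_update!r}")


def _as_matrix(dictionary) -> np.ndarray:
    if isinstance(dictionary, Dictionary):
        return dictionary.product
    return np.asarray(dictionary, dtype=float)


def pre_scan(dictionary, y, theta_size: int, k: int | None = None) -> PreScanSet:
    """The ``theta_size`` columns with largest |a_j^T y|, lower index on ties.

    Because ||A_I^T y||_2^2 is a sum of per-column terms, this equals the
    argmax over all size-``theta_size`` subsets of ``||A_I^T y||_2``.
    """
    A = _as_matrix(dictionary)
    n = A.shape[1]
    if k is not None and theta_size < k:
        raise ValueError(f"theta_size={theta_size} must be >= k={k}")
    if not 1 <= theta_size <= n:
        raise ValueError(f"theta_size={theta_size} out of range 1..{n}")
    corr = np.abs(A.T @ np.asarray(y, dtype=float))
    order = np.argsort(-corr, kind="stable")[:theta_size]
    return PreScanSet(
        indices=tuple(int(j) for j in order), correlations=corr[order]
    )


def residual(dictionary, y, index_set):
    """Least-squares fit on ``index_set`` and the projection residual.

    Returns ``(coefficients_on_set, residual_vector)`` with the residual
    orthogonal to the selected columns; an empty set leaves ``y`` untouched.
    """
    A = _as_matrix(dictionary)
    coef, r, _ = least_squares_on(A, np.asarray(y, dtype=float), index_set)
    return coef, r


def posterior_indices(dictionary, path, y, config: TPMPConfig, theta=None) -> tuple:
    """Greedy completion of a partial path to full cardinality K.

    Solves the residual sub-problem of recovering a (K - i)-sparse vector
    from ``r_Lambda_i`` over the allowed columns (the remaining dictionary by
    default), using the configured inner solver ("sp", "omp", "mmp", or
    "exhaustive" for tests).  Returns K - i indices disjoint from the path.

    "sp", "mmp" and "exhaustive" act on the residual sub-problem directly
    (the completion objective min_I ||r - A_I s_I||).  "omp" continues the
    joint greedy recursion from the path - each new atom is refit together
    with the path, equivalent to OMP on the path-projected dictionary - so
    the completion of the top pre-scan branch reproduces the plain OMP
    solution exactly.
    """
    A = _as_matrix(dictionary)
    path = tuple(path)
    k, i = config.k, len(path)
    need = k - i
    if need == 0:
        return ()
    if need < 0:
        raise ValueError(f"path of size {i} exceeds sparsity {k}")
    if config.posterior_domain == "theta":
        if theta is None:
            raise ValueError("posterior_domain='theta' requires the pre-scan set")
        domain = [j for j in theta if j not in path]
    else:
        domain = [j for j in range(A.shape[1]) if j not in path]
    if len(domain) < need:
        raise ValueError(
            f"completion domain of size {len(domain)} cannot supply {need} indices"
        )
    name = config.inner_solver
    if name == "omp":
        support = list(path)
        picked: list[int] = []
        allowed = set(domain)
        for _ in range(need):
            _, r_joint = residual(A, y, support)
            corr = np.abs(A.T @ r_joint)
            mask = np.full(A.shape[1], -1.0)
            idx = [j for j in allowed if j not in picked]
            mask[idx] = corr[idx]
            j = int(np.argmax(mask))
            picked.append(j)
            support.append(j)
        return tuple(sorted(picked))
    _, r = residual(A, y, path)
    sub = A[:, domain]
    if name == "exhaustive":
        best, best_res = None, math.inf
        for combo in itertools.combinations(range(len(domain)), need):
            _, rr, _ = least_squares_on(sub, r, combo)
            res = float(np.linalg.norm(rr))
            if res < best_res:
                best, best_res = combo, res
        local = list(best)
    elif name == "sp":
        local = list(_solvers.sp(sub, r, need).support)
    elif name == "mmp":
        local = list(_solvers.mmp(sub, r, need, L=config.inner_L).support)
    else:
        raise KeyError(f"unknown inner solver {name!r}")
    if len(local) < need:
        # inner solver hit a zero residual early; pad by residual correlation
        corr = np.abs(sub.T @ r)
        corr[local] = -1.0
        order = np.argsort(-corr, kind="stable")
        local += [int(j) for j in order if j not in local][: need - len(local)]
    return tuple(sorted(domain[j] for j in local))


def evaluate_candidate(dictionary, y, path, config: TPMPConfig, theta=None) -> Candidate:
    """Complete a path to cardinality K and price it at full size.

    The cost of a path is always the least-squares residual norm of its
    completed candidate ``Lambda_K = Lambda_i U {posterior indices}``, so
    partial paths compete on the same footing as full ones.
    """
    A = _as_matrix(dictionary)
    post = posterior_indices(A, path, y, config, theta=theta)
    full = tuple(sorted(set(path) | set(post)))
    coef, r = residual(A, y, full)
    return Candidate(
        full_set=full,
        posterior=post,
        residual_norm=float(np.linalg.norm(r)),
        coefficients=coef,
    )


def tpmp(dictionary, y, config: TPMPConfig, sigma2: float = 0.0):
    """Run the pruned tree search; returns ``(SolverResult, SearchState)``.

    Layer ``i`` expands every surviving path of layer ``i-1`` with branches
    from Theta, skipping supports already seen, evaluates each new path's
    full-size candidate, prunes against the layer threshold, and keeps the
    best candidate seen anywhere as the incumbent.  The search terminates
    early when the incumbent's squared residual falls below
    ``c * multiplier * sigma^2`` (plus a numerical-zero floor), or when the
    candidate budget is exhausted.
    """
    A = _as_matrix(dictionary)
    y = np.asarray(y, dtype=float)
    m, n = A.shape
    k = config.k
    if k > m:
        raise ValueError(f"sparsity k={k} exceeds measurement dimension m={m}")
    theta_size = config.theta_size if config.theta_size is not None else k
    scan = pre_scan(A, y, theta_size, k=k)
    theta = scan.indices

    multiplier = n if config.stop_multiplier == "n" else m
    stop_rss = config.c * multiplier * sigma2
    zero_floor = (config.zero_tol * max(float(np.linalg.norm(y)), 1.0)) ** 2

    state = SearchState(noise_sigma2=sigma2, stop_constant=config.c)
    state.layers.append([()])
    eps_running = math.inf  # epsilon_{i+1}: running min of candidate costs
    best_key = None
    stop = False
    budget_hit = False

    surviving = [()]
    for layer in range(1, k + 1):
        eps_frozen = eps_running  # epsilon_i, fixed at layer entry
        state.epsilons.append(eps_frozen)
        next_layer: list[tuple] = []
        seen: set = set()
        for path in surviving:
            for branch in theta:
                if branch in path:
                    continue
                new_path = path + (branch,)
                key = tuple(sorted(new_path))
                if key in seen:
                    continue  # duplicate support already expanded this layer
                seen.add(key)
                state.nodes_expanded += 1
                cand = evaluate_candidate(A, y, new_path, config, theta=theta)
                state.candidates_evaluated += 1
                eps_gate = eps_running if config.epsilon_update == "running" else eps_frozen
                survives = cand.residual_norm <= eps_gate
                if survives:
                    next_layer.append(new_path)
                else:
                    state.pruning_events += 1
                if config.literal_incumbent:
                    # Table-style overwrite: every surviving candidate becomes I*
                    improved = survives
                else:
                    improved = (
                        state.best is None
                        or cand.residual_norm < state.best.residual_norm
                        or (
                            cand.residual_norm == state.best.residual_norm
                            and cand.full_set < state.best.full_set
                        )
                    )
                if improved:
                    state.best = cand
                    best_key = cand.full_set
                if cand.residual_norm < eps_running:
                    eps_running = cand.residual_norm
                if (
                    state.best is not None
                    and state.best.residual_norm ** 2 <= max(stop_rss, zero_floor)
                ):
                    state.termination = "early_stop"
                    stop = True
                    break
                if state.candidates_evaluated >= config.max_candidates:
                    state.termination = "budget"
                    budget_hit = True
                    stop = True
                    break
            if stop:
                break
        state.layers.append(next_layer)
        surviving = next_layer
        if stop or not surviving:
            break

    if state.best is None:  # unreachable with eps_1 = inf; defensive only
        raise RuntimeError("tree search ended with no evaluated candidate")
    state.epsilons.append(eps_running)

    coef, r = residual(A, y, best_key)
    s_hat = np.zeros(n)
    s_hat[list(best_key)] = coef
    result = SolverResult(
        coefficients=s_hat,
        support=best_key,
        residual_norm=float(np.linalg.norm(r)),
        iterations=state.candidates_evaluated,
        diagnostics={
            "nodes": state.nodes_expanded,
            "candidates": state.candidates_evaluated,
            "pruning_events": state.pruning_events,
            "termination": state.termination,
            "truncated": budget_hit,
            "theta": theta,
        },
    )
    return result, state


def reconstruct(basis: BasisMatrix, sparse_estimate) -> np.ndarray:
    """Synthesize the time-domain signal ``x_hat = Psi s_hat``."""
    if isinstance(sparse_estimate, SparseSignal):
        s = sparse_estimate.coefficients
    elif isinstance(sparse_estimate, SolverResult):
        s = sparse_estimate.coefficients
    else:
        s = np.asarray(sparse_estimate, dtype=float)
    return basis.synthesize(s)
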