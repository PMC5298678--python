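"""The pruned tree search: pre-scan, completion costs, search semantics."""

import itertools
import math

import numpy as np
import pytest

from tpmp import (
    Dictionary,
    TPMPConfig,
    evaluate_candidate,
    l0_oracle,
    make_dct_basis,
    omp,
    posterior_indices,
    pre_scan,
    reconstruct,
    residual,
    synthesize_sparse_ecg,
    tpmp,
)
from tpmp.solvers import least_squares_on

from conftest import make_instance


class TestPreScan:
    def test_decoupled_on_orthonormal(self, ortho_matrix):
        y = 5 * ortho_matrix[:, 0] + 2 * ortho_matrix[:, 2]
        scan = pre_scan(ortho_matrix, y, 2)
        assert set(scan.indices) == {0, 2}
        assert scan.indices[0] == 0  # sorted by descending correlation
        assert np.all(np.diff(scan.correlations) <= 1e-12)

    def test_full_size_returns_universe(self, small_dictionary):
        _, sparse = synthesize_sparse_ecg(12, 2, seed=0)
        y = small_dictionary.product @ sparse.coefficients
        scan = pre_scan(small_dictionary, y, 12)
        assert set(scan.indices) == set(range(12))

    def test_equals_subset_enumeration(self, small_dictionary):
        # the separable objective makes top-theta correlations the exact
        # argmax of ||A_I^T y||_2 over all size-theta subsets
        _, sparse = synthesize_sparse_ecg(12, 3, seed=5)
        A = small_dictionary.product
        y = A @ sparse.coefficients
        scan = pre_scan(A, y, 3)
        best = max(
            itertools.combinations(range(12), 3),
            key=lambda idx: np.linalg.norm(A[:, idx].T @ y),
        )
        assert set(scan.indices) == set(best)

    def test_rejects_theta_below_k(self, small_dictionary):
        with pytest.raises(ValueError):
            pre_scan(small_dictionary, np.zeros(6), 2, k=3)


class TestResidual:
    def test_empty_set_returns_y(self, small_dictionary):
        y = np.arange(6.0)
        coef, r = residual(small_dictionary, y, ())
        assert coef.size == 0
        assert np.array_equal(r, y)

    def test_zero_at_true_support_noiseless(self):
        D, sparse, y, _ = make_instance(16, 8, 3, 7)
        _, r = residual(D, y, sparse.support)
        assert np.linalg.norm(r) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_residual_orthogonal_to_columns(self, seed):
        D, _, y, _ = make_instance(16, 8, 3, seed, snr_db=20)
        idx = [1, 5, 9]
        _, r = residual(D, y, idx)
        assert np.abs(D.product[:, idx].T @ r).max() < 1e-8 * np.linalg.norm(y)


class TestPosteriorIndices:
    def test_complete_path_gives_empty_set(self):
        D, sparse, y, _ = make_instance(12, 6, 2, 0)
        cfg = TPMPConfig(k=2)
        assert posterior_indices(D, sparse.support, y, cfg) == ()

    def test_orthonormal_completion_recovers_rest(self, ortho_matrix):
        y = 3 * ortho_matrix[:, 1] - 2 * ortho_matrix[:, 6] + ortho_matrix[:, 8]
        cfg = TPMPConfig(k=3, inner_solver="omp")
        assert posterior_indices(ortho_matrix, (1,), y, cfg) == (6, 8)

    @pytest.mark.parametrize("inner", ["sp", "omp", "mmp"])
    def test_disjoint_and_right_size(self, inner):
        D, sparse, y, _ = make_instance(16, 8, 4, 3, snr_db=20)
        cfg = TPMPConfig(k=4, inner_solver=inner)
        path = sparse.support[:2]
        post = posterior_indices(D, path, y, cfg)
        assert len(post) == 2
        assert not set(post) & set(path)

    def test_sp_matches_exhaustive_on_benign_instances(self, benign_completion_seeds):
        # instances pre-screened so the (K-i)-sparse completion sub-problem is
        # solved exactly by SP; enumeration is the oracle
        for seed in benign_completion_seeds:
            D, sparse, y, _ = make_instance(16, 8, 3, seed)
            path = (sparse.support[0],)
            exh = posterior_indices(D, path, y, TPMPConfig(k=3, inner_solver="exhaustive"))
            got = posterior_indices(D, path, y, TPMPConfig(k=3, inner_solver="sp"))
            assert got == exh

    def test_theta_domain_restriction(self):
        D, sparse, y, _ = make_instance(12, 6, 2, 1)
        cfg = TPMPConfig(k=2, posterior_domain="theta")
        theta = (0, 1, 2)
        post = posterior_indices(D, (0,), y, cfg, theta=theta)
        assert set(post) <= {1, 2}

    def test_domain_too_small(self):
        D, _, y, _ = make_instance(12, 6, 3, 1)
        cfg = TPMPConfig(k=3, posterior_domain="theta")
        with pytest.raises(ValueError):
            posterior_indices(D, (0,), y, cfg, theta=(0, 1))


@pytest.fixture(scope="module")
def benign_completion_seeds():
    # screened once against the exhaustive oracle; frozen by seed list below
    return (1, 2, 4, 6, 8)


class TestEvaluateCandidate:
    def test_true_support_costs_zero_noiseless(self):
        D, sparse, y, _ = make_instance(12, 6, 2, 2)
        cand = evaluate_candidate(D, y, sparse.support, TPMPConfig(k=2))
        assert cand.residual_norm < 1e-9
        assert cand.full_set == tuple(sorted(sparse.support))

    def test_true_partial_path_completes_to_zero(self, ortho_matrix):
        y = 2 * ortho_matrix[:, 3] + ortho_matrix[:, 7]
        cand = evaluate_candidate(ortho_matrix, y, (3,), TPMPConfig(k=2))
        assert cand.residual_norm < 1e-10
        assert cand.full_set == (3, 7)

    @pytest.mark.parametrize("seed", range(20))
    def test_never_beats_l0_oracle(self, seed):
        D, sparse, y, _ = make_instance(12, 6, 2, seed, snr_db=15)
        oracle = l0_oracle(D, y, 2)
        cand = evaluate_candidate(D, y, (seed % 12,), TPMPConfig(k=2))
        assert cand.residual_norm >= oracle.residual_norm - 1e-9

    def test_cost_always_full_cardinality(self):
        D, sparse, y, _ = make_instance(16, 8, 4, 5, snr_db=20)
        cand = evaluate_candidate(D, y, sparse.support[:1], TPMPConfig(k=4))
        assert len(cand.full_set) == 4


class TestTpmpSearch:
    def test_noiseless_stops_at_first_zero_residual(self):
        D, sparse, y, _ = make_instance(64, 28, 5, 3, bias=True)
        result, state = tpmp(D, y, TPMPConfig(k=5, c=0.0))
        assert state.termination == "early_stop"
        assert result.residual_norm < 1e-8
        assert set(result.support) == set(sparse.support)

    def test_k1_picks_best_single_column(self):
        D, _, y, _ = make_instance(12, 6, 1, 9, snr_db=10)
        result, _ = tpmp(D, y, TPMPConfig(k=1, theta_size=12))
        best = min(
            range(12),
            key=lambda j: np.linalg.norm(
                least_squares_on(D.product, y, [j])[1]
            ),
        )
        assert result.support == (best,)

    @pytest.mark.parametrize("noisy", [False, True])
    def test_matches_l0_oracle_small_instances(self, noisy):
        cfg = TPMPConfig(k=2, theta_size=10, inner_solver="exhaustive", c=0.0)
        for seed in range(30):
            D, sparse, y, sigma2 = make_instance(
                10, 6, 2, seed, snr_db=40 if noisy else None
            )
            result, _ = tpmp(D, y, cfg, sigma2=sigma2)
            oracle = l0_oracle(D, y, 2)
            assert np.isclose(
                result.residual_norm, oracle.residual_norm,
                atol=1e-9 * (1 + np.linalg.norm(y)),
            )

    def test_pruning_threshold_monotone(self):
        D, _, y, sigma2 = make_instance(32, 12, 4, 1, snr_db=20)
        _, state = tpmp(D, y, TPMPConfig(k=4, theta_size=8), sigma2=sigma2)
        eps = [e for e in state.epsilons]
        assert all(b <= a for a, b in zip(eps, eps[1:]))

    def test_incumbent_dominates_omp(self):
        # the tree evaluates at least one full greedy completion, so its best
        # candidate can never lose to plain OMP
        for seed in range(25):
            D, _, y, sigma2 = make_instance(32, 12, 4, seed, snr_db=20)
            result, _ = tpmp(
                D, y, TPMPConfig(k=4, theta_size=8, inner_solver="omp"),
                sigma2=sigma2,
            )
            assert result.residual_norm <= omp(D, y, 4).residual_norm + 1e-9

    def test_duplicate_suppression_bounds_candidates(self):
        D, _, y, sigma2 = make_instance(24, 12, 3, 2, snr_db=15)
        theta = 6
        _, state = tpmp(D, y, TPMPConfig(k=3, theta_size=theta), sigma2=sigma2)
        cap = sum(math.comb(theta, i) for i in range(1, 4))
        assert state.candidates_evaluated <= cap

    def test_early_stop_never_degrades_quiet_runs(self):
        # when the stop bound never fires, c > 0 must not change the result
        for seed in range(10):
            D, _, y, sigma2 = make_instance(24, 10, 3, seed, snr_db=10)
            base, st0 = tpmp(D, y, TPMPConfig(k=3, c=0.0), sigma2=sigma2)
            res, st1 = tpmp(D, y, TPMPConfig(k=3, c=1.0), sigma2=sigma2)
            stop_bound = 1.0 * 24 * sigma2
            if st1.termination != "early_stop":
                assert res.support == base.support
            else:
                assert res.residual_norm**2 <= stop_bound * (1 + 1e-9)

    def test_early_stop_honors_bound_at_return(self):
        for seed in range(10):
            D, _, y, sigma2 = make_instance(32, 16, 4, seed, snr_db=40)
            res, state = tpmp(D, y, TPMPConfig(k=4, c=1.0), sigma2=sigma2)
            if state.termination == "early_stop":
                assert res.residual_norm**2 <= 1.0 * 32 * sigma2 * (1 + 1e-9)

    def test_stop_multiplier_m_is_stricter(self):
        D, _, y, sigma2 = make_instance(32, 16, 4, 0, snr_db=40)
        _, st_n = tpmp(D, y, TPMPConfig(k=4, c=1.0, stop_multiplier="n"), sigma2=sigma2)
        _, st_m = tpmp(D, y, TPMPConfig(k=4, c=1.0, stop_multiplier="m"), sigma2=sigma2)
        assert st_m.candidates_evaluated >= st_n.candidates_evaluated

    def test_budget_truncation_flag(self):
        D, _, y, sigma2 = make_instance(32, 12, 4, 3, snr_db=20)
        res, state = tpmp(
            D, y, TPMPConfig(k=4, theta_size=10, max_candidates=5), sigma2=sigma2
        )
        assert state.termination == "budget"
        assert res.diagnostics["truncated"]
        assert len(res.support) == 4

    def test_k_above_m_rejected(self):
        D, _, y, _ = make_instance(12, 4, 2, 0)
        with pytest.raises(ValueError):
            tpmp(D, y, TPMPConfig(k=5))

    def test_literal_incumbent_mode_runs(self):
        D, _, y, sigma2 = make_instance(16, 8, 2, 5, snr_db=20)
        res, _ = tpmp(
            D, y, TPMPConfig(k=2, literal_incumbent=True), sigma2=sigma2
        )
        assert len(res.support) == 2

    def test_running_epsilon_never_loosens(self):
        D, _, y, sigma2 = make_instance(24, 10, 3, 4, snr_db=15)
        _, frozen = tpmp(D, y, TPMPConfig(k=3, epsilon_update="frozen"), sigma2=sigma2)
        _, running = tpmp(D, y, TPMPConfig(k=3, epsilon_update="running"), sigma2=sigma2)
        assert running.best.residual_norm <= frozen.best.residual_norm + 1e-12
        assert running.candidates_evaluated <= frozen.candidates_evaluated


class TestReconstruct:
    def test_zero_and_identity(self, dct8):
        assert np.allclose(reconstruct(dct8, np.zeros(8)), 0.0)
        x, sparse = synthesize_sparse_ecg(8, 2, seed=0)
        assert np.allclose(reconstruct(dct8, sparse), x, atol=1e-12)

    def test_isometry(self, dct8):
        s = np.random.default_rng(1).normal(size=8)
        assert np.isclose(np.linalg.norm(reconstruct(dct8, s)), np.linalg.norm(s))
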