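import inspect

import numpy as np
import pytest

from fedpca import (
    AGGREGATOR,
    CommLog,
    LocalSummary,
    SitePartition,
    Subspace,
    angle_degrees,
    ap_cov,
    ap_stack,
    centralized_pca,
    local_subspace,
    merge_proxy_covariance,
    p_cov,
    qr_merge,
    qr_pca,
    reconstruction_error,
    split_by_sizes,
)
from fedpca.synthetic_data import SpectrumSpec, generate_lowrank

from conftest import make_matrix


def max_pairwise_angle(Va, Vb):
    return max(
        angle_degrees(Va[:, j], Vb[:, j]) for j in range(Va.shape[1])
    )


class TestSubspaceType:
    def test_rejects_nonorthonormal(self):
        with pytest.raises(ValueError, match="orthonormal"):
            Subspace(np.array([[1.0, 1.0], [0.0, 0.0]]), np.array([2.0, 1.0]))

    def test_rejects_increasing_eigenvalues(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            Subspace(np.eye(2), np.array([1.0, 2.0]))


class TestCentralizedPCA:
    def test_diagonal_covariance(self, small_centered):
        # (1/4)A'A = diag(2, 0.5) by direct eigendecomposition
        sub = centralized_pca(small_centered, 1)
        np.testing.assert_allclose(np.abs(sub.V), [[1.0], [0.0]], atol=1e-12)
        np.testing.assert_allclose(sub.eigenvalues, [2.0], atol=1e-12)

    def test_rank_bound_centered(self):
        # a centered n x d matrix has at most n-1 nonzero eigenvalues
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 10))
        A -= A.mean(axis=0)
        sub = centralized_pca(make_matrix(A), 3)
        assert np.sum(sub.eigenvalues > 1e-20) <= 2

    def test_full_rank_reconstruction_zero(self, small_centered):
        sub = centralized_pca(small_centered, 2)
        assert reconstruction_error(small_centered, sub.V) < 1e-10

    def test_k_too_large_rejected(self, small_centered):
        with pytest.raises(ValueError, match="min"):
            centralized_pca(small_centered, 3)

    def test_eigenvalues_are_sv_squared_over_n(self, planted):
        sub = centralized_pca(planted, 5)
        s = np.linalg.svd(planted.values, compute_uv=False)
        np.testing.assert_allclose(sub.eigenvalues, s[:5] ** 2 / planted.n)


class TestLocalSubspace:
    def test_rank1_row(self):
        summ = local_subspace(make_matrix([[3.0, 0.0, 0.0]]), 1)
        np.testing.assert_allclose(np.abs(summ.V_loc), [[1.0], [0.0], [0.0]])
        np.testing.assert_allclose(summ.singular_values, [3.0])

    def test_k_prime_capped_with_warning(self):
        A = make_matrix(np.random.default_rng(1).normal(size=(4, 9)))
        with pytest.warns(UserWarning, match="truncated"):
            summ = local_subspace(A, 9)
        assert summ.k_prime == 4

    def test_full_rank_reconstruction_identity(self):
        A = make_matrix(np.random.default_rng(2).normal(size=(6, 4)))
        summ = local_subspace(A, 4)
        recon = (summ.V_loc * summ.singular_values**2) @ summ.V_loc.T
        np.testing.assert_allclose(recon, A.values.T @ A.values, atol=1e-8)


class TestMergeProxyCovariance:
    def test_orthogonal_rank1_sites(self):
        s1 = LocalSummary(0, np.array([[1.0], [0.0]]), np.array([3.0]))
        s2 = LocalSummary(1, np.array([[0.0], [1.0]]), np.array([4.0]))
        acc = merge_proxy_covariance([s1, s2])
        np.testing.assert_allclose(acc.M, np.diag([9.0, 16.0]))

    def test_full_rank_equals_summed_gram(self, planted_partition):
        summaries = [
            local_subspace(site, min(site.n, site.d), site=i)
            for i, site in enumerate(planted_partition.sites)
        ]
        acc = merge_proxy_covariance(summaries)
        gram = sum(s.values.T @ s.values for s in planted_partition.sites)
        np.testing.assert_allclose(acc.M, gram, atol=1e-8)

    def test_duplication_linearity(self):
        s1 = LocalSummary(0, np.array([[0.6], [0.8]]), np.array([2.0]))
        one = merge_proxy_covariance([s1]).M
        two = merge_proxy_covariance([s1, s1]).M
        np.testing.assert_allclose(two, 2 * one)

    def test_dimension_mismatch_rejected(self):
        s1 = LocalSummary(0, np.eye(2), np.ones(2))
        s2 = LocalSummary(1, np.eye(3), np.ones(3))
        with pytest.raises(ValueError, match="d="):
            merge_proxy_covariance([s1, s2])


def two_rank1_sites():
    return SitePartition(
        [make_matrix([[3.0, 0.0]]), make_matrix([[0.0, 4.0]], "T")]
    )


class TestPCov:
    def test_orthogonal_rank1_toy(self):
        sub = p_cov(two_rank1_sites(), 1)
        np.testing.assert_allclose(np.abs(sub.V), [[0.0], [1.0]], atol=1e-12)
        np.testing.assert_allclose(sub.eigenvalues, [8.0])  # 16 / n=2

    def test_single_site_equals_centralized(self, planted):
        part = split_by_sizes(planted, [planted.n])
        sub = p_cov(part, 5)
        ref = centralized_pca(planted, 5)
        assert max_pairwise_angle(sub.V, ref.V) <= 1e-6
        np.testing.assert_allclose(sub.eigenvalues, ref.eigenvalues, rtol=1e-8)

    def test_skewed_partition_exact(self, planted, planted_partition):
        sub = p_cov(planted_partition, 5)
        ref = centralized_pca(planted, 5)
        assert max_pairwise_angle(sub.V, ref.V) <= 1e-6

    def test_comm_log(self, planted_partition):
        log = CommLog()
        p_cov(planted_partition, 3, log)
        d, S = planted_partition.d, planted_partition.n_sites
        assert log.total_scalars == S * d * d + S * d * 3
        assert log.num_rounds == 2


class TestApMethods:
    def test_ap_cov_full_rank_equals_p_cov(self, planted, planted_partition):
        ref = centralized_pca(planted, 4)
        with pytest.warns(UserWarning):
            sub = ap_cov(planted_partition, 4, planted.d)
        assert max_pairwise_angle(sub.V, ref.V) <= 1e-6

    def test_ap_rank1_orthogonal_exact(self):
        sub = ap_cov(two_rank1_sites(), 1, 1)
        np.testing.assert_allclose(np.abs(sub.V), [[0.0], [1.0]], atol=1e-12)

    def test_ap_stack_diagonal_toy(self):
        sub = ap_stack(two_rank1_sites(), 1, 1)
        np.testing.assert_allclose(np.abs(sub.V), [[0.0], [1.0]], atol=1e-12)
        np.testing.assert_allclose(sub.eigenvalues, [8.0])

    @pytest.mark.parametrize("k_prime", [2, 4, 8])
    def test_ap_cov_equals_ap_stack(self, planted_partition, k_prime):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            a = ap_cov(planted_partition, 2, k_prime)
            b = ap_stack(planted_partition, 2, k_prime)
        assert max_pairwise_angle(a.V, b.V) <= 1e-6
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, rtol=1e-8)

    def test_k_exceeds_k_prime_rejected(self, planted_partition):
        with pytest.raises(ValueError, match="k'"):
            ap_cov(planted_partition, 5, 3)

    def test_upload_smaller_than_p_cov(self, planted_partition):
        log = CommLog()
        k_prime = 4
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ap_stack(planted_partition, 2, k_prime, log)
        d = planted_partition.d
        uploads = [
            r.scalar_count for r in log.records if r.receiver == AGGREGATOR
        ]
        # per-client upload is d*k' eigenvector scalars + k' singular values
        per_client = d * k_prime + k_prime
        assert sum(uploads) <= planted_partition.n_sites * per_client
        assert per_client < d * d


class TestQrPca:
    def test_single_site_equals_centralized(self, planted):
        part = split_by_sizes(planted, [planted.n])
        sub = qr_pca(part, 5)
        ref = centralized_pca(planted, 5)
        assert max_pairwise_angle(sub.V, ref.V) <= 1e-6

    def test_rank1_toy_hand_qr(self):
        sub = qr_pca(two_rank1_sites(), 1)
        np.testing.assert_allclose(np.abs(sub.V), [[0.0], [1.0]], atol=1e-12)
        np.testing.assert_allclose(sub.eigenvalues, [8.0])

    def test_random_partition_exact(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(50, 20))
        A -= A.mean(axis=0)
        Am = make_matrix(A)
        part = split_by_sizes(Am, [17, 30, 3])
        sub = qr_pca(part, 5)
        ref = centralized_pca(Am, 5)
        assert max_pairwise_angle(sub.V, ref.V) <= 1e-6

    def test_factors_upper_triangular_and_ragged(self, planted_partition):
        factors = qr_merge(planted_partition)
        d = planted_partition.d
        for R, site in zip(factors.R_sites, planted_partition.sites):
            assert R.shape == (min(site.n, d), d)
            assert np.max(np.abs(np.tril(R, -1))) <= 1e-10
        assert factors.R_stacked.shape[0] == sum(
            min(s.n, d) for s in planted_partition.sites
        )
        assert np.max(np.abs(np.tril(factors.R_merged, -1))) <= 1e-10


class TestCrossAlgorithmProperties:
    def test_exactness_randomized(self):
        """p_cov and qr_pca match the centralized oracle on every simple
        eigenvector across randomized trials (subset of the 100-trial
        acceptance sweep for speed)."""
        rng = np.random.default_rng(2024)
        for trial in range(25):
            n = int(rng.integers(20, 60))
            d = int(rng.integers(5, 25))
            spec = SpectrumSpec(
                n, d,
                sorted(rng.uniform(1, 10, size=min(4, d)), reverse=True),
                0.05, seed=int(rng.integers(1e6)),
            )
            A = generate_lowrank(spec)
            S = int(rng.integers(1, 6))
            sizes = [1] * S
            remaining = n - S
            for i in range(S - 1):
                take = int(rng.integers(0, remaining + 1))
                sizes[i] += take
                remaining -= take
            sizes[-1] += remaining
            part = split_by_sizes(A, sizes)
            k = min(3, min(n, d))
            ref = centralized_pca(A, k)
            # simple-spectrum gate, including the gap at the subspace edge
            ext = centralized_pca(A, min(k + 1, min(n, d) - 1) or k)
            gaps = np.abs(np.diff(ext.eigenvalues)) / ext.eigenvalues[0]
            if np.any(gaps < 1e-4):
                continue  # near-degenerate: per-vector comparison undefined
            for algo in (p_cov, qr_pca):
                sub = algo(part, k)
                assert max_pairwise_angle(sub.V, ref.V) <= 1e-6, algo.__name__

    def test_site_order_invariance(self, planted, planted_partition):
        reordered = SitePartition(list(reversed(planted_partition.sites)))
        for algo in (lambda p: p_cov(p, 3), lambda p: qr_pca(p, 3)):
            a, b = algo(planted_partition), algo(reordered)
            np.testing.assert_allclose(a.V, b.V, atol=1e-10)
            np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)

    def test_ap_limit_recovery(self, planted, planted_partition):
        """ap_cov approaches the centralized answer as k' grows to full
        local rank."""
        ref = centralized_pca(planted, 2)
        import warnings

        angles = []
        for k_prime in (2, 5, 30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                sub = ap_cov(planted_partition, 2, k_prime)
            angles.append(max_pairwise_angle(sub.V, ref.V))
        assert angles[-1] <= 1e-6
        assert angles[-1] <= angles[0] + 1e-12

    def test_eigenvalue_scale_exact_methods(self, planted, planted_partition):
        ref = centralized_pca(planted, 4)
        for algo in (p_cov, qr_pca):
            sub = algo(planted_partition, 4)
            np.testing.assert_allclose(
                sub.eigenvalues, ref.eigenvalues, rtol=1e-8
            )


class TestDataAccessBoundary:
    """The aggregator must only see logged payloads, never raw site rows."""

    def test_aggregator_ops_take_payloads_only(self):
        from fedpca.pca_algorithms import merge_proxy_covariance
        from fedpca.subspace_iteration import aggregate_round

        for fn in (merge_proxy_covariance, aggregate_round):
            params = inspect.signature(fn).parameters
            assert "partition" not in params
            assert all(
                "SitePartition" not in str(p.annotation)
                and "DataMatrix" not in str(p.annotation)
                for p in params.values()
            )

    def test_raw_access_confined_to_client_functions(self, planted_partition, monkeypatch):
        """p_cov touches each site's raw rows exactly once, inside the
        client-scoped gram builder."""
        import fedpca.pca_algorithms as mod

        calls = []
        original = mod._client_gram

        def spy(A_s):
            calls.append(id(A_s))
            return original(A_s)

        monkeypatch.setattr(mod, "_client_gram", spy)
        p_cov(planted_partition, 2)
        assert len(calls) == planted_partition.n_sites
        assert len(set(calls)) == planted_partition.n_sites
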