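"""Group decomposition: concatenation bookkeeping, PCA retention rule,
fixed-point ICA recovery and back-reconstruction."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from conflictstop.epochs import EpochsSet, N_CHANNELS
from conflictstop.gica import back_reconstruct, concatenate, fit_group_ica, pca_reduce


def _epochs_from_arrays(arrays):
    data = {f"sub-{i + 1:02d}": {"congruent": a, "incongruent": a.copy()}
            for i, a in enumerate(arrays)}
    n_samp = arrays[0].shape[2]
    return EpochsSet(data=data, times=np.arange(n_samp, dtype=float),
                     channels=[f"E{i}" for i in range(arrays[0].shape[1])])


class TestConcatenate:
    def test_column_count(self):
        rng = np.random.default_rng(0)
        ep = _epochs_from_arrays([rng.normal(size=(3, N_CHANNELS, 307))] * 2)
        X, blocks, _ = concatenate(ep, "congruent")
        assert X.shape == (N_CHANNELS, 1842)

    def test_single_subject_identity(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, N_CHANNELS, 50))
        ep = _epochs_from_arrays([arr])
        X, _, means = concatenate(ep, "congruent")
        manual = arr.transpose(1, 0, 2).reshape(N_CHANNELS, -1)
        assert np.allclose(X, manual - manual.mean(axis=1, keepdims=True))
        assert np.allclose(X.mean(axis=1), 0.0)

    def test_ragged_trial_counts(self):
        rng = np.random.default_rng(2)
        arrays = [rng.normal(size=(n, N_CHANNELS, 31)) for n in (2, 5, 3)]
        data = {f"sub-{i:02d}": {"congruent": a} for i, a in enumerate(arrays)}
        ep = EpochsSet(data=data, times=np.arange(31.0),
                       channels=[f"E{i}" for i in range(N_CHANNELS)])
        X, blocks, _ = concatenate(ep, "congruent")
        assert X.shape[1] == sum(n * 31 for n in (2, 5, 3))
        for sub, (start, stop, n_trials) in blocks.items():
            assert stop - start == n_trials * 31

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        data = {
            "sub-01": {"congruent": rng.normal(size=(2, N_CHANNELS, 10))},
            "sub-02": {"congruent": rng.normal(size=(2, 30, 10))},
        }
        ep = EpochsSet(data=data, times=np.arange(10.0),
                       channels=[f"E{i}" for i in range(N_CHANNELS)])
        with pytest.raises(ValueError, match="channels"):
            concatenate(ep, "congruent")


class TestPCAReduce:
    def test_exact_low_rank(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(N_CHANNELS, 3))
        X = A @ rng.normal(size=(3, 4000))
        X -= X.mean(axis=1, keepdims=True)
        Y, eig, K = pca_reduce(X, retention=0.98, k_max=20)
        assert Y.shape[0] == 3
        # whitened scores have unit variance
        assert np.allclose((Y**2).mean(axis=1), 1.0, atol=1e-6)

    def test_flat_spectrum_hits_cap(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(N_CHANNELS, 20000))
        X -= X.mean(axis=1, keepdims=True)
        # flat spectrum: 98% of the eigenvalue mass needs ~59 of 60 dims
        Y, _, _ = pca_reduce(X, retention=0.98, k_max=20)
        assert Y.shape[0] == 20

    def test_full_retention_full_rank(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(N_CHANNELS, 20000))
        X -= X.mean(axis=1, keepdims=True)
        Y, _, _ = pca_reduce(X, retention=1.0, k_max=60)
        assert Y.shape[0] == 60

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError, match="retention"):
            pca_reduce(np.zeros((3, 10)), retention=1.5)


class TestGroupICA:
    def _laplacian_instance(self, seed=0, n=30000):
        rng = np.random.default_rng(seed)
        A_true = rng.normal(size=(N_CHANNELS, 2))
        A_true /= np.linalg.norm(A_true, axis=0)
        S = rng.laplace(size=(2, n))
        X = A_true @ S
        X -= X.mean(axis=1, keepdims=True)
        return A_true, X

    def test_known_mixing_recovered(self):
        A_true, X = self._laplacian_instance()
        Y, eig, K = pca_reduce(X, retention=0.98, k_max=20)
        decomp = fit_group_ica(Y, K, eig, np.zeros(N_CHANNELS), seed=0)
        R = np.abs(A_true.T @ decomp.A)
        ri, ci = linear_sum_assignment(-R)
        assert (R[ri, ci] > 0.99).all()

    def test_WA_identity_on_retained_subspace(self, small_decomps):
        for d in small_decomps:
            assert np.allclose(d.W @ d.A, np.eye(d.n_retained), atol=1e-8)

    def test_topographies_unit_norm_sign_fixed(self, small_decomps):
        for d in small_decomps:
            norms = np.linalg.norm(d.A, axis=0)
            assert np.allclose(norms, 1.0)
            peak = d.A[np.argmax(np.abs(d.A), axis=0), np.arange(d.A.shape[1])]
            assert (peak > 0).all()

    def test_same_seed_identical(self):
        _, X = self._laplacian_instance(seed=3, n=5000)
        Y, eig, K = pca_reduce(X)
        d1 = fit_group_ica(Y, K, eig, np.zeros(N_CHANNELS), seed=9)
        d2 = fit_group_ica(Y, K, eig, np.zeros(N_CHANNELS), seed=9)
        assert np.array_equal(d1.W, d2.W)

    def test_ground_truth_recovery(self, small_decomps, true_topographies):
        # with the default 4-source configuration both condition fits
        # recover every topography nearly perfectly after optimal pairing
        for d in small_decomps:
            R = np.abs(true_topographies @ d.A)
            ri, ci = linear_sum_assignment(-R)
            assert R[ri, ci].mean() > 0.95


class TestBackReconstruct:
    def test_known_activations_recovered(self, small_decomps):
        d = small_decomps[0]
        rng = np.random.default_rng(0)
        acts = rng.normal(size=(3, d.n_retained, 20))
        X_s = np.einsum("ck,tks->tcs", d.A, acts) + d.channel_means[None, :, None]
        C = back_reconstruct(d, X_s)
        assert np.allclose(C, acts, atol=1e-8)

    def test_zero_input_zero_activations(self, small_decomps):
        d = small_decomps[0]
        X_s = np.zeros((2, N_CHANNELS, 10)) + d.channel_means[None, :, None]
        assert np.allclose(back_reconstruct(d, X_s), 0.0)

    def test_exact_projection_identity(self, small_decomps, small_epochs):
        # C_s = W X_s exactly, for the subject data the decomposition saw
        d = small_decomps[0]
        arr = small_epochs.get("sub-01", "congruent")
        C = d.subject_activations["sub-01"]
        centered = arr - d.channel_means[None, :, None]
        assert np.allclose(C, np.einsum("kc,tcs->tks", d.W, centered), atol=1e-10)

    def test_backprojected_component_rank_one(self, small_decomps):
        d = small_decomps[0]
        C = d.subject_activations["sub-01"]
        back = d.A[:, 2][None, :, None] * C[:, 2, :][:, None, :]
        s = np.linalg.svd(back[0], compute_uv=False)
        assert s[1] < 1e-10 * max(s[0], 1e-30)

    def test_reconstruction_captures_retained_variance(self, small_decomps, small_epochs):
        d = small_decomps[0]
        arr = small_epochs.get("sub-02", "congruent")
        centered = arr - d.channel_means[None, :, None]
        C = back_reconstruct(d, arr)
        recon = np.einsum("ck,tks->tcs", d.A, C)
        resid = ((centered - recon) ** 2).sum() / (centered**2).sum()
        assert resid < 0.05

    def test_channel_mismatch_rejected(self, small_decomps):
        with pytest.raises(ValueError, match="incompatible"):
            back_reconstruct(small_decomps[0], np.zeros((2, 10, 5)))


def test_decomposition_hdf5_roundtrip(small_decomps, tmp_path):
    from conflictstop.gica import load_decomposition, save_decomposition

    d = small_decomps[0]
    path = tmp_path / "decomp.h5"
    save_decomposition(path, d)
    loaded = load_decomposition(path)
    assert np.allclose(loaded.W, d.W)
    assert np.allclose(loaded.A, d.A)
    assert loaded.n_retained == d.n_retained
    assert set(loaded.subject_activations) == set(d.subject_activations)
    assert np.allclose(
        loaded.subject_activations["sub-01"], d.subject_activations["sub-01"], atol=1e-3
    )
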