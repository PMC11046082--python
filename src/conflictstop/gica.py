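"""Group independent-component decomposition of stop-trial epochs.

The group model is ``C = W X``: epochs from all subjects are concatenated
along time into one channels-by-samples matrix ``X``, reduced by PCA
(retaining a configurable eigenvalue fraction, capped at ``k_max``),
unmixed with fixed-point ICA, and back-reconstructed per subject by
applying the shared demixing matrix ``W`` to each subject's own data.
Channels are the mixed variables, so the columns of the mixing matrix
``A = pinv(W)`` are spatial topographies shared across the group while
the activations ``C_s = W X_s`` are per-subject time courses.

Congruent and incongruent data are decomposed separately; matching the
two sets of topographies is the job of :mod:`conflictstop.corrmap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.decomposition import FastICA

from .epochs import EpochsSet

__all__ = [
    "GroupDecomposition",
    "concatenate",
    "pca_reduce",
    "fit_group_ica",
    "back_reconstruct",
    "decompose_condition",
    "save_decomposition",
    "load_decomposition",
]


@dataclass
class GroupDecomposition:
    """Result of one per-condition group decomposition.

    ``W`` (components x channels) maps centered channel data to component
    activations; ``A`` (channels x components) holds the unit-norm,
    sign-fixed topographies.  ``channel_means`` are the per-channel means
    removed before the fit and must be subtracted from any new data before
    applying ``W``.
    """

    eigenvalues: np.ndarray
    n_retained: int
    W: np.ndarray
    A: np.ndarray
    channel_means: np.ndarray
    condition: str = ""
    seed: int | None = None
    retention: float = 0.98
    subject_activations: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def concatenate(
    epochs: EpochsSet, condition: str
) -> tuple[np.ndarray, dict[str, tuple[int, int, int]], np.ndarray]:
    """Concatenate one condition's epochs across subjects.

    Returns ``(X, blocks, means)`` where ``X`` is channels x (sum over
    subjects of trials*samples) with the per-channel grand mean removed,
    ``blocks[subject] = (start_column, stop_column, n_trials)`` records
    each subject's column block ordered by (subject, trial, sample), and
    ``means`` holds the removed per-channel means.
    """
    n_ch = epochs.n_channels
    parts, blocks = [], {}
    start = 0
    for sub in epochs.subjects:
        arr = epochs.get(sub, condition)
        if arr.shape[1] != n_ch:
            raise ValueError(f"subject {sub} has {arr.shape[1]} channels, expected {n_ch}")
        n_trials, _, n_samp = arr.shape
        # (trials, ch, samples) -> (ch, trials*samples), trial-major columns
        parts.append(arr.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp))
        blocks[sub] = (start, start + n_trials * n_samp, n_trials)
        start += n_trials * n_samp
    X = np.concatenate(parts, axis=1)
    means = X.mean(axis=1, keepdims=True)
    return X - means, blocks, means.ravel()


def pca_reduce(
    X: np.ndarray, retention: float = 0.98, k_max: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-reduce and whiten centered channel data.

    ``n_retained`` is the smaller of ``k_max`` and the smallest k whose
    cumulative eigenvalue fraction reaches ``retention``.  Returns
    ``(Y, eigenvalues, K)`` with whitened scores ``Y = K X`` (k x samples,
    unit variance per row) and the full eigenvalue spectrum.
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError(f"retention must be in (0, 1], got {retention}")
    n = X.shape[1]
    cov = (X @ X.T) / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    frac = np.cumsum(eigvals) / eigvals.sum()
    k_needed = int(np.searchsorted(frac, retention - 1e-12) + 1)
    k = min(k_max, k_needed)
    nonzero = eigvals[:k] > 1e-12 * eigvals[0]
    if not nonzero.all():
        k = int(nonzero.sum())
    K = eigvecs[:, :k].T / np.sqrt(eigvals[:k])[:, None]
    return K @ X, eigvals, K


def fit_group_ica(
    Y: np.ndarray,
    K: np.ndarray,
    eigenvalues: np.ndarray,
    channel_means: np.ndarray,
    seed: int = 0,
    condition: str = "",
    retention: float = 0.98,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> GroupDecomposition:
    """Fixed-point ICA on whitened scores; returns the group decomposition.

    Uses the symmetric (parallel) FastICA fixed-point iteration with the
    tanh (logcosh) contrast.  The ICA unmixing is composed with the PCA
    projection so that ``W`` acts on raw (centered) channel data.
    Topographies are normalized to unit Euclidean norm with a positive
    maximum-magnitude entry; the activations absorb scale and sign.
    """
    ica = FastICA(
        algorithm="parallel",
        fun="logcosh",
        whiten=False,
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    )
    ica.fit(Y.T)
    if ica.n_iter_ >= max_iter:
        raise RuntimeError(
            f"fixed-point ICA did not converge within {max_iter} iterations (seed {seed})"
        )
    W = ica.components_ @ K  # components x channels, acts on centered data
    A = np.linalg.pinv(W)  # channels x components
    # resolve sign/scale indeterminacy: unit-norm topographies, positive peak
    norms = np.linalg.norm(A, axis=0)
    signs = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    A = A * (signs / norms)
    W = W * (norms * signs)[:, None]
    return GroupDecomposition(
        eigenvalues=np.asarray(eigenvalues),
        n_retained=W.shape[0],
        W=W,
        A=A,
        channel_means=np.asarray(channel_means).ravel(),
        condition=condition,
        seed=seed,
        retention=retention,
    )


def back_reconstruct(
    decomp: GroupDecomposition, subject_data: np.ndarray
) -> np.ndarray:
    """Project one subject's epochs onto the group components.

    ``subject_data`` is (trials, channels, samples) in the raw channel
    space; the group per-channel means are removed and ``C_s = W X_s`` is
    returned reshaped to (trials, components, samples).
    """
    arr = np.asarray(subject_data, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[1] != decomp.n_channels:
        raise ValueError(
            f"subject data shape {arr.shape} incompatible with {decomp.n_channels} channels"
        )
    centered = arr - decomp.channel_means[None, :, None]
    return np.einsum("kc,tcs->tks", decomp.W, centered)


def decompose_condition(
    epochs: EpochsSet,
    condition: str,
    seed: int = 0,
    retention: float = 0.98,
    k_max: int = 20,
) -> GroupDecomposition:
    """Full per-condition pipeline: concatenate, PCA-whiten, fixed-point
    ICA, and back-reconstruct every subject's activations."""
    X, _blocks, raw_means = concatenate(epochs, condition)
    Y, eigvals, K = pca_reduce(X, retention=retention, k_max=k_max)
    decomp = fit_group_ica(
        Y, K, eigvals, raw_means, seed=seed, condition=condition, retention=retention
    )
    for sub in epochs.subjects:
        acts = back_reconstruct(decomp, epochs.get(sub, condition))
        decomp.subject_activations[sub] = acts
    return decomp


def save_decomposition(path, decomp: GroupDecomposition) -> None:
    """HDF5 layout: /eigenvalues, /W, /A, /channel_means,
    /sub-<ID>/activations, with provenance attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eigenvalues", data=decomp.eigenvalues)
        f.create_dataset("W", data=decomp.W)
        f.create_dataset("A", data=decomp.A)
        f.create_dataset("channel_means", data=decomp.channel_means)
        f.attrs["n_retained"] = decomp.n_retained
        f.attrs["condition"] = decomp.condition
        f.attrs["retention"] = decomp.retention
        if decomp.seed is not None:
            f.attrs["seed"] = int(decomp.seed)
        for sub, acts in decomp.subject_activations.items():
            f.create_group(sub).create_dataset("activations", data=np.asarray(acts, np.float32))


def load_decomposition(path) -> GroupDecomposition:
    with h5py.File(path, "r") as f:
        decomp = GroupDecomposition(
            eigenvalues=np.asarray(f["eigenvalues"]),
            n_retained=int(f.attrs["n_retained"]),
            W=np.asarray(f["W"]),
            A=np.asarray(f["A"]),
            channel_means=np.asarray(f["channel_means"]),
            condition=str(f.attrs.get("condition", "")),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            retention=float(f.attrs.get("retention", 0.98)),
        )
        for sub in f:
            if isinstance(f[sub], h5py.Group):
                decomp.subject_activations[sub] = np.asarray(f[sub]["activations"], np.float64)
    return decomp
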