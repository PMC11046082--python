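"""Per-subject time-resolved decoding of congruent vs. incongruent stop trials.

For every matched component pair, each condition's trials are
back-projected to the 60-channel sensor space (``A_k x C_{s,k}``), giving
rank-1 channel data whose spatial pattern is the component topography.
A linear maximum-margin classifier (SVM, C = 1) is trained per time
sample on the 60 channel amplitudes under stratified k-fold
cross-validation with seeded under-sampling of the majority class;
performance is the area under the ROC curve (AUC) of the decision
values, averaged across test folds.  Temporal generalization trains at
one sample and evaluates at every other sample within the same folds, so
the diagonal of the generalization matrix reproduces the time course
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import sklearn
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .corrmap import ICPair
from .epochs import epoch_times
from .gica import GroupDecomposition

__all__ = [
    "DecodingResult",
    "backproject_pair",
    "decode_timecourse",
    "temporal_generalization",
    "decode_pair_group",
    "save_decoding",
    "load_decoding",
]


@dataclass
class DecodingResult:
    """Cross-validated decoding of one subject on one component pair."""

    auc_diag: np.ndarray
    auc_tg: np.ndarray | None
    n_trials_used: int
    folds: np.ndarray
    seed: int


def backproject_pair(
    pair: ICPair,
    decomp_congruent: GroupDecomposition,
    decomp_incongruent: GroupDecomposition,
    subject: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project one component pair to channel space for one subject.

    Returns ``(congruent, incongruent)`` tensors of shape
    (trials, channels, samples), each ``A_k x C_{s,k}`` for the pair's
    component in the respective decomposition.  When ``sign_flip`` is
    set, the incongruent topography and activation are both negated to
    align the spatial patterns; the back-projected product is unchanged
    by this, which is exactly why the channel-space data of a matched
    pair are directly comparable.
    """
    out = []
    for decomp, idx, flip in (
        (decomp_congruent, pair.index_congruent, False),
        (decomp_incongruent, pair.index_incongruent, pair.sign_flip),
    ):
        if subject not in decomp.subject_activations:
            raise KeyError(f"subject {subject!r} missing from {decomp.condition or 'decomposition'}")
        acts = decomp.subject_activations[subject][:, idx, :]  # trials x samples
        topo = decomp.A[:, idx].copy()
        if flip:
            topo, acts = -topo, -acts
        out.append(topo[None, :, None] * acts[:, None, :])
    return out[0], out[1]


def _balance(
    X0: np.ndarray, X1: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Under-sample the majority class to the minority count (seeded)."""
    n = min(len(X0), len(X1))
    keep0 = np.sort(rng.choice(len(X0), size=n, replace=False))
    keep1 = np.sort(rng.choice(len(X1), size=n, replace=False))
    X = np.concatenate([X0[keep0], X1[keep1]])
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    return X, y


def _auc_rows(scores: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Rank-based AUC of decision values, one per row of ``scores``
    (rows x observations); equivalent to the Mann-Whitney statistic."""
    n1 = int(pos.sum())
    n0 = pos.size - n1
    ranks = rankdata(scores, axis=1)
    return (ranks[:, pos].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def _cv_decode(
    cong: np.ndarray,
    incong: np.ndarray,
    n_folds: int,
    seed: int,
    generalize: bool,
) -> DecodingResult:
    cong = np.asarray(cong, np.float64)
    incong = np.asarray(incong, np.float64)
    n_min = min(len(cong), len(incong))
    if n_min < n_folds:
        raise ValueError(
            f"only {n_min} trials in the smaller class but {n_folds} folds requested; "
            "reduce n_folds"
        )
    rng = np.random.default_rng(seed)
    X, y = _balance(cong, incong, rng)
    n_times = X.shape[2]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    fold_of = np.empty(len(y), int)
    auc_diag = np.zeros((n_folds, n_times))
    auc_tg = np.zeros((n_folds, n_times, n_times)) if generalize else None
    with sklearn.config_context(assume_finite=True):
        for f, (tr, te) in enumerate(skf.split(X[:, :, 0], y)):
            fold_of[te] = f
            # per-time, per-channel standardization from training statistics
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = np.ascontiguousarray(((X[te] - mu) / sd).transpose(2, 0, 1))
            pos = y[te] == 1
            ytr = y[tr]
            for t in range(n_times):
                clf = LinearSVC(C=1.0, dual=False)
                clf.fit(Xtr[:, :, t], ytr)
                w, b = clf.coef_.ravel(), clf.intercept_[0]
                if generalize:
                    scores = Xte @ w + b  # (n_times, n_test)
                    auc_tg[f, t] = _auc_rows(scores, pos)
                    auc_diag[f, t] = auc_tg[f, t, t]
                else:
                    auc_diag[f, t] = _auc_rows((Xte[t] @ w + b)[None, :], pos)[0]
    return DecodingResult(
        auc_diag=auc_diag.mean(axis=0),
        auc_tg=auc_tg.mean(axis=0) if generalize else None,
        n_trials_used=n_min,
        folds=fold_of,
        seed=seed,
    )


def decode_timecourse(
    cong: np.ndarray, incong: np.ndarray, n_folds: int = 5, seed: int = 0
) -> DecodingResult:
    """AUC(t) for congruent vs. incongruent trials (trials x channels x
    samples per condition)."""
    return _cv_decode(cong, incong, n_folds, seed, generalize=False)


def temporal_generalization(
    cong: np.ndarray, incong: np.ndarray, n_folds: int = 5, seed: int = 0
) -> DecodingResult:
    """AUC(t_train, t_test): train at each sample, test at every sample
    within the same cross-validation split.  ``auc_tg[i, j]`` is training
    time i, testing time j; its diagonal equals the plain time course for
    the same seed and folds."""
    return _cv_decode(cong, incong, n_folds, seed, generalize=True)


def decode_pair_group(
    pairs: list[ICPair],
    decomp_congruent: GroupDecomposition,
    decomp_incongruent: GroupDecomposition,
    n_folds: int = 5,
    seed: int = 0,
    generalize: bool = True,
) -> dict[int, dict[str, DecodingResult]]:
    """Decode every subject on every matched pair.

    Returns ``results[pair_index][subject]``; the per-run seed is derived
    deterministically from ``seed``, the pair index and the subject order.
    """
    subjects = sorted(decomp_congruent.subject_activations)
    results: dict[int, dict[str, DecodingResult]] = {}
    for k, pair in enumerate(pairs):
        results[k] = {}
        for i, sub in enumerate(subjects):
            cong, incong = backproject_pair(pair, decomp_congruent, decomp_incongruent, sub)
            run_seed = int(np.random.SeedSequence([seed, k, i]).generate_state(1)[0] % (2**31))
            results[k][sub] = _cv_decode(cong, incong, n_folds, run_seed, generalize)
    return results


def save_decoding(path, results: dict[int, dict[str, DecodingResult]]) -> None:
    """HDF5 layout: /pair-<K>/sub-<ID>/{auc_diag, auc_tg}, with /times."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=epoch_times())
        for k, subs in results.items():
            g = f.create_group(f"pair-{k + 1}")
            for sub, res in subs.items():
                gs = g.create_group(sub)
                gs.create_dataset("auc_diag", data=res.auc_diag)
                if res.auc_tg is not None:
                    gs.create_dataset("auc_tg", data=np.asarray(res.auc_tg, np.float32))
                gs.attrs["seed"] = res.seed
                gs.attrs["n_trials_used"] = res.n_trials_used


def load_decoding(path) -> dict[int, dict[str, DecodingResult]]:
    results: dict[int, dict[str, DecodingResult]] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            if not name.startswith("pair-"):
                continue
            k = int(name.split("-")[1]) - 1
            results[k] = {}
            for sub in f[name]:
                gs = f[name][sub]
                results[k][sub] = DecodingResult(
                    auc_diag=np.asarray(gs["auc_diag"]),
                    auc_tg=np.asarray(gs["auc_tg"], np.float64) if "auc_tg" in gs else None,
                    n_trials_used=int(gs.attrs["n_trials_used"]),
                    folds=np.array([]),
                    seed=int(gs.attrs["seed"]),
                )
    return results
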