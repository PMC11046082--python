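"""Match independent components across conditions by topography correlation.

The two per-condition group decompositions come back with arbitrary
component order, scale and sign, so comparable components must be paired
before any cross-condition analysis.  Pairing is done by greedy
correlation clustering of the component topographies ("inverse weights"):
each cluster is seeded from a template component and absorbs all
still-unconsumed components whose absolute Pearson correlation with the
template reaches the match threshold, capped per condition.  The greedy
pass is repeated over many randomized template orders and the most
recurrent clustering is kept, which makes the outcome insensitive to the
arbitrary component order of the ICA fits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gica import GroupDecomposition

__all__ = ["ICPair", "match_components", "save_pairs", "load_pairs"]


@dataclass(frozen=True)
class ICPair:
    """A matched congruent/incongruent component pair.

    ``correlation`` is the signed Pearson correlation between the two
    topographies; ``sign_flip`` is set when it is negative (ICA sign is
    arbitrary, so a perfectly matched pair may correlate at -1).
    """

    index_congruent: int
    index_incongruent: int
    correlation: float
    sign_flip: bool


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of A and columns of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Ac /= np.linalg.norm(Ac, axis=0)
    Bc /= np.linalg.norm(Bc, axis=0)
    return Ac.T @ Bc


def _greedy_clustering(
    R: np.ndarray, order: np.ndarray, threshold: float, max_per_group: int
) -> tuple[tuple[int, int], ...]:
    """One greedy pass over templates; returns the emitted pairs.

    Components are indexed 0..kA-1 (condition A) and kA..kA+kB-1
    (condition B).  A template claims, per condition, the up-to-
    ``max_per_group`` unconsumed components most correlated with it
    (itself included) above threshold; the cluster emits its single best
    cross-condition pair.
    """
    kA, kB = R.shape
    consumed = np.zeros(kA + kB, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for tpl in order:
        if consumed[tpl]:
            continue
        # |r| of every component to the template (r=1 to itself)
        if tpl < kA:
            to_A = np.abs(_self_corr_row(R, tpl, kA, kB, side="A"))
            to_B = np.abs(R[tpl])
        else:
            to_A = np.abs(R[:, tpl - kA])
            to_B = np.abs(_self_corr_row(R, tpl, kA, kB, side="B"))
        members_A = _claim(to_A, consumed[:kA], threshold, max_per_group, force=tpl if tpl < kA else None)
        members_B = _claim(to_B, consumed[kA:], threshold, max_per_group,
                           force=tpl - kA if tpl >= kA else None)
        if not members_A and not members_B:
            continue
        for i in members_A:
            consumed[i] = True
        for j in members_B:
            consumed[kA + j] = True
        if members_A and members_B:
            sub = np.abs(R[np.ix_(members_A, members_B)])
            ia, jb = np.unravel_index(np.argmax(sub), sub.shape)
            i, j = members_A[ia], members_B[jb]
            pairs.append((i, j, float(R[i, j])))
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))
    return tuple((i, j) for i, j, _ in pairs)


def _self_corr_row(R, tpl, kA, kB, side):
    """Within-condition correlations are not available from the
    cross-condition matrix; a template always matches itself (r=1) and is
    assumed distinct from its within-condition siblings (ICA components
    are decorrelated), so the row is 1 at the template and 0 elsewhere."""
    n = kA if side == "A" else kB
    row = np.zeros(n)
    row[tpl if side == "A" else tpl - kA] = 1.0
    return row


def _claim(scores, consumed, threshold, max_per_group, force=None):
    cand = [i for i in np.argsort(scores)[::-1]
            if scores[i] >= threshold and not consumed[i]]
    members = cand[:max_per_group]
    if force is not None and force not in members:
        members = [force] + members[: max_per_group - 1]
    return members


def match_components(
    decomp_A: GroupDecomposition,
    decomp_B: GroupDecomposition,
    threshold: float = 0.85,
    max_per_group: int = 3,
    n_init: int = 40,
    seed: int = 0,
) -> list[ICPair]:
    """Pair components of two decompositions by topography correlation.

    Runs the greedy clustering from ``n_init`` seeded random template
    orders and keeps the most recurrent set of pairs (ties broken by
    higher total absolute correlation, then by lower component indices).
    Returns pairs sorted by descending absolute correlation; emits a
    warning (not an error) when nothing correlates above threshold.
    """
    if decomp_A.n_channels != decomp_B.n_channels:
        raise ValueError("decompositions do not share a channel space")
    R = _corr_matrix(decomp_A.A, decomp_B.A)
    kA, kB = R.shape
    rng = np.random.default_rng(seed)
    counts: dict[tuple, int] = {}
    for _ in range(n_init):
        order = rng.permutation(kA + kB)
        clustering = _greedy_clustering(R, order, threshold, max_per_group)
        counts[clustering] = counts.get(clustering, 0) + 1

    def rank(item):
        clustering, n = item
        total = sum(abs(R[i, j]) for i, j in clustering)
        return (-n, -total, clustering)

    best = min(counts.items(), key=rank)[0]
    if not best:
        warnings.warn(
            f"no component pair correlates above |r| >= {threshold}", stacklevel=2
        )
    return [
        ICPair(
            index_congruent=int(i),
            index_incongruent=int(j),
            correlation=float(R[i, j]),
            sign_flip=bool(R[i, j] < 0),
        )
        for i, j in best
    ]


def save_pairs(path, pairs: list[ICPair]) -> None:
    payload = [
        {"pair_id": k + 1, "idx_congruent": p.index_congruent,
         "idx_incongruent": p.index_incongruent,
         "correlation": p.correlation, "sign_flip": p.sign_flip}
        for k, p in enumerate(pairs)
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_pairs(path) -> list[ICPair]:
    payload = json.loads(Path(path).read_text())
    return [
        ICPair(
            index_congruent=int(d["idx_congruent"]),
            index_incongruent=int(d["idx_incongruent"]),
            correlation=float(d["correlation"]),
            sign_flip=bool(d["sign_flip"]),
        )
        for d in payload
    ]
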