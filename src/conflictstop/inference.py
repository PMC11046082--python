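"""Group-level tests of decoding against chance with cluster correction.

Sample-level statistics are Wilcoxon signed-rank tests of AUC - 0.5
across subjects, standardized to z.  Multiple comparisons over time (or
over the train x test plane of a temporal-generalization matrix) are
corrected by cluster-based permutation: supra-threshold samples are
grouped by adjacency (4-connectivity in 2-D), each cluster's mass is the
sum of its z values, and the observed masses are referred to the
permutation distribution of the maximal cluster mass under random
per-subject sign flips of AUC - 0.5 — the exact exchangeability scheme
for a one-sample test against chance.

Sign flips leave the ranks of |AUC - 0.5| untouched, so the whole
permutation null reduces to sign patterns times a fixed signed-rank
matrix; this makes 2-D permutation runs cheap.  Exact sample-level
p-values (dynamic-programming enumeration of the sign-flip null) are
used for n <= 25 subjects, the normal approximation above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, stats

__all__ = ["Cluster", "ClusterResult", "test_vs_chance", "cluster_permutation"]

CHANCE = 0.5


# ---------------------------------------------------------------------------
# signed-rank machinery (vectorized over samples/pixels)


def _signed_ranks(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column signed ranks and rank variances.

    ``D`` is (n_subjects, n_columns).  Zeros are dropped from the ranking
    (Wilcoxon convention) and contribute neither to the statistic nor to
    its variance.  Returns ``(S, var)`` where column sums of ``S`` give
    the statistic ``W = sum(sign * rank)`` and ``var = sum(rank^2)`` over
    nonzero entries is its exact sign-flip variance (tie-robust).
    """
    absD = np.abs(D)
    zero = absD == 0
    # push zeros below every nonzero value so they occupy the lowest ranks
    masked = np.where(zero, -np.inf, absD)
    ranks = stats.rankdata(masked, axis=0, method="average")
    ranks = ranks - zero.sum(axis=0)[None, :]  # shift out the zero block
    ranks = np.where(zero, 0.0, ranks)
    S = np.sign(D) * ranks
    var = (ranks**2).sum(axis=0)
    return S, var


@lru_cache(maxsize=4096)
def _exact_null_sf(double_ranks: tuple[int, ...]) -> np.ndarray:
    """Survival function of |W| under the exact sign-flip null.

    ``double_ranks`` are the nonzero ranks times 2 (integers even with
    midrank ties).  Returns ``sf`` with ``sf[w] = P(|W*2| >= w)`` indexed
    by doubled statistic value 0..2T.
    """
    total = int(sum(double_ranks))
    # distribution of (W*2 + total)/... : track sum of +r over chosen signs
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:-r] if r > 0 else pmf
        pmf = 0.5 * (pmf + shifted)
    # S+ = sum of positive doubled ranks; W*2 = 2*S+ - total
    w_vals = np.abs(2 * np.arange(total + 1) - total)
    sf = np.zeros(2 * total + 2)
    for val, p in zip(w_vals, pmf):
        sf[val] += p
    return np.cumsum(sf[::-1])[::-1]


def _exact_p(W: float, double_ranks: tuple[int, ...]) -> float:
    sf = _exact_null_sf(double_ranks)
    w = min(int(round(abs(W) * 2)), len(sf) - 1)
    return float(min(1.0, sf[w]))


def _exact_crit(double_ranks: tuple[int, ...], alpha: float) -> float:
    """Smallest |W| whose two-sided exact p is below ``alpha`` (in
    undoubled units); +inf when no attainable value is significant."""
    sf = _exact_null_sf(double_ranks)
    below = np.nonzero(sf < alpha)[0]
    return float(below[0]) / 2.0 if below.size else np.inf


def test_vs_chance(auc: np.ndarray, exact_max_n: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Signed-rank test of AUC against chance, per sample across subjects.

    ``auc`` is (n_subjects, ...); returns ``(z, p)`` of the trailing
    shape.  z is the standardized signed-rank statistic
    ``W / sqrt(sum rank^2)``; p is two-sided, exact for small cohorts.
    Samples where every subject sits exactly at chance yield z = 0,
    p = 1 (degenerate, not an error).
    """
    auc = np.asarray(auc, dtype=np.float64)
    n_sub = auc.shape[0]
    if n_sub < 5:
        raise ValueError(f"need at least 5 subjects, got {n_sub}")
    shape = auc.shape[1:]
    D = (auc - CHANCE).reshape(n_sub, -1)
    S, var = _signed_ranks(D)
    W = S.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, W / np.sqrt(var), 0.0)
    p = np.ones_like(z)
    if n_sub <= exact_max_n:
        for c in range(D.shape[1]):
            if var[c] == 0:
                continue
            dr = tuple(int(round(2 * r)) for r in np.abs(S[:, c]) if r != 0)
            p[c] = _exact_p(W[c], tuple(sorted(dr)))
    else:
        nz = var > 0
        p[nz] = 2.0 * stats.norm.sf(np.abs(z[nz]))
    return z.reshape(shape), p.reshape(shape)


# ---------------------------------------------------------------------------
# cluster permutation


@dataclass
class Cluster:
    """One supra-threshold cluster: member sample indices (1-D) or pixel
    coordinates (2-D), summed z mass, and its permutation p-value."""

    indices: np.ndarray
    mass: float
    p: float

    def extent_1d(self) -> tuple[int, int]:
        return int(self.indices.min()), int(self.indices.max())


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha: float
    n_permutations: int
    z: np.ndarray = field(default_factory=lambda: np.array([]))
    null_max_mass: np.ndarray = field(default_factory=lambda: np.array([]))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _label_clusters(supra: np.ndarray) -> list[np.ndarray]:
    """Connected supra-threshold sets: runs in 1-D, 4-connectivity in 2-D."""
    if supra.ndim == 1:
        labels, n = ndimage.label(supra)
    else:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labels, n = ndimage.label(supra, structure=structure)
    return [np.argwhere(labels == i + 1) for i in range(n)]


_STRUCTURE_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _max_cluster_mass(z: np.ndarray, supra: np.ndarray) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = supra & ((z > 0) if sign > 0 else (z < 0))
        if not mask.any():
            continue
        structure = None if z.ndim == 1 else _STRUCTURE_2D
        labels, n = ndimage.label(mask, structure=structure)
        if n:
            sums = ndimage.sum_labels(z, labels, index=np.arange(1, n + 1))
            best = max(best, float(np.abs(sums).max()))
    return best


def cluster_permutation(
    auc: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    exact_max_n: int = 25,
) -> ClusterResult:
    """Cluster-corrected test of AUC against chance.

    ``auc`` is (n_subjects, n_times) for the decoding time course or
    (n_subjects, n_times, n_times) for the generalization matrix.
    Clusters form where the sample-level two-sided p falls below
    ``alpha_cluster`` (same-sign neighbors only); the cluster mass is the
    summed standardized signed-rank z and its p-value is
    ``(1 + #{null max mass >= observed}) / (1 + n_perm)`` under random
    per-subject sign flips.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives an unstable p-value floor of {1 / (n_perm + 1):.3f}",
            stacklevel=2,
        )
    auc = np.asarray(auc, dtype=np.float64)
    n_sub = auc.shape[0]
    if n_sub < 5:
        raise ValueError(f"need at least 5 subjects, got {n_sub}")
    shape = auc.shape[1:]
    D = (auc - CHANCE).reshape(n_sub, -1)
    S, var = _signed_ranks(D)
    W_obs = S.sum(axis=0)
    sqrtvar = np.sqrt(np.where(var > 0, var, 1.0))
    z_obs = np.where(var > 0, W_obs / sqrtvar, 0.0)

    # per-pixel critical |W| for the cluster-forming threshold
    if n_sub <= exact_max_n:
        crit = np.full(D.shape[1], np.inf)
        cache: dict[tuple, float] = {}
        for c in range(D.shape[1]):
            if var[c] == 0:
                continue
            dr = tuple(sorted(int(round(2 * r)) for r in np.abs(S[:, c]) if r != 0))
            if dr not in cache:
                cache[dr] = _exact_crit(dr, alpha_cluster)
            crit[c] = cache[dr]
    else:
        crit = stats.norm.isf(alpha_cluster / 2.0) * sqrtvar
        crit[var == 0] = np.inf

    supra_obs = np.abs(W_obs) >= crit

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_max = np.empty(n_perm)
    dead = var == 0
    for b in range(n_perm):
        W_b = flips[b] @ S
        z_b = W_b / sqrtvar
        z_b[dead] = 0.0
        supra_b = np.abs(W_b) >= crit
        null_max[b] = _max_cluster_mass(z_b.reshape(shape), supra_b.reshape(shape))

    clusters: list[Cluster] = []
    z_map = z_obs.reshape(shape)
    supra_map = supra_obs.reshape(shape)
    for sign in (1, -1):
        mask = supra_map & ((z_map > 0) if sign > 0 else (z_map < 0))
        if not mask.any():
            continue
        for idx in _label_clusters(mask):
            mass = abs(z_map[tuple(idx.T)].sum())
            p = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
            clusters.append(Cluster(indices=idx.squeeze(-1) if idx.shape[1] == 1 else idx,
                                    mass=float(mass), p=float(p)))
    clusters.sort(key=lambda c: -c.mass)
    return ClusterResult(
        clusters=clusters,
        alpha=alpha_cluster,
        n_permutations=n_perm,
        z=z_map,
        null_max_mass=null_max,
    )


def cluster_report(
    result: ClusterResult, times: np.ndarray, analysis: str = "diag"
) -> list[dict]:
    """JSON-ready cluster summaries with millisecond extents."""
    out = []
    for c in result.clusters:
        if c.indices.ndim == 1:
            lo, hi = c.extent_1d()
            entry = {"start_ms": float(times[lo]), "end_ms": float(times[hi])}
        else:
            (r0, c0), (r1, c1) = c.indices.min(axis=0), c.indices.max(axis=0)
            entry = {
                "train_start_ms": float(times[r0]),
                "train_end_ms": float(times[r1]),
                "test_start_ms": float(times[c0]),
                "test_end_ms": float(times[c1]),
            }
        entry.update({"analysis": analysis, "mass": c.mass, "p": c.p})
        out.append(entry)
    return out
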