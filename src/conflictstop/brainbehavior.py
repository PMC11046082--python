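"""Leave-one-out nonlinear regression from decoding strength to behavior.

For each matched component pair, every subject's decoding AUC averaged
over the pair's significant time window is regressed onto the subject's
congruency effect on SSRT (incongruent minus congruent, ms) with a small
feed-forward neural network (one hidden layer of 5 tanh units, linear
output).  Accuracy is evaluated by leave-one-out cross-validation: each
subject is predicted by a network trained on all others, and the
root-mean-square error over held-out predictions summarizes the pair.
Pairs are compared by paired t-tests on the per-subject squared errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BrainBehaviorResult",
    "mean_auc_in_window",
    "loo_nn_regression",
    "compare_rmse",
    "save_results",
]


@dataclass
class BrainBehaviorResult:
    """LOO regression outcome for one component pair."""

    rmse: float
    rmse_ci: tuple[float, float]
    predictions: np.ndarray
    observed: np.ndarray
    subjects: list[str] = field(default_factory=list)

    @property
    def squared_errors(self) -> np.ndarray:
        return (self.predictions - self.observed) ** 2


def mean_auc_in_window(auc_diag: np.ndarray, window: tuple[int, int]) -> float:
    """Mean AUC over the sample-index window ``[start, stop]`` (inclusive),
    typically the extent of the pair's significant cluster."""
    start, stop = window
    if stop < start:
        raise ValueError(
            f"empty AUC window {window}: the pair has no significant cluster and "
            "should be skipped"
        )
    return float(np.asarray(auc_diag)[start : stop + 1].mean())


N_HIDDEN = 5
WEIGHT_DECAY = 0.5


class _SkipNet:
    """Feed-forward network for scalar-input regression:
    ``f(x) = c0 + c1 x + sum_j v_j tanh(w_j x + b_j)``.

    The tanh hidden layer (5 units) captures nonlinearity; the linear
    bypass ``c0 + c1 x`` lets a purely linear relationship pass through
    unshrunk and keeps extrapolation at the edges of the input range
    linear rather than saturating.  Weight decay is applied to the hidden
    weights only, so an uninformative input collapses the fit toward the
    least-squares line and an exactly linear target is recovered with no
    penalty-induced bias.  Trained full batch by L-BFGS with analytic
    gradients.
    """

    def __init__(self, params: np.ndarray):
        self.params = params

    @staticmethod
    def _unpack(theta):
        w = theta[:N_HIDDEN]
        b = theta[N_HIDDEN : 2 * N_HIDDEN]
        v = theta[2 * N_HIDDEN : 3 * N_HIDDEN]
        c0, c1 = theta[3 * N_HIDDEN], theta[3 * N_HIDDEN + 1]
        return w, b, v, c0, c1

    @classmethod
    def _loss_grad(cls, theta, x, y, alpha):
        w, b, v, c0, c1 = cls._unpack(theta)
        h = np.tanh(np.outer(x, w) + b)  # n x H
        f = c0 + c1 * x + h @ v
        r = f - y
        n = x.size
        loss = 0.5 * np.mean(r**2) + 0.5 * alpha * (w @ w + v @ v)
        dh = (1.0 - h**2) * v  # n x H
        grad = np.empty_like(theta)
        grad[:N_HIDDEN] = (r @ (dh * x[:, None])) / n + alpha * w
        grad[N_HIDDEN : 2 * N_HIDDEN] = (r @ dh) / n
        grad[2 * N_HIDDEN : 3 * N_HIDDEN] = (r @ h) / n + alpha * v
        grad[3 * N_HIDDEN] = r.mean()
        grad[3 * N_HIDDEN + 1] = (r @ x) / n
        return loss, grad

    @classmethod
    def fit(cls, x, y, seed: int, alpha: float = WEIGHT_DECAY, n_restarts: int = 5):
        """Seeded restarts; the parameters with the best training loss win."""
        rng = np.random.default_rng(seed)
        best, best_loss = None, np.inf
        for _ in range(n_restarts):
            theta0 = 0.5 * rng.normal(size=3 * N_HIDDEN + 2)
            res = optimize.minimize(
                cls._loss_grad,
                theta0,
                args=(x, y, alpha),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
            if np.isfinite(res.fun) and res.fun < best_loss:
                best, best_loss = res.x, res.fun
        if best is None:
            raise RuntimeError(f"network training failed in all restarts (seed {seed})")
        return cls(best)

    def predict(self, x: np.ndarray) -> np.ndarray:
        w, b, v, c0, c1 = self._unpack(self.params)
        return c0 + c1 * x + np.tanh(np.outer(x, w) + b) @ v


def _fit_network(x: np.ndarray, y: np.ndarray, seed: int) -> _SkipNet:
    return _SkipNet.fit(x, y, seed)


def loo_nn_regression(
    inputs: np.ndarray,
    targets: np.ndarray,
    seed: int = 0,
    subjects: list[str] | None = None,
    n_bootstrap: int = 1000,
) -> BrainBehaviorResult:
    """Leave-one-out network regression of per-subject scalars.

    ``inputs`` are window-averaged AUCs, ``targets`` the SSRT congruency
    effects in ms, one of each per subject (at least 10 subjects).
    Inputs and targets are standardized with training-fold statistics
    inside every LOO split, so the held-out subject never influences its
    own prediction.  The RMSE confidence interval is a subject-level
    bootstrap (95%, ``n_bootstrap`` resamples).
    """
    x = np.asarray(inputs, dtype=np.float64).ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs and targets must align one-per-subject")
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 subjects for LOO regression, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs and targets must be finite")
    preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        mx, sx = x[tr].mean(), x[tr].std()
        my, sy = y[tr].mean(), y[tr].std()
        sx = sx if sx > 0 else 1.0
        sy = sy if sy > 0 else 1.0
        net = _fit_network((x[tr] - mx) / sx, (y[tr] - my) / sy, seed=seed * 1009 + i)
        preds[i] = net.predict(np.array([(x[i] - mx) / sx]))[0] * sy + my
    errs2 = (preds - y) ** 2
    rmse = float(np.sqrt(errs2.mean()))
    rng = np.random.default_rng(seed)
    boot = np.sqrt(
        errs2[rng.integers(0, n, size=(n_bootstrap, n))].mean(axis=1)
    )
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return BrainBehaviorResult(
        rmse=rmse,
        rmse_ci=ci,
        predictions=preds,
        observed=y,
        subjects=list(subjects) if subjects is not None else [f"sub-{i+1:02d}" for i in range(n)],
    )


def compare_rmse(
    results: dict[int, BrainBehaviorResult],
) -> list[dict]:
    """Pairwise paired t-tests on per-subject squared errors across pairs.

    Returns one entry per unordered pair of component pairs with the t
    statistic and two-sided p.  Identical error vectors are degenerate
    (no variance in the differences) and reported with t = 0, p = 1.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 component pairs to compare RMSEs")
    out = []
    for a, b in combinations(sorted(results), 2):
        ea, eb = results[a].squared_errors, results[b].squared_errors
        if ea.shape != eb.shape:
            raise ValueError("RMSE comparison requires the same subjects in both pairs")
        diffs = ea - eb
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(), 0.0):
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = stats.ttest_rel(ea, eb)
            degenerate = False
        out.append(
            {"pair_a": a, "pair_b": b, "t": float(t), "p": float(p), "degenerate": degenerate}
        )
    return out


def save_results(
    path, results: dict[int, BrainBehaviorResult], comparisons: list[dict]
) -> None:
    payload = {
        "pairs": [
            {
                "pair_id": k + 1,
                "rmse_ms": res.rmse,
                "rmse_ci": list(res.rmse_ci),
                "predictions": [
                    {"subject": s, "predicted": float(p), "observed": float(o)}
                    for s, p, o in zip(res.subjects, res.predictions, res.observed)
                ],
            }
            for k, res in sorted(results.items())
        ],
        "comparisons": comparisons,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
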