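"""Synthetic Simon/stop-signal sessions and stop-trial EEG with known ground truth.

Behavioral sessions follow the independent-race account of stopping: on
every trial a go process and (on stop trials) a stop process race, and a
response is emitted only if the go process finishes before the stop
process plus the stop-signal delay (SSD).  Finishing times are
ex-Gaussian, one parameter set per congruency condition, and the SSD is
staircase-tracked separately per condition so that long-run stopping
probability converges on 0.5.

EEG epochs for stop trials are built from a small number of ground-truth
spatial topographies.  Each source carries a shared event-related
waveform plus a condition effect (incongruent minus congruent) injected
only inside that source's time window; the noise is structured
background EEG plus a white Gaussian floor (see :class:`GroundTruth`).
Because the per-trial data are a sum of outer products ``topography x
activation``, every downstream stage (group ICA, topography matching,
decoding) has an exact known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .epochs import (
    CONDITIONS,
    N_CHANNELS,
    N_SAMPLES,
    EpochsSet,
    default_channel_names,
    epoch_times,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExGauss",
    "RaceParams",
    "TaskDesign",
    "SourceSpec",
    "GroundTruth",
    "default_race_params",
    "default_task_design",
    "default_ground_truth",
    "make_source",
    "generate_session",
    "generate_group_sessions",
    "generate_group_eeg",
    "simulate_epochs",
    "speed_warnings",
]


# ---------------------------------------------------------------------------
# behavioral ground truth


@dataclass(frozen=True)
class ExGauss:
    """Ex-Gaussian distribution (normal + independent exponential), in ms.

    ``sigma`` and ``tau`` may be zero, which degenerates to a shifted
    normal / exponential / constant; the mean is ``mu + tau``.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("ex-Gaussian sigma and tau must be >= 0")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        out = np.full(size, float(self.mu))
        if self.sigma > 0:
            out = out + rng.normal(0.0, self.sigma, size)
        if self.tau > 0:
            out = out + rng.exponential(self.tau, size)
        return out


@dataclass(frozen=True)
class RaceParams:
    """Generative parameters of the go/stop race, one set per congruency.

    ``go`` and ``stop`` map condition name -> finishing-time distribution.
    ``miss_rate`` is the probability that the go process never produces a
    response; ``error_rate`` the probability a response uses the wrong
    effector.
    """

    go: dict[str, ExGauss]
    stop: dict[str, ExGauss]
    miss_rate: float = 0.01
    error_rate: float = 0.02

    def __post_init__(self):
        for p, name in ((self.miss_rate, "miss_rate"), (self.error_rate, "error_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for cond in CONDITIONS:
            if cond not in self.go or cond not in self.stop:
                raise ValueError(f"race parameters missing condition {cond!r}")


def default_race_params() -> RaceParams:
    """Defaults reproducing the study-scale condition means.

    Go finishing times average ~494 ms (congruent) and ~522 ms
    (incongruent), a ~28 ms congruency cost; stop finishing times average
    ~270 vs ~279 ms, a ~9 ms cost.
    """
    return RaceParams(
        go={
            "congruent": ExGauss(400.0, 50.0, 93.7),
            "incongruent": ExGauss(400.0, 50.0, 121.57),
        },
        stop={
            "congruent": ExGauss(220.0, 20.0, 49.86),
            "incongruent": ExGauss(220.0, 20.0, 59.01),
        },
    )


@dataclass(frozen=True)
class TaskDesign:
    """Trial counts and staircase constants of the stop-signal Simon task."""

    n_blocks: int = 9
    go_per_block: int = 80
    stop_per_block: int = 24
    initial_ssd_ms: float = 250.0
    ssd_step_ms: float = 50.0
    ssd_min_ms: float = 50.0
    ssd_max_ms: float = 1000.0
    max_rt_ms: float = 1700.0
    warning_threshold_ms: float = 450.0
    warning_window: int = 50

    def __post_init__(self):
        # each block splits evenly over 2 congruencies x 2 positions
        for n, name in ((self.go_per_block, "go_per_block"), (self.stop_per_block, "stop_per_block")):
            if n <= 0 or n % 4 != 0:
                raise ValueError(
                    f"{name} must be a positive multiple of 4 (congruency x position split), got {n}"
                )
        if not (self.ssd_min_ms <= self.initial_ssd_ms <= self.ssd_max_ms):
            raise ValueError("initial SSD outside the [min, max] SSD bounds")
        if self.ssd_step_ms <= 0:
            raise ValueError("SSD step must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * (self.go_per_block + self.stop_per_block)

    @property
    def n_go(self) -> int:
        return self.n_blocks * self.go_per_block

    @property
    def n_stop(self) -> int:
        return self.n_blocks * self.stop_per_block


def default_task_design() -> TaskDesign:
    """936 trials: 9 blocks of 80 go + 24 stop, evenly split by congruency."""
    return TaskDesign()


LOG_COLUMNS = [
    "subject",
    "block",
    "trial",
    "condition",
    "position",
    "is_stop",
    "ssd_ms",
    "rt_ms",
    "response",
    "outcome",
]


def _block_layout(design: TaskDesign, rng: np.random.Generator):
    """Randomized (is_stop, condition, position) sequence for one block."""
    entries = []
    for is_stop, n in ((0, design.go_per_block), (1, design.stop_per_block)):
        per_cell = n // 4
        for cond in CONDITIONS:
            for pos in ("left", "right"):
                entries.extend([(is_stop, cond, pos)] * per_cell)
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


def generate_session(
    race: RaceParams | None = None,
    design: TaskDesign | None = None,
    seed: int = 0,
    subject: str = "sub-01",
) -> pd.DataFrame:
    """Simulate one full session; returns one row per trial.

    The SSD staircase is tracked separately for congruent and incongruent
    stop trials: +step after a correct rejection, -step after a failed
    stop, clamped to the design bounds.  A response occurs on a stop trial
    iff the go finishing time beats ``SSD + stop finishing time``.
    """
    race = race or default_race_params()
    design = design or default_task_design()
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    ssd = {c: design.initial_ssd_ms for c in CONDITIONS}
    recent_rts: list[float] = []
    n_warnings = 0
    trial_no = 0
    for block in range(1, design.n_blocks + 1):
        for is_stop, cond, pos in _block_layout(design, rng):
            trial_no += 1
            t_go = race.go[cond].sample(rng, ())
            go_finishes = rng.random() >= race.miss_rate and t_go <= design.max_rt_ms
            correct_side = pos if cond == "congruent" else ("left" if pos == "right" else "right")
            if is_stop:
                cur_ssd = ssd[cond]
                t_stop = race.stop[cond].sample(rng, ())
                responded = go_finishes and (t_go < cur_ssd + t_stop)
                if responded:
                    side = correct_side
                    if rng.random() < race.error_rate:
                        side = "left" if side == "right" else "right"
                    rows.append((subject, block, trial_no, cond, pos, 1, cur_ssd,
                                 float(t_go), side, "failed_stop"))
                    recent_rts.append(float(t_go))
                else:
                    rows.append((subject, block, trial_no, cond, pos, 1, cur_ssd,
                                 np.nan, "none", "correct_rejection"))
                step = design.ssd_step_ms if not responded else -design.ssd_step_ms
                ssd[cond] = float(np.clip(cur_ssd + step, design.ssd_min_ms, design.ssd_max_ms))
            else:
                if not go_finishes:
                    rows.append((subject, block, trial_no, cond, pos, 0, np.nan,
                                 np.nan, "none", "miss"))
                else:
                    side = correct_side
                    outcome = "hit"
                    if rng.random() < race.error_rate:
                        side = "left" if side == "right" else "right"
                        outcome = "incorrect"
                    rows.append((subject, block, trial_no, cond, pos, 0, np.nan,
                                 float(t_go), side, outcome))
                    recent_rts.append(float(t_go))
            # speed-up warning: logged only, no effect on the simulated RTs
            if len(recent_rts) >= design.warning_window:
                window = recent_rts[-design.warning_window:]
                if np.mean(window) > design.warning_threshold_ms:
                    n_warnings += 1
    if n_warnings:
        logger.debug("session %s: %d speed-up warning events", subject, n_warnings)
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def generate_group_sessions(
    race: RaceParams | None = None,
    design: TaskDesign | None = None,
    n_subjects: int = 53,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """One simulated session per subject, with per-subject derived seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    return {
        f"sub-{i + 1:02d}": generate_session(race, design, int(seeds[i]), f"sub-{i + 1:02d}")
        for i in range(n_subjects)
    }


def speed_warnings(
    records: pd.DataFrame, window: int = 50, threshold_ms: float = 450.0
) -> list[int]:
    """Trial numbers at which the mean RT of the last ``window`` responded
    trials exceeded ``threshold_ms`` (the speed-up warning events)."""
    rts = records.loc[records["rt_ms"].notna(), ["trial", "rt_ms"]].to_numpy()
    out = []
    for i in range(window - 1, len(rts)):
        if rts[i - window + 1 : i + 1, 1].mean() > threshold_ms:
            out.append(int(rts[i, 0]))
    return out


# ---------------------------------------------------------------------------
# EEG ground truth


@dataclass(frozen=True)
class SourceSpec:
    """One ground-truth EEG source.

    ``topography`` is a unit-norm weight vector over the channels;
    ``baseline_erp`` the condition-shared waveform over the epoch (in
    source-activation units); the condition effect (incongruent minus
    congruent mean activation difference of ``effect_size``) is applied
    only inside ``window_ms``.  With the default sensor-noise scale of 1,
    ``effect_size`` is the standardized discriminability d along the
    topography axis.
    """

    topography: np.ndarray
    window_ms: tuple[float, float]
    effect_size: float
    baseline_erp: np.ndarray

    def __post_init__(self):
        topo = np.asarray(self.topography, dtype=np.float64)
        if not np.isclose(np.linalg.norm(topo), 1.0, atol=1e-8):
            raise ValueError("source topography must have unit Euclidean norm")
        times = epoch_times()
        lo, hi = self.window_ms
        if lo >= hi or lo < times[0] or hi > times[-1] + (1000.0 / 256.0):
            raise ValueError(f"effect window {self.window_ms} outside the epoch bounds")
        if np.asarray(self.baseline_erp).shape != (N_SAMPLES,):
            raise ValueError(f"baseline_erp must have {N_SAMPLES} samples")

    def window_mask(self, times: np.ndarray | None = None) -> np.ndarray:
        times = epoch_times() if times is None else times
        lo, hi = self.window_ms
        return (times >= lo) & (times <= hi)


def make_source(
    topography: np.ndarray,
    window_ms: tuple[float, float],
    effect_size: float,
    baseline_erp: np.ndarray | None = None,
) -> SourceSpec:
    """Build a :class:`SourceSpec`, normalizing the topography."""
    topo = np.asarray(topography, dtype=np.float64)
    norm = np.linalg.norm(topo)
    if norm == 0:
        raise ValueError("topography must be nonzero")
    if baseline_erp is None:
        baseline_erp = np.zeros(N_SAMPLES)
    return SourceSpec(topo / norm, tuple(window_ms), float(effect_size), np.asarray(baseline_erp, float))


@dataclass(frozen=True)
class GroundTruth:
    """Complete generative configuration of the group EEG simulation.

    The sensor noise has two parts, both scaled by ``noise_sd``: a white
    Gaussian floor of standard deviation ``noise_sd`` on every channel,
    and a structured "background EEG" built from ``n_background`` strong,
    spatially smooth sources with super-Gaussian (Laplacian) activations
    and geometrically decaying gains.  The background topographies are
    constructed orthogonal to the signal topographies (so the trialwise
    noise variance along each signal axis is exactly ``noise_sd**2``,
    keeping closed-form decoding oracles exact) and are drawn separately
    per condition, emulating the condition-varying residual structure
    that leaves only the genuine components matchable across conditions.
    The decaying background spectrum is also what makes the eigenvalue
    retention rule land near 20 retained dimensions, as in real scalp
    recordings.
    """

    race: RaceParams
    sources: tuple[SourceSpec, ...]
    n_subjects: int = 53
    noise_sd: float = 1.0
    subject_jitter: float = 0.05
    seed: int = 0
    n_background: int = 16
    background_var: float = 1900.0
    background_decay: float = 0.8

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_background < 0 or self.n_background > N_CHANNELS - len(self.sources):
            raise ValueError("n_background must fit in the channel space with the sources")

    def background_gains(self) -> np.ndarray:
        """Per-background-source standard deviations (units of noise_sd)."""
        if self.n_background == 0:
            return np.zeros(0)
        rho = self.background_decay
        weights = rho ** np.arange(self.n_background)
        var = self.background_var * weights / weights.sum()
        return self.noise_sd * np.sqrt(var)


def _smooth_random_topography(rng: np.random.Generator, smooth: float = 2.0) -> np.ndarray:
    """Spatially smooth unit-norm random pattern over the channel index."""
    raw = rng.normal(size=N_CHANNELS)
    idx = np.arange(N_CHANNELS)
    kernel = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / smooth) ** 2)
    topo = kernel @ raw
    return topo / np.linalg.norm(topo)


def _erp_bump(
    center_ms: float, width_ms: float, amplitude: float, freq_hz: float = 0.0
) -> np.ndarray:
    """Gabor-like waveform: Gaussian envelope times an optional carrier."""
    t = epoch_times()
    env = np.exp(-0.5 * ((t - center_ms) / width_ms) ** 2)
    if freq_hz > 0:
        env = env * np.cos(2 * np.pi * freq_hz * (t - center_ms) / 1000.0)
    return amplitude * env


def _orthogonalized_waveforms(raw: np.ndarray, target_var: float) -> np.ndarray:
    """Gram-Schmidt the source waveforms (rows) so their time courses are
    exactly uncorrelated over the epoch, rescaled to a common variance.
    Temporally correlated sources would violate the independence the
    group decomposition relies on."""
    out = raw.astype(np.float64).copy()
    for i in range(len(out)):
        for j in range(i):
            out[i] -= (out[i] @ out[j]) / (out[j] @ out[j]) * out[j]
        out[i] *= np.sqrt(target_var) / out[i].std()
    return out


def default_ground_truth(
    n_subjects: int = 53,
    noise_sd: float = 1.0,
    subject_jitter: float = 0.1,
    seed: int = 0,
    n_sources: int = 4,
) -> GroundTruth:
    """Four-source ground truth emulating the component structure of a
    conflict-modulated stopping study.

    Source waveforms are Gaussian bumps at distinct latencies with a
    time-ensemble RMS of ~3.5 relative to the unit white-noise floor;
    condition effects sit in early-attentional through response-related
    windows with standardized sizes 0.5-0.8, i.e. single-source peak
    decodability (AUC) around 0.64-0.71.
    """
    rng = np.random.default_rng(seed + 987_654)
    # baseline waveforms at well-separated latencies: temporally disjoint
    # source activity is what makes the sources statistically independent
    # (and hence separable); the condition-effect windows may still overlap
    specs = [
        # (window, effect size, bump center, bump width, carrier Hz, sign)
        ((85.0, 245.0), 0.5, 120.0, 50.0, 0.0, 1.0),
        ((300.0, 700.0), 0.8, 430.0, 70.0, 3.0, -1.0),
        ((90.0, 420.0), 0.6, 680.0, 60.0, 6.0, 1.0),
        ((110.0, 430.0), 0.6, 900.0, 55.0, 9.0, -1.0),
    ][:n_sources]
    raw = np.stack([
        _erp_bump(center, width, sign, freq)
        for _, _, center, width, freq, sign in specs
    ])
    waveforms = _orthogonalized_waveforms(raw, target_var=12.0)
    # orthonormal smooth topographies: without this, one source's condition
    # effect leaks into the others' spatial axes and the per-window effect
    # sizes are no longer the generative d values
    smooth = np.stack([_smooth_random_topography(rng) for _ in specs]).T
    topos, _ = np.linalg.qr(smooth)
    sources = tuple(
        make_source(topos[:, i], window, effect, wf)
        for i, ((window, effect, *_), wf) in enumerate(zip(specs, waveforms))
    )
    return GroundTruth(
        race=default_race_params(),
        sources=sources,
        n_subjects=n_subjects,
        noise_sd=noise_sd,
        subject_jitter=subject_jitter,
        seed=seed,
    )


def _subject_topographies(truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """Seeded jitter of the group topographies, renormalized; shape
    (n_sources, n_channels)."""
    topos = np.stack([s.topography for s in truth.sources])
    jitter = truth.subject_jitter * rng.normal(size=topos.shape) / np.sqrt(N_CHANNELS)
    out = topos + jitter
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def background_topographies(truth: GroundTruth, condition: str) -> np.ndarray:
    """Orthonormal background topographies for one condition, shape
    (n_background, n_channels).

    Smooth random patterns, orthogonalized against the group signal
    topographies and among themselves; seeded from ``truth.seed`` and the
    condition so the two conditions get independent background sets while
    every subject shares them.
    """
    if truth.n_background == 0:
        return np.zeros((0, N_CHANNELS))
    rng = np.random.default_rng(truth.seed + 13_571 + 1000 * CONDITIONS.index(condition))
    raw = np.stack([_smooth_random_topography(rng) for _ in range(truth.n_background)])
    basis = raw.T
    if truth.sources:
        # project out span(signal topographies); they are correlated, so a
        # proper oblique projector is required, not sum of rank-1 terms
        S = np.stack([s.topography for s in truth.sources]).T  # channels x k
        Q_sig, _ = np.linalg.qr(S)
        basis = basis - Q_sig @ (Q_sig.T @ basis)
    q, _ = np.linalg.qr(basis)
    return q.T[: truth.n_background]


def _condition_epochs(
    truth: GroundTruth,
    topos: np.ndarray,
    bg_topos: np.ndarray,
    condition: str,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    sign = +0.5 if condition == "incongruent" else -0.5
    epochs = np.zeros((n_trials, N_CHANNELS, N_SAMPLES))
    for k, src in enumerate(truth.sources):
        activation = src.baseline_erp + sign * src.effect_size * src.window_mask()
        epochs += topos[k][None, :, None] * activation[None, None, :]
    gains = truth.background_gains()
    if gains.size and gains.any():
        # unit-variance Laplacian background activations, scaled per source
        acts = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n_trials, gains.size, N_SAMPLES))
        epochs += np.einsum("cj,tjs->tcs", bg_topos.T * gains, acts)
    if truth.noise_sd > 0:
        epochs += truth.noise_sd * rng.normal(size=epochs.shape)
    return epochs


def generate_group_eeg(
    logs: dict[str, pd.DataFrame], truth: GroundTruth
) -> EpochsSet:
    """Epoch the stop trials of each subject's session into synthetic EEG.

    Only stop trials are epoched, one epoch per stop trial in the log,
    split by congruency.  Each epoch is the sum over ground-truth sources
    of ``topography x activation(t)`` plus isotropic Gaussian sensor
    noise; the per-subject topographies are seeded jitters of the group
    topographies.
    """
    if truth.sources and truth.sources[0].topography.shape != (N_CHANNELS,):
        raise ValueError(f"ground-truth topographies must have {N_CHANNELS} channels")
    sub_seeds = np.random.SeedSequence(truth.seed).generate_state(len(logs)) % (2**31)
    bg = {c: background_topographies(truth, c) for c in CONDITIONS}
    data: dict[str, dict[str, np.ndarray]] = {}
    for i, (sub, log) in enumerate(sorted(logs.items())):
        rng = np.random.default_rng(int(sub_seeds[i]))
        topos = _subject_topographies(truth, rng)
        stop = log[log["is_stop"] == 1]
        data[sub] = {}
        for cond in CONDITIONS:
            n_trials = int((stop["condition"] == cond).sum())
            data[sub][cond] = _condition_epochs(truth, topos, bg[cond], cond, n_trials, rng)
    return EpochsSet(
        data=data,
        times=epoch_times(),
        channels=default_channel_names(),
        seed=truth.seed,
    )


def simulate_epochs(truth: GroundTruth, n_trials_per_condition: int = 108) -> EpochsSet:
    """Generate stop-trial epochs directly with a fixed per-cell trial
    count, bypassing the behavioral simulation (for decoding studies where
    the staircase is irrelevant)."""
    sub_seeds = np.random.SeedSequence(truth.seed).generate_state(truth.n_subjects) % (2**31)
    bg = {c: background_topographies(truth, c) for c in CONDITIONS}
    data: dict[str, dict[str, np.ndarray]] = {}
    for i in range(truth.n_subjects):
        sub = f"sub-{i + 1:02d}"
        rng = np.random.default_rng(int(sub_seeds[i]))
        topos = _subject_topographies(truth, rng)
        data[sub] = {
            cond: _condition_epochs(truth, topos, bg[cond], cond, n_trials_per_condition, rng)
            for cond in CONDITIONS
        }
    return EpochsSet(data=data, times=epoch_times(), channels=default_channel_names(), seed=truth.seed)


def null_ground_truth(n_subjects: int = 10, seed: int = 0, **kwargs) -> GroundTruth:
    """Ground truth whose sources carry no condition information
    (every effect size zero); used for chance-level calibration."""
    truth = default_ground_truth(n_subjects=n_subjects, seed=seed, **kwargs)
    sources = tuple(replace(s, effect_size=0.0) for s in truth.sources)
    return replace(truth, sources=sources)
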