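"""Behavioral analysis of stop-signal Simon sessions.

Covers trial classification, the SSD staircase rule, SSRT estimation by
the mean method (mean correct-go RT minus mean SSD), the subject
exclusion rules (stopping-probability range, SSRT congruency-difference
cut-off, Tukey outlier fences) and paired nonparametric congruency
contrasts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import CONDITIONS
from .synth import LOG_COLUMNS

__all__ = [
    "BehaviorSummary",
    "ExclusionReport",
    "read_trial_log",
    "write_trial_log",
    "next_ssd",
    "classify_trials",
    "estimate_ssrt",
    "summarize_subject",
    "summarize_group",
    "apply_exclusions",
    "congruency_contrast",
]

GO_OUTCOMES = ("hit", "incorrect", "miss")
STOP_OUTCOMES = ("correct_rejection", "failed_stop")

# measurements entering the Tukey outlier screen, each assessed per condition
TUKEY_MEASURES = ("mean_go_rt", "go_accuracy", "ssrt", "p_respond_stop")


# ---------------------------------------------------------------------------
# trial-log I/O


def read_trial_log(path) -> pd.DataFrame:
    """Read the TSV trial-log dialect (one row per trial)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "response": str})
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log {path} missing columns {sorted(missing)}")
    validate_records(df)
    return df


def write_trial_log(path, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.3f")


def validate_records(records: pd.DataFrame) -> None:
    bad = set(records["outcome"]) - set(GO_OUTCOMES) - set(STOP_OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    stop = records[records["is_stop"] == 1]
    go = records[records["is_stop"] == 0]
    if stop["ssd_ms"].isna().any():
        raise ValueError("stop trials with missing SSD")
    if len(stop) and not stop["ssd_ms"].between(50, 1000).all():
        raise ValueError("stop-trial SSD outside [50, 1000] ms")
    if go["ssd_ms"].notna().any():
        raise ValueError("go trials must not carry an SSD")
    rts = records["rt_ms"].dropna()
    if len(rts) and (rts <= 0).any():
        raise ValueError("non-positive RTs present")


# ---------------------------------------------------------------------------
# staircase and classification


def next_ssd(
    current_ssd: float,
    stopped: bool,
    step: float = 50.0,
    lo: float = 50.0,
    hi: float = 1000.0,
) -> float:
    """One staircase update: +step after a correct stop, -step after a
    failed stop, clamped to ``[lo, hi]``."""
    if not lo <= current_ssd <= hi:
        raise ValueError(f"current SSD {current_ssd} outside [{lo}, {hi}] ms")
    return float(np.clip(current_ssd + (step if stopped else -step), lo, hi))


def classify_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Outcome counts per condition (rows: condition, columns: outcomes).

    Go outcomes are hit / incorrect / miss; stop outcomes are
    correct_rejection / failed_stop.  Counts partition the trials.
    """
    validate_records(records)
    outcomes = GO_OUTCOMES + STOP_OUTCOMES
    table = pd.DataFrame(0, index=list(CONDITIONS), columns=list(outcomes), dtype=int)
    counts = records.groupby(["condition", "outcome"]).size()
    for (cond, out), n in counts.items():
        table.loc[cond, out] = int(n)
    return table


# ---------------------------------------------------------------------------
# SSRT and summaries


def estimate_ssrt(records: pd.DataFrame, condition: str) -> float:
    """Mean-method SSRT: mean correct-go RT minus mean SSD, in ms.

    The staircase holds p(respond|stop) near 0.5, so the mean SSD
    estimates the delay at which stopping succeeds half the time; the
    stop process latency is the gap between that delay and the mean go
    finishing time.  Only correct (hit) go trials enter the go mean; all
    stop trials of the condition enter the SSD mean.
    """
    sel = records[records["condition"] == condition]
    go_rts = sel.loc[(sel["is_stop"] == 0) & (sel["outcome"] == "hit"), "rt_ms"]
    ssds = sel.loc[sel["is_stop"] == 1, "ssd_ms"]
    if go_rts.empty or ssds.empty:
        raise ValueError(
            f"cannot estimate SSRT for {condition!r}: "
            f"{len(go_rts)} correct go trials, {len(ssds)} stop trials"
        )
    return float(go_rts.mean() - ssds.mean())


def summarize_subject(records: pd.DataFrame) -> pd.DataFrame:
    """Per-condition behavioral summary for one subject's session.

    Columns: mean_go_rt, go_accuracy, p_respond_stop, mean_ssd, ssrt,
    mean_failed_stop_rt.  By construction ``ssrt = mean_go_rt - mean_ssd``.
    """
    rows = {}
    for cond in CONDITIONS:
        sel = records[records["condition"] == cond]
        go = sel[sel["is_stop"] == 0]
        stop = sel[sel["is_stop"] == 1]
        hits = go[go["outcome"] == "hit"]
        failed = stop[stop["outcome"] == "failed_stop"]
        rows[cond] = {
            "mean_go_rt": float(hits["rt_ms"].mean()),
            "go_accuracy": float(len(hits) / len(go)) if len(go) else np.nan,
            "p_respond_stop": float(len(failed) / len(stop)) if len(stop) else np.nan,
            "mean_ssd": float(stop["ssd_ms"].mean()),
            "ssrt": estimate_ssrt(records, cond),
            "mean_failed_stop_rt": float(failed["rt_ms"].mean()) if len(failed) else np.nan,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "condition"
    return out


def summarize_group(logs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-subject summaries into a (subject, condition)-indexed frame."""
    frames = []
    for sub, log in sorted(logs.items()):
        s = summarize_subject(log)
        s.insert(0, "subject", sub)
        frames.append(s.reset_index())
    return pd.concat(frames, ignore_index=True).set_index(["subject", "condition"])


# ---------------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionReport:
    """Per-subject inclusion flags with the reasons for any exclusion."""

    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def excluded(self) -> list[str]:
        return sorted(s for s, r in self.reasons.items() if r)

    @property
    def included(self) -> list[str]:
        return sorted(s for s, r in self.reasons.items() if not r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": sorted(self.reasons),
                "included": [not self.reasons[s] for s in sorted(self.reasons)],
                "reasons": [",".join(self.reasons[s]) for s in sorted(self.reasons)],
            }
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.reasons, indent=1, sort_keys=True))


def _tukey_outliers(values: pd.Series) -> pd.Series:
    q1, q3 = values.quantile([0.25, 0.75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def apply_exclusions(
    summaries: pd.DataFrame,
    stop_prob_range: tuple[float, float] = (0.25, 0.75),
    ssrt_diff_cutoff: float = 50.0,
    min_cohort_for_tukey: int = 4,
) -> ExclusionReport:
    """Apply the three behavioral exclusion rules to a group summary.

    * ``stop_probability``: p(respond|stop) outside ``stop_prob_range``
      in either condition (SSRT estimates are unreliable away from 0.5).
    * ``ssrt_direction``: SSRT difference (incongruent minus congruent)
      larger than ``ssrt_diff_cutoff`` ms.
    * ``tukey_outlier``: value outside the Tukey fences
      [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (computed across subjects, per measure
      per condition) in more than one of the 8 measurements
      ({go RT, go accuracy, SSRT, p(respond|stop)} x condition).

    ``summaries`` must be indexed by (subject, condition) as returned by
    :func:`summarize_group`.
    """
    subjects = sorted(summaries.index.get_level_values("subject").unique())
    reasons: dict[str, list[str]] = {s: [] for s in subjects}
    lo, hi = stop_prob_range

    for sub in subjects:
        probs = summaries.loc[sub, "p_respond_stop"]
        if ((probs < lo) | (probs > hi)).any():
            reasons[sub].append("stop_probability")
        diff = summaries.loc[(sub, "incongruent"), "ssrt"] - summaries.loc[(sub, "congruent"), "ssrt"]
        if diff > ssrt_diff_cutoff:
            reasons[sub].append("ssrt_direction")

    if len(subjects) < min_cohort_for_tukey:
        warnings.warn(
            f"Tukey outlier rule skipped: cohort of {len(subjects)} < {min_cohort_for_tukey}",
            stacklevel=2,
        )
    else:
        n_flags = pd.Series(0, index=subjects)
        for measure in TUKEY_MEASURES:
            for cond in CONDITIONS:
                col = summaries.xs(cond, level="condition")[measure]
                n_flags = n_flags.add(_tukey_outliers(col).astype(int), fill_value=0)
        for sub in subjects:
            if n_flags[sub] > 1:
                reasons[sub].append("tukey_outlier")

    return ExclusionReport(reasons=reasons)


# ---------------------------------------------------------------------------
# paired contrasts


def congruency_contrast(
    congruent: np.ndarray, incongruent: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of a paired congruency effect.

    Returns ``(statistic, p)``.  Zero differences are discarded
    (Wilcoxon convention); the p-value is exact for n <= 25 remaining
    pairs and uses the continuity-corrected normal approximation above
    that.  If every difference is zero the contrast is degenerate and
    ``(0.0, 1.0)`` is returned.
    """
    congruent = np.asarray(congruent, dtype=float)
    incongruent = np.asarray(incongruent, dtype=float)
    if congruent.shape != incongruent.shape:
        raise ValueError("paired samples must have equal length")
    diffs = incongruent - congruent
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 0.0, 1.0
    method = "exact" if diffs.size <= 25 else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)
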