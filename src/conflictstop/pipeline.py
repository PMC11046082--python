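"""End-to-end orchestration: simulate -> behavior -> group ICA (x2
conditions) -> topography matching -> decoding -> cluster inference ->
brain-behavior regression.

Every stage writes its outputs into the run directory and records a
sha256 checksum in ``manifest.json``; a stage is skipped on re-run when
its outputs already match the manifest, and a downstream stage refuses
to run when an upstream checksum no longer matches (provenance guard).
All stage seeds derive from one master seed via a counter scheme
(``SeedSequence([master, stage_index])``), so two runs with the same
config are numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import behavior as beh
from . import brainbehavior as bb
from . import corrmap as cm
from . import decode as dec
from . import gica
from . import inference as inf
from . import synth
from .epochs import CONDITIONS, load_epochs, save_epochs

logger = logging.getLogger(__name__)

STAGES = ["simulate", "behavior", "gica", "corrmap", "decode", "infer", "brainbehavior"]

STAGE_DEPS = {
    "simulate": [],
    "behavior": ["simulate"],
    "gica": ["simulate"],
    "corrmap": ["gica"],
    "decode": ["corrmap", "gica"],
    "infer": ["decode"],
    "brainbehavior": ["infer", "behavior", "decode"],
}


@dataclass
class PipelineConfig:
    """All pipeline parameters with study-faithful task defaults.

    The task design, staircase and race parameters mirror the study; the
    cohort size and EEG trial counts default to a desk-scale run (12
    subjects) that exercises every stage in minutes — raise
    ``n_subjects`` for study-scale cohorts.
    """

    seed: int = 0
    n_subjects: int = 12
    # task design (defaults: 9 blocks of 80 go + 24 stop = 936 trials)
    n_blocks: int = 9
    go_per_block: int = 80
    stop_per_block: int = 24
    # synthetic EEG ground truth
    n_sources: int = 4
    noise_sd: float = 1.0
    subject_jitter: float = 0.1
    # group ICA
    retention: float = 0.98
    k_max: int = 20
    # matching
    match_threshold: float = 0.85
    max_per_group: int = 3
    n_init: int = 40
    # decoding
    n_folds: int = 5
    temporal_generalization: bool = True
    # inference
    alpha_cluster: float = 0.05
    alpha_sig: float = 0.05
    n_perm: int = 1000
    # behavior
    apply_exclusions: bool = True

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, run_dir: Path):
        self.path = run_dir / "manifest.json"
        self.data = (
            json.loads(self.path.read_text())
            if self.path.exists()
            else {"config_hash": None, "stages": {}}
        )

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def record(self, stage: str, files: list[Path], seed: int, duration: float) -> None:
        self.data["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "seed": seed,
            "duration_s": round(duration, 3),
        }
        self.save()

    def verify(self, stage: str, run_dir: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None:
            return False
        for name, digest in entry["files"].items():
            f = run_dir / name
            if not f.exists() or _sha256(f) != digest:
                return False
        return True


def _require(manifest: Manifest, stage: str, run_dir: Path) -> None:
    if not manifest.verify(stage, run_dir):
        raise RuntimeError(
            f"upstream stage {stage!r} is missing or its outputs no longer match "
            "the manifest; re-run it before continuing"
        )


def run_pipeline(config: PipelineConfig, run_dir, stages: list[str] | None = None) -> Path:
    """Run (or resume) the pipeline; returns the run directory.

    Stage outputs live flat in ``run_dir``; ``manifest.json`` carries the
    config hash, per-stage seeds, durations and output checksums.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(run_dir)
    if manifest.data["config_hash"] not in (None, config.digest()):
        raise RuntimeError("run directory was produced by a different config")
    manifest.data["config_hash"] = config.digest()
    config.to_yaml(run_dir / "config.yaml")
    manifest.save()

    for stage in stages or STAGES:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        # provenance guard: refuse to run or reuse a stage whose recorded
        # upstream outputs have changed since they were produced
        for dep in STAGE_DEPS[stage]:
            if dep in manifest.data["stages"]:
                _require(manifest, dep, run_dir)
        if manifest.verify(stage, run_dir):
            logger.info("stage %s: cached, skipping", stage)
            continue
        t0 = time.time()
        seed = config.stage_seed(stage)
        try:
            files = _STAGE_FUNCS[stage](config, run_dir, manifest, seed)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest.record(stage, files, seed, time.time() - t0)
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return run_dir


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    design = synth.TaskDesign(
        n_blocks=config.n_blocks,
        go_per_block=config.go_per_block,
        stop_per_block=config.stop_per_block,
    )
    logs = synth.generate_group_sessions(
        design=design, n_subjects=config.n_subjects, seed=seed
    )
    truth = synth.default_ground_truth(
        n_subjects=config.n_subjects,
        noise_sd=config.noise_sd,
        subject_jitter=config.subject_jitter,
        seed=seed,
        n_sources=config.n_sources,
    )
    epochs = synth.generate_group_eeg(logs, truth)
    files = []
    for sub, log in logs.items():
        f = run_dir / f"{sub}_events.tsv"
        beh.write_trial_log(f, log)
        files.append(f)
    f = run_dir / "epochs.h5"
    save_epochs(f, epochs)
    files.append(f)
    return files


def _load_logs(config: PipelineConfig, run_dir: Path) -> dict:
    return {
        f.name.replace("_events.tsv", ""): beh.read_trial_log(f)
        for f in sorted(run_dir.glob("sub-*_events.tsv"))
    }


def _stage_behavior(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    _require(manifest, "simulate", run_dir)
    logs = _load_logs(config, run_dir)
    summaries = beh.summarize_group(logs)
    files = [run_dir / "behavior_summary.tsv"]
    summaries.to_csv(files[0], sep="\t", float_format="%.4f")
    if config.apply_exclusions:
        report = beh.apply_exclusions(summaries)
        f = run_dir / "exclusions.json"
        report.to_json(f)
        files.append(f)
    # headline congruency contrasts
    contrasts = {}
    for measure in ("ssrt", "mean_go_rt"):
        cong = summaries.xs("congruent", level="condition")[measure].to_numpy()
        incong = summaries.xs("incongruent", level="condition")[measure].to_numpy()
        stat, p = beh.congruency_contrast(cong, incong)
        contrasts[measure] = {
            "mean_congruent": float(cong.mean()),
            "mean_incongruent": float(incong.mean()),
            "wilcoxon_statistic": stat,
            "p": p,
        }
    f = run_dir / "contrasts.json"
    f.write_text(json.dumps(contrasts, indent=1))
    files.append(f)
    return files


def _stage_gica(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    _require(manifest, "simulate", run_dir)
    epochs = load_epochs(run_dir / "epochs.h5")
    files = []
    for i, cond in enumerate(CONDITIONS):
        decomp = gica.decompose_condition(
            epochs, cond, seed=seed + i, retention=config.retention, k_max=config.k_max
        )
        f = run_dir / f"gica_{cond}.h5"
        gica.save_decomposition(f, decomp)
        files.append(f)
    return files


def _stage_corrmap(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    _require(manifest, "gica", run_dir)
    dA = gica.load_decomposition(run_dir / "gica_congruent.h5")
    dB = gica.load_decomposition(run_dir / "gica_incongruent.h5")
    pairs = cm.match_components(
        dA,
        dB,
        threshold=config.match_threshold,
        max_per_group=config.max_per_group,
        n_init=config.n_init,
        seed=seed,
    )
    f = run_dir / "pairs.json"
    cm.save_pairs(f, pairs)
    return [f]


def _stage_decode(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    _require(manifest, "corrmap", run_dir)
    dA = gica.load_decomposition(run_dir / "gica_congruent.h5")
    dB = gica.load_decomposition(run_dir / "gica_incongruent.h5")
    pairs = cm.load_pairs(run_dir / "pairs.json")
    results = dec.decode_pair_group(
        pairs, dA, dB, n_folds=config.n_folds, seed=seed,
        generalize=config.temporal_generalization,
    )
    f = run_dir / "decoding.h5"
    dec.save_decoding(f, results)
    return [f]


def _stage_infer(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    _require(manifest, "decode", run_dir)
    results = dec.load_decoding(run_dir / "decoding.h5")
    times = synth.epoch_times()
    report = []
    windows = {}
    for k in sorted(results):
        subs = sorted(results[k])
        diag = np.stack([results[k][s].auc_diag for s in subs])
        res = inf.cluster_permutation(
            diag, alpha_cluster=config.alpha_cluster, n_perm=config.n_perm, seed=seed + k
        )
        sig = res.significant(config.alpha_sig)
        if sig:
            lo, hi = sig[0].extent_1d()
            windows[k + 1] = [int(lo), int(hi)]
        report.append({"pair_id": k + 1, "analysis": "diag",
                       "clusters": inf.cluster_report(res, times, "diag")})
        if results[k][subs[0]].auc_tg is not None:
            tg = np.stack([results[k][s].auc_tg for s in subs])
            res_tg = inf.cluster_permutation(
                tg, alpha_cluster=config.alpha_cluster, n_perm=config.n_perm,
                seed=seed + 100 + k,
            )
            report.append({"pair_id": k + 1, "analysis": "tg",
                           "clusters": inf.cluster_report(res_tg, times, "tg")})
    f = run_dir / "clusters.json"
    f.write_text(json.dumps({"report": report, "significant_windows": windows}, indent=1))
    return [f]


def _stage_brainbehavior(config: PipelineConfig, run_dir: Path, manifest: Manifest, seed: int):
    _require(manifest, "infer", run_dir)
    _require(manifest, "behavior", run_dir)
    results = dec.load_decoding(run_dir / "decoding.h5")
    clusters = json.loads((run_dir / "clusters.json").read_text())
    windows = {int(k): v for k, v in clusters["significant_windows"].items()}
    import pandas as pd

    summaries = pd.read_csv(run_dir / "behavior_summary.tsv", sep="\t").set_index(
        ["subject", "condition"]
    )
    dssrt = (
        summaries.xs("incongruent", level="condition")["ssrt"]
        - summaries.xs("congruent", level="condition")["ssrt"]
    )
    bb_results: dict[int, bb.BrainBehaviorResult] = {}
    for k in sorted(results):
        if k + 1 not in windows:
            logger.info("pair %d has no significant cluster; skipped", k + 1)
            continue
        lo, hi = windows[k + 1]
        subs = sorted(results[k])
        inputs = np.array(
            [bb.mean_auc_in_window(results[k][s].auc_diag, (lo, hi)) for s in subs]
        )
        targets = dssrt.loc[subs].to_numpy()
        bb_results[k] = bb.loo_nn_regression(inputs, targets, seed=seed + k, subjects=subs)
    f = run_dir / "brainbehavior.json"
    if len(bb_results) >= 2:
        comparisons = bb.compare_rmse(bb_results)
    else:
        comparisons = []
    bb.save_results(f, bb_results, comparisons)
    return [f]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "gica": _stage_gica,
    "corrmap": _stage_corrmap,
    "decode": _stage_decode,
    "infer": _stage_infer,
    "brainbehavior": _stage_brainbehavior,
}
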