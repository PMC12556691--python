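"""End-to-end orchestration: simulate -> score -> model, with a manifest.

Stages (all driven by one serialisable :class:`PipelineConfig`):

1. ``simulate``              dyad pose series, schedule, traits
2. ``score-kinematics``      per-video synchrony and complexity
3. ``analyze-behaviour``     observer trials + trait/rating models
4. ``process-fnirs``         synthetic recordings -> ROI HbDiff estimates
5. ``link-brain-behaviour``  brain-behaviour + moderation models

Every stage reads its inputs from and writes its outputs to the run
directory; ``run_all`` chains them and writes a manifest with the config
hash, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import TraitEffectsModel, RatingEffectsModel
from .brain import BodyCompetenceModerationModel, BrainBehaviourModel, build_brain_records
from .kinematics import movement_complexity, smooth_pose, synchrony_score
from .pose import PoseSequence
from .synthetic import (
    DyadSimConfig,
    FnirsSimConfig,
    ObserverSimConfig,
    generate_fnirs_recording,
    generate_follower,
    generate_leader,
    generate_observer_data,
    generate_schedule,
    generate_traits,
)
from .fnirs import FnirsPipeline, load_recording, save_recording

__all__ = ["PipelineConfig", "run_all", "STAGES"]


@dataclass
class PipelineConfig:
    """Fully serialisable settings for one pipeline run.

    The demo defaults are scaled down (8 videos, 6 observers, 4 fNIRS
    participants, 24 long channels) so a complete run finishes in
    minutes; ``observer``, ``fnirs`` and ``sampler`` accept keyword
    overrides for the corresponding config objects.
    """

    seed: int = 0
    n_videos: int = 8
    n_participants: int = 12
    n_fnirs_participants: int = 6
    n_frames: int = 400
    fps: float = 25.0
    lag_frames: int = 3
    video_noise_range: tuple[float, float] = (0.0, 12.0)
    amplitude_scale: float = 1.0
    smooth_before_metrics: bool = True
    smooth_window: int = 13
    smooth_polyorder: int = 2
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    observer: dict = field(default_factory=dict)
    fnirs: dict = field(default_factory=lambda: {"n_long_channels": 24, "n_short_channels": 4})
    sampler: dict = field(default_factory=lambda: {"draws": 500, "warmup": 500, "chains": 2})
    fnirs_weighting: str = "inverse_variance"
    short_pc_variance: float = 0.95

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["video_noise_range"] = list(d["video_noise_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "video_noise_range" in d:
            d["video_noise_range"] = tuple(d["video_noise_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise ValueError(f"missing required input {path.name!r} ({what}); run the earlier stage first")
    return path


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    """Generate pose series for every video, the schedule, and traits."""
    outdir.mkdir(parents=True, exist_ok=True)
    poses = outdir / "poses"
    poses.mkdir(exist_ok=True)
    schedule = generate_schedule(cfg.n_videos, seed=cfg.seed)
    schedule.trials.to_csv(outdir / "schedule.csv", index=False)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 10)))
    noise_lo, noise_hi = cfg.video_noise_range
    for v in range(cfg.n_videos):
        dyad_cfg = DyadSimConfig(
            n_frames=cfg.n_frames,
            fps=cfg.fps,
            lag_frames=cfg.lag_frames,
            follower_noise_sd=float(rng.uniform(noise_lo, noise_hi)),
            amplitude_scale=cfg.amplitude_scale,
            seed=int(rng.integers(2**31 - 1)),
        )
        leader = generate_leader(dyad_cfg)
        follower = generate_follower(leader, dyad_cfg)
        leader.to_tsv(poses / f"video{v:03d}_leader.tsv")
        follower.to_tsv(poses / f"video{v:03d}_follower.tsv")
    generate_traits(cfg.n_participants, seed=cfg.seed).to_csv(outdir / "traits.csv", index=False)


def stage_score_kinematics(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Synchrony and complexity per video -> video_metrics.csv."""
    poses = _require(outdir / "poses", "pose tables from the simulate stage")
    schedule = pd.read_csv(_require(outdir / "schedule.csv", "experiment schedule"))
    conds = (
        schedule[schedule["trial_type"] == "observe"][["video_id", "condition"]]
        .drop_duplicates()
        .set_index("video_id")["condition"]
    )
    rows = []
    for v in range(cfg.n_videos):
        leader = PoseSequence.from_tsv(poses / f"video{v:03d}_leader.tsv", fps=cfg.fps)
        follower = PoseSequence.from_tsv(poses / f"video{v:03d}_follower.tsv", fps=cfg.fps)
        if cfg.smooth_before_metrics:
            leader = smooth_pose(leader, cfg.smooth_window, cfg.smooth_polyorder)
            follower = smooth_pose(follower, cfg.smooth_window, cfg.smooth_polyorder)
        sync = synchrony_score(leader, follower)
        comp = movement_complexity(leader, follower, m=cfg.sampen_m, r_factor=cfg.sampen_r_factor)
        row = {"video_id": v, "condition": conds.get(v, "unknown"), "synchrony": sync, "complexity": comp.value}
        row.update({f"complexity_{k}": c for k, c in enumerate(comp.components)})
        rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(outdir / "video_metrics.csv", index=False)
    return metrics


def stage_analyze_behaviour(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Simulate observer trials and fit the trait and rating models."""
    metrics = pd.read_csv(_require(outdir / "video_metrics.csv", "kinematic metrics"))
    traits = pd.read_csv(_require(outdir / "traits.csv", "participant traits"))
    obs_cfg = ObserverSimConfig(n_participants=cfg.n_participants, seed=cfg.seed, **cfg.observer)
    measured = metrics.rename(columns={"synchrony": "synchrony"})[["video_id", "condition", "synchrony"]]
    trials, _ = generate_observer_data(measured, traits, obs_cfg)
    trials = trials.merge(metrics[["video_id", "complexity"]], on="video_id")
    trials.to_csv(outdir / "trials.csv", index=False)

    trait_summary = TraitEffectsModel(seed=cfg.seed, **cfg.sampler).fit(trials, traits).summary_
    rating_summary = RatingEffectsModel(seed=cfg.seed + 1, **cfg.sampler).fit(trials).summary_
    trait_summary.insert(0, "model", "trait")
    rating_summary.insert(0, "model", "rating")
    summary = pd.concat([trait_summary, rating_summary], ignore_index=True)
    summary.to_csv(outdir / "behaviour_summary.csv", index=False)
    return summary


def stage_process_fnirs(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Simulate recordings for the fNIRS subsample and estimate ROI responses."""
    schedule = generate_schedule(cfg.n_videos, seed=cfg.seed)
    fnirs_dir = outdir / "fnirs"
    pipeline = FnirsPipeline(weighting=cfg.fnirs_weighting, short_pc_variance=cfg.short_pc_variance)
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
    for i in range(cfg.n_fnirs_participants):
        pid = f"P{i:03d}"
        rec_dir = fnirs_dir / pid
        if rec_dir.exists():
            rec = load_recording(rec_dir)
        else:
            sim_cfg = FnirsSimConfig(seed=int(rng.integers(2**31 - 1)), **cfg.fnirs)
            rec, _truth = generate_fnirs_recording(schedule, sim_cfg)
            save_recording(rec, rec_dir)
        est = pipeline.roi_estimates(rec)
        est.insert(0, "participant_id", pid)
        rows.append(est)
    estimates = pd.concat(rows, ignore_index=True)
    estimates.to_csv(outdir / "roi_estimates.csv", index=False)
    return estimates


def stage_link_brain_behaviour(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Fit the brain-behaviour and body-competence moderation models."""
    estimates = pd.read_csv(_require(outdir / "roi_estimates.csv", "ROI haemodynamic estimates"))
    trials = pd.read_csv(_require(outdir / "trials.csv", "behavioural trials"))
    traits = pd.read_csv(_require(outdir / "traits.csv", "participant traits"))
    fnirs_pids = set(estimates["participant_id"])
    records = build_brain_records(
        estimates,
        trials[trials["participant_id"].isin(fnirs_pids)],
        traits,
    )
    # HbDiff is in mol/L here; rescale to micromolar for interpretable slopes
    records = records.assign(hbdiff=records["hbdiff"] * 1e6)
    model = BrainBehaviourModel(seed=cfg.seed + 2, **cfg.sampler).fit(records)
    model.roi_table_.to_csv(outdir / "brain_summary.csv", index=False)
    moderation = BodyCompetenceModerationModel(seed=cfg.seed + 3, **cfg.sampler).fit(records)
    moderation.summary_.to_csv(outdir / "moderation_summary.csv", index=False)
    return model.roi_table_


STAGES = {
    "simulate": stage_simulate,
    "score-kinematics": stage_score_kinematics,
    "analyze-behaviour": stage_analyze_behaviour,
    "process-fnirs": stage_process_fnirs,
    "link-brain-behaviour": stage_link_brain_behaviour,
}


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order; write and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES.items():
        fn(cfg, outdir)
    outputs = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.suffix in {".csv", ".tsv", ".json"} and p.name != "manifest.json"
    )
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
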