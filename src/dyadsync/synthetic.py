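"""Synthetic-data generators for every input of the analysis pipeline.

Four kinds of input are emulated, each with known ground truth:

* dyadic pose kinematics — a leader mover whose joints follow smooth
  band-limited sinusoid mixtures, and a follower that replays the leader
  with a lag, an amplitude scale, and additive Gaussian coordinate noise
  (a minimal mirror-game model: noise maps monotonically to synchrony);
* the experiment schedule — an even split of videos into performed and
  unknown conditions, presented in 3-trial blocks (mirror the performed
  sequence, then observe the performed and an unknown video in random
  order);
* observer trial data — estimation errors from a linear model with
  per-condition intercepts, trait effects, participant random
  intercepts and Gaussian residuals, plus enjoyment and recognition
  responses;
* fNIRS recordings — known HbO/HbR responses pushed through the forward
  Beer-Lambert relation to two-wavelength intensities, with a shared
  superficial (scalp) component, linear drift, white noise and optional
  motion artifacts.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behaviour import TRAITS, zscore
from .fnirs import (
    ROIS,
    ChannelRecording,
    MontageSpec,
    PPFParams,
    condition_regressor,
    forward_mbll,
)
from .pose import JOINTS, PoseSequence

__all__ = [
    "DyadSimConfig",
    "ObserverSimConfig",
    "FnirsSimConfig",
    "ExperimentSchedule",
    "generate_leader",
    "generate_follower",
    "generate_schedule",
    "generate_traits",
    "generate_observer_data",
    "make_montage",
    "generate_fnirs_recording",
    "generate_brain_behaviour_records",
]

#: Anatomical rest pose (x, y) in pixel-like units, one row per joint.
REST_POSE = np.array(
    [
        [320.0, 100.0],  # neck
        [260.0, 110.0],  # l_shoulder
        [380.0, 110.0],  # r_shoulder
        [230.0, 180.0],  # l_elbow
        [410.0, 180.0],  # r_elbow
        [210.0, 250.0],  # l_hand
        [430.0, 250.0],  # r_hand
    ]
)

#: Movement amplitude (pixels) per joint: trunk joints near-stationary,
#: elbows mobile, hands most mobile.
JOINT_AMPLITUDE = np.array([2.0, 3.0, 3.0, 18.0, 18.0, 40.0, 40.0])


@dataclass(frozen=True)
class DyadSimConfig:
    """Leader/follower kinematics simulation settings.

    lag_frames delays the follower; follower_noise_sd (coordinate units)
    controls how loosely the follower tracks; amplitude_scale rescales
    the follower's coordinates.
    """

    n_frames: int = 400
    fps: float = 25.0
    lag_frames: int = 3
    follower_noise_sd: float = 2.0
    amplitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.lag_frames < 0 or self.lag_frames >= self.n_frames:
            raise ValueError("need 0 <= lag_frames < n_frames")
        if self.follower_noise_sd < 0:
            raise ValueError("follower_noise_sd must be >= 0")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def generate_leader(config: DyadSimConfig) -> PoseSequence:
    """Smooth leader trajectories: 3-6 random-phase sinusoids (<= 1 Hz)
    per joint coordinate, riding on the anatomical rest pose."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_frames) / config.fps
    coords = np.empty((config.n_frames, len(JOINTS), 2))
    for j in range(len(JOINTS)):
        for axis in range(2):
            k = rng.integers(3, 7)
            freqs = rng.uniform(0.1, 1.0, size=k)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
            amps = rng.dirichlet(np.ones(k)) * JOINT_AMPLITUDE[j]
            wave = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)
            coords[:, j, axis] = REST_POSE[j, axis] + wave
    return PoseSequence(coords=coords, fps=config.fps)


def generate_follower(leader: PoseSequence, config: DyadSimConfig) -> PoseSequence:
    """Follower = amplitude_scale * leader(t - lag) + Gaussian coordinate noise.

    The first lag_frames frames hold the (scaled) rest pose. The noise
    stream is independent of the leader's (seed offset), so the same
    config drives both generators coherently.
    """
    if config.lag_frames >= leader.n_frames:
        raise ValueError("lag_frames must be smaller than the leader sequence length")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    lag = config.lag_frames
    coords = np.empty_like(leader.coords)
    coords[:lag] = REST_POSE[None, :, :]
    coords[lag:] = leader.coords[: leader.n_frames - lag]
    coords = config.amplitude_scale * coords
    if config.follower_noise_sd > 0:
        coords = coords + rng.normal(0.0, config.follower_noise_sd, size=coords.shape)
    return PoseSequence(coords=coords, fps=leader.fps)


# --------------------------------------------------------------------------
# schedule

#: Within-block timing (seconds): video length, gap after the mirroring
#: trial, and the rating period after each observation trial.
VIDEO_S = 16.0
POST_MIRROR_GAP_S = 4.0
RATING_GAP_S = 8.0
BLOCK_S = VIDEO_S + POST_MIRROR_GAP_S + 2 * (VIDEO_S + RATING_GAP_S)


@dataclass(frozen=True)
class ExperimentSchedule:
    """Block/trial schedule with video conditions and onset times.

    ``trials`` has one row per trial slot: block, slot (0 = mirroring,
    1-2 = observation), trial_type, video_id, condition, onset (s).
    """

    trials: pd.DataFrame
    n_videos: int
    seed: int

    @property
    def video_conditions(self) -> pd.DataFrame:
        """Per-video condition assignment (video_id, condition)."""
        obs = self.trials[self.trials["trial_type"] == "observe"]
        return obs[["video_id", "condition"]].drop_duplicates().sort_values("video_id").reset_index(drop=True)

    @property
    def events(self) -> pd.DataFrame:
        """Observation-trial events for the fNIRS GLM: onset, condition, duration."""
        obs = self.trials[self.trials["trial_type"] == "observe"]
        return pd.DataFrame(
            {"onset": obs["onset"].to_numpy(), "condition": obs["condition"].to_numpy(), "duration": VIDEO_S}
        )

    @property
    def duration(self) -> float:
        return float(self.trials["onset"].max() + VIDEO_S + RATING_GAP_S)


def generate_schedule(n_videos: int, seed: int = 0) -> ExperimentSchedule:
    """Randomly split videos into performed/unknown halves and build blocks.

    Each of the n_videos/2 blocks starts with mirroring one performed
    video, followed by observing that performed video and one unknown
    video in random order.
    """
    if n_videos % 2 != 0 or n_videos <= 0:
        raise ValueError("n_videos must be a positive even number")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_videos)
    performed = np.sort(order[: n_videos // 2])
    unknown = np.sort(order[n_videos // 2 :])
    unknown_order = rng.permutation(unknown)
    rows = []
    for b in range(n_videos // 2):
        base = b * BLOCK_S
        pv, uv = int(performed[b]), int(unknown_order[b])
        rows.append({"block": b, "slot": 0, "trial_type": "mirror", "video_id": pv, "condition": "performed", "onset": base})
        obs = [(pv, "performed"), (uv, "unknown")]
        if rng.random() < 0.5:
            obs.reverse()
        for k, (vid, cond) in enumerate(obs):
            onset = base + VIDEO_S + POST_MIRROR_GAP_S + k * (VIDEO_S + RATING_GAP_S)
            rows.append({"block": b, "slot": k + 1, "trial_type": "observe", "video_id": vid, "condition": cond, "onset": onset})
    return ExperimentSchedule(trials=pd.DataFrame(rows), n_videos=n_videos, seed=seed)


# --------------------------------------------------------------------------
# observer behaviour

#: Plausible raw trait-score distributions (mean, sd) for the generator.
TRAIT_DISTRIBUTIONS = {
    "extraversion": (3.2, 0.8),
    "self_esteem": (30.0, 5.0),
    "body_perception": (3.4, 0.6),
    "body_competence": (3.6, 0.6),
    "empathy": (44.0, 10.0),
    "autistic_traits": (17.0, 6.0),
}


def generate_traits(n_participants: int, seed: int = 0) -> pd.DataFrame:
    """Raw trait scores for n participants (Gaussian around plausible means)."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    data = {"participant_id": [f"P{i:03d}" for i in range(n_participants)]}
    for t in TRAITS:
        mu, sd = TRAIT_DISTRIBUTIONS[t]
        data[t] = rng.normal(mu, sd, size=n_participants)
    return pd.DataFrame(data)


@dataclass(frozen=True)
class ObserverSimConfig:
    """Ground-truth generative model for estimation errors.

    The per-condition intercepts and trait coefficients default to the
    magnitudes seen in studies of this task (underestimation around
    14-19 error units, trait effects of a few units per SD), so recovery
    studies run at realistic effect sizes. ``trait_coefficients`` are per
    z-unit of each trait; ``trait_condition_coefficients`` add a
    condition-specific slope change (unknown minus performed).
    """

    n_participants: int = 43
    intercept_performed: float = 14.4
    intercept_unknown: float = 19.1
    trait_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "extraversion": -0.10,
            "self_esteem": 1.76,
            "body_perception": 1.16,
            "body_competence": -2.27,
            "empathy": -2.25,
            "autistic_traits": 1.66,
        }
    )
    trait_condition_coefficients: dict[str, float] = field(default_factory=dict)
    random_intercept_sd: float = 7.0
    residual_sd: float = 15.0
    enjoyment_intercept: float = 50.0
    enjoyment_link: float = 1.0
    enjoyment_noise_sd: float = 10.0
    recognition_hit_rate: float = 0.75
    recognition_false_alarm_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in ("random_intercept_sd", "residual_sd", "enjoyment_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.trait_coefficients) - set(TRAITS)
        unknown |= set(self.trait_condition_coefficients) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown trait names: {sorted(unknown)}")


def generate_observer_data(
    measured: pd.DataFrame,
    traits: pd.DataFrame,
    config: ObserverSimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one trial table from measured synchrony and trait scores.

    ``measured`` needs columns (video_id, condition, synchrony), with
    synchrony on [0, 1]. For participant i and video v the error is

        D_iv = intercept_cond + sum_k beta_k z_ik + u_i + eps_iv,

    and the recorded estimate is E_iv = clamp(100 S_v - D_iv, 0, 100).
    Enjoyment is a noisy linear function of -D (less underestimation,
    more enjoyment); recognition responses are Bernoulli with the
    configured hit/false-alarm rates. Returns (trials, truth).
    """
    required = {"video_id", "condition", "synchrony"}
    if not required <= set(measured.columns):
        raise ValueError(f"measured table needs columns {sorted(required)}")
    s = measured["synchrony"].to_numpy(dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("measured synchrony must lie in [0, 1]")
    if traits["participant_id"].nunique() != len(traits):
        raise ValueError("duplicate participants in traits table")
    if len(traits) != config.n_participants:
        raise ValueError(
            f"traits table has {len(traits)} participants but config.n_participants={config.n_participants}"
        )
    missing = set(TRAITS) - set(traits.columns)
    if missing:
        raise ValueError(f"traits table missing columns: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    z = np.column_stack([zscore(traits[t]) for t in TRAITS])
    beta = np.array([config.trait_coefficients.get(t, 0.0) for t in TRAITS])
    beta_cond = np.array([config.trait_condition_coefficients.get(t, 0.0) for t in TRAITS])
    u = rng.normal(0.0, config.random_intercept_sd, size=config.n_participants)

    n_videos = len(measured)
    rows = []
    cond_is_unknown = (measured["condition"] == "unknown").to_numpy()
    intercepts = np.where(cond_is_unknown, config.intercept_unknown, config.intercept_performed)
    for i, pid in enumerate(traits["participant_id"]):
        trait_part = float(z[i] @ beta)
        trait_cond_part = float(z[i] @ beta_cond)
        eps = rng.normal(0.0, config.residual_sd, size=n_videos)
        d = intercepts + trait_part + cond_is_unknown * trait_cond_part + u[i] + eps
        est = np.clip(100.0 * s - d, 0.0, 100.0)
        enjoy = np.clip(
            config.enjoyment_intercept
            - config.enjoyment_link * d
            + rng.normal(0.0, config.enjoyment_noise_sd, size=n_videos),
            0.0,
            100.0,
        )
        p_yes = np.where(cond_is_unknown, config.recognition_false_alarm_rate, config.recognition_hit_rate)
        recog = rng.random(n_videos) < p_yes
        for v in range(n_videos):
            rows.append(
                {
                    "participant_id": pid,
                    "video_id": measured["video_id"].iloc[v],
                    "condition": measured["condition"].iloc[v],
                    "measured_synchrony": s[v],
                    "estimated_synchrony": est[v],
                    "enjoyment": enjoy[v],
                    "recognized": bool(recog[v]),
                    "true_error": d[v],
                }
            )
    trials = pd.DataFrame(rows)
    truth = {
        "intercept_performed": config.intercept_performed,
        "intercept_unknown": config.intercept_unknown,
        "trait_coefficients": dict(config.trait_coefficients),
        "trait_condition_coefficients": dict(config.trait_condition_coefficients),
        "random_intercepts": {pid: float(ui) for pid, ui in zip(traits["participant_id"], u)},
        "random_intercept_sd": config.random_intercept_sd,
        "residual_sd": config.residual_sd,
    }
    return trials, truth


# --------------------------------------------------------------------------
# fNIRS forward model


@dataclass(frozen=True)
class FnirsSimConfig:
    """Forward-model settings for synthetic two-wavelength recordings.

    ``true_amplitude`` maps (roi, condition) to the peak HbO response in
    mol/L (defaults: 1 uM performed, 0.7 uM unknown, every ROI); HbR is
    ``hbr_ratio`` times HbO (canonical polarity -1/3). superficial_sd is
    the OD-scale SD of the shared scalp component; white_noise_sd is
    relative intensity noise; drift_slope is OD/s. ``artifact_spec``
    lists (time_s, magnitude, kind) with kind "spike" or "shift".
    """

    sampling_rate: float = 2.6
    n_long_channels: int = 78
    n_short_channels: int = 8
    true_amplitude: dict[tuple[str, str], float] | None = None
    hbr_ratio: float = -1.0 / 3.0
    superficial_sd: float = 3e-3
    white_noise_sd: float = 5e-4
    drift_slope: float = 2e-5
    cardiac_freq: float = 1.1
    artifact_spec: Sequence[tuple[float, float, str]] = ()
    ppf: PPFParams = field(default_factory=PPFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_long_channels <= 0 or self.n_short_channels <= 0:
            raise ValueError("channel counts must be positive")
        for name in ("superficial_sd", "white_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def amplitude(self, roi: str, condition: str) -> float:
        if self.true_amplitude is None:
            return 1.0e-6 if condition == "performed" else 0.7e-6
        if (roi, condition) not in self.true_amplitude:
            raise KeyError(f"no amplitude configured for ROI {roi!r}, condition {condition!r}")
        return self.true_amplitude[(roi, condition)]


def make_montage(n_long: int = 78, n_short: int = 8, seed: int = 0) -> MontageSpec:
    """Synthetic montage: long channels (~30 mm) round-robin over the 12
    ROIs, short channels at 8 mm distributed across ROIs."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    rows = []
    for i in range(n_long):
        rows.append(
            {
                "channel": f"L{i:02d}",
                "source": f"S{i % 24 + 1}",
                "detector": f"D{i % 23 + 1}",
                "distance_mm": float(rng.uniform(28.0, 32.0)),
                "is_short": False,
                "roi": ROIS[i % len(ROIS)],
            }
        )
    for i in range(n_short):
        rows.append(
            {
                "channel": f"S{i:02d}",
                "source": f"S{i % 24 + 1}",
                "detector": f"SD{i + 1}",
                "distance_mm": 8.0,
                "is_short": True,
                "roi": ROIS[(i * len(ROIS) // max(n_short, 1)) % len(ROIS)],
            }
        )
    return MontageSpec(channels=pd.DataFrame(rows))


@dataclass(frozen=True)
class FnirsTruth:
    """Ground truth stored alongside a simulated recording."""

    channel_amplitudes: pd.DataFrame  # channel, condition, hbo_amp, hbr_amp
    roi_amplitudes: pd.DataFrame  # roi, condition, hbo_amp, hbr_amp


def generate_fnirs_recording(
    schedule: ExperimentSchedule,
    config: FnirsSimConfig,
    montage: MontageSpec | None = None,
) -> tuple[ChannelRecording, FnirsTruth]:
    """Forward-simulate a two-wavelength recording for one participant.

    Long channels carry the event-locked haemodynamic response of their
    ROI (unit-peak boxcar x HRF regressor times the configured
    amplitude), converted to decadic OD by the forward Beer-Lambert
    relation and to intensities I = I0 * 10**(-OD). Short channels carry
    no event-locked component. All channels share the superficial scalp
    component (Mayer-wave + cardiac oscillations, channel-specific
    gains), linear drift with channel-specific sign, white intensity
    noise, and any configured artifacts.
    """
    montage = montage if montage is not None else make_montage(config.n_long_channels, config.n_short_channels, config.seed)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 5)))
    fs = config.sampling_rate
    n_times = int(np.ceil((schedule.duration + 30.0) * fs))
    t = np.arange(n_times) / fs
    events = schedule.events
    conditions = sorted(events["condition"].unique())
    regressors = {
        cond: condition_regressor(
            events.loc[events["condition"] == cond, "onset"].to_numpy(), n_times, fs, VIDEO_S
        )
        for cond in conditions
    }

    # shared superficial component, unit SD: Mayer wave + cardiac + slow noise
    phases = rng.uniform(0, 2 * np.pi, size=2)
    sup = 0.6 * np.sin(2 * np.pi * 0.095 * t + phases[0]) + 0.35 * np.sin(
        2 * np.pi * config.cardiac_freq * t + phases[1]
    )
    slow = np.convolve(rng.normal(size=n_times), np.ones(25) / 25.0, mode="same")
    sup = sup + 0.5 * slow
    sup = sup / sup.std()

    ch = montage.channels
    n_channels = len(ch)
    intensities = np.empty((n_channels, 2, n_times))
    gains = rng.uniform(0.5, 1.5, size=n_channels)
    drift_sign = rng.choice([-1.0, 1.0], size=n_channels)
    i0 = rng.uniform(0.5, 2.0, size=n_channels)

    amp_rows = []
    for ci in range(n_channels):
        info = ch.iloc[ci]
        hbo = np.zeros(n_times)
        hbr = np.zeros(n_times)
        if not info["is_short"]:
            for cond in conditions:
                a = config.amplitude(info["roi"], cond)
                hbo += a * regressors[cond]
                hbr += config.hbr_ratio * a * regressors[cond]
                amp_rows.append(
                    {
                        "channel": info["channel"],
                        "roi": info["roi"],
                        "condition": cond,
                        "hbo_amp": a,
                        "hbr_amp": config.hbr_ratio * a,
                    }
                )
        od = forward_mbll(hbo, hbr, info["distance_mm"], config.ppf)  # (2, n_times), decadic
        od = od + gains[ci] * config.superficial_sd * sup[None, :]
        od = od + drift_sign[ci] * config.drift_slope * t[None, :]
        for when, mag, kind in config.artifact_spec:
            idx = int(round(when * fs))
            if not 0 <= idx < n_times:
                continue
            if kind == "spike":
                od[:, idx] += mag
            elif kind == "shift":
                od[:, idx:] += mag
            else:
                raise ValueError(f"unknown artifact kind {kind!r}")
        sig = i0[ci] * 10.0 ** (-od)
        if config.white_noise_sd > 0:
            sig = sig + rng.normal(0.0, config.white_noise_sd * i0[ci], size=sig.shape)
        intensities[ci] = sig

    rec = ChannelRecording(intensities=intensities, sampling_rate=fs, events=events, montage=montage)
    channel_amps = pd.DataFrame(amp_rows)
    roi_amps = (
        channel_amps.groupby(["roi", "condition"], as_index=False)[["hbo_amp", "hbr_amp"]].mean()
        if len(amp_rows)
        else pd.DataFrame(columns=["roi", "condition", "hbo_amp", "hbr_amp"])
    )
    return rec, FnirsTruth(channel_amplitudes=channel_amps, roi_amplitudes=roi_amps)


# --------------------------------------------------------------------------
# brain-behaviour records


def generate_brain_behaviour_records(
    n_participants: int = 43,
    slopes: dict[tuple[str, str], float] | None = None,
    roi_intercepts: dict[str, float] | None = None,
    moderation: float = 0.0,
    random_intercept_sd: float = 0.05,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Participant x ROI x condition HbDiff records with known slopes.

    ``slopes`` maps (roi, condition) to the effect of the (z-scored)
    per-condition mean estimation error on HbDiff; missing cells get 0.
    ``moderation`` adds a body-competence interaction: the error slope
    becomes slope + moderation * bc_z. The error predictor is z-scored
    within the generated sample so configured slopes are exactly on the
    scale the model estimates.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6)))
    slopes = slopes or {}
    roi_intercepts = roi_intercepts or {}
    pids = [f"P{i:03d}" for i in range(n_participants)]
    err = {c: zscore(rng.normal(0.0, 1.0, size=n_participants)) for c in ("performed", "unknown")}
    recog = rng.uniform(0.4, 0.95, size=n_participants)
    enjoy = np.clip(rng.normal(50.0, 12.0, size=n_participants), 0, 100)
    bc_z = zscore(rng.normal(0.0, 1.0, size=n_participants))
    u = rng.normal(0.0, random_intercept_sd, size=n_participants)
    rows = []
    for i, pid in enumerate(pids):
        for roi in ROIS:
            for cond in ("performed", "unknown"):
                slope = slopes.get((roi, cond), 0.0) + moderation * bc_z[i]
                hb = (
                    roi_intercepts.get(roi, 0.0)
                    + slope * err[cond][i]
                    + u[i]
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "roi": roi,
                        "condition": cond,
                        "hbdiff": hb,
                        "mean_estimation_error": err[cond][i],
                        "recognition_rate": recog[i],
                        "mean_enjoyment": enjoy[i],
                        "body_competence_z": bc_z[i],
                    }
                )
    return pd.DataFrame(rows)
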