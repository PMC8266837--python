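"""Seeded synthetic multimodal scan-session generator.

Generates full scan sessions whose statistical structure matches a routine
second-trimester scanning workload: scan durations from a truncated-normal
model, an anatomy timeline from a semi-Markov process whose long-run label
time fractions equal the configured shares, machine UI events (freeze /
save / biometric measurement displays) at segment boundaries, a gaze point
stream with an image-centered attractor and measurement-box glances, a
scripted smooth transducer trajectory rendered as a 100 Hz IMU stream with
ground-truth orientation, and sonographer utterances sampled from a tagged
lexicon.  Everything is reproducible from the configuration seed plus the
scan index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import clips as _clips
from .language import DEFAULT_LEXICON
from .reference import (
    ANATOMY_LABELS,
    GAZE_SAMPLE_RATE_HZ,
    IMU_SAMPLE_RATE_HZ,
    POS_TAGS,
    POS_TOKEN_PCT,
    SCAN_DURATION_BOUNDS_MIN,
    SCAN_DURATION_MEAN_MIN,
    SCAN_DURATION_SD_MIN,
    SCAN_TIME_SHARE_PCT,
    SCREEN_HEIGHT,
    SCREEN_WIDTH,
    VIDEO_FRAME_RATE_HZ,
    normalized_shares,
)
from .screen import DEFAULT_AOIS, IMAGE_AREA, MEASUREMENT_BOX
from .session import LabelSegment, MachineEvent, ScanSession, validate_timeline
from .workflow import label_centroids

ALL_STREAMS = ("ui", "gaze", "imu", "transcript", "clips")

#: Typical biometric measurement display values (mm): mean and SD per type.
_MEASUREMENT_VALUE_MODEL = {"HC": (175.0, 10.0), "AC": (150.0, 12.0), "FL": (34.0, 3.0)}


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Defaults encode the reference workload: 30 fps video, 90 Hz gaze,
    100 Hz IMU, truncated-normal scan durations of 36.2 +/- 11.6 min on
    [10, 90], and label time shares from the reference share table.
    """

    seed: int = 0
    frame_rate: float = VIDEO_FRAME_RATE_HZ
    gaze_rate: float = GAZE_SAMPLE_RATE_HZ
    imu_rate: float = IMU_SAMPLE_RATE_HZ
    duration_mean: float = SCAN_DURATION_MEAN_MIN          # minutes
    duration_sd: float = SCAN_DURATION_SD_MIN              # minutes
    duration_bounds: tuple[float, float] = SCAN_DURATION_BOUNDS_MIN
    label_set: tuple[str, ...] = ANATOMY_LABELS
    time_shares: dict[str, float] = field(
        default_factory=lambda: normalized_shares(SCAN_TIME_SHARE_PCT)
    )
    #: Dirichlet concentration of per-scan share perturbations (None: off).
    share_concentration: Optional[float] = 60.0
    dwell_shape: float = 2.0
    #: Mean segment dwell (seconds); scalar or per-label mapping.
    mean_dwell_s: float | dict[str, float] = 20.0
    #: Freeze probability per segment; save probabilities per freeze.
    event_rates: dict[str, float] = field(
        default_factory=lambda: {"freeze": 0.6, "image_save": 0.5, "clip_save": 0.1}
    )
    #: Biometric measurement displays per scan, by type.
    measurement_plan: dict[str, int] = field(
        default_factory=lambda: {"HC": 1, "AC": 2, "FL": 1}
    )
    #: Probability that the sonographer glances at the measurement box
    #: around a measurement display.
    p_measurement_glance: float = 0.93
    gaze_sigma_px: float = 12.0
    gaze_dropout: float = 0.02
    gyro_sigma: float = 0.005       # rad/s
    accel_sigma: float = 0.05       # m/s^2
    mag_sigma: float = 0.01
    #: Scripted-motion scales: rotation amplitude (rad) and translation
    #: amplitude (m) of the smooth sinusoidal transducer trajectory.
    rot_amp_rad: float = 0.35
    trans_amp_m: float = 0.01
    pos_weights: dict[str, float] = field(
        default_factory=lambda: {t: p / 100.0 for t, p in POS_TOKEN_PCT.items()}
    )
    lexicon: Optional[dict[str, str]] = None
    utterance_rate: float = 0.4     # sentences per timeline segment
    max_sentence_words: int = 83
    feature_noise: float = 0.35
    streams: tuple[str, ...] = ALL_STREAMS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.time_shares.values()) - 1.0) > 1e-9:
            raise ConfigError("time_shares: must sum to 1 within 1e-9")
        if set(self.time_shares) != set(self.label_set):
            raise ConfigError("time_shares: keys must match label_set")
        if any(v < 0 for v in self.time_shares.values()):
            raise ConfigError("time_shares: negative share")
        if abs(sum(self.pos_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("pos_weights: must sum to 1 within 1e-9")
        if set(self.pos_weights) != set(POS_TAGS):
            raise ConfigError("pos_weights: keys must be the five POS tags")
        for name in ("frame_rate", "gaze_rate", "imu_rate", "duration_mean",
                     "duration_sd", "dwell_shape"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be strictly positive")
        lo, hi = self.duration_bounds
        if not lo < self.duration_mean < hi:
            raise ConfigError("duration_bounds: must bracket duration_mean")
        dwell = self.mean_dwell_s
        if isinstance(dwell, dict):
            if any(v <= 0 for v in dwell.values()):
                raise ConfigError("mean_dwell_s: dwell means must be positive")
        elif dwell <= 0:
            raise ConfigError("mean_dwell_s: must be positive")
        for k, v in self.event_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"event_rates[{k}]: probability outside [0, 1]")
        if any(v < 0 for v in self.measurement_plan.values()):
            raise ConfigError("measurement_plan: counts must be non-negative")
        unknown = set(self.streams) - set(ALL_STREAMS)
        if unknown:
            raise ConfigError(f"streams: unknown stream names {sorted(unknown)}")

    def dwell_means(self) -> np.ndarray:
        if isinstance(self.mean_dwell_s, dict):
            return np.array([self.mean_dwell_s[lab] for lab in self.label_set])
        return np.full(len(self.label_set), float(self.mean_dwell_s))


def _scan_rng(config: GeneratorConfig, scan_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(int(scan_index),))
    )


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------


def sample_duration(config: GeneratorConfig, rng: np.random.Generator) -> float:
    """One scan duration (seconds): truncated normal by resampling."""
    lo, hi = config.duration_bounds
    while True:
        d = rng.normal(config.duration_mean, config.duration_sd)
        if lo <= d <= hi:
            return d * 60.0


def sample_durations(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """n scan durations in minutes (vector form of :func:`sample_duration`)."""
    return np.array([sample_duration(config, rng) for _ in range(n)]) / 60.0


def sample_timeline(
    config: GeneratorConfig, duration: float, rng: np.random.Generator
) -> list[LabelSegment]:
    """Semi-Markov anatomy timeline covering [0, duration].

    Labels are drawn with probability proportional to ``share / mean_dwell``
    so the long-run time fraction of each label equals its configured share;
    dwell times are gamma with the configured shape.  Per-scan shares are
    first perturbed by a Dirichlet draw to model between-scan variability.
    """
    shares = np.array([config.time_shares[lab] for lab in config.label_set])
    if config.share_concentration and np.count_nonzero(shares) > 1:
        pos = shares > 0
        perturbed = np.zeros_like(shares)
        perturbed[pos] = rng.dirichlet(config.share_concentration * shares[pos])
        shares = perturbed
    dwell = config.dwell_means()
    p = shares / dwell
    p = p / p.sum()
    scale = dwell / config.dwell_shape

    segments: list[LabelSegment] = []
    t = 0.0
    while t < duration:
        k = rng.choice(len(p), p=p)
        d = rng.gamma(config.dwell_shape, scale[k])
        end = min(t + max(d, 1e-3), duration)
        segments.append(LabelSegment(config.label_set[k], t, end))
        t = end
    return segments


def _synth_ui(
    config: GeneratorConfig,
    timeline: Sequence[LabelSegment],
    duration: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[MachineEvent]]:
    """Per-frame UI table plus the ground-truth machine event list."""
    fps = config.frame_rate
    n_frames = int(round(duration * fps))
    frozen = np.zeros(n_frames, dtype=bool)
    save_kind = np.full(n_frames, "", dtype=object)
    meas_type = np.full(n_frames, "", dtype=object)
    meas_value = np.full(n_frames, np.nan)

    # Freeze intervals: at most one per segment, in the later part of the
    # segment, separated by >= 1 s so measurement debouncing never merges
    # displays across acquisitions.
    min_gap_frames = int(np.ceil(fps))
    intervals: list[tuple[int, int]] = []  # inclusive frame ranges
    p_freeze = config.event_rates.get("freeze", 0.0)
    segment_order = list(range(len(timeline)))
    planned = [i for i in segment_order if rng.random() < p_freeze]
    total_meas = sum(config.measurement_plan.values())
    # guarantee enough freezes to host every planned measurement display
    extra = [i for i in segment_order if i not in planned]
    rng.shuffle(extra)
    while len(planned) < total_meas and extra:
        planned.append(extra.pop())
    planned.sort()

    last_end = -min_gap_frames - 1
    for i in planned:
        seg = timeline[i]
        # freeze length capped well below the segment so a start slot always
        # exists in the later part of the segment
        fdur = min(rng.uniform(2.0, 6.0), 0.6 * seg.duration)
        t0 = rng.uniform(seg.start + 0.2 * seg.duration, seg.end - fdur)
        f0 = int(np.ceil(t0 * fps))
        f1 = min(int(np.floor((t0 + fdur) * fps)), n_frames - 1)
        if f0 <= last_end + min_gap_frames or f1 - f0 < 3:
            continue
        intervals.append((f0, f1))
        frozen[f0 : f1 + 1] = True
        last_end = f1

    # Fallback: if the random plan produced fewer freezes than planned
    # measurement displays, carve extra freeze intervals out of the longest
    # unfrozen stretches so every planned display has a host acquisition.
    need = int(np.ceil(3.0 * fps))
    while len(intervals) < total_meas:
        gaps = []
        prev = -1
        for g0, g1 in sorted(intervals):
            gaps.append((prev + 1 + min_gap_frames, g0 - 1 - min_gap_frames))
            prev = g1
        gaps.append((prev + 1 + min_gap_frames, n_frames - 1 - min_gap_frames))
        usable = [(lo, hi) for lo, hi in gaps if hi - lo + 1 >= need]
        if not usable:
            raise ValueError("scan too short to host the configured measurement_plan")
        lo, hi = max(usable, key=lambda g: g[1] - g[0])
        mid = (lo + hi) // 2
        f0 = mid - need // 2
        f1 = f0 + need - 1
        intervals.append((f0, f1))
        intervals.sort()
        frozen[f0 : f1 + 1] = True

    freeze_events: list[MachineEvent] = []
    save_events: list[MachineEvent] = []
    meas_events: list[MachineEvent] = []
    for f0, f1 in intervals:
        freeze_events.append(MachineEvent("freeze_on", f0 / fps, f0))
        if f1 + 1 < n_frames:
            freeze_events.append(MachineEvent("freeze_off", (f1 + 1) / fps, f1 + 1))
        candidates = list(range(f0 + max(3, int(0.3 * fps)), f1 + 1))
        rng.shuffle(candidates)
        for kind in ("image_save", "clip_save"):
            if candidates and rng.random() < config.event_rates.get(kind, 0.0):
                fs = candidates.pop()
                save_kind[fs] = kind
                save_events.append(MachineEvent(kind, fs / fps, fs))

    # Biometric measurement displays, each hosted by its own freeze interval.
    plan = [t for t, c in sorted(config.measurement_plan.items()) for _ in range(c)]
    rng.shuffle(plan)
    host = rng.permutation(len(intervals))[: len(plan)]
    for mtype, idx in zip(plan, sorted(host)):
        f0, f1 = intervals[idx]
        fm = int(rng.integers(f0 + 2, max(f0 + 3, f1 - 2)))
        mean, sd = _MEASUREMENT_VALUE_MODEL[mtype]
        value = round(max(1.0, rng.normal(mean, sd)), 1)
        meas_type[fm : f1 + 1] = mtype
        meas_value[fm : f1 + 1] = value
        meas_events.append(
            MachineEvent(
                "measurement_display", fm / fps, fm, {"type": mtype, "value_mm": value}
            )
        )

    thermal = np.clip(
        0.4 + np.cumsum(rng.normal(0.0, 0.002, n_frames)), 0.1, 1.5
    ).round(1)

    ui = pd.DataFrame(
        {
            "frame_index": np.arange(n_frames, dtype=np.int64),
            "frozen": frozen,
            "save_kind": save_kind,
            "meas_type": meas_type,
            "meas_value": meas_value,
            "thermal_index": thermal,
        }
    )
    events = sorted(
        freeze_events + save_events + meas_events, key=lambda e: (e.t, e.frame_index)
    )
    return ui, events


def _synth_gaze(
    config: GeneratorConfig,
    duration: float,
    meas_events: Sequence[MachineEvent],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gaze point stream: image-centered attractor with measurement glances."""
    n = int(np.floor(duration * config.gaze_rate))
    t = np.arange(n) / config.gaze_rate
    cx, cy = IMAGE_AREA.center
    ax = np.full(n, cx)
    ay = np.full(n, cy)
    mx, my = MEASUREMENT_BOX.center
    for e in meas_events:
        if rng.random() < config.p_measurement_glance:
            # keep the glance inside the recorded stream even for displays
            # right at the end of the scan
            g0 = min(e.t + rng.uniform(0.0, 1.0), max(0.0, duration - 0.9))
            mask = (t >= g0) & (t <= g0 + 0.8)
            ax[mask] = mx
            ay[mask] = my
    x = np.clip(ax + rng.normal(0.0, config.gaze_sigma_px, n), 0, SCREEN_WIDTH - 1)
    y = np.clip(ay + rng.normal(0.0, config.gaze_sigma_px, n), 0, SCREEN_HEIGHT - 1)
    valid = rng.random(n) >= config.gaze_dropout
    return pd.DataFrame({"t": t, "x": x, "y": y, "valid": valid})


def _sinusoid_bank(
    rng: np.random.Generator, amp: float, f_lo: float, f_hi: float, k: int = 2
):
    amps = rng.uniform(0.4 * amp, amp, k)
    freqs = rng.uniform(f_lo, f_hi, k)
    phases = rng.uniform(0.0, 2 * np.pi, k)

    def value(t: np.ndarray) -> np.ndarray:
        return sum(a * np.sin(2 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases))

    def rate(t: np.ndarray) -> np.ndarray:
        return sum(
            a * 2 * np.pi * f * np.cos(2 * np.pi * f * t + p)
            for a, f, p in zip(amps, freqs, phases)
        )

    def accel(t: np.ndarray) -> np.ndarray:
        return sum(
            -a * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t + p)
            for a, f, p in zip(amps, freqs, phases)
        )

    return value, rate, accel


def _synth_imu(
    config: GeneratorConfig, duration: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scripted smooth transducer trajectory rendered as an IMU stream.

    Attitude follows sinusoidal yaw/pitch/roll time courses (aerospace ZYX
    convention, world z up); body angular rates come from the exact Euler
    kinematics, so the gyro, accelerometer and magnetometer channels are
    mutually consistent with the ground-truth orientation.
    """
    from .motion import GRAVITY, MAG_REF

    n = int(np.floor(duration * config.imu_rate)) + 1
    t = np.arange(n) / config.imu_rate

    roll_f, roll_r, _ = _sinusoid_bank(rng, config.rot_amp_rad, 0.05, 0.3)
    pitch_f, pitch_r, _ = _sinusoid_bank(rng, 0.6 * config.rot_amp_rad, 0.05, 0.3)
    yaw_f, yaw_r, _ = _sinusoid_bank(rng, config.rot_amp_rad, 0.05, 0.3)
    roll, droll = roll_f(t), roll_r(t)
    pitch, dpitch = pitch_f(t), pitch_r(t)
    yaw, dyaw = yaw_f(t), yaw_r(t)

    # body angular rates for R = Rz(yaw) Ry(pitch) Rx(roll)
    gx = droll - dyaw * np.sin(pitch)
    gy = dpitch * np.cos(roll) + dyaw * np.cos(pitch) * np.sin(roll)
    gz = -dpitch * np.sin(roll) + dyaw * np.cos(pitch) * np.cos(roll)

    acc_w = np.zeros((n, 3))
    for axis in range(3):
        _, _, a_fn = _sinusoid_bank(rng, config.trans_amp_m, 0.1, 0.8)
        acc_w[:, axis] = a_fn(t)

    rot = Rotation.from_euler("ZYX", np.column_stack([yaw, pitch, roll]))
    accel_body = rot.apply(acc_w - GRAVITY, inverse=True)
    mag_body = rot.apply(np.tile(MAG_REF, (n, 1)), inverse=True)

    gyro = np.column_stack([gx, gy, gz])
    if config.gyro_sigma > 0:
        gyro = gyro + rng.normal(0.0, config.gyro_sigma, (n, 3))
    if config.accel_sigma > 0:
        accel_body = accel_body + rng.normal(0.0, config.accel_sigma, (n, 3))
    if config.mag_sigma > 0:
        mag_body = mag_body + rng.normal(0.0, config.mag_sigma, (n, 3))
    mag_body = mag_body / np.linalg.norm(mag_body, axis=1, keepdims=True)

    xyzw = rot.as_quat()
    quats = np.column_stack([xyzw[:, 3], xyzw[:, 0], xyzw[:, 1], xyzw[:, 2]])
    flip = quats[:, 0] < 0
    quats[flip] = -quats[flip]

    imu = pd.DataFrame(
        {
            "t": t,
            "gx": gyro[:, 0], "gy": gyro[:, 1], "gz": gyro[:, 2],
            "ax": accel_body[:, 0], "ay": accel_body[:, 1], "az": accel_body[:, 2],
            "mx": mag_body[:, 0], "my": mag_body[:, 1], "mz": mag_body[:, 2],
        }
    )
    truth = pd.DataFrame(
        {
            "t": t,
            "qw": quats[:, 0], "qx": quats[:, 1], "qy": quats[:, 2], "qz": quats[:, 3],
            "lax": acc_w[:, 0], "lay": acc_w[:, 1], "laz": acc_w[:, 2],
        }
    )
    return imu, truth


def sample_transcript(
    config: GeneratorConfig, n_sentences: int, rng: np.random.Generator
) -> list[list[str]]:
    """Sample sonographer utterances from the tagged lexicon.

    Each word is drawn by first sampling a POS tag from ``pos_weights``,
    then a word uniformly from that tag's lexicon entries.
    """
    lexicon = config.lexicon if config.lexicon is not None else DEFAULT_LEXICON
    by_tag: dict[str, list[str]] = {tag: [] for tag in POS_TAGS}
    for word, tag in lexicon.items():
        by_tag[tag].append(word)
    for tag in POS_TAGS:
        if config.pos_weights[tag] > 0 and not by_tag[tag]:
            raise ConfigError(f"lexicon: no words available for tag {tag!r}")
        by_tag[tag].sort()
    weights = np.array([config.pos_weights[tag] for tag in POS_TAGS])

    sentences = []
    for _ in range(n_sentences):
        length = 1 + min(int(rng.poisson(7)), config.max_sentence_words - 1)
        tags = rng.choice(len(POS_TAGS), size=length, p=weights)
        sentences.append(
            [by_tag[POS_TAGS[k]][rng.integers(len(by_tag[POS_TAGS[k]]))] for k in tags]
        )
    return sentences


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def simulate_session(config: GeneratorConfig, scan_id: int) -> ScanSession:
    """Generate one fully reproducible synthetic scan session.

    ``scan_id`` is the integer scan index; together with ``config.seed`` it
    determines every stream.  Which streams are generated is controlled by
    ``config.streams`` (the ground-truth timeline is always present).
    """
    rng = _scan_rng(config, scan_id)
    duration = sample_duration(config, rng)
    timeline = sample_timeline(config, duration, rng)
    validate_timeline(timeline, duration)

    session = ScanSession(
        scan_id=f"scan_{int(scan_id):04d}",
        seed=int(config.seed),
        duration=duration,
        frame_rate=config.frame_rate,
        timeline=timeline,
    )

    if "ui" in config.streams:
        session.ui, session.ui_events = _synth_ui(config, timeline, duration, rng)
    if "gaze" in config.streams:
        meas = [e for e in session.ui_events if e.kind == "measurement_display"]
        session.gaze = _synth_gaze(config, duration, meas, rng)
    if "imu" in config.streams:
        session.imu, session.imu_truth = _synth_imu(config, duration, rng)
    if "transcript" in config.streams:
        n_utter = int(rng.binomial(len(timeline), min(1.0, config.utterance_rate)))
        session.transcript = sample_transcript(config, n_utter, rng)
    if "clips" in config.streams and session.ui_events:
        truth_clips = _clips.extract_clips(
            session.ui_events, duration, scan_id=session.scan_id
        )
        _clips.label_clips(truth_clips, timeline)
        cents = label_centroids(config.label_set)
        feats = np.stack(
            [cents[c.label] for c in truth_clips]
        ) + rng.normal(0.0, config.feature_noise, (len(truth_clips), len(config.label_set)))
        session.clips_truth = pd.DataFrame(
            {
                "clip_id": [c.clip_id for c in truth_clips],
                "t_start": [c.t_start for c in truth_clips],
                "t_end": [c.t_end for c in truth_clips],
                "anchor": [c.anchor_event for c in truth_clips],
                "label": [c.label for c in truth_clips],
            }
        )
        session.clip_features = feats
    return session


def simulate_cohort(config: GeneratorConfig, n_scans: int) -> list[ScanSession]:
    """Generate ``n_scans`` independent sessions (scan indices 0..n-1)."""
    return [simulate_session(config, i) for i in range(n_scans)]


def timeline_only(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config generating only the ground-truth timeline (fast)."""
    return replace(config, streams=())


def plant_fixation(
    session: ScanSession, aoi_name: str, t_start: float, dwell_ms: float
) -> ScanSession:
    """Relocate gaze samples in a window into a named AOI (test fixture).

    Samples with ``t_start <= t <= t_start + dwell_ms/1000`` are moved to
    the AOI center and marked valid; all other samples are untouched.
    """
    if session.gaze is None:
        raise ValueError("session has no gaze stream")
    if aoi_name not in DEFAULT_AOIS:
        raise KeyError(f"unknown AOI {aoi_name!r}")
    t_end = t_start + dwell_ms / 1000.0
    if t_start < 0 or t_end > session.duration:
        raise ValueError(
            f"fixation window [{t_start}, {t_end}] outside scan [0, {session.duration}]"
        )
    aoi = DEFAULT_AOIS[aoi_name]
    cx, cy = aoi.center
    mask = (session.gaze["t"] >= t_start) & (session.gaze["t"] <= t_end)
    session.gaze.loc[mask, "x"] = cx
    session.gaze.loc[mask, "y"] = cy
    session.gaze.loc[mask, "valid"] = True
    return session
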