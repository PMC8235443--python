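"""Synthetic paired silhouette-video / wrist-accelerometer cohorts.

Generates fully in-memory (or on-disk) cohorts of spousal subject pairs,
one Parkinson's disease (PD) subject and one healthy control (HC) per
pair, performing kitchen-style activity.  The two streams carry
complementary, class-dependent structure:

* the binary silhouette video shows a body-shaped blob whose centroid
  drifts at a class-dependent walking speed (bradykinesia: PD slower),
  with slow postural sway and a tremor-driven oscillation of one arm;
* the tri-axial wrist acceleration contains a gravity offset, a
  low-frequency (<2 Hz) activity component whose amplitude is lower for
  PD, a 4-6 Hz tremor sinusoid present only in PD, and white noise.

Every output is a pure function of the subject profile (which carries
its own seed), so cohorts are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SubjectProfile",
    "CohortParams",
    "SilhouetteSequence",
    "RawAccelSequence",
    "generate_cohort",
    "render_silhouette_sequence",
    "synthesize_accel",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: default silhouette frame rate, frames/s
DEFAULT_FPS = 8.0
#: default accelerometer sampling rate, Hz (wrist-worn logger)
DEFAULT_ACCEL_RATE = 100.0
#: default synthetic frame size (quarter linear scale of a 256x320 camera)
DEFAULT_HEIGHT, DEFAULT_WIDTH = 64, 80
#: silhouette-domain tremor displacement per unit acceleration, pixels/g
TREMOR_PX_PER_G = 12.0


@dataclass(frozen=True)
class SubjectProfile:
    """Movement phenotype of one simulated subject.

    ``walk_speed`` is the centroid drift rate in pixels/frame,
    ``posture_sway`` the slow positional jitter amplitude in pixels,
    ``tremor_amp`` the tremor acceleration amplitude in g (0 for HC),
    ``tremor_freq`` the tremor frequency in Hz (resting-tremor band),
    ``base_activity_amp`` the low-frequency activity amplitude in g.
    """

    subject_id: str
    pair_id: int
    label: str  # "PD" or "HC"
    walk_speed: float
    posture_sway: float
    tremor_amp: float
    tremor_freq: float
    base_activity_amp: float
    duration: float
    seed: int

    def __post_init__(self):
        if self.label not in ("PD", "HC"):
            raise ValueError(f"label must be 'PD' or 'HC', got {self.label!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.label == "PD" and not 4.0 <= self.tremor_freq <= 6.0:
            raise ValueError("PD tremor_freq must lie in the 4-6 Hz resting-tremor band")
        if self.label == "PD" and self.tremor_amp <= 0:
            raise ValueError("PD subjects must have positive tremor amplitude")


@dataclass(frozen=True)
class CohortParams:
    """Class-conditional distributions the cohort is drawn from.

    Defaults encode a clearly expressed motor phenotype: PD subjects walk
    slower (bradykinesia), generate less low-frequency movement energy,
    and carry a 4-6 Hz resting tremor absent in controls.  Amplitudes are
    in g, speeds in pixels/frame at the default 64x80 frame scale.
    """

    hc_walk_speed_mean: float = 1.4
    hc_walk_speed_sd: float = 0.20
    pd_walk_speed_mean: float = 0.6
    pd_walk_speed_sd: float = 0.10
    posture_sway: float = 1.5
    pd_tremor_amp_mean: float = 0.25
    pd_tremor_amp_sd: float = 0.05
    tremor_freq_low: float = 4.0
    tremor_freq_high: float = 6.0
    hc_base_activity_amp: float = 0.30
    pd_base_activity_amp: float = 0.18
    base_activity_sd: float = 0.04
    duration: float = 120.0


@dataclass
class SilhouetteSequence:
    """Ordered binary frames with strictly increasing timestamps."""

    frames: np.ndarray  # (N, H, W) uint8 in {0, 1}
    fps: float
    timestamps: np.ndarray  # (N,) seconds
    subject_id: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RawAccelSequence:
    """Timestamped tri-axial acceleration series in g units."""

    samples: np.ndarray  # (T, 3) float, axes (x, y, z)
    rate: float
    timestamps: np.ndarray  # (T,) seconds
    subject_id: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be a (T, 3) array")
        if len(self.timestamps) != len(self.samples):
            raise ValueError("timestamps and samples must have equal length")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def generate_cohort(
    n_pairs: int,
    params: CohortParams | None = None,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Draw ``2 * n_pairs`` subject profiles, one PD and one HC per pair.

    Profiles are a deterministic function of ``(n_pairs, params, seed)``.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    for pair in range(n_pairs):
        for label in ("PD", "HC"):
            if label == "PD":
                # clipping keeps every PD subject below the HC class mean
                walk = float(np.clip(rng.normal(p.pd_walk_speed_mean, p.pd_walk_speed_sd),
                                     0.1, 0.75 * p.hc_walk_speed_mean))
                tremor_amp = float(np.clip(rng.normal(p.pd_tremor_amp_mean, p.pd_tremor_amp_sd),
                                           0.05, None))
                tremor_freq = float(rng.uniform(p.tremor_freq_low, p.tremor_freq_high))
                activity = float(np.clip(rng.normal(p.pd_base_activity_amp, p.base_activity_sd),
                                         0.02, None))
            else:
                walk = float(np.clip(rng.normal(p.hc_walk_speed_mean, p.hc_walk_speed_sd),
                                     p.hc_walk_speed_mean - 2.5 * p.hc_walk_speed_sd, None))
                tremor_amp = 0.0
                tremor_freq = 5.0  # unused when amplitude is zero
                activity = float(np.clip(rng.normal(p.hc_base_activity_amp, p.base_activity_sd),
                                         0.02, None))
            profiles.append(
                SubjectProfile(
                    subject_id=f"pair{pair:02d}_{label.lower()}",
                    pair_id=pair,
                    label=label,
                    walk_speed=walk,
                    posture_sway=p.posture_sway,
                    tremor_amp=tremor_amp,
                    tremor_freq=tremor_freq,
                    base_activity_amp=activity,
                    duration=p.duration,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return profiles


def _body_mask(
    yy: np.ndarray,
    xx: np.ndarray,
    cx: float,
    cy: float,
    scale: float,
    arm_dx: float,
) -> np.ndarray:
    """Rasterise a standing body: head, torso ellipse, legs, and two arms.

    ``arm_dx`` displaces the right hand blob horizontally (tremor)."""
    head_r = 0.10 * scale
    torso_a, torso_b = 0.16 * scale, 0.26 * scale  # half-width, half-height
    head_cy = cy - torso_b - head_r
    mask = ((xx - cx) / torso_a) ** 2 + ((yy - cy) / torso_b) ** 2 <= 1.0
    mask |= (xx - cx) ** 2 + (yy - head_cy) ** 2 <= head_r**2
    # legs: two vertical strokes below the torso
    leg_top = cy + 0.8 * torso_b
    leg_bot = cy + torso_b + 0.34 * scale
    leg_w = 0.05 * scale
    for side in (-1.0, 1.0):
        lx = cx + side * 0.08 * scale
        mask |= (np.abs(xx - lx) <= leg_w) & (yy >= leg_top) & (yy <= leg_bot)
    # arms: strokes beside the torso; right hand blob carries the tremor
    arm_w = 0.045 * scale
    arm_top = cy - 0.8 * torso_b
    arm_bot = cy + 0.3 * torso_b
    for side in (-1.0, 1.0):
        ax = cx + side * (torso_a + 0.07 * scale)
        mask |= (np.abs(xx - ax) <= arm_w) & (yy >= arm_top) & (yy <= arm_bot)
    hand_r = 0.07 * scale
    hand_x = cx + torso_a + 0.07 * scale + arm_dx
    hand_y = cy + 0.45 * torso_b
    mask |= (xx - hand_x) ** 2 + (yy - hand_y) ** 2 <= hand_r**2
    return mask


def _waypoint_walk(
    rng: np.random.Generator,
    n: int,
    span: float,
    speed: float,
    dwell_frames_mean: float,
) -> np.ndarray:
    """Piecewise station-to-station walk: dwell, then transit at ``speed``.

    With ``dwell_frames_mean == 0`` the walk is continuous (no pauses),
    so the centroid path length over k frames is exactly k * speed.
    Positions are returned in [0, span]."""
    pos = np.empty(n)
    x = rng.uniform(0.0, span)
    i = 0
    while i < n:
        if dwell_frames_mean > 0:
            dwell = int(rng.uniform(0.5, 1.5) * dwell_frames_mean)
            stop = min(i + dwell, n)
            pos[i:stop] = x
            i = stop
            if i >= n:
                break
        # next station at least 30% of the span away
        target = rng.uniform(0.0, span)
        while abs(target - x) < 0.3 * span:
            target = rng.uniform(0.0, span)
        step = speed if speed > 0 else 0.0
        if step == 0.0:
            pos[i:] = x
            break
        n_steps = max(int(np.ceil(abs(target - x) / step)), 1)
        direction = np.sign(target - x)
        stop = min(i + n_steps, n)
        pos[i:stop] = x + direction * step * np.arange(1, stop - i + 1)
        x = float(pos[stop - 1]) if stop > i else x
        i = stop
    return np.clip(pos, 0.0, span)


def render_silhouette_sequence(
    profile: SubjectProfile,
    height: int = DEFAULT_HEIGHT,
    width: int = DEFAULT_WIDTH,
    fps: float = DEFAULT_FPS,
    dwell_mean: float = 4.0,
) -> SilhouetteSequence:
    """Render a binary body-shaped blob working at and walking between
    kitchen stations.

    The centroid dwells at stations (``dwell_mean`` seconds on average, default 4;
    0 disables pauses) and transits between them at ``walk_speed``
    pixels/frame, with ``posture_sway`` slow jitter throughout; one hand
    oscillates at ``tremor_freq`` scaled by ``tremor_amp``.  Frame count
    is ``floor(duration * fps)``.
    """
    scale = 0.75 * height
    half_w = 0.30 * scale  # half-extent of the template incl. tremor margin
    half_h = 0.62 * scale
    x_min, x_max = half_w + 1.0, width - half_w - 2.0
    y_mid = height / 2.0
    if x_min >= x_max or half_h * 2 >= height - 2:
        raise ValueError(
            f"body template (scale {scale:.0f} px) does not fit in a {height}x{width} frame"
        )
    n = int(np.floor(profile.duration * fps))
    rng = np.random.default_rng(profile.seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float32)
    t = np.arange(n) / fps

    span = x_max - x_min
    cx = x_min + _waypoint_walk(rng, n, span, profile.walk_speed, dwell_mean * fps)
    # slow postural sway on both axes (incommensurate low frequencies)
    sway_phase = rng.uniform(0, 2 * np.pi, size=2)
    sway_x = profile.posture_sway * np.sin(2 * np.pi * 0.31 * t + sway_phase[0])
    sway_y = profile.posture_sway * np.sin(2 * np.pi * 0.23 * t + sway_phase[1])
    # tremor displacement of the hand blob, attenuated g -> pixels
    trem_phase = rng.uniform(0, 2 * np.pi)
    arm_dx = TREMOR_PX_PER_G * profile.tremor_amp * np.sin(
        2 * np.pi * profile.tremor_freq * t + trem_phase
    )

    frames = np.empty((n, height, width), dtype=np.uint8)
    for i in range(n):
        mask = _body_mask(yy, xx, cx[i] + sway_x[i], y_mid + sway_y[i], scale, arm_dx[i])
        frames[i] = mask.astype(np.uint8)
    return SilhouetteSequence(
        frames=frames,
        fps=fps,
        timestamps=np.arange(n) / fps,
        subject_id=profile.subject_id,
    )


def synthesize_accel(
    profile: SubjectProfile,
    rate: float = DEFAULT_ACCEL_RATE,
    noise_sd: float = 0.03,
) -> RawAccelSequence:
    """Synthesise the wrist acceleration stream for one subject.

    Output = gravity offset + low-frequency (<2 Hz) activity component
    + tremor sinusoid on a wrist-dominant axis mix + white noise.
    Sample count is ``floor(duration * rate)``.
    """
    n = int(np.floor(profile.duration * rate))
    rng = np.random.default_rng(profile.seed + 1)
    t = np.arange(n) / rate

    tilt = rng.uniform(0.0, 0.25)  # radians off vertical
    azim = rng.uniform(0, 2 * np.pi)
    gravity = np.array([np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)])

    samples = np.tile(gravity, (n, 1))
    for axis in range(3):
        f1, f2 = rng.uniform(0.3, 1.8, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        samples[:, axis] += profile.base_activity_amp * (
            0.6 * np.sin(2 * np.pi * f1 * t + ph1) + 0.4 * np.sin(2 * np.pi * f2 * t + ph2)
        )
    if profile.tremor_amp > 0:
        mix = np.array([0.75, 0.60, 0.28])
        mix /= np.linalg.norm(mix)
        trem = profile.tremor_amp * np.sin(2 * np.pi * profile.tremor_freq * t + rng.uniform(0, 2 * np.pi))
        samples += trem[:, None] * mix
    samples += rng.normal(0.0, noise_sd, size=(n, 3))
    return RawAccelSequence(
        samples=samples,
        rate=rate,
        timestamps=np.arange(n) / rate,
        subject_id=profile.subject_id,
    )


def simulate_cohort(
    n_pairs: int,
    params: CohortParams | None = None,
    seed: int = 0,
    height: int = DEFAULT_HEIGHT,
    width: int = DEFAULT_WIDTH,
    fps: float = DEFAULT_FPS,
    accel_rate: float = DEFAULT_ACCEL_RATE,
) -> tuple[list[SubjectProfile], dict[str, tuple[SilhouetteSequence, RawAccelSequence]]]:
    """Generate profiles and render both streams for every subject."""
    profiles = generate_cohort(n_pairs, params, seed)
    sequences = {
        p.subject_id: (
            render_silhouette_sequence(p, height, width, fps),
            synthesize_accel(p, accel_rate),
        )
        for p in profiles
    }
    return profiles, sequences


def write_cohort(
    profiles: list[SubjectProfile],
    sequences: dict[str, tuple[SilhouetteSequence, RawAccelSequence]],
    out_dir: str | Path,
    silhouette_format: str = "npz",
) -> pd.DataFrame:
    """Write a cohort to disk and return its manifest.

    Silhouettes go to one packed ``.npz`` per subject (default) or to
    per-frame 8-bit PNGs (values 0/255) named ``<subject>/<index:06d>.png``
    with a frame-time sidecar CSV; acceleration goes to a
    ``timestamp,x,y,z`` CSV.  The manifest (one row per subject) is
    written as ``manifest.csv`` and the round trip through
    :func:`read_cohort` is lossless.
    """
    if silhouette_format not in ("npz", "png"):
        raise ValueError(f"silhouette_format must be 'npz' or 'png', got {silhouette_format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for profile in profiles:
        sid = profile.subject_id
        sil, acc = sequences[sid]
        try:
            if silhouette_format == "npz":
                sil_path = out / f"{sid}_silhouette.npz"
                np.savez_compressed(
                    sil_path, frames=sil.frames, timestamps=sil.timestamps, fps=sil.fps
                )
            else:
                sil_path = out / sid
                sil_path.mkdir(exist_ok=True)
                for i, frame in enumerate(sil.frames):
                    iio.imwrite(sil_path / f"{i:06d}.png", (frame * 255).astype(np.uint8))
                pd.DataFrame({"timestamp": sil.timestamps}).to_csv(
                    sil_path / "frame_times.csv", index=False
                )
            acc_path = out / f"{sid}_accel.csv"
            acc_df = pd.DataFrame(acc.samples, columns=["x", "y", "z"])
            acc_df.insert(0, "timestamp", acc.timestamps)
            # default float formatting is the shortest round-trip repr -> lossless
            acc_df.to_csv(acc_path, index=False)
        except OSError as err:
            raise OSError(f"failed writing data for {sid} under {out}: {err}") from err
        rows.append(
            {
                "subject_id": sid,
                "pair_id": profile.pair_id,
                "label": profile.label,
                "silhouette_path": str(sil_path.relative_to(out)),
                "silhouette_format": silhouette_format,
                "accel_path": str(acc_path.relative_to(out)),
                "fps": sil.fps,
                "accel_rate": acc.rate,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "profiles.json", "w") as fh:
        json.dump([dataclasses.asdict(p) for p in profiles], fh, indent=1)
    return manifest


def read_cohort(
    cohort_dir: str | Path,
) -> tuple[pd.DataFrame, dict[str, tuple[SilhouetteSequence, RawAccelSequence]]]:
    """Read a cohort written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    sequences: dict[str, tuple[SilhouetteSequence, RawAccelSequence]] = {}
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        sil_path = root / row["silhouette_path"]
        if row["silhouette_format"] == "npz":
            with np.load(sil_path) as z:
                sil = SilhouetteSequence(z["frames"], float(z["fps"]), z["timestamps"], sid)
        else:
            frame_files = sorted(sil_path.glob("[0-9]" * 6 + ".png"))
            frames = np.stack([(iio.imread(f) > 127).astype(np.uint8) for f in frame_files])
            times = pd.read_csv(sil_path / "frame_times.csv")["timestamp"].to_numpy()
            sil = SilhouetteSequence(frames, float(row["fps"]), times, sid)
        acc_df = pd.read_csv(root / row["accel_path"], float_precision="round_trip")
        acc = RawAccelSequence(
            acc_df[["x", "y", "z"]].to_numpy(),
            float(row["accel_rate"]),
            acc_df["timestamp"].to_numpy(),
            sid,
        )
        sequences[sid] = (sil, acc)
    return manifest, sequences
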