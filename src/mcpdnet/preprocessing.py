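"""Paired-input construction: multi-scale temporal silhouette encoding,
accelerometer resampling, and timestamp-synchronised pairing.

The silhouette stream is encoded by stacking running averages of the
last ``t_d`` binary frames at ``D`` time scales into one ``H x W x D``
input; the accelerometer stream is anti-alias resampled to a low rate
(10 Hz by default elsewhere) and cut into causal windows of ``t_D``
samples whose last sample is the nearest predecessor of the paired
silhouette frame's timestamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .synthetic import RawAccelSequence, SilhouetteSequence

__all__ = [
    "EncodingSpec",
    "EncodedSilhouetteInput",
    "AccelWindow",
    "PairedSample",
    "temporal_encode",
    "channel_spans",
    "resample_accel",
    "build_paired_dataset",
    "build_cohort_dataset",
    "normalize_for_display",
]


@dataclass(frozen=True)
class EncodingSpec:
    """Multi-scale temporal-averaging specification.

    ``intervals`` are window lengths in frames, strictly increasing; the
    defaults (5, 150, 250 frames at 8 fps) span sub-second posture up to
    half-minute mobility.
    """

    intervals: tuple[int, ...] = (5, 150, 250)
    fps: float = 8.0

    def __post_init__(self):
        ints = tuple(int(t) for t in self.intervals)
        object.__setattr__(self, "intervals", ints)
        if len(ints) < 1:
            raise ValueError("at least one interval is required")
        if any(t < 1 for t in ints):
            raise ValueError("intervals must be >= 1 frame")
        if any(b <= a for a, b in zip(ints, ints[1:])):
            raise ValueError("intervals must be strictly increasing")

    @property
    def depth(self) -> int:
        return len(self.intervals)

    @property
    def t_max(self) -> int:
        """Longest interval; also the earliest valid (1-based) frame index
        and the accelerometer window length in samples."""
        return self.intervals[-1]


@dataclass
class EncodedSilhouetteInput:
    """One ``H x W x D`` stack of temporal averages ending at a frame."""

    stack: np.ndarray  # (H, W, D) in [0, 1]
    frame_index: int  # 1-based index of the frame the stack ends at
    timestamp: float


@dataclass
class AccelWindow:
    """A ``t_D x 3`` resampled acceleration window paired to one frame."""

    window: np.ndarray  # (t_max, 3)
    frame_index: int
    end_timestamp: float


@dataclass
class PairedSample:
    """A synchronised (silhouette stack, accelerometer window) pair.

    Either element may be ``None`` downstream to model a missing
    modality at inference time; construction always fills both.
    """

    sil: EncodedSilhouetteInput | None
    acc: AccelWindow | None
    y: int  # 1 = PD, 0 = HC
    subject_id: str
    pair_id: int


def temporal_encode(
    seq: SilhouetteSequence, spec: EncodingSpec, i: int, dtype=np.float64
) -> EncodedSilhouetteInput:
    """Encode the silhouette stream at (1-based) frame index ``i``.

    Channel ``d`` is the arithmetic mean of the ``t_d`` frames ending at
    ``i``, i.e. frames ``i - t_d + 1 .. i``.  The earliest valid index is
    ``t_D`` (the longest interval).
    """
    t_max = spec.t_max
    if i < t_max:
        raise ValueError(
            f"frame index {i} underflows the longest window; earliest valid index is {t_max}"
        )
    if i > seq.n_frames:
        raise ValueError(f"frame index {i} beyond sequence of {seq.n_frames} frames")
    h, w = seq.frame_shape
    stack = np.empty((h, w, spec.depth), dtype=dtype)
    frames = seq.frames
    for d, t_d in enumerate(spec.intervals):
        # integer sum of 0/1 frames, then one exact division
        window_sum = frames[i - t_d : i].sum(axis=0, dtype=np.int64)
        stack[:, :, d] = window_sum / t_d
    return EncodedSilhouetteInput(
        stack=stack, frame_index=i, timestamp=float(seq.timestamps[i - 1])
    )


def channel_spans(spec: EncodingSpec, display: bool = False) -> list[float]:
    """Temporal span of each channel in seconds (``t_d / fps``).

    With ``display=True`` values are rounded half-up to one decimal, the
    convention used when quoting spans like 0.6 / 18.8 / 31.3 s.
    """
    if spec.fps <= 0:
        raise ValueError("fps must be positive")
    raw = [t / spec.fps for t in spec.intervals]
    if not display:
        return raw
    return [math.floor(v * 10 + 0.5) / 10 for v in raw]


def resample_accel(raw: RawAccelSequence, target_rate: float) -> RawAccelSequence:
    """Polyphase anti-aliased decimation of the acceleration stream.

    Output length is ``floor(duration * target_rate)`` with timestamps
    regenerated on the uniform target grid (starting at the original
    first timestamp).  Upsampling is not supported.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > raw.rate:
        raise ValueError(
            f"upsampling not supported: target {target_rate} Hz > source {raw.rate} Hz"
        )
    frac = Fraction(target_rate / raw.rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    n_out = int(np.floor(len(raw.samples) / raw.rate * target_rate))
    # linear-extension padding keeps the gravity offset exact at the edges
    out = resample_poly(raw.samples, up, down, axis=0, padtype="line")[:n_out]
    t0 = raw.timestamps[0] if len(raw.timestamps) else 0.0
    return RawAccelSequence(
        samples=out,
        rate=target_rate,
        timestamps=t0 + np.arange(n_out) / target_rate,
        subject_id=raw.subject_id,
    )


def build_paired_dataset(
    sil: SilhouetteSequence,
    acc: RawAccelSequence,
    spec: EncodingSpec,
    label: int,
    stride: int = 1,
    subject_id: str | None = None,
    pair_id: int = -1,
    dtype=np.float32,
) -> list[PairedSample]:
    """Emit synchronised samples at frame indices ``t_D, t_D+stride, ...``.

    For each valid frame the accelerometer window is the ``t_D`` samples
    whose last sample's timestamp is the nearest one at or before the
    frame's timestamp (causal pairing; an exact timestamp tie is the
    window end).  Frames with fewer than ``t_D`` preceding accelerometer
    samples, or whose nearest predecessor lags by more than one frame
    period, are skipped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    t_max = spec.t_max
    sid = subject_id or sil.subject_id
    frame_period = 1.0 / sil.fps
    # integer cumulative sum makes every channel an exact windowed mean
    cs = np.concatenate(
        [
            np.zeros((1,) + sil.frame_shape, dtype=np.int64),
            np.cumsum(sil.frames, axis=0, dtype=np.int64),
        ]
    )
    samples: list[PairedSample] = []
    acc_t = acc.timestamps
    for i in range(t_max, sil.n_frames + 1, stride):
        ts = float(sil.timestamps[i - 1])
        j = int(np.searchsorted(acc_t, ts, side="right")) - 1
        if j < t_max - 1:
            continue
        end_ts = float(acc_t[j])
        if ts - end_ts > frame_period:
            continue
        stack = np.empty(sil.frame_shape + (spec.depth,), dtype=dtype)
        for d, t_d in enumerate(spec.intervals):
            stack[:, :, d] = (cs[i] - cs[i - t_d]) / t_d
        samples.append(
            PairedSample(
                sil=EncodedSilhouetteInput(stack=stack, frame_index=i, timestamp=ts),
                acc=AccelWindow(
                    window=np.ascontiguousarray(acc.samples[j - t_max + 1 : j + 1], dtype=dtype),
                    frame_index=i,
                    end_timestamp=end_ts,
                ),
                y=int(label),
                subject_id=sid,
                pair_id=pair_id,
            )
        )
    if not samples:
        raise ValueError(
            "no paired samples could be built: silhouette spans "
            f"[{sil.timestamps[0]:.3f}, {sil.timestamps[-1]:.3f}] s, accelerometer spans "
            f"[{acc_t[0] if len(acc_t) else float('nan'):.3f}, "
            f"{acc_t[-1] if len(acc_t) else float('nan'):.3f}] s"
        )
    return samples


def build_cohort_dataset(
    manifest,
    sequences: dict[str, tuple[SilhouetteSequence, RawAccelSequence]],
    spec: EncodingSpec,
    stride: int = 1,
    target_rate: float = 10.0,
) -> list[PairedSample]:
    """Assemble the full paired dataset for a cohort.

    ``manifest`` is an iterable of mappings (or a DataFrame) with
    ``subject_id``, ``pair_id`` and ``label`` columns.  Each subject's
    accelerometer stream is resampled to ``target_rate`` before pairing.
    """
    rows = manifest.to_dict("records") if hasattr(manifest, "to_dict") else list(manifest)
    dataset: list[PairedSample] = []
    for row in rows:
        sid = row["subject_id"]
        sil, acc = sequences[sid]
        acc10 = resample_accel(acc, target_rate)
        dataset.extend(
            build_paired_dataset(
                sil,
                acc10,
                spec,
                label=1 if row["label"] == "PD" else 0,
                stride=stride,
                subject_id=sid,
                pair_id=int(row["pair_id"]),
            )
        )
    return dataset


def normalize_for_display(s: np.ndarray) -> np.ndarray:
    """Affine map of a signal to [0, 1]: ``(s - min) / (max - min)``.

    A constant signal maps to all zeros by convention.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("cannot normalise an empty array")
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)
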