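"""Audio input: WAV loading, resampling, peak normalization and framing.

Recordings are sustained-vowel phonations carrying a speaker id and a
normal/pathological label.  All analysis downstream works on float samples in
[-1, 1]; peak normalization removes recording gain so that level-based metrics
compare across recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from modspec.exceptions import (
    ChannelError,
    DegenerateSignalError,
    FormatError,
    TooShortError,
)

VALID_LABELS = ("normal", "pathological", "unknown")


@dataclass(frozen=True)
class Recording:
    """A mono recording with speaker/label metadata.

    samples are dimensionless floats; fs in Hz; label is one of
    ``normal`` / ``pathological`` / ``unknown``.
    """

    samples: np.ndarray
    fs: float
    speaker_id: str = ""
    label: str = "unknown"
    source_path: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ChannelError(f"expected a mono 1-D signal, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise FormatError("samples contain non-finite values")
        if self.label not in VALID_LABELS:
            raise FormatError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class FrameSet:
    """Equal-length windows cut from a recording, in temporal order."""

    frames: np.ndarray  # (n_frames, frame_len)
    frame_length_ms: float
    hop_ms: float
    recording: Recording

    def __len__(self) -> int:
        return self.frames.shape[0]


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Convert integer PCM (or float) WAV data to float64 in [-1, 1]."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        return (data.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise FormatError(f"unsupported WAV sample format {data.dtype}")


def resample(samples: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Band-limited polyphase resampling (Kaiser-windowed sinc filter).

    The rate ratio is approximated by a rational number with denominator
    <= 1000, exact for the common integer rates.
    """
    if fs == target_fs:
        return np.asarray(samples, dtype=np.float64)
    ratio = Fraction(int(round(target_fs)), int(round(fs))).limit_denominator(1000)
    return resample_poly(np.asarray(samples, dtype=np.float64), ratio.numerator, ratio.denominator)


def load_recording(
    path: str | Path,
    target_fs: float = 25_000.0,
    speaker_id: str = "",
    label: str = "unknown",
) -> Recording:
    """Read a mono PCM WAV, resample to ``target_fs`` and clip-free scale to [-1, 1].

    Raises ChannelError for multi-channel files and FormatError for
    unreadable or empty files.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        raise ChannelError(f"{path} has {data.shape[1]} channels; mono required")
    if data.size == 0:
        raise FormatError(f"{path} contains no samples")
    samples = resample(_pcm_to_float(data), fs, target_fs)
    return Recording(samples=samples, fs=target_fs, speaker_id=speaker_id, label=label, source_path=str(path))


def save_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV."""
    scaled = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(recording.fs)), (scaled * 32767.0).astype(np.int16))


def normalize(recording: Recording) -> Recording:
    """Scale so the maximum absolute sample is exactly 1 (peak normalization)."""
    peak = float(np.max(np.abs(recording.samples)))
    if peak == 0.0:
        raise DegenerateSignalError("cannot normalize an all-zero signal")
    return replace(recording, samples=recording.samples / peak)


def frame_signal(recording: Recording, frame_length_ms: float, hop_ms: float | None = None) -> FrameSet:
    """Cut the signal into frames of ``frame_length_ms``; default hop = frame length.

    A trailing partial frame is discarded.  Raises TooShortError if the signal
    does not contain one full frame.
    """
    if frame_length_ms < 1:
        raise TooShortError(f"frame_length_ms must be >= 1, got {frame_length_ms}")
    if hop_ms is None:
        hop_ms = frame_length_ms
    if hop_ms < 1:
        raise TooShortError(f"hop_ms must be >= 1, got {hop_ms}")
    frame_len = int(round(frame_length_ms * recording.fs / 1000.0))
    hop = int(round(hop_ms * recording.fs / 1000.0))
    n = len(recording.samples)
    if n < frame_len:
        raise TooShortError(
            f"signal of {n} samples is shorter than one {frame_len}-sample frame"
        )
    n_frames = (n - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameSet(
        frames=recording.samples[idx],
        frame_length_ms=frame_length_ms,
        hop_ms=hop_ms,
        recording=recording,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest CSV with required columns path,speaker_id,label."""
    df = pd.read_csv(path, dtype={"speaker_id": str})
    missing = {"path", "speaker_id", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest is missing columns {sorted(missing)}")
    bad = set(df["label"].unique()) - {"normal", "pathological"}
    if bad:
        raise FormatError(f"manifest labels must be normal/pathological, found {sorted(bad)}")
    return df
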