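"""Synthetic sustained vowels and tone stimuli.

The generator emulates labeled sustained-vowel corpora: each synthetic
speaker phonates a harmonic source (n harmonics with 1/k amplitude roll-off)
whose fundamental is perturbed cycle-to-cycle in period (jitter) and
amplitude (shimmer), slowly amplitude-modulated (tremor), and mixed with
white noise at a prescribed harmonics-to-noise ratio.  Elevated jitter and
shimmer and depressed HNR are the classic acoustic correlates of dysphonia,
so a "pathological" synthetic speaker is simply one drawn from perturbed
parameter ranges.

Tone stimuli (a pure tone and the same tone with sinusoidal AM) exercise the
modulation-spectrum calibration: the pure tone must land on the 0 Hz
modulation column at its carrier band, the AM tone must add sidebands at the
modulation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from modspec.exceptions import AliasingError, ParameterError
from modspec.signal_io import Recording, normalize, save_recording


@dataclass(frozen=True)
class VoiceSynthParams:
    """Source and perturbation parameters of one synthetic phonation.

    jitter_pct / shimmer_pct are Gaussian SDs of the cycle-to-cycle period /
    amplitude perturbation in percent (draws clipped at +-3 SD); hnr_db is the
    harmonic-to-noise power ratio of the added white noise (np.inf = clean);
    tremor is a slow sinusoidal AM of the whole waveform.
    """

    f0: float = 120.0
    n_harmonics: int = 30
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    hnr_db: float = np.inf
    tremor_rate_hz: float = 0.0
    tremor_extent_pct: float = 0.0
    duration_s: float = 3.0
    fs: float = 25_000.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ParameterError(f"f0 must be positive, got {self.f0}")
        if self.n_harmonics < 1:
            raise ParameterError("need at least one harmonic")
        if self.n_harmonics * self.f0 >= self.fs / 2:
            raise ParameterError(
                f"{self.n_harmonics} harmonics of {self.f0} Hz exceed Nyquist at fs={self.fs}"
            )
        for name in ("jitter_pct", "shimmer_pct", "tremor_extent_pct"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")


def pure_tone(f: float, duration_s: float = 1.0, fs: float = 25_000.0) -> Recording:
    """Unit-amplitude sinusoid, peak-normalized."""
    if not 0 < f < fs / 2:
        raise AliasingError(f"tone frequency {f} Hz outside (0, {fs / 2}) at fs={fs}")
    t = np.arange(int(round(duration_s * fs))) / fs
    return normalize(Recording(samples=np.cos(2 * np.pi * f * t), fs=fs))


def am_tone(
    fc: float,
    fm: float,
    depth: float = 0.5,
    duration_s: float = 1.0,
    fs: float = 25_000.0,
) -> Recording:
    """(1 + depth*cos(2*pi*fm*t)) * cos(2*pi*fc*t), peak-normalized."""
    if not 0 < fc < fs / 2:
        raise AliasingError(f"carrier {fc} Hz outside (0, {fs / 2}) at fs={fs}")
    if not 0 < fm < fs / 2:
        raise AliasingError(f"modulation rate {fm} Hz outside (0, {fs / 2}) at fs={fs}")
    if not 0 <= depth <= 1:
        raise ParameterError(f"depth must be in [0, 1], got {depth}")
    t = np.arange(int(round(duration_s * fs))) / fs
    samples = (1.0 + depth * np.cos(2 * np.pi * fm * t)) * np.cos(2 * np.pi * fc * t)
    return normalize(Recording(samples=samples, fs=fs))


def _synth_components(params: VoiceSynthParams, rng: np.random.Generator):
    """(harmonic part, noise part) before normalization.

    The harmonic part accumulates fundamental phase cycle by cycle: within
    cycle c the instantaneous frequency is f0 / (1 + jitter_c), so cycle c
    lasts (1 + jitter_c) nominal periods.  All harmonics share the phase, so
    they stay locked as in glottal phonation.  Shimmer scales each cycle's
    amplitude; tremor multiplies a slow sinusoid; noise is white Gaussian
    scaled to the requested HNR against the harmonic-part power.
    """
    n = int(round(params.duration_s * params.fs))
    n_cycles = int(np.ceil(params.duration_s * params.f0 * 1.5)) + 2
    jit = np.clip(rng.standard_normal(n_cycles), -3, 3) * params.jitter_pct / 100.0
    shim = np.clip(rng.standard_normal(n_cycles), -3, 3) * params.shimmer_pct / 100.0
    periods_s = (1.0 + jit) / params.f0

    # per-sample cycle index and fundamental phase (cycles)
    edges = np.concatenate(([0.0], np.cumsum(periods_s)))
    t = np.arange(n) / params.fs
    cycle_idx = np.searchsorted(edges, t, side="right") - 1
    frac = (t - edges[cycle_idx]) / periods_s[cycle_idx]
    phase = cycle_idx + frac  # fundamental phase in cycles

    harmonic = np.zeros(n)
    for k in range(1, params.n_harmonics + 1):
        harmonic += np.sin(2 * np.pi * k * phase) / k
    harmonic *= 1.0 + shim[cycle_idx]
    if params.tremor_extent_pct > 0 and params.tremor_rate_hz > 0:
        harmonic *= 1.0 + params.tremor_extent_pct / 100.0 * np.sin(
            2 * np.pi * params.tremor_rate_hz * t
        )

    if np.isinf(params.hnr_db):
        noise = np.zeros(n)
    else:
        noise = rng.standard_normal(n)
        p_h = float(np.mean(harmonic**2))
        p_n = float(np.mean(noise**2))
        noise *= np.sqrt(p_h / (p_n * 10.0 ** (params.hnr_db / 10.0)))
    return harmonic, noise


def synth_vowel(params: VoiceSynthParams, seed: int = 0, speaker_id: str = "", label: str = "unknown") -> Recording:
    """One synthetic sustained-vowel phonation, peak-normalized, seed-deterministic."""
    rng = np.random.default_rng(seed)
    harmonic, noise = _synth_components(params, rng)
    rec = Recording(
        samples=harmonic + noise,
        fs=params.fs,
        speaker_id=speaker_id,
        label=label,
    )
    return normalize(rec)


# parameter ranges (uniform draws) per effect level; "null" draws both classes
# from the normal ranges so labels carry no signal
_NORMAL_RANGES = {
    "f0": (100.0, 220.0),
    "jitter_pct": (0.0, 0.3),
    "shimmer_pct": (0.5, 2.0),
    "hnr_db": (25.0, 35.0),
    "tremor_rate_hz": (3.0, 7.0),
    "tremor_extent_pct": (0.0, 1.0),
}
_PATHOLOGICAL_RANGES = {
    "strong": {
        "f0": (100.0, 220.0),
        "jitter_pct": (1.5, 4.0),
        "shimmer_pct": (4.0, 10.0),
        "hnr_db": (5.0, 15.0),
        "tremor_rate_hz": (3.0, 7.0),
        "tremor_extent_pct": (2.0, 8.0),
    },
    "moderate": {
        "f0": (100.0, 220.0),
        "jitter_pct": (0.5, 1.5),
        "shimmer_pct": (2.0, 5.0),
        "hnr_db": (15.0, 25.0),
        "tremor_rate_hz": (3.0, 7.0),
        "tremor_extent_pct": (1.0, 3.0),
    },
    "null": _NORMAL_RANGES,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Geometry and class-parameter distributions of a synthetic corpus.

    ``effect`` picks preset pathological parameter ranges ("strong",
    "moderate", "null"); explicit ``normal_ranges``/``pathological_ranges``
    override the presets field by field (each value a (low, high) uniform
    range).  The seed fixes the whole corpus bit-for-bit.
    """

    n_speakers_per_class: int = 10
    duration_s: float = 3.0
    fs: float = 25_000.0
    effect: str = "strong"
    seed: int = 0
    n_harmonics: int = 30
    normal_ranges: dict = field(default_factory=dict)
    pathological_ranges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_speakers_per_class < 1:
            raise ParameterError("need at least one speaker per class")
        if self.effect not in _PATHOLOGICAL_RANGES:
            raise ParameterError(
                f"effect must be one of {sorted(_PATHOLOGICAL_RANGES)}, got {self.effect!r}"
            )

    def ranges_for(self, label: str) -> dict:
        base = dict(_NORMAL_RANGES if label == "normal" else _PATHOLOGICAL_RANGES[self.effect])
        base.update(self.normal_ranges if label == "normal" else self.pathological_ranges)
        return base


@dataclass(frozen=True)
class Corpus:
    """Recordings plus a manifest of per-speaker draw parameters."""

    spec: CorpusSpec
    recordings: list
    manifest: pd.DataFrame

    def to_wav_dir(self, out_dir: str | Path) -> Path:
        """Write WAV files and a manifest CSV consumable by signal_io."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in self.recordings:
            path = out_dir / f"{rec.speaker_id}.wav"
            save_recording(rec, path)
            rows.append({"path": str(path), "speaker_id": rec.speaker_id, "label": rec.label})
        manifest_path = out_dir / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest_path, index=False)
        return manifest_path


def make_corpus(spec: CorpusSpec) -> Corpus:
    """Draw one labeled synthetic corpus: one recording per synthetic speaker."""
    root = np.random.default_rng(spec.seed)
    recordings = []
    rows = []
    for label in ("normal", "pathological"):
        ranges = spec.ranges_for(label)
        for i in range(spec.n_speakers_per_class):
            draw_rng = np.random.default_rng(root.integers(0, 2**31))
            draws = {k: float(draw_rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
            params = VoiceSynthParams(
                n_harmonics=min(spec.n_harmonics, int(spec.fs / 2 / draws["f0"]) - 1),
                duration_s=spec.duration_s,
                fs=spec.fs,
                **draws,
            )
            speaker_id = f"{label[:4]}{i:03d}"
            rec = synth_vowel(
                params,
                seed=int(draw_rng.integers(0, 2**31)),
                speaker_id=speaker_id,
                label=label,
            )
            recordings.append(rec)
            rows.append({"speaker_id": speaker_id, "label": label, **draws})
    return Corpus(spec=spec, recordings=recordings, manifest=pd.DataFrame(rows))
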