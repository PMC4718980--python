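"""Modulation spectrum of a frame: sTFT filterbank -> subband envelopes -> FFT.

The modulation spectrum (MS) is the joint distribution of signal energy over
acoustic frequency f_a (carrier subband) and modulation frequency f_m (the
rate at which the subband envelope fluctuates).  A steady tone is a single
point on the 0 Hz modulation column; amplitude modulation at rate r adds
sidebands at +-r Hz in the same acoustic band.

Computation, incoherent (Hilbert-envelope) demodulation:

1. sTFT filterbank: Hann window of ``2 * (n_acoustic_bands - 1)`` samples so
   the one-sided FFT yields exactly ``n_acoustic_bands`` uniform bands with
   centers ``k * fs / (2 * (n_acoustic_bands - 1))`` spanning 0..fs/2.
2. The magnitude of each band's coefficient sequence over time is the subband
   envelope (for a narrow band this is the Hilbert envelope of the subband
   signal), sampled at ``fs / stft_hop_samples``.
3. Each envelope is zero-padded (or truncated) to ``n_mod_bands`` points and
   Fourier transformed; columns are reordered to a symmetric -/0/+ modulation
   axis.  The envelope mean is removed before the transform and its total
   (the value an unpadded transform would place at DC) is re-assigned to the
   0 Hz column, which therefore still carries the central modulation-band
   energy; without this, the zero-padded rectangular window leaks the large
   DC term into the neighbouring modulation bins and buries genuine low-rate
   sidebands.  No taper is applied to the envelope.

With an even FFT length the -Nyquist modulation bin has no positive partner;
all other columns obey |E(f_a, f_m)| == |E(f_a, -f_m)| for real input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from modspec.exceptions import EmptySelectionError, ModspecError, TooShortError


@dataclass(frozen=True)
class ModSpecConfig:
    """Configuration of the MS analysis.

    Defaults: 128 acoustic bands, 1024 (two-sided)
    modulation bands, Hilbert-envelope demodulation, 180 ms frames.  The sTFT
    hop of 32 samples gives an envelope rate of fs/32 (781.25 Hz at 25 kHz),
    i.e. a usable modulation range of about +-390 Hz.
    """

    n_acoustic_bands: int = 128
    n_mod_bands: int = 1024
    demodulation: str = "hilbert_envelope"
    stft_hop_samples: int = 32
    frame_length_ms: float = 180.0
    floor_db: float = -120.0

    def __post_init__(self) -> None:
        if self.n_acoustic_bands < 2:
            raise ModspecError("n_acoustic_bands must be >= 2")
        if self.n_mod_bands < 2:
            raise ModspecError("n_mod_bands must be >= 2")
        if self.demodulation != "hilbert_envelope":
            raise ModspecError(
                f"only hilbert_envelope demodulation is supported, got {self.demodulation!r}"
            )
        if self.stft_hop_samples < 1:
            raise ModspecError("stft_hop_samples must be >= 1")

    @property
    def stft_window_samples(self) -> int:
        # one-sided bin count of a real FFT of length 2*(n-1) is exactly n
        return 2 * (self.n_acoustic_bands - 1)


@dataclass(frozen=True)
class ModSpectrum:
    """Complex MS matrix with its acoustic and modulation frequency axes."""

    E: np.ndarray  # (n_acoustic, n_mod) complex
    fa_centers: np.ndarray  # Hz, one per row
    fm_centers: np.ndarray  # Hz, one per column, ascending through 0
    fs: float

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.E)

    @property
    def fm_bin_width(self) -> float:
        return float(self.fm_centers[1] - self.fm_centers[0])

    @property
    def fa_band_width(self) -> float:
        return float(self.fa_centers[1] - self.fa_centers[0])


def compute_modspec(frame: np.ndarray, fs: float, config: ModSpecConfig | None = None) -> ModSpectrum:
    """Compute the modulation spectrum of one frame.

    Raises TooShortError if the frame is shorter than one sTFT window.
    """
    if config is None:
        config = ModSpecConfig()
    frame = np.asarray(frame, dtype=np.float64)
    win_len = config.stft_window_samples
    if len(frame) < win_len:
        raise TooShortError(
            f"frame of {len(frame)} samples is shorter than the {win_len}-sample sTFT window"
        )
    window = hann(win_len, sym=False)
    segments = sliding_window_view(frame, win_len)[:: config.stft_hop_samples]
    # subband envelopes: |sTFT| per acoustic band over time, shape (n_bands, n_hops)
    envelopes = np.abs(np.fft.rfft(segments * window, axis=1)).T
    n_mod = config.n_mod_bands
    env = envelopes[:, :n_mod]
    env_mean = env.mean(axis=1, keepdims=True)
    E = np.fft.fftshift(np.fft.fft(env - env_mean, n=n_mod, axis=1), axes=1)
    E[:, n_mod // 2] += env_mean[:, 0] * env.shape[1]  # DC of the unpadded envelope
    env_rate = fs / config.stft_hop_samples
    fm_centers = (np.arange(n_mod) - n_mod // 2) * (env_rate / n_mod)
    fa_centers = np.arange(config.n_acoustic_bands) * fs / win_len
    return ModSpectrum(E=E, fa_centers=fa_centers, fm_centers=fm_centers, fs=fs)


def restrict(ms: ModSpectrum, fa_low: float, fa_high: float, fm_high: float) -> ModSpectrum:
    """Keep acoustic bands with fa_low <= f_a <= fa_high and |f_m| <= fm_high.

    The 0 Hz modulation column is always retained.  Raises
    EmptySelectionError when no band centers fall in a requested range.
    """
    if fa_low >= fa_high:
        raise ModspecError(f"fa_low ({fa_low}) must be < fa_high ({fa_high})")
    if fm_high <= 0:
        raise ModspecError(f"fm_high must be > 0, got {fm_high}")
    rows = (ms.fa_centers >= fa_low) & (ms.fa_centers <= fa_high)
    cols = np.abs(ms.fm_centers) <= fm_high
    cols |= ms.fm_centers == 0.0
    if not rows.any():
        raise EmptySelectionError(f"no acoustic band centers in [{fa_low}, {fa_high}] Hz")
    if not cols.any():
        raise EmptySelectionError(f"no modulation band centers with |f_m| <= {fm_high} Hz")
    return replace(
        ms,
        E=ms.E[np.ix_(rows, cols)],
        fa_centers=ms.fa_centers[rows],
        fm_centers=ms.fm_centers[cols],
    )


def modulus_db(ms: ModSpectrum, floor_db: float = -120.0) -> np.ndarray:
    """20*log10(|E|) with zeros (and anything below) clamped to ``floor_db``."""
    if floor_db >= 0:
        raise ModspecError(f"floor_db must be negative, got {floor_db}")
    mod = ms.modulus
    floor_lin = 10.0 ** (floor_db / 20.0)
    return 20.0 * np.log10(np.maximum(mod, floor_lin))
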