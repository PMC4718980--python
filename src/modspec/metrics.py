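"""The six scalar modulation-spectrum metrics.

MSH (modulation spectrum homogeneity) sums, over every cell of the dB
modulus, the absolute deviation of the cell from the mean of the N x N
neighbourhood around it: the less homogeneous the MS image (typical of
dysphonic voices), the larger the value.  For even N the window cannot be
centred on the cell; it spans rows/columns [i - N/2 + 1, i + N/2], so the
anchor sits just above-left of the window centre.  Windows are truncated at
the matrix borders and averaged over the cells actually available.

CIL (cumulative intersection level) is the intersection of the increasing and
decreasing cumulative histogram curves of the dB modulus — the median level.

RALA (ratio of points above linear average) counts cells at or above the
linear-unit mean modulus versus cells below it; energy dispersed away from
the 0 Hz modulation column (a pathological trait) raises it.

MSP25/75/95 are percentiles of the dB modulus distribution (linear
interpolation between closest ranks, the numpy default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from modspec.exceptions import DegenerateSpectrumError, SizeError
from modspec.spectrum import ModSpecConfig, ModSpectrum, compute_modspec, modulus_db, restrict

METRIC_NAMES = ("msh", "cil", "rala", "msp25", "msp75", "msp95")


@dataclass(frozen=True)
class MetricVector:
    """The six metrics for one frame."""

    msh: float
    cil: float
    rala: float
    msp25: float
    msp75: float
    msp95: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class RALABreakdown:
    """Cell counts behind a RALA value."""

    na: int  # cells with |E| >= mean
    nb: int  # cells with |E| < mean
    nt: int
    mean_modulus: float

    @property
    def ratio(self) -> float:
        return self.na / self.nb


def _window_means(matrix: np.ndarray, mask_n: int) -> np.ndarray:
    """Mean of the N x N window anchored at each cell, truncated at borders.

    Even N anchors the cell above-left of centre: rows i-N/2+1 .. i+N/2.
    Implemented with an integral image; O(cells) regardless of N.
    """
    rows, cols = matrix.shape
    if mask_n % 2 == 0:
        lo, hi = mask_n // 2 - 1, mask_n // 2
    else:
        lo = hi = (mask_n - 1) // 2
    # integral image with a zero border: S[i, j] = sum of matrix[:i, :j]
    S = np.zeros((rows + 1, cols + 1))
    S[1:, 1:] = matrix.cumsum(axis=0).cumsum(axis=1)
    i = np.arange(rows)
    j = np.arange(cols)
    r0 = np.clip(i - lo, 0, rows)[:, None]
    r1 = np.clip(i + hi + 1, 0, rows)[:, None]
    c0 = np.clip(j - lo, 0, cols)[None, :]
    c1 = np.clip(j + hi + 1, 0, cols)[None, :]
    totals = S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]
    counts = (r1 - r0) * (c1 - c0)
    return totals / counts


def msh(ms_db: np.ndarray, mask_n: int = 6) -> float:
    """Sum of |cell - local N x N mean| over the dB modulus matrix."""
    ms_db = np.asarray(ms_db, dtype=np.float64)
    if mask_n < 2:
        raise SizeError(f"mask_n must be >= 2, got {mask_n}")
    if ms_db.shape[0] < mask_n or ms_db.shape[1] < mask_n:
        raise SizeError(f"matrix {ms_db.shape} is smaller than the {mask_n}x{mask_n} mask")
    # centring costs nothing (the statistic is shift-invariant) and makes a
    # constant matrix give exactly 0 despite the cumsum round-off
    work = ms_db - ms_db.mean()
    return float(np.sum(np.abs(work - _window_means(work, mask_n))))


def cil(ms_db: np.ndarray) -> float:
    """Median of the dB modulus (the cumulative-curve intersection level)."""
    ms_db = np.asarray(ms_db, dtype=np.float64)
    if ms_db.size == 0:
        raise SizeError("cannot compute CIL of an empty matrix")
    # shares the percentile path so CIL == MSP50 holds bit for bit
    return float(np.percentile(ms_db, 50))


def rala(ms_linear: np.ndarray) -> RALABreakdown:
    """Count cells >= mean vs. < mean of the linear modulus; ratio = na/nb."""
    ms_linear = np.asarray(ms_linear, dtype=np.float64)
    if ms_linear.size == 0:
        raise SizeError("cannot compute RALA of an empty matrix")
    mean = float(ms_linear.mean())
    na = int(np.count_nonzero(ms_linear >= mean))
    nb = ms_linear.size - na
    if nb == 0:
        raise DegenerateSpectrumError("all cells equal the mean modulus; RALA undefined")
    return RALABreakdown(na=na, nb=nb, nt=ms_linear.size, mean_modulus=mean)


def msp(ms_db: np.ndarray, p: float) -> float:
    """p-th percentile of the dB modulus, linear interpolation between ranks."""
    ms_db = np.asarray(ms_db, dtype=np.float64)
    if ms_db.size == 0:
        raise SizeError("cannot compute a percentile of an empty matrix")
    if not 0 < p < 100:
        raise SizeError(f"percentile must be in (0, 100), got {p}")
    return float(np.percentile(ms_db, p))


def metrics_from_spectrum(
    ms: ModSpectrum,
    tuned,
    mask_n: int = 6,
    floor_db: float = -120.0,
) -> MetricVector:
    """All six metrics from one already-computed (unrestricted) spectrum.

    ``tuned`` maps metric name -> (fm_high, fa_low, fa_high); see
    :func:`modspec.tuning.tuned_defaults`.  RALA is computed on the linear
    modulus, all others on dB.
    """
    ranges = tuned.metric_ranges if hasattr(tuned, "metric_ranges") else tuned
    values: dict[str, float] = {}
    cache: dict[tuple, ModSpectrum] = {}
    for name in METRIC_NAMES:
        fm_high, fa_low, fa_high = ranges[name]
        key = (fm_high, fa_low, fa_high)
        if key not in cache:
            cache[key] = restrict(ms, fa_low, fa_high, fm_high)
        sub = cache[key]
        try:
            if name == "rala":
                values[name] = rala(sub.modulus).ratio
            elif name == "msh":
                values[name] = msh(modulus_db(sub, floor_db), mask_n)
            elif name == "cil":
                values[name] = cil(modulus_db(sub, floor_db))
            else:
                values[name] = msp(modulus_db(sub, floor_db), float(name[3:]))
        except (DegenerateSpectrumError, SizeError) as exc:
            raise type(exc)(f"metric {name}: {exc}") from exc
    return MetricVector(**values)


def compute_all_metrics(
    frame: np.ndarray,
    fs: float,
    config: ModSpecConfig | None = None,
    tuned=None,
    mask_n: int = 6,
) -> MetricVector:
    """Compute the MS of one frame once, then every metric on its own restriction."""
    from modspec.tuning import tuned_defaults  # deferred: tuning imports detector

    if config is None:
        config = ModSpecConfig()
    if tuned is None:
        tuned = tuned_defaults()
    frame = np.asarray(frame, dtype=np.float64)
    if not np.any(frame):
        raise DegenerateSpectrumError("all-zero frame has a degenerate modulation spectrum")
    ms = compute_modspec(frame, fs, config)
    return metrics_from_spectrum(ms, tuned, mask_n=mask_n, floor_db=config.floor_db)
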