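"""Cilia beat kinetics: kymographs, beat frequency and beat amplitude.

High-speed phase-contrast recordings (250 frames per second) of beating cilia
are reduced to either a line-ROI kymograph (position along a line x time) or a
scalar trace per ROI (mean intensity, or tip position).  Beat frequency is
estimated two ways and cross-checked:

* primary: cycles counted as prominent peaks of the detrended trace, divided
  by the trace duration (the cycle convention: one peak = one full beat);
* spectral: the dominant non-DC frequency of the periodogram.

The two must agree within one cycle per duration (= the frequency resolution
floor 1/duration) for an unflagged result.  The peak-prominence threshold is
3x the robust noise SD of the trace, estimated from the residual of a
sinusoid fitted at the spectral frequency, so a noiseless trace is counted
exactly and a noisy one ignores sub-threshold wiggles.

Beat amplitude is the peak-to-peak excursion (max - min) of a tip-position
series, in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "BeatTrace",
    "Kymograph",
    "FrequencyResult",
    "make_kymograph",
    "beat_frequency",
    "beat_amplitude",
]


@dataclass
class BeatTrace:
    """A uniformly sampled ROI intensity or tip-position time series."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    roi: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.samples) < 2:
            raise ValueError("trace needs at least 2 samples")

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / rate)."""
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class Kymograph:
    """Position-along-line x time intensity image."""

    data: np.ndarray  # (n_positions, n_frames)
    line: np.ndarray  # (k, 2) polyline vertices, pixel coordinates (x, y)
    duration_ms: float


@dataclass
class FrequencyResult:
    """Beat-frequency estimate with its spectral cross-check."""

    frequency_hz: float  # primary (peak-count) estimate
    spectral_hz: float
    n_peaks: int
    resolution_hz: float  # 1/duration frequency floor
    flagged: bool
    flag_reason: str = ""


def _polyline_samples(line: np.ndarray) -> np.ndarray:
    """Sample points at ~unit pixel spacing along a polyline (x, y)."""
    line = np.asarray(line, dtype=float).reshape(-1, 2)
    if len(line) < 2:
        raise ValueError("line needs at least 2 vertices")
    segs = np.diff(line, axis=0)
    lengths = np.hypot(segs[:, 0], segs[:, 1])
    total = float(lengths.sum())
    if total < 2.0:
        raise ValueError(f"line of length {total:.2f} px is shorter than 2 px")
    n = int(np.floor(total)) + 1
    targets = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    pts = np.empty((n, 2))
    for k, t in enumerate(targets):
        i = min(np.searchsorted(cum, t, side="right") - 1, len(segs) - 1)
        frac = (t - cum[i]) / lengths[i] if lengths[i] > 0 else 0.0
        pts[k] = line[i] + frac * segs[i]
    return pts


def make_kymograph(
    movie: np.ndarray,
    line: np.ndarray,
    window_ms: float = 200.0,
    sampling_rate: float = 250.0,
    start_frame: int = 0,
) -> Kymograph:
    """Sample intensity along a polyline for each frame of a time window.

    ``movie`` is (t, y, x); ``line`` a polyline in pixel coordinates (x, y)
    inside the frame.  Intensities are bilinearly interpolated at unit spacing
    along the line.  The default window is 200 ms.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (t, y, x)")
    n_frames = int(round(window_ms / 1000.0 * sampling_rate))
    if n_frames < 1 or start_frame + n_frames > movie.shape[0]:
        raise ValueError("window exceeds the movie duration")
    pts = _polyline_samples(line)
    h, w = movie.shape[1:]
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h - 1):
        raise ValueError("line extends outside the frame")
    coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col) for map_coordinates
    data = np.empty((len(pts), n_frames))
    for j in range(n_frames):
        data[:, j] = ndimage.map_coordinates(movie[start_frame + j], coords, order=1, mode="nearest")
    return Kymograph(data=data, line=np.asarray(line, dtype=float), duration_ms=n_frames / sampling_rate * 1000.0)


def _spectral_peak(x: np.ndarray, fs: float) -> float:
    """Dominant non-DC frequency of the periodogram (0 if the trace is flat)."""
    freqs, psd = signal.periodogram(x, fs=fs)
    if len(psd) < 2 or np.all(psd[1:] == 0):
        return 0.0
    return float(freqs[1:][np.argmax(psd[1:])])


def beat_frequency(trace: BeatTrace, prominence_factor: float = 3.0) -> FrequencyResult:
    """Estimate beat frequency by peak counting with a spectral cross-check.

    The trace is linearly detrended; the dominant periodogram frequency gives
    the spectral estimate and (via a least-squares sinusoid fit at that
    frequency) the residual noise SD used to set the peak-prominence threshold
    ``prominence_factor * noise_sd``.  The primary estimate is
    n_peaks / duration.  Results are flagged when no peaks clear the threshold
    (frequency 0) or the two estimators disagree by more than one cycle per
    duration.
    """
    x = signal.detrend(trace.samples, type="linear")
    duration = trace.duration
    resolution = 1.0 / duration
    ptp = float(np.ptp(x))
    if ptp == 0:
        return FrequencyResult(0.0, 0.0, 0, resolution, True, "constant trace")

    f_spec = _spectral_peak(x, trace.sampling_rate)
    if f_spec > 0:
        t = trace.times
        design = np.column_stack([np.cos(2 * np.pi * f_spec * t), np.sin(2 * np.pi * f_spec * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        noise_sd = float(np.std(x - design @ coef))
    else:
        noise_sd = float(np.std(x))

    prominence = max(prominence_factor * noise_sd, 1e-3 * ptp)
    peaks, _ = signal.find_peaks(x, prominence=prominence)
    n_peaks = len(peaks)
    if n_peaks == 0:
        return FrequencyResult(0.0, f_spec, 0, resolution, True, "no peaks above prominence")
    f_peak = n_peaks / duration
    flagged = abs(f_peak - f_spec) > resolution
    reason = "peak-count and spectral estimates disagree" if flagged else ""
    return FrequencyResult(f_peak, f_spec, n_peaks, resolution, flagged, reason)


def beat_amplitude(
    tip_positions_um: np.ndarray,
    sampling_rate: float | None = None,
    expected_frequency_hz: float | None = None,
) -> tuple[float, bool]:
    """Peak-to-peak beat amplitude (um): max - min of the tip-position series.

    When the expected beat frequency and sampling rate are given, traces
    shorter than one beat period are flagged (the excursion then underestimates
    the amplitude).  Returns ``(amplitude_um, flagged)``.
    """
    x = np.asarray(tip_positions_um, dtype=float).reshape(-1)
    if len(x) == 0:
        raise ValueError("empty tip-position series")
    flagged = False
    if expected_frequency_hz and sampling_rate:
        if len(x) < sampling_rate / expected_frequency_hz:
            warnings.warn("trace shorter than one expected beat period", stacklevel=2)
            flagged = True
    return float(np.max(x) - np.min(x)), flagged
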