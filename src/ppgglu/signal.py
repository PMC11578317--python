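"""Waveform containers, CSV round-tripping, conditioning and beat segmentation.

The segmentation follows the start-point rule used for fingertip PPG glucose
work: the initial lowest point (trough) preceding the first beat that shows
the double-peak morphology (systolic then diastolic peak) is taken as the
starting point, and subsequent beats are delimited trough to trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import MissingColumnError, ParseError, SegmentationError, ValidationError

__all__ = [
    "PPGRecord",
    "BeatSegment",
    "read_ppg_csv",
    "write_ppg_csv",
    "condition_signal",
    "segment_beats",
    "segments_to_frame",
]

#: Default analysis band in Hz: keeps the 1-3 Hz heart-rate fundamental and
#: the harmonics that shape the dicrotic notch, rejects baseline wander and
#: mains-frequency interference.
DEFAULT_BAND = (0.5, 8.0)

_GRID_TOL = 1e-9  # max deviation of sample spacing from uniformity, seconds


@dataclass(frozen=True)
class PPGRecord:
    """A uniformly sampled transmitted-light PPG waveform."""

    times: np.ndarray
    intensities: np.ndarray
    sampling_rate: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if times.ndim != 1 or times.shape != intens.shape:
            raise ValidationError("times and intensities must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValidationError("a PPGRecord needs at least 2 samples")
        if not np.all(np.isfinite(intens)):
            raise ValidationError("intensities must be finite")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.ptp(dt) > _GRID_TOL:
            raise ValidationError("times must lie on a uniform grid (within 1e-9 s)")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + 1.0 / self.sampling_rate


def read_ppg_csv(path: str | Path) -> PPGRecord:
    """Read a waveform CSV with columns ``time_s,intensity``.

    The sampling rate is inferred from the median sample spacing.  Raises
    :class:`MissingColumnError` for absent columns, :class:`ParseError` for
    non-monotone time or fewer than 2 rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_s", "intensity"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 rows, got {len(df)}")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: time_s is not strictly increasing")
    rate = 1.0 / float(np.median(np.diff(times)))
    return PPGRecord(
        times=times,
        intensities=df["intensity"].to_numpy(dtype=float),
        sampling_rate=rate,
    )


def write_ppg_csv(record: PPGRecord, path: str | Path) -> None:
    """Write the waveform as ``time_s,intensity`` CSV (bit-exact round trip)."""
    pd.DataFrame({"time_s": record.times, "intensity": record.intensities}).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def condition_signal(record: PPGRecord, band: tuple[float, float] = DEFAULT_BAND) -> PPGRecord:
    """Zero-phase band-pass conditioning with baseline (DC) removal.

    Implemented as an ideal frequency-domain mask over the real FFT: bins
    outside ``band`` (inclusive) are zeroed.  The mask is idempotent, so
    conditioning an already conditioned record is a no-op up to floating
    point, and a constant signal maps to all zeros.
    """
    lo, hi = band
    nyquist = record.sampling_rate / 2.0
    if not 0 < lo < hi < nyquist:
        raise ValidationError(
            f"band must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz), got {band}"
        )
    x = record.intensities
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / record.sampling_rate)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    filtered = np.fft.irfft(spec, n=len(x))
    return replace(record, intensities=filtered)


@dataclass(frozen=True)
class BeatSegment:
    """Half-open sample-index range of one beat, anchored at a trough."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start_index}, {self.end_index})"
            )

    def slice(self) -> slice:
        return slice(self.start_index, self.end_index)


#: Upper bound on the human heart rate used for trough separation, Hz.
MAX_HEART_RATE_HZ = 3.0

#: A trough must be at least this prominent, relative to the robust signal
#: span, to count as a beat boundary; keeps dicrotic-notch dips out.
_TROUGH_PROMINENCE_FRAC = 0.3

#: A local maximum must be at least this prominent, relative to the beat's
#: peak-to-trough span, to count toward the double-peak test.
_DOUBLE_PEAK_PROMINENCE_FRAC = 0.1


def _find_troughs(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    span = float(np.percentile(x, 98) - np.percentile(x, 2))
    if span <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(sampling_rate / MAX_HEART_RATE_HZ))
    troughs, _ = find_peaks(-x, distance=distance, prominence=_TROUGH_PROMINENCE_FRAC * span)
    return troughs


def _is_double_peak(beat: np.ndarray) -> bool:
    span = float(np.ptp(beat))
    if span <= 0:
        return False
    peaks, _ = find_peaks(beat, prominence=_DOUBLE_PEAK_PROMINENCE_FRAC * span)
    return len(peaks) >= 2


def segment_beats(record: PPGRecord) -> list[BeatSegment]:
    """Segment a conditioned recording into beats, trough to trough.

    The first segment starts at the trough preceding the first beat that
    exhibits the double-peak morphology; subsequent segments follow trough to
    trough.  Raises :class:`SegmentationError` when the recording is too
    short to contain two troughs, or when no double-peak beat is found.
    """
    x = record.intensities
    troughs = _find_troughs(x, record.sampling_rate)
    if len(troughs) < 2:
        raise SegmentationError(
            "cannot segment: fewer than two beat troughs found "
            f"(recording of {record.duration:.2f} s)"
        )
    for i in range(len(troughs) - 1):
        beat = x[troughs[i] : troughs[i + 1]]
        if _is_double_peak(beat):
            return [
                BeatSegment(int(troughs[j]), int(troughs[j + 1]))
                for j in range(i, len(troughs) - 1)
            ]
    raise SegmentationError("no valid start point: no double-peak beat found")


def segments_to_frame(segments: list[BeatSegment]) -> pd.DataFrame:
    """Segments as a ``start_index,end_index`` table (CSV-exportable)."""
    return pd.DataFrame(
        {
            "start_index": [s.start_index for s in segments],
            "end_index": [s.end_index for s in segments],
        }
    )
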