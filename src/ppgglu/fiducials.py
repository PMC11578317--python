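"""Fiducial-point location and the 11-feature vector per beat.

The feature set realizes "temporal and spectral" beat descriptors anchored
to the four named fiducial points, with the three anchored amplitudes
(SP-Bot, DP-Bot, DN-Bot) placed first.  The exact composition is a package
assumption and is isolated behind :data:`FEATURE_NAMES` so alternates can be
swapped in without touching callers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import DegenerateBeatError, FeatureError, ValidationError
from .signal import DEFAULT_BAND, PPGRecord, condition_signal, segment_beats
from .synthetic import CohortEntry, SubjectProfile

__all__ = [
    "FiducialSet",
    "FeatureRow",
    "FEATURE_NAMES",
    "P_FEATURE_NAMES",
    "locate_fiducials",
    "extract_features",
    "aggregate_recording",
    "build_feature_table",
    "correlation_report",
    "encode_profile",
]

#: Fixed, documented feature order.  Amplitudes are relative to Bot (a.u.),
#: times are within-beat seconds.
FEATURE_NAMES = (
    "f01_sp_bot",          # SP-Bot amplitude
    "f02_dp_bot",          # DP-Bot amplitude
    "f03_dn_bot",          # DN-Bot amplitude
    "f04_t_sp",            # systolic peak time from beat start
    "f05_t_dn",            # dicrotic notch time
    "f06_t_dp",            # diastolic peak time
    "f07_period",          # beat period
    "f08_dp_sp_ratio",     # (DP-Bot)/(SP-Bot)
    "f09_dn_sp_ratio",     # (DN-Bot)/(SP-Bot)
    "f10_rise_slope",      # (SP-Bot)/t_SP systolic rise slope
    "f11_spectral_ratio",  # power at the beat fundamental / total AC power
)

P_FEATURE_NAMES = ("p_age", "p_sex", "p_height", "p_weight")


@dataclass(frozen=True)
class FiducialSet:
    """Times (s, relative to beat start) and amplitudes of SP/DN/DP/Bot."""

    t_sp: float
    a_sp: float
    t_dn: float
    a_dn: float
    t_dp: float
    a_dp: float
    t_bot: float
    a_bot: float
    notch_fallback_used: bool = False

    def __post_init__(self) -> None:
        if not self.t_bot <= self.t_sp < self.t_dn < self.t_dp:
            raise ValidationError(
                "fiducial times must satisfy t_bot <= t_sp < t_dn < t_dp, got "
                f"({self.t_bot}, {self.t_sp}, {self.t_dn}, {self.t_dp})"
            )


@dataclass(frozen=True)
class FeatureRow:
    """Per-recording model inputs: 11 X-features, P-features and the y-label."""

    x: np.ndarray
    p: np.ndarray
    y: float | None = None
    subject_id: str | None = None
    n_beats: int = 0
    n_beats_skipped: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if x.shape != (len(FEATURE_NAMES),):
            raise ValidationError(f"expected {len(FEATURE_NAMES)} X-features, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValidationError("X-features must be finite")
        if self.y is not None and not self.y > 0:
            raise ValidationError(f"y-label must be > 0 mmol/L, got {self.y}")


def _smoothed_derivative(beat: np.ndarray, sampling_rate: float) -> np.ndarray:
    window = int(round(0.05 * sampling_rate))
    window = max(5, window | 1)  # odd, at least 5
    window = min(window, len(beat) if len(beat) % 2 else len(beat) - 1)
    if window < 5:
        raise DegenerateBeatError("beat too short for derivative smoothing")
    return savgol_filter(beat, window, polyorder=3, deriv=1)


def locate_fiducials(beat: np.ndarray, sampling_rate: float) -> FiducialSet:
    """Locate Bot, SP, DN and DP within one beat.

    Bot is the beat minimum up to the systolic peak; SP the global maximum;
    DN the deepest interior local minimum after SP; DP the highest local
    maximum after DN.  When no interior minimum exists (a notch-free
    "shoulder" beat), DN/DP fall back to zero crossings of a smoothed first
    derivative after SP — or, if the derivative never crosses zero, to the
    flattest point of the decay and a point 50 ms beyond it — and
    ``notch_fallback_used`` is set.
    """
    beat = np.asarray(beat, dtype=float)
    n = len(beat)
    if n < 8:
        raise DegenerateBeatError(f"beat of {n} samples is too short")
    if np.ptp(beat) <= 0:
        raise DegenerateBeatError("flat beat")
    diffs = np.diff(beat)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        raise DegenerateBeatError("monotone beat")
    i_sp = int(np.argmax(beat))
    if i_sp >= n - 3:
        raise DegenerateBeatError("systolic peak at beat boundary")
    i_bot = int(np.argmin(beat[: i_sp + 1]))

    # The beat ends in the inter-beat trough (the global low region), where
    # noise or filter ringing produces spurious deep local minima; restrict
    # the notch search to the first 70% of the post-systolic span and the
    # diastolic-peak search to the first 90%.
    m = n - i_sp
    dn_hi = i_sp + max(3, int(0.7 * m))
    dp_hi = i_sp + max(4, int(0.9 * m))
    fallback = False
    tail = beat[i_sp:dn_hi]
    minima, _ = find_peaks(-tail)
    i_dn = i_dp = None
    if len(minima) > 0:
        i_dn = i_sp + int(minima[np.argmin(tail[minima])])
        dp_seg = beat[i_dn:dp_hi]
        maxima, _ = find_peaks(dp_seg)
        if len(maxima) > 0:
            i_dp = i_dn + int(maxima[np.argmax(dp_seg[maxima])])
    if i_dn is None or i_dp is None:
        fallback = True
        d = _smoothed_derivative(beat, sampling_rate)
        dn_cand = dp_cand = None
        for k in range(i_sp + 1, dp_hi - 1):
            if dn_cand is None and d[k] < 0 <= d[k + 1]:
                dn_cand = k + 1
            elif dn_cand is not None and d[k] >= 0 > d[k + 1]:
                dp_cand = k
                break
        if dn_cand is not None and dp_cand is not None and dn_cand < dp_cand:
            i_dn, i_dp = dn_cand, dp_cand
        else:
            # shoulder: flattest point of the decay stands in for the notch,
            # a point 50 ms later for the diastolic peak
            lo = i_sp + 1
            i_dn = lo + int(np.argmax(d[lo:dn_hi]))
            i_dp = min(i_dn + max(1, int(round(0.05 * sampling_rate))), n - 2)
            if i_dp <= i_dn:
                raise DegenerateBeatError("no post-systolic structure found")
    dt = 1.0 / sampling_rate
    return FiducialSet(
        t_sp=i_sp * dt,
        a_sp=float(beat[i_sp]),
        t_dn=i_dn * dt,
        a_dn=float(beat[i_dn]),
        t_dp=i_dp * dt,
        a_dp=float(beat[i_dp]),
        t_bot=i_bot * dt,
        a_bot=float(beat[i_bot]),
        notch_fallback_used=fallback,
    )


def extract_features(
    fiducials: FiducialSet, beat: np.ndarray, sampling_rate: float
) -> np.ndarray:
    """The 11-feature vector of one beat, in :data:`FEATURE_NAMES` order.

    Amplitude features are anchored to Bot, so they are invariant to the
    waveform's DC offset; the two ratios and the spectral ratio are
    additionally invariant to amplitude scaling.
    """
    beat = np.asarray(beat, dtype=float)
    f = fiducials
    amp_sp = f.a_sp - f.a_bot
    amp_dp = f.a_dp - f.a_bot
    amp_dn = f.a_dn - f.a_bot
    if f.t_sp <= 0:
        raise FeatureError("systolic rise slope undefined: t_SP is zero")
    if amp_sp <= 0:
        raise DegenerateBeatError("non-positive systolic amplitude")
    period = len(beat) / sampling_rate
    z = beat - beat.mean()
    power = np.abs(np.fft.rfft(z)) ** 2
    total = float(power[1:].sum())
    if len(power) < 3 or total <= 0:
        raise FeatureError("spectral ratio undefined for this beat")
    features = np.array(
        [
            amp_sp,
            amp_dp,
            amp_dn,
            f.t_sp,
            f.t_dn,
            f.t_dp,
            period,
            amp_dp / amp_sp,
            amp_dn / amp_sp,
            amp_sp / f.t_sp,
            float(power[1]) / total,
        ]
    )
    if not np.all(np.isfinite(features)):
        raise FeatureError("non-finite feature encountered")
    return features


def encode_profile(profile: SubjectProfile | None) -> np.ndarray:
    """P-feature encoding: age, sex (F=0/M=1), height (cm), weight (kg)."""
    if profile is None:
        return np.full(len(P_FEATURE_NAMES), np.nan)
    return np.array(
        [profile.age, 1.0 if profile.sex == "M" else 0.0, profile.height, profile.weight]
    )


def aggregate_recording(
    record: PPGRecord,
    profile: SubjectProfile | None = None,
    glucose: float | None = None,
    condition: bool = True,
    band: tuple[float, float] = DEFAULT_BAND,
) -> FeatureRow:
    """Per-recording X-feature means over all non-degenerate beats.

    Beats that raise a degenerate-beat or feature error are skipped and
    counted in ``n_beats_skipped``; if every beat fails, the recording-level
    error is raised.
    """
    work = condition_signal(record, band) if condition else record
    segments = segment_beats(work)
    rows = []
    skipped = 0
    for seg in segments:
        beat = work.intensities[seg.slice()]
        try:
            fid = locate_fiducials(beat, work.sampling_rate)
            rows.append(extract_features(fid, beat, work.sampling_rate))
        except (DegenerateBeatError, FeatureError):
            skipped += 1
    if not rows:
        raise DegenerateBeatError(
            f"all {len(segments)} beats degenerate; nothing to aggregate"
        )
    return FeatureRow(
        x=np.mean(rows, axis=0),
        p=encode_profile(profile),
        y=glucose,
        subject_id=record.subject_id,
        n_beats=len(rows),
        n_beats_skipped=skipped,
    )


def build_feature_table(
    entries: Sequence[CohortEntry],
    condition: bool = True,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Feature table for a simulated cohort: one row per recording.

    Columns are ``f01..f11``, the P-features, ``y_glucose`` plus
    ``subject_id`` bookkeeping.  Missing P-features are imputed with the
    cohort median; imputed columns are listed in ``df.attrs['imputed']``.
    """
    records = []
    for entry in entries:
        row = aggregate_recording(
            entry.record, profile=entry.profile, glucose=entry.glucose,
            condition=condition, band=band,
        )
        rec = dict(zip(FEATURE_NAMES, row.x))
        rec.update(zip(P_FEATURE_NAMES, row.p))
        rec["y_glucose"] = row.y
        rec["subject_id"] = row.subject_id
        rec["n_beats"] = row.n_beats
        rec["n_beats_skipped"] = row.n_beats_skipped
        records.append(rec)
    df = pd.DataFrame(records)
    imputed = []
    for col in P_FEATURE_NAMES:
        if df[col].isna().any():
            df[col] = df[col].fillna(df[col].median())
            imputed.append(col)
    df.attrs["imputed"] = imputed
    return df


def correlation_report(table: pd.DataFrame | Sequence[FeatureRow]) -> pd.Series:
    """Pearson correlation of each of the 11 X-features with the y-label.

    Zero-variance features are reported as NaN (flagged in
    ``series.attrs['undefined']``), never silently as 0.  Requires at least
    3 labelled rows.
    """
    if not isinstance(table, pd.DataFrame):
        rows = list(table)
        table = pd.DataFrame(
            {name: [r.x[i] for r in rows] for i, name in enumerate(FEATURE_NAMES)}
            | {"y_glucose": [r.y for r in rows]}
        )
    if len(table) < 3:
        raise ValidationError(f"need >= 3 rows for correlations, got {len(table)}")
    y = table["y_glucose"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("y-label has zero variance")
    out = {}
    undefined = []
    for name in FEATURE_NAMES:
        v = table[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            out[name] = np.nan
            undefined.append(name)
        else:
            out[name] = float(np.corrcoef(v, y)[0, 1])
    series = pd.Series(out, name="pearson_r")
    series.attrs["undefined"] = undefined
    return series
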