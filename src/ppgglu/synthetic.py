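"""Synthetic PPG cohorts with a glucose-linked beat morphology.

Fingertip photoplethysmograms are transmitted-light intensity traces whose
single-beat shape carries four landmark ("fiducial") points: the systolic
peak (SP), the dicrotic notch (DN), the diastolic peak (DP) and the bottom
trough (Bot).  This module generates waveforms in which the three anchored
amplitudes SP-Bot, DP-Bot and DN-Bot are affine functions of the blood
glucose concentration, so the downstream feature-extraction and regression
stages can be tested against a known, recoverable signal.

Beat model
----------
One beat of period ``T`` is the sum of two Gaussian pulses (systolic and
diastolic) minus a narrow Gaussian notch.  The diastolic pulse is wide
enough to ride the systolic decay as a shoulder: without the notch the beat
is a single hump, and it is the notch that carves the DN local minimum and
thereby separates the DP local maximum.  Component amplitudes and centres
are calibrated by a damped fixed-point iteration so that the waveform's
measured fiducial amplitudes and times hit the requested targets (to well
under 1%), which makes the generator ground truth exact by construction.

Noise model
-----------
Additive white Gaussian noise whose standard deviation decreases linearly
with glucose (clipped below at a floor): low-glucose recordings are noisier,
mimicking the weaker glucose contribution to light absorption at low
concentrations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signal import PPGRecord, write_ppg_csv

__all__ = [
    "BeatParams",
    "SubjectProfile",
    "GlucoseLink",
    "ScenarioSpec",
    "BeatTruth",
    "CohortEntry",
    "default_link",
    "simulate_beat",
    "beat_ground_truth",
    "simulate_recording",
    "simulate_cohort",
    "scenario_preset",
    "SCENARIO_PRESETS",
    "write_cohort",
]

# Beat-shape constants, as fractions of the beat period.  Chosen once so that
# (a) the calibration below converges across the physiological amplitude
# range, (b) with the notch removed the beat is unimodal after SP (shoulder),
# and (c) with the default notch all four fiducials exist with a DP
# prominence well above the 10% double-peak detection threshold.
_SYS_CENTER_FRAC = 0.17
_SYS_WIDTH_FRAC = 0.10
_NOTCH_WIDTH_FRAC = 0.05
_DIA_CENTER_FRAC = 0.46
_DIA_WIDTH_FRAC = 0.18

#: The systolic upstroke is steeper than the decay: the rising-side width is
#: this fraction of the decay-side width, which also brings both window
#: endpoints down to near the beat minimum.
_SYS_RISE_RATIO = 0.4

#: Diastolic component amplitude, as a fraction of the requested DP-Bot
#: amplitude, used when the notch is absent and DP cannot be calibrated.
_SHOULDER_FRAC = 0.8

_CALIBRATION_ITERS = 14
_FINE_GRID_N = 8192


@dataclass(frozen=True)
class BeatParams:
    """Target morphology of a single PPG beat.

    Amplitudes are fiducial amplitudes relative to the beat bottom (a.u.):
    ``systolic_amplitude`` is SP-Bot, ``diastolic_amplitude`` is DP-Bot, and
    ``notch_depth`` is the DP-DN depth (so DN-Bot equals
    ``diastolic_amplitude - notch_depth``).  Times are within-beat times in
    seconds; ``pulse_widths`` are the Gaussian standard deviations of the
    systolic pulse, diastolic pulse and notch, in seconds.
    """

    systolic_amplitude: float = 1.0
    diastolic_amplitude: float = 0.52
    notch_depth: float = 0.22
    beat_period: float = 0.8
    systolic_time: float | None = None
    diastolic_time: float | None = None
    pulse_widths: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.beat_period > 0:
            raise ValidationError(f"beat_period must be > 0, got {self.beat_period}")
        if not self.systolic_amplitude > 0:
            raise ValidationError(
                f"systolic_amplitude must be > 0, got {self.systolic_amplitude}"
            )
        if not self.diastolic_amplitude > 0:
            raise ValidationError(
                f"diastolic_amplitude must be > 0, got {self.diastolic_amplitude}"
            )
        if self.notch_depth < 0:
            raise ValidationError(f"notch_depth must be >= 0, got {self.notch_depth}")
        if self.notch_depth >= min(self.systolic_amplitude, self.diastolic_amplitude):
            raise ValidationError(
                "notch_depth must be smaller than both pulse amplitudes, got "
                f"notch_depth={self.notch_depth}"
            )
        t_sys = self.t_systolic
        t_dia = self.t_diastolic
        if not 0 < t_sys < t_dia < self.beat_period:
            raise ValidationError(
                "require 0 < systolic_time < diastolic_time < beat_period, got "
                f"systolic_time={t_sys}, diastolic_time={t_dia}, "
                f"beat_period={self.beat_period}"
            )
        for w in self.widths:
            if not w > 0:
                raise ValidationError(f"pulse_widths must be > 0, got {self.pulse_widths}")

    @property
    def t_systolic(self) -> float:
        if self.systolic_time is not None:
            return self.systolic_time
        return _SYS_CENTER_FRAC * self.beat_period

    @property
    def t_diastolic(self) -> float:
        if self.diastolic_time is not None:
            return self.diastolic_time
        return _DIA_CENTER_FRAC * self.beat_period

    @property
    def widths(self) -> tuple[float, float, float]:
        if self.pulse_widths is not None:
            return self.pulse_widths
        T = self.beat_period
        return (_SYS_WIDTH_FRAC * T, _DIA_WIDTH_FRAC * T, _NOTCH_WIDTH_FRAC * T)


@dataclass(frozen=True)
class SubjectProfile:
    """Personal covariates of one subject (the model's P-features)."""

    subject_id: str
    age: float = 30.0
    sex: str = "M"
    height: float = 175.0
    weight: float = 70.0

    def __post_init__(self) -> None:
        for name in ("age", "height", "weight"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class GlucoseLink:
    """Affine map from blood glucose (mmol/L) to beat fiducial amplitudes.

    Each anchored amplitude a(g) = baseline + slope * (g - reference_glucose),
    in a.u.  The additive waveform noise has standard deviation
    ``max(noise_floor, noise_intercept - noise_slope * g)`` — a monotone
    non-increasing function of glucose.
    """

    sp_baseline: float = 1.0
    dp_baseline: float = 0.52
    dn_baseline: float = 0.30
    sp_slope: float = 0.10
    dp_slope: float = 0.06
    dn_slope: float = 0.035
    reference_glucose: float = 5.0
    noise_intercept: float = 0.06
    noise_slope: float = 0.008
    noise_floor: float = 0.004

    def __post_init__(self) -> None:
        for name in ("sp_slope", "dp_slope", "dn_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.noise_floor < 0 or self.noise_slope < 0:
            raise ValidationError("noise_floor and noise_slope must be >= 0")

    def amplitudes(self, glucose: float) -> tuple[float, float, float]:
        """(SP-Bot, DP-Bot, DN-Bot) target amplitudes at ``glucose`` mmol/L."""
        dg = glucose - self.reference_glucose
        return (
            self.sp_baseline + self.sp_slope * dg,
            self.dp_baseline + self.dp_slope * dg,
            self.dn_baseline + self.dn_slope * dg,
        )

    def noise_sd(self, glucose: float) -> float:
        return max(self.noise_floor, self.noise_intercept - self.noise_slope * glucose)

    def scaled_noise(self, factor: float) -> "GlucoseLink":
        """Copy of this link with all noise parameters multiplied by ``factor``."""
        return dataclasses.replace(
            self,
            noise_intercept=self.noise_intercept * factor,
            noise_slope=self.noise_slope * factor,
            noise_floor=self.noise_floor * factor,
        )

    @classmethod
    def noiseless(cls, **kwargs) -> "GlucoseLink":
        return cls(noise_intercept=0.0, noise_slope=0.0, noise_floor=0.0, **kwargs)


def default_link(noise_scale: float = 1.0) -> GlucoseLink:
    """The study-condition glucose link, optionally with scaled noise."""
    return GlucoseLink().scaled_noise(noise_scale)


_SCENARIO_NAMES = ("nir_single", "solar_single", "multi_patient")


@dataclass(frozen=True)
class ScenarioSpec:
    """Shape of one synthetic measurement campaign."""

    name: str
    n_records: int
    glucose_range: tuple[float, float]
    n_subjects: int = 1
    duration: float = 8.0
    sampling_rate: float = 500.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _SCENARIO_NAMES:
            raise ValidationError(
                f"unknown scenario name {self.name!r}; valid names: "
                + ", ".join(_SCENARIO_NAMES)
            )
        if not self.n_records > 0:
            raise ValidationError(f"n_records must be > 0, got {self.n_records}")
        lo, hi = self.glucose_range
        if not lo < hi:
            raise ValidationError(f"glucose_range lower must be < upper, got {self.glucose_range}")
        if not lo > 0:
            raise ValidationError("glucose_range must be positive")
        if not self.sampling_rate >= 50.0:
            raise ValidationError(f"sampling_rate must be >= 50 Hz, got {self.sampling_rate}")
        if not self.n_subjects > 0:
            raise ValidationError("n_subjects must be > 0")


#: Named presets mirroring the three measurement campaigns (plus the
#: 88-record single-individual training-scale variant).
SCENARIO_PRESETS: dict[str, ScenarioSpec] = {
    "nir_single": ScenarioSpec("nir_single", 292, (4.4, 6.4)),
    "nir_single_88": ScenarioSpec("nir_single", 88, (4.4, 6.4)),
    "solar_single": ScenarioSpec("solar_single", 237, (4.4, 6.4), noise_scale=3.0),
    "multi_patient": ScenarioSpec(
        "multi_patient", 626, (3.9, 15.0), n_subjects=49, noise_scale=2.0
    ),
}


def scenario_preset(name: str) -> ScenarioSpec:
    try:
        return SCENARIO_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown scenario preset {name!r}; valid presets: "
            + ", ".join(sorted(SCENARIO_PRESETS))
        ) from None


# ---------------------------------------------------------------------------
# Beat synthesis
# ---------------------------------------------------------------------------


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _gauss_two_sided(
    t: np.ndarray, center: float, width_left: float, width_right: float
) -> np.ndarray:
    width = np.where(t < center, width_left, width_right)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


@dataclass(frozen=True)
class _BeatComponents:
    """Calibrated pulse components of one beat."""

    amps: tuple[float, float, float]  # systolic, diastolic, notch
    centers: tuple[float, float, float]
    widths: tuple[float, float, float]
    period: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        cs, cd, cn = self.amps
        ts, td, tn = self.centers
        ss, sd, sn = self.widths
        out = cs * _gauss_two_sided(t, ts, _SYS_RISE_RATIO * ss, ss)
        out = out + cd * _gauss(t, td, sd)
        if cn != 0.0:
            out = out - cn * _gauss(t, tn, sn)
        return out


@dataclass(frozen=True)
class BeatTruth:
    """Generator ground truth for one beat (times relative to beat start, s)."""

    t_sp: float
    a_sp: float
    t_dn: float | None
    a_dn: float | None
    t_dp: float | None
    a_dp: float | None
    t_bot: float
    bot_value: float
    has_notch: bool
    start_time: float = 0.0

    def shifted(self, offset: float) -> "BeatTruth":
        return dataclasses.replace(self, start_time=self.start_time + offset)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _measure_fiducials(t: np.ndarray, x: np.ndarray) -> dict:
    """Fiducials of a noise-free beat evaluated on a fine grid.

    Bot is the window's global minimum — the inter-beat trough, which in a
    recording is where trough-to-trough segmentation anchors each beat.
    """
    i_sp = int(np.argmax(x))
    i_bot = int(np.argmin(x))
    out = {
        "t_sp": float(t[i_sp]),
        "a_sp": float(x[i_sp] - x[i_bot]),
        "t_bot": float(t[i_bot]),
        "bot_value": float(x[i_bot]),
    }
    seg = x[i_sp:]
    d = np.diff(seg)
    mins = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    if len(mins) == 0:
        return out
    i_dn = i_sp + int(mins[np.argmin(seg[mins])])
    seg2 = x[i_dn:]
    d2 = np.diff(seg2)
    maxs = np.nonzero((d2[:-1] > 0) & (d2[1:] <= 0))[0] + 1
    if len(maxs) == 0:
        return out
    i_dp = i_dn + int(maxs[np.argmax(seg2[maxs])])
    out.update(
        t_dn=float(t[i_dn]),
        a_dn=float(x[i_dn] - x[i_bot]),
        t_dp=float(t[i_dp]),
        a_dp=float(x[i_dp] - x[i_bot]),
    )
    return out


def _calibrate(params: BeatParams) -> tuple[_BeatComponents, BeatTruth]:
    """Fit component amplitudes/centres so measured fiducials hit targets."""
    T = params.beat_period
    ss, sd, sn = params.widths
    t_sys, t_dia = params.t_systolic, params.t_diastolic
    t_notch = 0.5 * (t_sys + t_dia)  # notch centred between the two pulses
    a_sp = params.systolic_amplitude
    a_dp = params.diastolic_amplitude
    a_dn = params.diastolic_amplitude - params.notch_depth
    t = np.linspace(0.0, T, _FINE_GRID_N)

    if params.notch_depth == 0.0:
        comp = _BeatComponents(
            (a_sp, _SHOULDER_FRAC * a_dp, 0.0), (t_sys, t_dia, t_notch), (ss, sd, sn), T
        )
        # only the systolic peak can be calibrated in the shoulder case
        cs, cts = a_sp, t_sys
        for _ in range(_CALIBRATION_ITERS):
            comp = _BeatComponents(
                (cs, _SHOULDER_FRAC * a_dp, 0.0), (cts, t_dia, t_notch), (ss, sd, sn), T
            )
            m = _measure_fiducials(t, comp(t))
            cs += a_sp - m["a_sp"]
            cts += t_sys - m["t_sp"]
        m = _measure_fiducials(t, comp(t))
        truth = BeatTruth(
            t_sp=m["t_sp"],
            a_sp=m["a_sp"],
            t_dn=None,
            a_dn=None,
            t_dp=None,
            a_dp=None,
            t_bot=m["t_bot"],
            bot_value=m["bot_value"],
            has_notch=False,
        )
        return comp, truth

    cs, cd, cn = a_sp, _SHOULDER_FRAC * a_dp, params.notch_depth
    cts, ctd = t_sys, t_dia
    comp = _BeatComponents((cs, cd, cn), (cts, ctd, t_notch), (ss, sd, sn), T)
    for _ in range(_CALIBRATION_ITERS):
        comp = _BeatComponents((cs, cd, cn), (cts, ctd, t_notch), (ss, sd, sn), T)
        m = _measure_fiducials(t, comp(t))
        if "a_dn" not in m:
            raise ValidationError(
                "beat calibration failed: no dicrotic notch emerges for "
                f"params {params!r}"
            )
        cs += a_sp - m["a_sp"]
        cts += t_sys - m["t_sp"]
        cd += a_dp - m["a_dp"]
        ctd += t_dia - m["t_dp"]
        cn += m["a_dn"] - a_dn
    m = _measure_fiducials(t, comp(t))
    if "a_dn" not in m:
        raise ValidationError(f"beat calibration failed for params {params!r}")
    truth = BeatTruth(
        t_sp=m["t_sp"],
        a_sp=m["a_sp"],
        t_dn=m["t_dn"],
        a_dn=m["a_dn"],
        t_dp=m["t_dp"],
        a_dp=m["a_dp"],
        t_bot=m["t_bot"],
        bot_value=m["bot_value"],
        has_notch=True,
    )
    return comp, truth


def simulate_beat(params: BeatParams, sampling_rate: float = 500.0) -> np.ndarray:
    """One noise-free beat sampled at ``sampling_rate`` Hz.

    The segment has length ``round(beat_period * sampling_rate)``; its global
    maximum lies at the systolic time, followed (for a nonzero notch) by the
    dicrotic-notch local minimum and the diastolic-peak local maximum, with
    the endpoints near the beat minimum.
    """
    if not sampling_rate > 0:
        raise ValidationError(f"sampling_rate must be > 0, got {sampling_rate}")
    comp, _ = _calibrate(params)
    n = int(round(params.beat_period * sampling_rate))
    t = np.arange(n) / sampling_rate
    return comp(t)


def beat_ground_truth(params: BeatParams) -> BeatTruth:
    """Fiducial times/amplitudes of the continuous beat model for ``params``."""
    _, truth = _calibrate(params)
    return truth


# ---------------------------------------------------------------------------
# Recordings and cohorts
# ---------------------------------------------------------------------------

_DEFAULT_PROFILE = SubjectProfile("S001", age=30.0, sex="M", height=175.0, weight=70.0)

#: Relative amplitude attenuation per BMI unit above 25 kg/m^2 — a simple
#: stand-in for thicker tissue transmitting less pulsatile light.
_BMI_GAIN_SLOPE = 0.005


def _subject_gain(profile: SubjectProfile) -> float:
    return float(np.clip(1.0 - _BMI_GAIN_SLOPE * (profile.bmi - 25.0), 0.7, 1.3))


def simulate_recording(
    profile: SubjectProfile,
    glucose: float,
    link: GlucoseLink | None = None,
    duration: float = 8.0,
    sampling_rate: float = 500.0,
    seed: int | None = None,
) -> tuple[PPGRecord, list[BeatTruth]]:
    """A multi-beat PPG recording at a fixed glucose level, plus ground truth.

    The beat rate is drawn uniformly in 60-100 bpm (inside the 1-3 Hz human
    heart-rate band), the recording starts at a random phase of the beat
    cycle, and white Gaussian noise with ``link.noise_sd(glucose)`` is added.
    Ground truth lists the true fiducials of every complete beat.
    """
    if link is None:
        link = default_link()
    if not glucose > 0:
        raise ValidationError(f"glucose must be > 0 mmol/L, got {glucose}")
    rng = np.random.default_rng(seed)
    bpm = rng.uniform(60.0, 100.0)
    period = 60.0 / bpm
    if duration < 3.0 * period:
        raise ValidationError(
            f"duration {duration} s too short: must cover >= 3 beats of period "
            f"{period:.3f} s"
        )
    a_sp, a_dp, a_dn = link.amplitudes(glucose)
    gain = _subject_gain(profile)
    params = BeatParams(
        systolic_amplitude=gain * a_sp,
        diastolic_amplitude=gain * a_dp,
        notch_depth=gain * (a_dp - a_dn),
        beat_period=period,
    )
    comp, truth = _calibrate(params)
    phase = rng.uniform(0.0, period)
    n = int(round(duration * sampling_rate))
    times = np.arange(n) / sampling_rate
    x = comp((times + phase) % period)
    sd = link.noise_sd(glucose)
    if sd > 0:
        x = x + rng.normal(0.0, sd, size=n)
    record = PPGRecord(times=times, intensities=x, sampling_rate=sampling_rate,
                       subject_id=profile.subject_id)
    # Ground truth lists the beats that trough-to-trough segmentation can
    # recover: both delimiting troughs (at start + t_bot and one period
    # earlier) must lie inside the record, away from the edges by a small
    # margin where peak detection is unreliable.
    margin = 0.05
    truths: list[BeatTruth] = []
    start = -phase
    while start < duration:
        prev_trough = start - period + truth.t_bot
        this_trough = start + truth.t_bot
        if prev_trough >= margin and this_trough <= duration - margin:
            truths.append(truth.shifted(start))
        start += period
    return record, truths


@dataclass(frozen=True)
class CohortEntry:
    """One simulated measurement: waveform, subject, reference glucose, truth."""

    record: PPGRecord
    profile: SubjectProfile
    glucose: float
    beats: tuple[BeatTruth, ...]


def _draw_profiles(n_subjects: int, rng: np.random.Generator) -> list[SubjectProfile]:
    if n_subjects == 1:
        return [_DEFAULT_PROFILE]
    profiles = []
    for i in range(n_subjects):
        sex = "F" if rng.random() < 0.5 else "M"
        height = float(np.clip(rng.normal(162.0 if sex == "F" else 175.0, 7.0), 140, 200))
        weight = float(np.clip(rng.normal(68.0 if sex == "F" else 80.0, 13.0), 40, 140))
        age = float(rng.integers(25, 76))
        profiles.append(
            SubjectProfile(f"P{i + 1:03d}", age=age, sex=sex, height=height, weight=weight)
        )
    return profiles


def simulate_cohort(
    spec: ScenarioSpec,
    link: GlucoseLink | None = None,
    seed: int | None = None,
) -> list[CohortEntry]:
    """Simulate ``spec.n_records`` recordings with known glucose labels.

    Labels are drawn uniformly on the closed glucose range; the two range
    endpoints are always inserted once (records 0 and 1) so the label min and
    max are deterministic.  The ``multi_patient`` scenario draws distinct
    subject profiles and assigns records to subjects round-robin.
    """
    if link is None:
        link = default_link(spec.noise_scale)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng = np.random.default_rng(ss)
    lo, hi = spec.glucose_range
    labels = rng.uniform(lo, hi, size=spec.n_records)
    labels[0] = lo
    if spec.n_records > 1:
        labels[1] = hi
    n_subjects = spec.n_subjects if spec.name == "multi_patient" else 1
    profiles = _draw_profiles(n_subjects, rng)
    child_seeds = ss.spawn(spec.n_records)
    entries = []
    for i in range(spec.n_records):
        profile = profiles[i % len(profiles)]
        record, beats = simulate_recording(
            profile,
            float(labels[i]),
            link=link,
            duration=spec.duration,
            sampling_rate=spec.sampling_rate,
            seed=child_seeds[i],
        )
        entries.append(CohortEntry(record, profile, float(labels[i]), tuple(beats)))
    return entries


def write_cohort(entries: Sequence[CohortEntry], outdir: str | Path) -> Path:
    """Write waveform CSVs, ground-truth JSON sidecars and a manifest CSV.

    Returns the manifest path.  The manifest has columns
    ``record_path,subject_id,glucose_mmol_per_l``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, entry in enumerate(entries):
        name = f"record_{i:04d}.csv"
        write_ppg_csv(entry.record, outdir / name)
        sidecar = {
            "subject": dataclasses.asdict(entry.profile),
            "glucose_mmol_per_l": entry.glucose,
            "beats": [b.to_dict() for b in entry.beats],
        }
        (outdir / f"record_{i:04d}.truth.json").write_text(
            json.dumps(sidecar, sort_keys=True, indent=1)
        )
        rows.append(
            {
                "record_path": name,
                "subject_id": entry.profile.subject_id,
                "glucose_mmol_per_l": entry.glucose,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
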