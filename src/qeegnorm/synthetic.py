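"""Synthetic normative-cohort generator.

Emulates the statistical structure the normative pipeline assumes: ages
4.5-81 years, two sexes, per-band log-power age trajectories with the three
canonical developmental trends (sharp juvenile decline of the slow bands,
steady adult decline of alpha, steady adult rise of beta), lognormal
between-subject variation, screening scores spanning the instrument
categories, and injectable anomalies (e.g. theta or beta3 excess).

The age trend of mean log band power is piecewise: an exponential-decay
segment over [4.5, 20) joined continuously to a linear segment over
[20, 81] — the simplest smooth form reproducing all three trend shapes.
A between-sex difference is applied symmetrically (+offset/2 to females,
-offset/2 to males) so the pooled-cohort mixture has SD
``sqrt(noise_sd**2 + offset**2 / 4)``.

Only the spectral-power structure of resting EEG is emulated; no attempt is
made at realistic waveform morphology (spindles, blinks, alpha reactivity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_NAMES, BANDS, CHANNEL_REGION, MONTAGE_1020, PARTITION_BANDS, check_band, check_channel
from .eligibility import CNSVS_TESTS, KWPPSI_TESTS, ScreeningScores, assign_age_group, raw_from_percentile

__all__ = [
    "TrendParams",
    "CohortConfig",
    "Subject",
    "Cohort",
    "DEFAULT_TREND_PARAMS",
    "DEFAULT_SEX_OFFSET",
    "trend_mean_log_power",
    "sample_cohort",
    "synthesize_eeg",
    "inject_anomaly",
]

JUVENILE_KNEE = 20.0  # age (years) where the decay segment hands over to the linear one


@dataclass(frozen=True)
class TrendParams:
    """Piecewise age-trend parameters for one band's mean log power.

    mean(age) = base + amp * exp(-rate * (age - 4.5))          for age < 20
              = mean(20) + slope * (age - 20)                  for age >= 20
    (natural-log µV² units throughout).
    """

    base: float
    amp: float
    rate: float
    slope: float

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        juvenile = self.base + self.amp * np.exp(-self.rate * (age - 4.5))
        at_knee = self.base + self.amp * np.exp(-self.rate * (JUVENILE_KNEE - 4.5))
        adult = at_knee + self.slope * (age - JUVENILE_KNEE)
        return np.where(age < JUVENILE_KNEE, juvenile, adult)


#: Default per-band trends: delta/theta drop sharply through childhood then
#: stay flat; alpha declines steadily through adulthood; the beta family rises.
DEFAULT_TREND_PARAMS: dict[str, TrendParams] = {
    "delta": TrendParams(base=2.2, amp=1.6, rate=0.18, slope=-0.002),
    "theta": TrendParams(base=1.6, amp=1.4, rate=0.16, slope=-0.002),
    "alpha": TrendParams(base=1.9, amp=0.3, rate=0.08, slope=-0.009),
    "beta": TrendParams(base=0.8, amp=0.4, rate=0.12, slope=0.006),
    "beta3": TrendParams(base=0.0, amp=0.3, rate=0.12, slope=0.007),
    "gamma": TrendParams(base=-0.4, amp=0.2, rate=0.10, slope=0.004),
}

#: Default between-sex log-power differences (female minus male); theta is the
#: band the sex-difference experiments target.
DEFAULT_SEX_OFFSET: dict[str, float] = {band: 0.0 for band in BAND_NAMES}
DEFAULT_SEX_OFFSET["theta"] = 0.15

#: Mild spatial modulation of each band's trend by scalp region (log units);
#: posterior-dominant alpha, frontal-dominant slow waves.
_REGION_OFFSETS: dict[str, dict[str, float]] = {
    "delta": {"frontal": 0.10, "central": 0.0, "temporal": -0.05, "parietal": 0.0, "occipital": -0.05},
    "theta": {"frontal": 0.10, "central": 0.05, "temporal": -0.05, "parietal": 0.0, "occipital": -0.05},
    "alpha": {"frontal": -0.15, "central": -0.05, "temporal": -0.05, "parietal": 0.10, "occipital": 0.25},
    "beta": {"frontal": 0.05, "central": 0.05, "temporal": 0.0, "parietal": 0.0, "occipital": -0.05},
    "beta3": {"frontal": 0.05, "central": 0.05, "temporal": 0.0, "parietal": 0.0, "occipital": -0.05},
    "gamma": {"frontal": 0.0, "central": 0.0, "temporal": 0.05, "parietal": 0.0, "occipital": -0.05},
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort."""

    n_per_sex: int = 400
    age_range: tuple[float, float] = (4.5, 81.0)
    trend_params: Mapping[str, TrendParams] = field(
        default_factory=lambda: dict(DEFAULT_TREND_PARAMS)
    )
    sex_offset: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_OFFSET)
    )
    noise_sd: float = 0.3
    screening_fail_fraction: float = 0.0
    condition: str = "EC"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if lo < 4.5 or hi > 81.0:
            raise ValueError("age_range must lie within [4.5, 81]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.screening_fail_fraction < 1:
            raise ValueError("screening_fail_fraction must be in [0, 1)")
        if self.n_per_sex < 2:
            raise ValueError("n_per_sex must be >= 2 to support any downstream fit")
        if self.condition not in ("EC", "EO"):
            raise ValueError("condition must be 'EC' or 'EO'")


@dataclass(frozen=True)
class Subject:
    """One synthetic subject: demographics, screening record, band powers."""

    id: str
    age: float
    sex: str
    condition: str
    screening: ScreeningScores
    band_log_powers: pd.DataFrame  # index: channel, columns: band
    noise_sd: float = 0.3
    is_anomalous: bool = False
    anomaly_spec: Optional[tuple] = None  # (band, channels, shift_sd)
    screening_should_fail: bool = False


@dataclass
class Cohort:
    """A sampled cohort plus the configuration that produced it."""

    subjects: list
    config: CohortConfig

    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.id for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "condition": [s.condition for s in self.subjects],
                "is_anomalous": [s.is_anomalous for s in self.subjects],
                "screening_should_fail": [s.screening_should_fail for s in self.subjects],
            }
        )

    def band_power_table(self) -> pd.DataFrame:
        """Long-format table: one row per (subject, channel, band)."""
        frames = []
        for s in self.subjects:
            lp = s.band_log_powers.stack()
            lp.index.names = ["channel", "band"]
            df = lp.rename("log_power").reset_index()
            df.insert(0, "subject_id", s.id)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out["power_uv2"] = np.exp(out["log_power"])
        return out[["subject_id", "channel", "band", "power_uv2", "log_power"]]

    def screening_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            sc = s.screening
            row: dict = {"subject_id": s.id, "age": s.age, "sex": s.sex}
            for t in KWPPSI_TESTS:
                row[f"kwppsi_{t}"] = sc.kwppsi.get(t)
            for t in CNSVS_TESTS:
                row[f"cnsvs_{t}"] = sc.cnsvs.get(t)
            row.update(
                mmse=sc.mmse,
                stai_state=sc.stai_state,
                stai_trait=sc.stai_trait,
                cdi=sc.cdi,
                bdi=sc.bdi,
                kcbcl_depression_pct=sc.kcbcl_depression_pct,
                kcbcl_anxiety_pct=sc.kcbcl_anxiety_pct,
                behavioral_expert_pass=sc.behavioral_expert_pass,
                history_flags=";".join(sorted(sc.history_flags)),
            )
            rows.append(row)
        return pd.DataFrame(rows)


def trend_mean_log_power(
    age: float,
    sex: str,
    band: str,
    channel: str,
    trend_params: Mapping[str, TrendParams] | None = None,
    sex_offset: Mapping[str, float] | None = None,
):
    """Mean log band power (natural-log µV²) at a given age, sex and site.

    Smooth and continuous in age (piecewise-differentiable at the knee near
    age 20); the sex offset shifts females up and males down by half the
    configured between-sex difference for that band.
    """
    check_band(band)
    check_channel(channel)
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    params = (trend_params or DEFAULT_TREND_PARAMS)[band]
    offset = (sex_offset or DEFAULT_SEX_OFFSET).get(band, 0.0)
    region = CHANNEL_REGION[channel]
    spatial = _REGION_OFFSETS[band][region]
    half = offset / 2.0 if sex == "female" else -offset / 2.0
    value = params(age) + spatial + half
    return float(value) if np.isscalar(age) else value


def _trend_matrix(age: float, sex: str, config: CohortConfig) -> np.ndarray:
    """(n_channels, n_bands) matrix of trend means for one subject."""
    out = np.empty((len(MONTAGE_1020), len(BAND_NAMES)))
    for j, band in enumerate(BAND_NAMES):
        params = config.trend_params[band]
        offset = config.sex_offset.get(band, 0.0)
        half = offset / 2.0 if sex == "female" else -offset / 2.0
        base = params(age) + half
        for i, ch in enumerate(MONTAGE_1020):
            out[i, j] = base + _REGION_OFFSETS[band][CHANNEL_REGION[ch]]
    return out


def _sample_screening(rng: np.random.Generator, age: float, sex: str, should_fail: bool) -> ScreeningScores:
    """Draw a screening record that passes (or fails) the eligibility rules."""
    group = assign_age_group(age)

    def benign_raw() -> float:
        # percentile uniform in (25, 75) -> comfortably clear of the 7% rule
        return round(raw_from_percentile(rng.uniform(25, 75)), 1)

    kw: dict[str, float] = {}
    cn: dict[str, float] = {}
    mmse = stai_s = stai_t = cdi = bdi = dep = anx = None
    expert: Optional[bool] = None
    flags: set[str] = set()

    if group == "infant":
        kw = {t: benign_raw() for t in KWPPSI_TESTS}
        dep = round(float(rng.uniform(5, 85)), 1)
        anx = round(float(rng.uniform(5, 85)), 1)
        expert = True
    else:
        cn = {t: benign_raw() for t in CNSVS_TESTS}
        stai_s = int(rng.integers(20, 51))
        stai_t = int(rng.integers(20, 51))
        if group == "child":
            cdi = int(rng.integers(0, 16))
            expert = True
        else:
            bdi = int(rng.integers(0, 10))
        if group == "adult2":
            mmse = int(rng.integers(27, 31))

    if should_fail:
        modes = ["history", "cognitive", "emotional"]
        if group in ("infant", "child"):
            modes.append("behavioral")
        mode = modes[rng.integers(len(modes))]
        if mode == "history":
            flags.add(rng.choice(["head_trauma", "epilepsy", "psychiatric_history"]))
        elif mode == "cognitive":
            # one required test below the 2nd percentile
            bad = round(raw_from_percentile(rng.uniform(0.2, 1.5)), 1)
            if group == "infant":
                kw[rng.choice(KWPPSI_TESTS)] = bad
            else:
                cn[rng.choice(CNSVS_TESTS)] = bad
        elif mode == "emotional":
            if group == "infant":
                key = rng.choice(["dep", "anx"])
                if key == "dep":
                    dep = round(float(rng.uniform(98.1, 100)), 1)
                else:
                    anx = round(float(rng.uniform(98.1, 100)), 1)
            elif group == "child":
                cdi = int(rng.integers(29, 41))
            else:
                bdi = int(rng.integers(24, 41))
        else:  # behavioral
            expert = False

    return ScreeningScores(
        kwppsi=kw,
        cnsvs=cn,
        mmse=mmse,
        stai_state=stai_s,
        stai_trait=stai_t,
        cdi=cdi,
        bdi=bdi,
        kcbcl_depression_pct=dep,
        kcbcl_anxiety_pct=anx,
        behavioral_expert_pass=expert,
        history_flags=frozenset(flags),
    )


def sample_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Sample a full cohort: demographics, screening records, band powers.

    Log band power = age/sex/site trend + Gaussian(0, noise_sd) residual,
    i.e. power itself is lognormal.  Deterministic given the config seed
    (or an explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    lo, hi = config.age_range
    subjects = []
    counter = 0
    for sex in ("male", "female"):
        ages = rng.uniform(lo, hi, size=config.n_per_sex)
        fails = rng.random(config.n_per_sex) < config.screening_fail_fraction
        for age, should_fail in zip(ages, fails):
            counter += 1
            sid = f"S{counter:05d}"
            trend = _trend_matrix(age, sex, config)
            noise = rng.normal(0.0, config.noise_sd, size=trend.shape)
            table = pd.DataFrame(
                trend + noise, index=list(MONTAGE_1020), columns=list(BAND_NAMES)
            )
            screening = _sample_screening(rng, float(age), sex, bool(should_fail))
            subjects.append(
                Subject(
                    id=sid,
                    age=float(age),
                    sex=sex,
                    condition=config.condition,
                    screening=screening,
                    band_log_powers=table,
                    noise_sd=config.noise_sd,
                    screening_should_fail=bool(should_fail),
                )
            )
    return Cohort(subjects=subjects, config=config)


def inject_anomaly(
    subject: Subject, band: str, channels: Iterable[str], shift: float
) -> Subject:
    """Return a copy of *subject* with excess power injected.

    Log power in the named band and channels is increased by
    ``shift * subject.noise_sd``, so *shift* reads directly as a target
    z-score against a correctly calibrated normative model.  All other
    cells are untouched.
    """
    check_band(band)
    channels = list(channels)
    if not channels:
        raise ValueError("channel set for anomaly injection must be non-empty")
    for ch in channels:
        check_channel(ch)
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    table = subject.band_log_powers.copy()
    table.loc[channels, band] += shift * subject.noise_sd
    return replace(
        subject,
        band_log_powers=table,
        is_anomalous=True,
        anomaly_spec=(band, tuple(channels), float(shift)),
    )


def synthesize_eeg(
    subject: Subject,
    fs: float = 250.0,
    duration: float = 240.0,
    rng: np.random.Generator | None = None,
    calibration_iters: int = 3,
    bandpass: tuple[float, float] = (1.0, 45.5),
    notch: float | None = 60.0,
):
    """Synthesize a multichannel resting-state EEG matching the subject's band powers.

    Each channel is a sum over the partition bands of brick-wall band-limited
    Gaussian noise (built in the frequency domain, so components do not leak
    across band edges).  A short fixed-point calibration (i) makes each band
    component zero-sum across channels, so that common-average re-referencing
    downstream is a no-op, and (ii) rescales components so that the Welch
    band power of the *filtered* composite — the same band-pass/notch filters
    the extraction stage applies — matches the subject's target power
    (µV², i.e. ``exp(log_power)``) per channel and band.

    Returns ``(data, fs, channel_labels)`` with *data* of shape
    (19, duration*fs) in µV.
    """
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    nyq = fs / 2.0
    for name in PARTITION_BANDS:
        if BANDS[name].high >= nyq:
            raise ValueError(
                f"band {name} upper edge {BANDS[name].high} Hz is at/above Nyquist ({nyq} Hz)"
            )
    if rng is None:
        import zlib

        rng = np.random.default_rng(np.random.SeedSequence(zlib.crc32(subject.id.encode())))
    n = int(round(duration * fs))
    n_ch = len(MONTAGE_1020)
    targets = np.exp(
        subject.band_log_powers.loc[list(MONTAGE_1020), list(PARTITION_BANDS)].to_numpy()
    )
    if not np.isfinite(targets).all():
        targets = np.nan_to_num(targets, nan=0.0, posinf=0.0, neginf=0.0)

    # brick-wall band noise: Gaussian rfft coefficients confined to band bins
    freqs_fft = np.fft.rfftfreq(n, d=1.0 / fs)
    comps = []
    for name in PARTITION_BANDS:
        band = BANDS[name]
        sel = (freqs_fft >= band.low) & (freqs_fft < band.high)
        spec = np.zeros((n_ch, len(freqs_fft)), dtype=complex)
        spec[:, sel] = rng.standard_normal((n_ch, sel.sum())) + 1j * rng.standard_normal(
            (n_ch, sel.sum())
        )
        comps.append(np.fft.irfft(spec, n=n, axis=-1))

    # the filters the extraction stage will apply (zero-phase)
    sos = sps.butter(4, list(bandpass), btype="bandpass", fs=fs, output="sos")
    if notch is not None:
        nb, na = sps.iirnotch(notch, 30.0, fs=fs)

    def extraction_view(x: np.ndarray) -> np.ndarray:
        y = sps.sosfiltfilt(sos, x, axis=-1)
        if notch is not None:
            y = sps.filtfilt(nb, na, y, axis=-1)
        return y

    nperseg = int(2 * fs)

    def band_powers_of(x: np.ndarray) -> np.ndarray:
        freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
        out = np.empty((n_ch, len(PARTITION_BANDS)))
        for j, name in enumerate(PARTITION_BANDS):
            band = BANDS[name]
            bsel = (freqs >= band.low) & (freqs <= band.high)
            out[:, j] = np.trapezoid(psd[:, bsel], freqs[bsel], axis=-1)
        return out

    # joint fixed-point calibration against the filtered composite
    for _ in range(calibration_iters):
        comps = [c - c.mean(axis=0, keepdims=True) for c in comps]
        measured = band_powers_of(extraction_view(sum(comps)))
        for j in range(len(PARTITION_BANDS)):
            scale = np.sqrt(
                np.divide(
                    targets[:, j], measured[:, j],
                    out=np.zeros_like(targets[:, j]), where=measured[:, j] > 0,
                )
            )
            comps[j] *= scale[:, None]
    return sum(comps), fs, list(MONTAGE_1020)
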