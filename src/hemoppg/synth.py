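"""Synthetic eight-wavelength PPG cohort generator.

Emulates transmissive finger PPG under the Beer-Lambert forward model of
:mod:`hemoppg.optics`: each channel is a DC level modulated by a periodic
cardiac waveform with per-wavelength fractional depth ``r_lambda``, plus
respiratory baseline wander, additive wide-band noise, a mains tone, and
occasional motion transients.  Ground-truth hemoglobin (and SpO2, heart rate)
is carried on every record, so the generator doubles as a parameter-recovery
test bed for the full estimation pipeline.

What it deliberately does NOT model: photon scattering / melanin, reflective
probes, beat-to-beat heart-rate variability and pulse-shape variability.  See
docs/methods.md for the implications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import HemoppgError
from .optics import (
    DEFAULT_WAVELENGTHS,
    OpticalConfig,
    PhysioState,
    dc_levels,
    modulation_depth,
)

DEFAULT_FS = 100.0       # Hz, acquisition sample rate
DEFAULT_DURATION = 120.0  # s per subject


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbance model, amplitudes relative to the channel DC level.

    white_sd        SD of additive Gaussian noise (fraction of DC).
    drift_amp       amplitude of the respiratory baseline-wander sinusoid.
    drift_freq      wander frequency in Hz; None = use the subject's resp_rate.
    powerline_amp   amplitude of the mains tone (fraction of DC).
    powerline_freq  mains frequency in Hz (50 Hz aliases to Nyquist at fs=100).
    motion_prob     probability of a motion transient per 5 s segment.
    motion_amp      peak amplitude of a motion transient (fraction of DC).
    """

    white_sd: float = 0.002
    drift_amp: float = 0.02
    drift_freq: float | None = None
    powerline_amp: float = 0.005
    powerline_freq: float = 50.0
    motion_prob: float = 0.05
    motion_amp: float = 0.05

    def __post_init__(self) -> None:
        for name in ("white_sd", "drift_amp", "powerline_amp", "motion_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_freq is not None and not 0 < self.drift_freq < 0.5:
            raise ValueError("drift_freq must lie in (0, 0.5) Hz")
        if not 0 <= self.motion_prob <= 1:
            raise ValueError("motion_prob must be a probability")
        if self.powerline_freq <= 0:
            raise ValueError("powerline_freq must be > 0")

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        """All disturbance amplitudes zero (oracle conditions)."""
        return cls(white_sd=0.0, drift_amp=0.0, powerline_amp=0.0,
                   motion_prob=0.0, motion_amp=0.0)


@dataclass
class MultiChannelPPG:
    """Eight aligned PPG sample streams.

    channels: array of shape (n_samples, 8), one column per wavelength.
    """

    channels: np.ndarray
    fs: float
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != len(self.wavelengths):
            raise ValueError("channels must be (n_samples, n_wavelengths)")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SubjectRecord:
    """One synthetic subject: PPG plus metadata and ground truth."""

    subject_id: str
    ppg: MultiChannelPPG
    age: float
    gender: int            # 0 = female, 1 = male
    hb_ref: float          # reference hemoglobin, g/dL
    spo2: float = math.nan
    heart_rate: float = math.nan


def _hann_bump(phase: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine bump on the unit circle of phase, zero outside its support."""
    u = (phase - center) / half_width
    out = np.zeros_like(phase)
    inside = np.abs(u) < 1.0
    out[inside] = np.cos(0.5 * np.pi * u[inside]) ** 2
    return out


def pulse_waveform(phase: np.ndarray) -> np.ndarray:
    """Periodic unit-range cardiac waveform as a function of phase in [0, 1).

    Raised-cosine systolic lobe plus a smaller dicrotic bump; the two lobes are
    disjoint so the waveform spans exactly [0, 1] over each cycle (min 0 during
    diastole, max 1 at the systolic peak).  Only the peak-to-trough amplitude
    enters the AC/DC features, so the morphology is a free design choice.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    return _hann_bump(phase, 0.20, 0.18) + 0.30 * _hann_bump(phase, 0.55, 0.15)


def generate_ppg(
    state: PhysioState,
    optics: OpticalConfig | None = None,
    noise: NoiseConfig | None = None,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> MultiChannelPPG:
    """Simulate one subject's eight-channel transmissive PPG.

    Per channel: I(t) = DC * (1 - r * pulse(t)) + DC * disturbances, where
    DC = I0 * exp(-baseline_absorbance) and r is the Beer-Lambert modulation
    depth of :func:`hemoppg.optics.modulation_depth`.  Drift, mains tone and
    motion transients are shared across channels (they are common-mode
    physical disturbances); the wide-band noise is independent per channel.
    Pure function of (parameters, seed).
    """
    optics = optics or OpticalConfig()
    noise = noise or NoiseConfig()
    if duration < 10.0:
        raise ValueError("duration must be >= 10 s")
    if fs <= 0:
        raise ValueError("fs must be > 0")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    phase = (t * state.heart_rate / 60.0) % 1.0
    pulse = pulse_waveform(phase)

    r = modulation_depth(state, optics)          # (8,)
    dc = dc_levels(optics)                        # (8,)

    # Common-mode disturbances (one realisation shared by all channels).
    drift_freq = noise.drift_freq if noise.drift_freq is not None else state.resp_rate
    drift = noise.drift_amp * np.sin(2 * np.pi * drift_freq * t + rng.uniform(0, 2 * np.pi))
    mains = noise.powerline_amp * np.sin(
        2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
    )
    motion = np.zeros(n)
    seg_len = int(5 * fs)
    tau = 0.3  # s, transient time constant
    for start in range(0, n, seg_len):
        if rng.uniform() < noise.motion_prob:
            t0 = t[start] + rng.uniform(0, seg_len / fs)
            sign = rng.choice((-1.0, 1.0))
            motion += sign * noise.motion_amp * np.exp(-((t - t0) ** 2) / (2 * tau**2))
    common = drift + mains + motion

    white = rng.normal(0.0, 1.0, size=(n, len(dc))) if noise.white_sd > 0 else 0.0

    channels = dc[None, :] * (
        1.0 - np.outer(pulse, r) + common[:, None] + noise.white_sd * white
    )
    return MultiChannelPPG(channels=channels, fs=fs, wavelengths=optics.wavelengths)


# ---------------------------------------------------------------------------
# Hemoglobin samplers
# ---------------------------------------------------------------------------

class HbSampler:
    """Distribution over reference hemoglobin values (g/dL)."""

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def mean(self) -> float:
        """Analytic mean of the distribution (used as a Monte-Carlo oracle)."""
        raise NotImplementedError


@dataclass(frozen=True)
class PointMass(HbSampler):
    value: float = 14.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value


@dataclass(frozen=True)
class ClinicalHbSampler(HbSampler):
    """Mixture emulating a clinical cohort: mass concentrated in the normal
    12-16 g/dL range with sparse abnormal tails.

    weight_normal * Normal(mu, sd) + (1 - weight_normal) * Uniform(lo, hi),
    truncated to (bound_lo, bound_hi) by rejection.
    """

    weight_normal: float = 0.8
    mu: float = 14.0
    sd: float = 1.0
    uniform_lo: float = 7.0
    uniform_hi: float = 19.0
    bound_lo: float = 4.0
    bound_hi: float = 22.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            k = size - filled
            comp = rng.uniform(size=k) < self.weight_normal
            draw = np.where(
                comp,
                rng.normal(self.mu, self.sd, size=k),
                rng.uniform(self.uniform_lo, self.uniform_hi, size=k),
            )
            ok = draw[(draw > self.bound_lo) & (draw < self.bound_hi)]
            out[filled:filled + ok.size] = ok
            filled += ok.size
        return out

    def mean(self) -> float:
        # Rejection truncation of the mixture: E = sum_k w_k p_k m_k / sum_k w_k p_k
        # with p_k the in-bounds mass and m_k the conditional in-bounds mean.
        a = (self.bound_lo - self.mu) / self.sd
        b = (self.bound_hi - self.mu) / self.sd
        p_n = stats.norm.cdf(b) - stats.norm.cdf(a)
        m_n = stats.truncnorm.mean(a, b, loc=self.mu, scale=self.sd)
        lo = max(self.uniform_lo, self.bound_lo)
        hi = min(self.uniform_hi, self.bound_hi)
        p_u = (hi - lo) / (self.uniform_hi - self.uniform_lo)
        m_u = 0.5 * (lo + hi)
        w = self.weight_normal
        num = w * p_n * m_n + (1 - w) * p_u * m_u
        den = w * p_n + (1 - w) * p_u
        return float(num / den)


# Cohort demographics: moments of the emulated clinical population.
_AGE_MEAN, _AGE_SD = 41.7, 24.3
_AGE_LO, _AGE_HI = 18.0, 90.0
_MALE_FRACTION = 100.0 / 249.0
_SPO2_MEAN, _SPO2_SD = 0.97, 0.02
_SPO2_LO, _SPO2_HI = 0.88, 1.0


def generate_cohort(
    n: int,
    hb_sampler: HbSampler | None = None,
    optics: OpticalConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
) -> list[SubjectRecord]:
    """Generate ``n`` synthetic subject records.

    Per-subject PPG seed is ``seed + index`` (documented fan-out); metadata for
    subject ``i`` comes from an independent child stream of the same seed.
    Age and gender moments approximate the emulated clinical population
    (age 41.7 +/- 24.3 years truncated to [18, 90]; P(male) = 100/249);
    SpO2 ~ 97 +/- 2 % truncated to [88, 100] %; heart rate uniform 55-95 bpm.
    """
    if n < 1:
        raise HemoppgError(f"cohort size must be >= 1, got {n}")
    hb_sampler = hb_sampler or ClinicalHbSampler()
    optics = optics or OpticalConfig()
    noise = noise or NoiseConfig()

    records: list[SubjectRecord] = []
    for i in range(n):
        sub_seed = seed + i
        meta_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=sub_seed, spawn_key=(1,))
        )
        hb = float(hb_sampler.sample(meta_rng, 1)[0])
        a, b = (_AGE_LO - _AGE_MEAN) / _AGE_SD, (_AGE_HI - _AGE_MEAN) / _AGE_SD
        age = float(stats.truncnorm.rvs(a, b, loc=_AGE_MEAN, scale=_AGE_SD,
                                        random_state=meta_rng))
        gender = int(meta_rng.uniform() < _MALE_FRACTION)
        a, b = (_SPO2_LO - _SPO2_MEAN) / _SPO2_SD, (_SPO2_HI - _SPO2_MEAN) / _SPO2_SD
        spo2 = float(stats.truncnorm.rvs(a, b, loc=_SPO2_MEAN, scale=_SPO2_SD,
                                         random_state=meta_rng))
        hr = float(meta_rng.uniform(55.0, 95.0))
        resp = float(meta_rng.uniform(0.15, 0.35))

        state = PhysioState(hb_total=hb, spo2=spo2, heart_rate=hr, resp_rate=resp)
        ppg = generate_ppg(state, optics, noise, duration=duration, fs=fs, seed=sub_seed)
        records.append(
            SubjectRecord(
                subject_id=f"S{i:04d}", ppg=ppg, age=age, gender=gender,
                hb_ref=hb, spo2=spo2, heart_rate=hr,
            )
        )
    return records
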