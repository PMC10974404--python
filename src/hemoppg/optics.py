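"""Beer-Lambert optical forward model for multi-wavelength transmissive PPG.

The pulsatile change in absorbance at wavelength ``lambda`` produced by arterial
blood pulsation is

    dA(lambda) = (eps_oxy(lambda)*c1 + eps_deoxy(lambda)*c2 + mu_bg(lambda)) * dL

where ``c1 = spo2 * c_tHb`` and ``c2 = (1 - spo2) * c_tHb`` are the oxygenated and
reduced hemoglobin concentrations (g/dL), ``dL`` is the beat-synchronous change of
the average optical path length, and ``mu_bg`` is the absorption coefficient of the
non-hemoglobin fraction of the pulsing blood volume (plasma, i.e. mostly water).
The ratio of two channels cancels ``dL`` (and the source intensity), which is what
makes AC/DC ratio-of-ratios features usable across probes and subjects.

The background term matters: without it the two-chromophore ratio depends only on
oxygen saturation (total Hb cancels between numerator and denominator), and no
amount of regression could recover hemoglobin from ratio features.  Water absorbs
strongly in the near infrared (especially at 940 nm), so the hemoglobin:plasma
proportion of whole blood - i.e. the hemoglobin concentration itself - shifts the
ratios.  Setting ``ext_background`` to zeros recovers the idealised two-chromophore
model.

Default extinction values come from the standard literature compilations of
oxy-/deoxy-hemoglobin molar extinction and water absorption spectra; they are
configuration defaults (any positive, wavelength-distinct table exercises the
pipeline), not measured data shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidPairError

#: The eight LED centre wavelengths (nm) of the acquisition design.
DEFAULT_WAVELENGTHS: tuple[float, ...] = (
    610.0, 630.0, 660.0, 690.0, 750.0, 805.0, 850.0, 940.0,
)

# Molar extinction coefficients, cm^-1 / (mol/L), standard compilation values.
_MOLAR_EXT_OXY = (1092.0, 610.0, 319.6, 276.0, 518.0, 865.0, 1058.0, 1214.0)
_MOLAR_EXT_DEOXY = (9443.0, 5149.0, 3226.6, 2407.0, 1405.2, 762.0, 691.3, 693.4)

# g/dL -> mol/L for hemoglobin (64,500 g/mol): c[mol/L] = c[g/dL] * 10 / 64500
_GDL_TO_MOLAR = 10.0 / 64500.0

# Water absorption coefficient (cm^-1) at the eight wavelengths, scaled by the
# non-hemoglobin (plasma) volume fraction of whole blood (~0.85).
_BACKGROUND_ABS = (0.0022, 0.0025, 0.0031, 0.0043, 0.024, 0.018, 0.037, 0.227)

# Static (non-pulsatile) tissue absorbance per channel; sets the DC level shape.
_BASELINE_ABSORBANCE = (2.2, 2.1, 2.0, 1.9, 1.7, 1.6, 1.5, 1.4)


def _ext_per_gdl(molar: tuple[float, ...]) -> tuple[float, ...]:
    return tuple(m * _GDL_TO_MOLAR for m in molar)


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the probe/tissue system.

    Extinction coefficients are expressed per (g/dL) of hemoglobin per cm of
    path; ``ext_background`` is an absorption coefficient per cm (it multiplies
    the path change directly, not a concentration).  ``path_pulse_amplitude``
    is the beat-synchronous optical path change dL in cm.
    """

    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    ext_oxy: tuple[float, ...] = _ext_per_gdl(_MOLAR_EXT_OXY)
    ext_deoxy: tuple[float, ...] = _ext_per_gdl(_MOLAR_EXT_DEOXY)
    ext_background: tuple[float, ...] = _BACKGROUND_ABS
    baseline_absorbance: tuple[float, ...] = _BASELINE_ABSORBANCE
    path_pulse_amplitude: float = 0.008
    incident_intensity: float = 1.0e4

    def __post_init__(self) -> None:
        n = len(self.wavelengths)
        if n != 8:
            raise ValueError(f"expected exactly 8 wavelengths, got {n}")
        wl = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name in ("ext_oxy", "ext_deoxy", "ext_background", "baseline_absorbance"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.shape != (n,):
                raise ValueError(f"{name} must have one value per wavelength")
            if name in ("ext_oxy", "ext_deoxy") and not np.all(vals > 0):
                raise ValueError(f"{name} entries must be > 0")
            if not np.all(vals >= 0):
                raise ValueError(f"{name} entries must be >= 0")
        if self.path_pulse_amplitude <= 0:
            raise ValueError("path_pulse_amplitude must be > 0")
        if self.incident_intensity <= 0:
            raise ValueError("incident_intensity must be > 0")

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths)

    def without_background(self) -> "OpticalConfig":
        """Idealised two-chromophore variant (mu_bg = 0 at every wavelength)."""
        return replace(self, ext_background=(0.0,) * self.n_channels)


@dataclass(frozen=True)
class PhysioState:
    """Physiological state of one subject.

    hb_total: total hemoglobin concentration c_tHb in g/dL.
    spo2:     arterial oxygen saturation as a fraction in [0.7, 1.0].
    heart_rate: beats per minute.
    resp_rate:  respiration rate in Hz (drives baseline wander).
    """

    hb_total: float
    spo2: float = 0.97
    heart_rate: float = 72.0
    resp_rate: float = 0.25

    def __post_init__(self) -> None:
        if not 4.0 < self.hb_total < 22.0:
            raise ValueError(f"hb_total {self.hb_total} outside (4, 22) g/dL")
        if not 0.7 <= self.spo2 <= 1.0:
            raise ValueError(f"spo2 {self.spo2} outside [0.7, 1.0]")
        if not 40.0 <= self.heart_rate <= 180.0:
            raise ValueError(f"heart_rate {self.heart_rate} outside [40, 180] bpm")
        if not 0.0 < self.resp_rate < 0.5:
            raise ValueError(f"resp_rate {self.resp_rate} outside (0, 0.5) Hz")

    @property
    def c_oxy(self) -> float:
        """Oxygenated Hb concentration c1 = spo2 * c_tHb (g/dL)."""
        return self.spo2 * self.hb_total

    @property
    def c_deoxy(self) -> float:
        """Reduced Hb concentration c2 = (1 - spo2) * c_tHb (g/dL)."""
        return (1.0 - self.spo2) * self.hb_total


def pulsatile_absorbance(state: PhysioState, optics: OpticalConfig) -> np.ndarray:
    """Per-channel pulsatile absorbance slope dA/dL (per cm of path change).

    This is eps_oxy*c1 + eps_deoxy*c2 + mu_bg for each wavelength.
    """
    eo = np.asarray(optics.ext_oxy, dtype=float)
    ed = np.asarray(optics.ext_deoxy, dtype=float)
    bg = np.asarray(optics.ext_background, dtype=float)
    return eo * state.c_oxy + ed * state.c_deoxy + bg


def modulation_depth(state: PhysioState, optics: OpticalConfig) -> np.ndarray:
    """Per-channel fractional AC/DC modulation r_lambda = dA/dL * dL.

    In the small-modulation regime the transmitted intensity is
    I(t) = DC * (1 - r * pulse(t)), so r is exactly the (max-min)/DC ratio of a
    noiseless channel.
    """
    return pulsatile_absorbance(state, optics) * optics.path_pulse_amplitude


def dc_levels(optics: OpticalConfig) -> np.ndarray:
    """Static transmitted intensity per channel: I0 * exp(-A_baseline)."""
    a = np.asarray(optics.baseline_absorbance, dtype=float)
    return optics.incident_intensity * np.exp(-a)


def theoretical_ratio(i: int, j: int, state: PhysioState, optics: OpticalConfig) -> float:
    """Closed-form ratio-of-ratios R_ij between channels i and j (0-based).

    R_ij = dA_i / dA_j; the path change dL and source intensity cancel exactly,
    which is the point of the ratio feature.

    Raises
    ------
    InvalidPairError
        If ``i == j`` (the ratio of a channel with itself is trivially 1 and
        never a feature).
    """
    if i == j:
        raise InvalidPairError(f"ratio requires two distinct channels, got i=j={i}")
    n = optics.n_channels
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"channel index out of range for {n} channels")
    da = pulsatile_absorbance(state, optics)
    return float(da[i] / da[j])


def ordered_pairs(n_channels: int = 8) -> list[tuple[int, int]]:
    """All ordered channel pairs (i, j), i != j, in the canonical feature order.

    For 8 channels this is R_12..R_18, R_21, R_23..R_28, ..., R_81..R_87:
    56 pairs (0-based indices returned).
    """
    return [(i, j) for i in range(n_channels) for j in range(n_channels) if i != j]


def theoretical_ratio_vector(state: PhysioState, optics: OpticalConfig) -> np.ndarray:
    """All N*(N-1) closed-form ratios in canonical order (56 for 8 channels)."""
    da = pulsatile_absorbance(state, optics)
    return np.array([da[i] / da[j] for i, j in ordered_pairs(optics.n_channels)])
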