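"""AC/DC ratio-of-ratios feature extraction.

The preprocessed channels are cut into non-overlapping 5 s windows; in each
window the pulsatile (AC) and static (DC) amplitudes are measured per channel,
per-channel perfusions AC/DC are averaged across windows, and the 56 ordered
ratios

    R_ij = (AC_i / DC_i) / (AC_j / DC_j),   i != j over the 8 channels,

are formed, with age and gender appended, giving a 58-entry vector.  The
ratios are invariant to any per-channel intensity scaling, which is the
property that makes them usable across probes and couplings.

Two AC read-outs are provided.  :func:`extract_ac_dc` is the single-channel
differential method: beat landmarks from derivative sign changes, AC = mean
peak-to-trough amplitude over complete cycles.  The cohort pipeline
(:func:`build_feature_vector`) instead uses a multi-channel refinement,
:func:`extract_ac_dc_channels`: beats are landmarked once on a high-SNR
reference (the perfusion-normalized sum of the *other* seven channels) and
each channel's AC is the least-squares projection of its window onto that
reference, scaled by the reference's own peak-to-trough amplitude.  The
projection is a linear functional of the channel's samples, so — unlike a
max/min read-out — its noise is zero-mean: it avoids the selection bias of
reading extrema of a noisy trace, which otherwise inflates the AC of the
low-perfusion channels by up to ~10% and swamps the hemoglobin signal.
Leaving the channel itself out of its reference keeps the landmark choice
statistically independent of the channel's noise; landmark jitter affects all
channels' (identically shaped) beats equally and cancels in the ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    DegenerateChannelError,
    InvalidSignalError,
    NoPulseError,
    UnusableRecordError,
)
from .optics import ordered_pairs
from .preprocess import (
    PreprocessConfig,
    Signal1D,
    comb_filter,
    estimate_period,
    lowpass_filter,
    remove_baseline,
)
from .synth import SubjectRecord

__all__ = [
    "ACDCPair", "FeatureVector", "Standardizer", "build_feature_vector",
    "compute_ratios", "extract_ac_dc", "extract_ac_dc_channels",
    "feature_labels", "feature_table", "record_perfusions", "segment_windows",
]

DEFAULT_WINDOW_S = 5.0
# Landmark prominence as a fraction of the window range: keeps systolic
# excursions, rejects the dicrotic wiggle and residual noise extrema.
_PROMINENCE_FRAC = 0.5


@dataclass(frozen=True)
class ACDCPair:
    """Pulsatile and static amplitudes of one channel window."""

    ac: float
    dc: float
    channel: float  # wavelength, nm

    def __post_init__(self) -> None:
        if self.dc <= 0:
            raise InvalidSignalError(f"DC must be > 0, got {self.dc}")
        if self.ac < 0:
            raise InvalidSignalError(f"AC must be >= 0, got {self.ac}")

    @property
    def perfusion(self) -> float:
        """AC/DC, the fractional modulation of the channel."""
        return self.ac / self.dc


@dataclass
class FeatureVector:
    """56 ordered ratios plus age and gender, in the canonical label order."""

    ratios: np.ndarray
    age: float
    gender: int
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        n = len(self.wavelengths)
        if self.ratios.shape != (n * (n - 1),):
            raise ValueError(f"expected {n * (n - 1)} ratios")
        if not np.all(np.isfinite(self.ratios)) or np.any(self.ratios <= 0):
            raise ValueError("ratios must be finite and > 0")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.ratios, [self.age, float(self.gender)]])

    @property
    def labels(self) -> list[str]:
        return feature_labels(self.wavelengths)


def feature_labels(wavelengths) -> list[str]:
    """Canonical column names: R_610_630, ..., age, gender."""
    wl = [int(round(w)) for w in wavelengths]
    names = [f"R_{wl[i]}_{wl[j]}" for i, j in ordered_pairs(len(wl))]
    return names + ["age", "gender"]


def segment_windows(x: Signal1D, win_len: float = DEFAULT_WINDOW_S) -> list[np.ndarray]:
    """Non-overlapping consecutive windows; the trailing partial one is dropped."""
    w = int(round(win_len * x.fs))
    if w < 1:
        raise ValueError("window length must cover at least one sample")
    n_win = len(x) // w
    return [x.samples[k * w:(k + 1) * w] for k in range(n_win)]


def extract_ac_dc(
    window_ac_source: np.ndarray,
    window_dc_source: np.ndarray,
    fs: float,
    channel: float = 0.0,
) -> ACDCPair | None:
    """AC and DC amplitudes of one window; None when no complete cycle is found.

    Beat landmarks come from derivative sign changes (the differential method):
    local maxima and minima of the AC source, prominence-filtered so only the
    principal cardiac excursion survives.  Each peak is paired with the nearest
    preceding trough; AC is the mean peak-to-trough amplitude over complete
    cycles.  DC is the mean of the DC-source window.
    """
    ac_w = np.asarray(window_ac_source, dtype=float)
    dc_w = np.asarray(window_dc_source, dtype=float)
    if ac_w.shape != dc_w.shape:
        raise ValueError("AC and DC source windows must have the same length")
    if ac_w.size < 2 * fs:
        raise ValueError("window must span at least 2 s")

    dc = float(np.mean(dc_w))
    if dc <= 0:
        raise InvalidSignalError("non-positive DC amplitude")

    pairs = _landmark_pairs(ac_w, reference_scale=max(abs(dc), 1.0))
    if pairs is None:
        return None
    amplitudes = [ac_w[p] - ac_w[t] for p, t in pairs]
    if not amplitudes:
        return None
    return ACDCPair(ac=float(np.mean(amplitudes)), dc=dc, channel=channel)


def _landmark_pairs(x: np.ndarray, reference_scale: float = 1.0):
    """(peak, preceding trough) index pairs from derivative sign changes.

    Extrema are prominence-filtered at half the window range so the dicrotic
    shoulder and residual noise wiggles are not mistaken for beats.  Returns
    None when the window is flat or holds no complete cycle.
    """
    rng = float(np.max(x) - np.min(x))
    if rng <= 0 or rng < 1e-12 * reference_scale:
        return None
    prominence = _PROMINENCE_FRAC * rng
    peaks, _ = find_peaks(x, prominence=prominence)
    troughs, _ = find_peaks(-x, prominence=prominence)
    if peaks.size == 0 or troughs.size == 0:
        return None
    pairs = []
    for p in peaks:
        prior = troughs[troughs < p]
        if prior.size:
            pairs.append((int(p), int(prior[-1])))
    return pairs or None


def _folded_amplitude(x: np.ndarray, period: float) -> float | None:
    """Peak-to-trough amplitude of the cycle-averaged beat.

    Folds the trace at the (possibly fractional) cardiac period with linear
    interpolation and reads the range of the averaged beat, which suppresses
    the positive bias a max/min read-out picks up from residual noise.
    """
    n_cycles = int(np.floor(len(x) / period))
    if n_cycles < 1:
        return None
    grid = np.arange(int(np.floor(period)))
    idx = np.arange(len(x))
    beats = [np.interp(grid + k * period, idx, x) for k in range(n_cycles)]
    beat = np.mean(beats, axis=0)
    return float(beat.max() - beat.min())


def extract_ac_dc_channels(
    ac_windows: np.ndarray,
    dc_windows: np.ndarray,
    fs: float,
    wavelengths,
    period: float | None = None,
) -> list[ACDCPair] | None:
    """Joint AC/DC read-out for all channels of one window (see module docs).

    ``ac_windows`` and ``dc_windows`` are (n_channels, n_samples) arrays.
    When the cardiac ``period`` (samples, fractional allowed) is known, the
    reference amplitude is read from the cycle-averaged beat; otherwise from
    the mean of per-beat landmark amplitudes.  Returns one ACDCPair per
    channel, or None when any channel lacks a complete beat in its
    leave-one-out reference or yields a non-positive amplitude.
    """
    ac_windows = np.asarray(ac_windows, dtype=float)
    dc_windows = np.asarray(dc_windows, dtype=float)
    n_ch = ac_windows.shape[0]
    dc = dc_windows.mean(axis=1)
    if np.any(dc <= 0):
        raise InvalidSignalError("non-positive DC amplitude")
    norm = ac_windows / dc[:, None]          # perfusion-normalized channels
    total = norm.sum(axis=0)
    out: list[ACDCPair] = []
    for c in range(n_ch):
        ref = total - norm[c]                # leave-one-out reference beat train
        pairs = _landmark_pairs(ref)
        if pairs is None:
            return None
        ref_amp = None
        if period is not None:
            ref_amp = _folded_amplitude(ref, period)
        if ref_amp is None:
            ref_amp = float(np.mean([ref[p] - ref[t] for p, t in pairs]))
        ref_c = ref - ref.mean()
        x_c = ac_windows[c] - ac_windows[c].mean()
        denom = float(ref_c @ ref_c)
        if denom <= 0 or ref_amp <= 0:
            return None
        ac = float((x_c @ ref_c) / denom * ref_amp)
        if ac <= 0:
            return None
        out.append(ACDCPair(ac=ac, dc=float(dc[c]), channel=wavelengths[c]))
    return out


def compute_ratios(pairs) -> np.ndarray:
    """The N*(N-1) ordered ratios R_ij from N per-channel ACDC pairs."""
    perfusion = np.array([p.perfusion for p in pairs])
    if np.any(perfusion == 0):
        raise DegenerateChannelError("a channel has zero AC; ratios undefined")
    return np.array([perfusion[i] / perfusion[j] for i, j in ordered_pairs(len(pairs))])


def record_perfusions(ppg, cfg: PreprocessConfig | None = None,
                      win_len: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """Per-channel mean AC/DC (perfusion) of one multi-channel record.

    The full estimation path: low-pass each channel (DC source), remove
    baseline wander, estimate the cardiac period once on the
    perfusion-normalized channel sum, comb-filter, window, read AC per window
    with :func:`extract_ac_dc_channels`, and average windows robustly.

    Raises
    ------
    UnusableRecordError
        When preprocessing fails or no window holds a complete beat on every
        channel.
    """
    cfg = cfg or PreprocessConfig()
    fs = ppg.fs
    n_ch = ppg.channels.shape[1]
    try:
        dc_sources = [
            lowpass_filter(Signal1D(ppg.channels[:, c], fs), cfg) for c in range(n_ch)
        ]
        detrended = [remove_baseline(d, cfg) for d in dc_sources]
        # One cardiac period per record, estimated on the perfusion-normalized
        # channel sum (best SNR); channels share the cardiac timing.
        ref_sum = np.sum(
            [b.samples / np.mean(d.samples) for b, d in zip(detrended, dc_sources)],
            axis=0,
        )
        period: float | None
        try:
            _, fundamental = estimate_period(Signal1D(ref_sum, fs), cfg)
            period = fs / fundamental
        except NoPulseError:
            if cfg.comb_enabled:
                raise
            period = None
        if cfg.comb_enabled:
            ac_sources = [comb_filter(b, period, cfg.comb_taps) for b in detrended]
        else:
            ac_sources = detrended
    except Exception as exc:  # flat/degenerate channels surface here
        raise UnusableRecordError(f"preprocessing failed ({exc})") from exc

    ac_windows = [segment_windows(ac, win_len) for ac in ac_sources]
    dc_windows = [segment_windows(dc, win_len) for dc in dc_sources]
    n_win = min(len(w) for w in ac_windows)

    perfusions: list[np.ndarray] = []
    for w in range(n_win):
        pairs = extract_ac_dc_channels(
            np.array([ac_windows[c][w] for c in range(n_ch)]),
            np.array([dc_windows[c][w] for c in range(n_ch)]),
            fs, ppg.wavelengths, period=period,
        )
        if pairs is not None:
            perfusions.append(np.array([p.perfusion for p in pairs]))
    if not perfusions:
        raise UnusableRecordError("no window with complete cycles on all channels")
    return _robust_window_mean(np.vstack(perfusions))


def _robust_window_mean(P: np.ndarray) -> np.ndarray:
    """Mean of per-window perfusion vectors after rejecting artifact windows.

    Motion transients are common-mode, so rejection is whole-window: a window
    is dropped when any channel deviates from the across-window median by more
    than 5x the median absolute deviation.  Falls back to the median when the
    rejection would discard everything.
    """
    med = np.median(P, axis=0)
    mad = np.median(np.abs(P - med), axis=0)
    tol = 5.0 * mad + 1e-15
    keep = np.all(np.abs(P - med) <= tol, axis=1)
    if not np.any(keep):
        return med
    return P[keep].mean(axis=0)


def build_feature_vector(
    record: SubjectRecord,
    cfg: PreprocessConfig | None = None,
    win_len: float = DEFAULT_WINDOW_S,
) -> FeatureVector:
    """Per-subject 58-entry feature vector.

    Every channel is preprocessed once; both AC and DC sources are windowed
    with identical boundaries.  A window contributes only if all 8 channels
    yield a valid ACDC pair (joint read-out of
    :func:`extract_ac_dc_channels`); per-channel perfusions are averaged
    across valid windows — the per-window read-out is unbiased, so the mean
    is the efficient aggregate, with gross windows already rejected by the
    validity checks — and the 56 ratios are formed from the averages.

    Raises
    ------
    UnusableRecordError
        If no window is valid on every channel (e.g. constant signals).
    """
    ppg = record.ppg
    try:
        mean_perf = record_perfusions(ppg, cfg, win_len)
    except UnusableRecordError as exc:
        raise UnusableRecordError(f"record {record.subject_id}: {exc}") from exc
    agg_pairs = [
        ACDCPair(ac=float(r), dc=1.0, channel=ppg.wavelengths[c])
        for c, r in enumerate(mean_perf)
    ]
    return FeatureVector(
        ratios=compute_ratios(agg_pairs), age=record.age, gender=record.gender,
        wavelengths=ppg.wavelengths,
    )


def feature_table(
    records,
    cfg: PreprocessConfig | None = None,
    win_len: float = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per subject.

    Columns: the 58 features in canonical order, then ``hb_ref``; the index is
    the subject id.  Records that yield no usable window are dropped (reported
    via the returned frame's attrs['n_dropped']).
    """
    rows, ids, refs = [], [], []
    n_dropped = 0
    for rec in records:
        try:
            fv = build_feature_vector(rec, cfg, win_len)
        except UnusableRecordError:
            n_dropped += 1
            continue
        rows.append(fv.values)
        ids.append(rec.subject_id)
        refs.append(rec.hb_ref)
    if not rows:
        raise UnusableRecordError("no usable record in the cohort")
    labels = feature_labels(records[0].ppg.wavelengths)
    df = pd.DataFrame(rows, columns=labels, index=pd.Index(ids, name="subject_id"))
    df["hb_ref"] = refs
    df.attrs["n_dropped"] = n_dropped
    return df


class Standardizer:
    """Column z-scoring with statistics learned from the training set only.

    Constant columns get unit scale so they pass through as zeros rather than
    dividing by zero (e.g. gender in a single-sex cohort).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
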