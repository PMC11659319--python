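"""ABR epoch processing: artifact rejection, averaging, filtering, peak picking.

The auditory brainstem response (ABR) is the scalp potential evoked in the
first ~10 ms after a transient sound. Raw acquisition yields a matrix of
single-sweep epochs (sweeps x samples, µV). Analysis reduces it to a handful
of wave features: wave I (auditory nerve, peak searched 1.3–2.3 ms) and
wave V (lateral lemniscus / inferior colliculus, searched 5.1–6.4 ms), each
characterised by peak latency and peak-to-following-trough amplitude, plus
two relative composites (I–V inter-peak latency, log V/I amplitude ratio).

Processing chain: reject sweeps whose absolute voltage exceeds the artifact
threshold (default 23.8 µV), average the accepted sweeps, bandpass filter
100–3000 Hz with a zero-phase 4th-order Butterworth (zero-phase so peak
latencies are not shifted), then pick peaks inside the per-wave windows.
Automated picking replaces manual confirmation; questionable picks carry QC
flags instead (``boundary-peak``, ``no-peak``, ``no-trough``) and flagged
records are excluded from analysis by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import signal

from .schema import InputError

#: artifact rejection threshold in µV
DEFAULT_REJECT_THRESHOLD_UV = 23.8
#: analysis bandpass in Hz
DEFAULT_BAND_HZ = (100.0, 3000.0)
#: minimum accepted sweeps before averaging warns
DEFAULT_MIN_SWEEPS = 2000
#: peak-search windows in ms post stimulus onset
WAVE_I_WINDOW_MS = (1.3, 2.3)
WAVE_V_WINDOW_MS = (5.1, 6.4)
#: how far past a peak the following trough is searched, ms
TROUGH_HORIZON_MS = 2.0

QC_CLEAN = "clean"
QC_NO_PEAK = "no-peak"
QC_BOUNDARY = "boundary-peak"
QC_NO_TROUGH = "no-trough"


@dataclass
class EpochSet:
    """Raw ABR sweeps.

    Attributes
    ----------
    data : ndarray, shape (n_sweeps, n_samples)
        Single-sweep voltages in µV; stimulus onset at time 0.
    sampling_rate : float
        Hz.
    onset_time : float
        Stimulus onset relative to the first sample, ms (0 = first sample).
    accepted_mask : ndarray of bool, shape (n_sweeps,)
        Sweeps still eligible for averaging.
    meta : dict
        Free-form provenance (generator seed, planted truth, ...).
    """

    data: np.ndarray
    sampling_rate: float
    onset_time: float = 0.0
    accepted_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise InputError("epoch data must be a non-empty 2-D sweeps x samples array")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if self.accepted_mask is None:
            self.accepted_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.accepted_mask = np.asarray(self.accepted_mask, dtype=bool)
            if self.accepted_mask.shape != (self.data.shape[0],):
                raise InputError("accepted_mask length must equal the number of sweeps")

    @property
    def n_sweeps(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sampling_rate * 1000.0 - self.onset_time

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1000.0


@dataclass
class ABRWaveform:
    """Averaged, filtered evoked response."""

    samples: np.ndarray  # µV
    sampling_rate: float  # Hz
    n_sweeps_accepted: int
    filter_band: tuple[float, float] = DEFAULT_BAND_HZ
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_sweeps_accepted < 1:
            raise InputError("waveform must average at least one sweep")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate * 1000.0 - self.onset_time

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.sampling_rate * 1000.0


@dataclass(frozen=True)
class ABRFeatures:
    """Wave I/V features plus derived composites (amplitudes are magnitudes)."""

    wave_i_latency: float  # ms
    wave_i_amplitude: float  # µV, peak-to-following-trough
    wave_v_latency: float  # ms
    wave_v_amplitude: float  # µV
    iv_latency_difference: float  # ms
    log_vi_amplitude_ratio: float  # natural log, NaN when undefined
    qc_flags: dict[str, str] = field(default_factory=dict)

    @property
    def is_clean(self) -> bool:
        return all(flag == QC_CLEAN for flag in self.qc_flags.values())


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = DEFAULT_REJECT_THRESHOLD_UV
) -> EpochSet:
    """Mark sweeps whose max absolute voltage exceeds ``threshold_uv`` as rejected.

    The data are untouched; only ``accepted_mask`` changes. Idempotent: the
    mask can only shrink, and re-applying the same threshold is a no-op.
    """
    if threshold_uv <= 0:
        raise InputError("threshold_uv must be positive")
    peak_abs = np.abs(epochs.data).max(axis=1)
    mask = epochs.accepted_mask & (peak_abs <= threshold_uv)
    return replace(epochs, accepted_mask=mask, meta=dict(epochs.meta))


def average_and_filter(
    epochs: EpochSet,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    min_sweeps: int = DEFAULT_MIN_SWEEPS,
) -> ABRWaveform:
    """Average accepted sweeps and bandpass filter (zero-phase Butterworth).

    Averaging and linear filtering commute, so the (cheaper) filter-the-mean
    order is used. Warns, rather than fails, when fewer than ``min_sweeps``
    sweeps are accepted so that small synthetic sets remain usable.
    """
    accepted = epochs.data[epochs.accepted_mask]
    n_acc = accepted.shape[0]
    if n_acc == 0:
        raise InputError("no accepted sweeps to average")
    if n_acc < min_sweeps:
        warnings.warn(
            f"only {n_acc} accepted sweeps (< {min_sweeps}); averaged response may be noisy",
            stacklevel=2,
        )
    low, high = band
    nyq = epochs.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise InputError(f"filter band {band} must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
    mean = accepted.mean(axis=0)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=epochs.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, mean)
    return ABRWaveform(
        samples=filtered,
        sampling_rate=epochs.sampling_rate,
        n_sweeps_accepted=n_acc,
        filter_band=(low, high),
        onset_time=epochs.onset_time,
    )


def pick_wave(
    waveform: ABRWaveform, window: tuple[float, float]
) -> tuple[float, float, str]:
    """Locate a wave inside ``window`` (ms) and measure it.

    Returns ``(latency_ms, amplitude_uv, qc_flag)``. Latency is the time of
    the maximum sample in the window; amplitude is peak minus the following
    trough, where the trough is the first local minimum after the peak
    searched up to 2 ms past it (falling back to the minimum over that
    horizon when no local minimum exists). QC flags: ``boundary-peak`` when
    the maximum sits on a window edge, ``no-peak`` for a flat window,
    ``no-trough`` when the horizon is empty (peak at the recording's end).
    """
    t = waveform.times_ms
    lo, hi = window
    if lo >= hi:
        raise InputError(f"window {window} must be increasing")
    in_win = np.flatnonzero((t >= lo) & (t <= hi))
    if in_win.size == 0:
        raise InputError(f"window {window} ms lies outside the waveform (0-{waveform.duration_ms:.2f} ms)")
    seg = waveform.samples[in_win]
    if np.ptp(seg) == 0.0:
        return float(t[in_win[seg.size // 2]]), 0.0, QC_NO_PEAK
    i_rel = int(np.argmax(seg))
    i_peak = int(in_win[i_rel])
    latency = float(t[i_peak])
    peak_val = float(waveform.samples[i_peak])
    flag = QC_CLEAN
    if i_rel == 0 or i_rel == seg.size - 1:
        flag = QC_BOUNDARY

    horizon = int(round(TROUGH_HORIZON_MS / 1000.0 * waveform.sampling_rate))
    after = waveform.samples[i_peak + 1 : i_peak + 1 + horizon]
    if after.size == 0:
        return latency, 0.0, QC_NO_TROUGH
    # first local minimum after the peak, else the minimum over the horizon
    interior = after[1:-1]
    is_min = (interior <= after[:-2]) & (interior <= after[2:]) if interior.size else np.array([], bool)
    if is_min.any():
        trough_val = float(after[1 + int(np.flatnonzero(is_min)[0])])
    else:
        trough_val = float(after.min())
    amplitude = max(peak_val - trough_val, 0.0)
    return latency, amplitude, flag


def extract_features(waveform: ABRWaveform) -> ABRFeatures:
    """Wave I and V picks plus the I–V latency difference and log V/I ratio.

    The amplitude ratio is reported as a natural log (the raw ratio is
    right-skewed; the log conforms to normality) and is NaN whenever either
    amplitude is zero, with the QC flag recording why.
    """
    if waveform.duration_ms - waveform.onset_time < WAVE_V_WINDOW_MS[1]:
        raise InputError("waveform must span at least 6.4 ms after stimulus onset")
    lat_i, amp_i, flag_i = pick_wave(waveform, WAVE_I_WINDOW_MS)
    lat_v, amp_v, flag_v = pick_wave(waveform, WAVE_V_WINDOW_MS)
    qc = {"wave_i": flag_i, "wave_v": flag_v}
    # amplitudes below 1e-9 µV are numerically zero (leakage from other waves)
    if amp_i > 1e-9 and amp_v > 1e-9:
        log_ratio = float(np.log(amp_v / amp_i))
    else:
        log_ratio = float("nan")
        qc["vi_ratio"] = "undefined-zero-amplitude"
    return ABRFeatures(
        wave_i_latency=lat_i,
        wave_i_amplitude=amp_i,
        wave_v_latency=lat_v,
        wave_v_amplitude=amp_v,
        iv_latency_difference=lat_v - lat_i,
        log_vi_amplitude_ratio=log_ratio,
        qc_flags=qc,
    )


def process_epoch_set(
    epochs: EpochSet,
    threshold_uv: float = DEFAULT_REJECT_THRESHOLD_UV,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    min_sweeps: int = DEFAULT_MIN_SWEEPS,
) -> ABRFeatures:
    """Full chain: reject -> average+filter -> feature extraction."""
    kept = reject_artifacts(epochs, threshold_uv)
    wave = average_and_filter(kept, band=band, min_sweeps=min_sweeps)
    return extract_features(wave)
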