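"""LFP/EEG processing: active-period detection, PSD, aperiodic 1/f fits.

Discontinuous developmental field potentials alternate between silent
stretches and oscillatory bouts ("active periods"). The detector band-pass
filters (4-20 Hz), downsamples to 100 Hz, averages channels, rectifies,
smooths with a 500 ms boxcar, and applies a dual absolute/relative
hysteresis threshold (seed above 100 uV or 4 SD, extend above 50 uV or
2 SD), then merges gaps < 1 s and drops bouts < 300 ms.

Spectra are Welch estimates (10 s windows, 5 s overlap) combined across
windows by the median; the aperiodic component is a straight line in
log10-power vs log10-frequency with iterative down-weighting of positive
(oscillatory-peak) outliers, emulating a fixed-mode spectral
parameterization. The 1/f exponent is minus the fitted slope, so a steeper
decay gives a larger exponent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .exceptions import ParameterError

__all__ = [
    "RawTraceSet",
    "DetectorParams",
    "ActivePeriod",
    "PSDEstimate",
    "AperiodicFit",
    "detect_active_periods",
    "active_period_stats",
    "compute_psd",
    "normalize_psd",
    "fit_aperiodic",
    "common_average_reference",
    "reject_artifact_epochs",
    "psd_modulation",
]


@dataclass
class RawTraceSet:
    """Multichannel voltage traces (uV), channels x samples."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: Optional[list] = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


@dataclass(frozen=True)
class DetectorParams:
    band: tuple = (4.0, 20.0)
    downsample_to: float = 100.0
    boxcar: float = 500.0  # ms
    abs_upper: float = 100.0  # uV
    rel_upper: float = 4.0  # SD
    abs_lower: float = 50.0  # uV
    rel_lower: float = 2.0  # SD
    merge_gap: float = 1.0  # s
    min_duration: float = 0.3  # s
    rectify: bool = True

    def __post_init__(self):
        if self.abs_lower >= self.abs_upper or self.rel_lower >= self.rel_upper:
            raise ParameterError("lower thresholds must be below upper thresholds")
        if self.min_duration <= 0:
            raise ParameterError("min_duration must be > 0")


@dataclass(frozen=True)
class ActivePeriod:
    start: float
    stop: float
    max_amplitude: float

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    window: float = 10.0
    overlap: float = 5.0
    averaging: str = "median"
    method: str = "welch-hann"
    normalized: bool = False


@dataclass
class AperiodicFit:
    """Aperiodic (1/f) component: log10 P(f) = offset - exponent * log10 f."""

    offset: float
    exponent: float
    fit_range: tuple
    r_squared: float
    n_points: int
    metadata: dict = field(default_factory=dict)


def _envelope(traces: RawTraceSet, params: DetectorParams):
    """Band-pass, downsample, channel-average, rectify, boxcar-smooth.

    Returns (envelope, fs_out). The envelope is in uV; its z-scored version
    (over the whole recording) supplies the relative thresholds.
    """
    fs = traces.sampling_rate
    lo, hi = params.band
    if fs < 2.0 * hi:
        raise ParameterError(
            f"sampling rate {fs} Hz cannot represent the {hi} Hz band edge"
        )
    n_box = int(round(params.boxcar / 1000.0 * params.downsample_to))
    if traces.data.shape[1] <= n_box * fs / params.downsample_to:
        raise ParameterError("trace shorter than the boxcar window")

    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, traces.data, axis=1)

    factor = fs / params.downsample_to
    if abs(factor - round(factor)) < 1e-9:
        down = signal.decimate(filtered, int(round(factor)), axis=1, zero_phase=True) \
            if factor > 1 else filtered
    else:
        down = signal.resample_poly(
            filtered, int(params.downsample_to), int(round(fs)), axis=1
        )
    avg = down.mean(axis=0)
    if params.rectify:
        avg = np.abs(avg)
    box = np.ones(max(1, n_box)) / max(1, n_box)
    env = np.convolve(avg, box, mode="same")
    return env, params.downsample_to


def detect_active_periods(
    traces: RawTraceSet, params: Optional[DetectorParams] = None
) -> list:
    """Dual absolute/relative hysteresis detection of active periods."""
    params = params or DetectorParams()
    env, fs = _envelope(traces, params)
    sd = env.std()
    z = (env - env.mean()) / sd if sd > 0 else np.zeros_like(env)

    above_lower = (env > params.abs_lower) | (z > params.rel_lower)
    seeds = (env > params.abs_upper) | (z > params.rel_upper)
    if not seeds.any():
        return []

    # contiguous runs above the lower threshold that contain a seed sample
    edges = np.diff(above_lower.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above_lower[0]:
        starts = np.r_[0, starts]
    if above_lower[-1]:
        stops = np.r_[stops, above_lower.size]

    periods = [
        (s, e) for s, e in zip(starts, stops) if seeds[s:e].any()
    ]
    if not periods:
        return []

    # merge neighbours separated by less than merge_gap
    gap_samples = params.merge_gap * fs
    merged = [periods[0]]
    for s, e in periods[1:]:
        if s - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    min_samples = params.min_duration * fs
    out = []
    for s, e in merged:
        if e - s >= min_samples:
            out.append(
                ActivePeriod(s / fs, e / fs, float(env[s:e].max()))
            )
    return out


def active_period_stats(periods: Sequence[ActivePeriod], total_duration: float) -> dict:
    """Proportion of time in active periods plus per-period summaries."""
    durations = [p.duration for p in periods]
    return {
        "percent_active": 100.0 * sum(durations) / total_duration,
        "n_periods": len(periods),
        "durations": durations,
        "max_amplitudes": [p.max_amplitude for p in periods],
    }


def compute_psd(
    trace: np.ndarray,
    sampling_rate: float,
    window: float = 10.0,
    overlap: float = 5.0,
    averaging: str = "median",
    detrend: str = "constant",
) -> PSDEstimate:
    """Welch PSD with Hann-tapered windows combined by the median.

    Median combination makes the estimate robust to sporadic high-power
    windows (movement artifacts, isolated bursts).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window * sampling_rate))
    if trace.size < nperseg:
        raise ParameterError(
            f"trace ({trace.size} samples) shorter than one {window} s window"
        )
    if averaging not in ("median", "mean"):
        raise ParameterError("averaging must be 'median' or 'mean'")
    freqs, power = signal.welch(
        trace,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * sampling_rate)),
        detrend=detrend,
        average=averaging,
    )
    return PSDEstimate(freqs, power, window, overlap, averaging)


def normalize_psd(psd: PSDEstimate, freq_range: tuple) -> PSDEstimate:
    """Divide power by the trapezoidal area under the curve over freq_range."""
    lo, hi = freq_range
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if mask.sum() < 2:
        raise ParameterError("freq_range must cover at least two PSD bins")
    area = np.trapezoid(psd.power[mask], psd.freqs[mask])
    if area <= 0:
        raise ParameterError("zero or negative area under the PSD")
    return replace(psd, power=psd.power / area, normalized=True)


def fit_aperiodic(
    psd: PSDEstimate,
    fit_range: tuple,
    n_iterations: int = 2,
    outlier_sd: float = 2.5,
) -> AperiodicFit:
    """Fit the aperiodic 1/f component over fit_range.

    Ordinary least squares of log10 power on log10 frequency, repeated
    n_iterations times with points whose positive residual exceeds
    outlier_sd residual-SDs removed between passes — oscillatory peaks sit
    above the aperiodic line, so only positive outliers are discarded.
    """
    lo, hi = fit_range
    mask = (psd.freqs >= lo) & (psd.freqs <= hi) & (psd.freqs > 0)
    if mask.sum() < 5:
        raise ParameterError("need at least 5 frequency bins in fit_range")
    p = psd.power[mask]
    if np.any(p <= 0):
        raise ParameterError("non-positive power inside fit_range")
    logf = np.log10(psd.freqs[mask])
    logp = np.log10(p)

    keep = np.ones(logf.size, dtype=bool)
    slope = intercept = 0.0
    for _ in range(n_iterations + 1):
        slope, intercept = np.polyfit(logf[keep], logp[keep], 1)
        resid = logp - (intercept + slope * logf)
        sd = resid[keep].std()
        if sd == 0:
            break
        new_keep = keep & ~(resid > outlier_sd * sd)
        if new_keep.sum() < 5 or new_keep.sum() == keep.sum():
            keep = new_keep if new_keep.sum() >= 5 else keep
            break
        keep = new_keep

    fitted = intercept + slope * logf[keep]
    ss_res = np.sum((logp[keep] - fitted) ** 2)
    ss_tot = np.sum((logp[keep] - logp[keep].mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        offset=float(intercept),
        exponent=float(-slope),
        fit_range=(lo, hi),
        r_squared=float(r2),
        n_points=int(keep.sum()),
        metadata={"n_iterations": n_iterations, "outlier_sd": outlier_sd},
    )


def common_average_reference(traces: RawTraceSet) -> RawTraceSet:
    """Subtract the across-channel mean at every sample."""
    if traces.n_channels < 2:
        raise ParameterError("common average reference needs >= 2 channels")
    return RawTraceSet(
        traces.data - traces.data.mean(axis=0, keepdims=True),
        traces.sampling_rate,
        traces.channel_labels,
    )


def reject_artifact_epochs(
    trace: np.ndarray,
    sampling_rate: float,
    epoch_length: float,
    k_sd: float = 2.0,
) -> np.ndarray:
    """Mask epochs whose mean analytic-signal envelope is > mean + k_sd * SD.

    Returns a boolean array (True = retained) with one entry per complete
    epoch of epoch_length seconds.
    """
    trace = np.asarray(trace, dtype=float)
    n_epoch = int(round(epoch_length * sampling_rate))
    n = trace.size // n_epoch
    if n < 2:
        raise ParameterError("need at least 2 complete epochs")
    if n < 3:
        warnings.warn("artifact rejection on only 2 epochs is unreliable", stacklevel=2)
    env = np.abs(signal.hilbert(trace[: n * n_epoch]))
    epoch_means = env.reshape(n, n_epoch).mean(axis=1)
    limit = epoch_means.mean() + k_sd * epoch_means.std()
    return epoch_means <= limit


def psd_modulation(psd_pre: PSDEstimate, psd_stim: PSDEstimate) -> np.ndarray:
    """Per-frequency modulation index (pre - stim) / (pre + stim)."""
    if psd_pre.freqs.shape != psd_stim.freqs.shape or not np.allclose(
        psd_pre.freqs, psd_stim.freqs
    ):
        raise ParameterError("PSD frequency grids do not match")
    denom = psd_pre.power + psd_stim.power
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = (psd_pre.power - psd_stim.power) / denom
    return np.where(denom == 0, np.nan, mi)
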