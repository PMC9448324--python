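"""Spike-train statistics: STTC, pair filtering, spatial profiles,
stimulation modulation, and PCA population trajectories.

The spike time tiling coefficient (STTC) quantifies pairwise correlation
between two spike trains A and B over a recording of length T:

    STTC = 1/2 [ (PA - TB) / (1 - PA*TB) + (PB - TA) / (1 - PB*TA) ]

where PA is the proportion of A's spikes falling within +-dt of any spike
of B, and TA is the proportion of the recording tiled by +-dt windows
around A's spikes (overlaps merged, window edges clipped to [0, T)). The
statistic is symmetric, bounded in [-1, 1] where defined, and insensitive
to firing rate. The lag dt sets the timescale; the default grid spans
2.5 ms to 10 s (log-spaced, containing exactly 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .exceptions import ParameterError

__all__ = [
    "SpikeTrainPair",
    "STTCResult",
    "TrialWindowSpec",
    "ModulationResult",
    "TrajectoryComponents",
    "sttc",
    "sttc_across_lags",
    "default_lags",
    "mean_pairwise_sttc",
    "filter_pairs",
    "sttc_distance_profile",
    "sttc_site_adjacency",
    "modulation_index",
    "classify_unit_modulation",
    "trial_rate_matrix",
    "population_trajectories",
]


@dataclass
class SpikeTrainPair:
    """Two sorted spike-time arrays sharing a recording epoch [0, T)."""

    train_a: np.ndarray
    train_b: np.ndarray
    epoch_duration: float
    site_a: Optional[int] = None
    site_b: Optional[int] = None
    distance: Optional[float] = None

    def __post_init__(self):
        self.train_a = np.asarray(self.train_a, dtype=float)
        self.train_b = np.asarray(self.train_b, dtype=float)
        if self.epoch_duration <= 0:
            raise ParameterError("epoch_duration must be > 0")
        for name, t in (("train_a", self.train_a), ("train_b", self.train_b)):
            if t.size and (t.min() < 0 or t.max() >= self.epoch_duration):
                raise ParameterError(f"{name} has spikes outside [0, epoch_duration)")
        if self.distance is not None and self.distance < 0:
            raise ParameterError("distance must be >= 0")


@dataclass
class STTCResult:
    lag: float
    value: float  # nan when undefined
    pa: float
    pb: float
    ta: float
    tb: float
    defined: bool = True
    reason: str = ""


def _tiled_fraction(times: np.ndarray, duration: float, lag: float) -> float:
    """Length fraction of [0, duration) covered by merged +-lag windows."""
    if times.size == 0:
        return 0.0
    starts = np.clip(times - lag, 0.0, duration)
    ends = np.clip(times + lag, 0.0, duration)
    prev_end = np.maximum.accumulate(np.r_[0.0, ends[:-1]])
    return float(np.sum(np.maximum(0.0, ends - np.maximum(starts, prev_end))) / duration)


def _coincident_fraction(a: np.ndarray, b: np.ndarray, lag: float) -> float:
    """Fraction of a's spikes with a b spike within +-lag (inclusive)."""
    if a.size == 0 or b.size == 0:
        return 0.0
    idx = np.searchsorted(b, a)
    d_right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    d_left = np.where(idx > 0, a - b[np.maximum(idx - 1, 0)], np.inf)
    return float(np.mean(np.minimum(d_right, d_left) <= lag))


def sttc(pair: SpikeTrainPair, lag: float) -> STTCResult:
    """Spike time tiling coefficient of one pair at one lag."""
    if lag <= 0:
        raise ParameterError("lag must be > 0")
    a, b, T = pair.train_a, pair.train_b, pair.epoch_duration
    ta = _tiled_fraction(a, T, lag)
    tb = _tiled_fraction(b, T, lag)
    if a.size == 0 or b.size == 0:
        return STTCResult(lag, np.nan, 0.0, 0.0, ta, tb, False, "empty spike train")
    pa = _coincident_fraction(a, b, lag)
    pb = _coincident_fraction(b, a, lag)
    da, db = 1.0 - pa * tb, 1.0 - pb * ta
    if da == 0.0 or db == 0.0:
        return STTCResult(lag, np.nan, pa, pb, ta, tb, False, "degenerate denominator")
    value = 0.5 * ((pa - tb) / da + (pb - ta) / db)
    return STTCResult(lag, float(value), pa, pb, ta, tb)


def default_lags(n: int = 13) -> np.ndarray:
    """Log-spaced lag grid from 2.5 ms to 10 s with the nearest point
    snapped to exactly 1 s."""
    lags = np.geomspace(0.0025, 10.0, n)
    lags[np.argmin(np.abs(lags - 1.0))] = 1.0
    return lags


def sttc_across_lags(pair: SpikeTrainPair, lags: Optional[Sequence[float]] = None):
    """STTC of one pair at each lag (default: the 13-point standard grid)."""
    lags = default_lags() if lags is None else np.asarray(lags, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ParameterError("lags must be positive and strictly ascending")
    return [sttc(pair, lag) for lag in lags]


def mean_pairwise_sttc(
    trains: Sequence[np.ndarray],
    duration: float,
    lag: float = 1.0,
    min_spikes: int = 1,
):
    """Mean STTC over all train pairs with >= min_spikes spikes each.

    Undefined pairs are skipped; returns (mean, n_pairs_used). Uses the
    compiled fast path shared with the conductance-grid sweep.
    """
    from ._kernels import pairwise_sttc_mean

    times = np.concatenate([np.asarray(t, float) for t in trains]) if trains else np.zeros(0)
    offsets = np.zeros(len(trains) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(t) for t in trains])
    return pairwise_sttc_mean(times, offsets, duration, lag, min_spikes)


def filter_pairs(
    pairs: Sequence[SpikeTrainPair],
    min_duration: float = 3600.0,
    min_spikes: int = 50,
):
    """Keep pairs recorded for >= min_duration with both trains >= min_spikes."""
    return [
        p
        for p in pairs
        if p.epoch_duration >= min_duration
        and p.train_a.size >= min_spikes
        and p.train_b.size >= min_spikes
    ]


def sttc_distance_profile(
    pairs: Sequence[SpikeTrainPair],
    lag: float = 1.0,
    distance_bins: Optional[np.ndarray] = None,
):
    """Mean +- SEM STTC per distance bin (half-open [lo, hi) bins, um).

    Default bins step 100 um from 0 to 100 um past the largest distance.
    Returns a DataFrame with columns bin_lo, bin_hi, mean_sttc, sem_sttc, n.
    """
    import pandas as pd

    dists = [p.distance for p in pairs]
    if any(d is None for d in dists):
        raise ParameterError("all pairs need a distance for the profile")
    if distance_bins is None:
        top = 100.0 * (np.floor(max(dists) / 100.0) + 1)
        distance_bins = np.arange(0.0, top + 1, 100.0)
    distance_bins = np.asarray(distance_bins, dtype=float)

    rows = []
    values = np.array([sttc(p, lag).value for p in pairs])
    dists = np.asarray(dists, dtype=float)
    for lo, hi in zip(distance_bins[:-1], distance_bins[1:]):
        sel = (dists >= lo) & (dists < hi) & np.isfinite(values)
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "mean_sttc": values[sel].mean() if n else np.nan,
                "sem_sttc": values[sel].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def sttc_site_adjacency(
    pairs: Sequence[SpikeTrainPair], lag: float = 1.0, n_sites: int = 16
) -> np.ndarray:
    """Symmetric site-by-site matrix of mean STTC at one lag.

    Cell (i, j) averages the STTC of every pair recorded on sites (i, j);
    the diagonal holds within-site pairs; unobserved cells are nan.
    """
    sums = np.zeros((n_sites, n_sites))
    counts = np.zeros((n_sites, n_sites), dtype=int)
    for p in pairs:
        if p.site_a is None or p.site_b is None:
            raise ParameterError("all pairs need site indices for the adjacency")
        if not (0 <= p.site_a < n_sites and 0 <= p.site_b < n_sites):
            raise ParameterError("site index outside [0, n_sites)")
        v = sttc(p, lag).value
        if not np.isfinite(v):
            continue
        i, j = p.site_a, p.site_b
        sums[i, j] += v
        counts[i, j] += 1
        if i != j:
            sums[j, i] += v
            counts[j, i] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass(frozen=True)
class TrialWindowSpec:
    """Comparison windows around a ramp stimulus (seconds).

    The stimulated rate is taken from the last stim_window seconds of the
    ramp; the baseline from the pre_window seconds before ramp onset.
    """

    pre_window: float = 1.5
    stim_window: float = 1.5
    alpha: float = 0.01


@dataclass
class ModulationResult:
    mi: float
    p_value: float
    label: str  # activated | inhibited | unmodulated


def modulation_index(value_pre: float, value_stim: float) -> float:
    """MI = (pre - stim) / (pre + stim), bounded in [-1, 1]; nan if both 0."""
    if value_pre < 0 or value_stim < 0:
        raise ParameterError("modulation index requires nonnegative values")
    denom = value_pre + value_stim
    if denom == 0:
        return np.nan
    return (value_pre - value_stim) / denom


def classify_unit_modulation(
    trial_spike_times: Sequence[np.ndarray],
    windows: Optional[TrialWindowSpec] = None,
    ramp_duration: float = 3.0,
) -> ModulationResult:
    """Label one unit activated / inhibited / unmodulated by a ramp stimulus.

    trial_spike_times holds, per trial, spike times relative to ramp onset
    (negative = pre-stimulus). Per-trial rates in the pre and late-stimulus
    windows are compared with a two-sided Wilcoxon signed-rank test across
    trials (zero-difference trials dropped); the MI is computed from the
    trial-mean rates. Needs >= 2 trials.
    """
    windows = windows or TrialWindowSpec()
    if len(trial_spike_times) < 2:
        raise ParameterError("need at least 2 trials")
    pre, stim = [], []
    for t in trial_spike_times:
        t = np.asarray(t, dtype=float)
        pre.append(np.sum((t >= -windows.pre_window) & (t < 0)) / windows.pre_window)
        stim.append(
            np.sum((t >= ramp_duration - windows.stim_window) & (t < ramp_duration))
            / windows.stim_window
        )
    pre, stim = np.asarray(pre), np.asarray(stim)
    mi = modulation_index(float(pre.mean()), float(stim.mean()))
    diffs = pre - stim
    if np.all(diffs == 0):
        return ModulationResult(0.0 if np.isfinite(mi) else np.nan, 1.0, "unmodulated")
    p = float(stats.wilcoxon(pre, stim, zero_method="wilcox").pvalue)
    label = "unmodulated"
    if p < windows.alpha:
        label = "activated" if stim.mean() > pre.mean() else "inhibited"
    return ModulationResult(float(mi), p, label)


def trial_rate_matrix(
    spike_times: np.ndarray,
    unit_ids: np.ndarray,
    n_units: int,
    onsets: Sequence[float],
    t_start: float,
    t_stop: float,
    bin_width: float = 0.01,
):
    """Trial-averaged unit x time firing-rate matrix (Hz) around stimulus
    onsets, covering [t_start, t_stop) relative to each onset."""
    n_bins = int(round((t_stop - t_start) / bin_width))
    mat = np.zeros((n_units, n_bins))
    for on in onsets:
        rel = spike_times - on
        sel = (rel >= t_start) & (rel < t_stop)
        b = ((rel[sel] - t_start) / bin_width).astype(int)
        np.add.at(mat, (unit_ids[sel], np.minimum(b, n_bins - 1)), 1.0)
    mat /= len(onsets) * bin_width
    times = t_start + (np.arange(n_bins) + 0.5) * bin_width
    return mat, times


def _smooth_and_zscore(
    rate_matrix: np.ndarray, bin_width: float, window: float, window_sd: float
):
    """Gaussian-smooth each unit's rate course and z-score it over time.

    The kernel has SD window_sd and total length window (both seconds).
    Units whose smoothed course has zero variance are dropped with a
    warning; returns (z, retained_unit_indices).
    """
    import warnings

    rate_matrix = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    n_units = rate_matrix.shape[0]
    sd_bins = window_sd / bin_width
    half = int(round(window / bin_width / 2))
    smooth = ndimage.gaussian_filter1d(
        rate_matrix, sd_bins, axis=1, mode="nearest",
        truncate=max(1.0, half / sd_bins),
    )
    sds = smooth.std(axis=1)
    retained = np.flatnonzero(sds > 0)
    if retained.size < n_units:
        warnings.warn(
            f"dropped {n_units - retained.size} constant unit(s) before PCA",
            stacklevel=2,
        )
    if retained.size < 2:
        raise ParameterError("fewer than 2 units with time-varying rates")
    z = (smooth[retained] - smooth[retained].mean(axis=1, keepdims=True)) / sds[
        retained, None
    ]
    return z, retained


@dataclass
class TrajectoryComponents:
    components: np.ndarray  # (n_components, n_time): PC scores over time
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_components, n_units_retained)
    retained_units: np.ndarray
    smoothing: dict = field(default_factory=dict)


def population_trajectories(
    rate_matrix: np.ndarray,
    bin_width: float = 0.01,
    n_components: int = 2,
    window: float = 0.5,
    window_sd: float = 0.05,
) -> TrajectoryComponents:
    """Low-dimensional population trajectories from trial-averaged rates.

    Each unit's rate course is convolved with a Gaussian kernel (window
    length 500 ms, SD 50 ms by default), z-scored across time, and the
    principal components are computed over units; the returned components
    are the PC scores over time. Zero-variance units are dropped with a
    warning. Sign convention: each component is flipped, if necessary, so
    its loading vector has nonnegative mean (ties broken toward a positive
    first loading).
    """
    from sklearn.decomposition import PCA

    rate_matrix = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    n_units, n_time = rate_matrix.shape
    if n_units < 2 or n_time < 2:
        raise ParameterError("need >= 2 units and >= 2 time bins")
    z, retained = _smooth_and_zscore(rate_matrix, bin_width, window, window_sd)

    n_components = min(n_components, retained.size, n_time)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.T).T  # (n_components, n_time)
    loadings = pca.components_  # (n_components, n_units)
    for k in range(n_components):
        m = loadings[k].mean()
        if m < 0 or (m == 0 and loadings[k, 0] < 0):
            loadings[k] *= -1
            scores[k] *= -1
    return TrajectoryComponents(
        components=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        retained_units=retained,
        smoothing={"window_s": window, "sd_s": window_sd, "bin_s": bin_width},
    )
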