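"""Synthetic data with exact ground truth for validating the analyses.

Three generator families:

* power-law / discontinuous LFP — a 1/f^beta Gaussian background (spectral
  synthesis) plus amplitude-enveloped oscillatory bursts at Poisson event
  times, emulating the alternation of silent and active periods in
  developing cortex. The inserted burst intervals are returned as ground
  truth for the active-period detector.
* correlated spike rasters — a copy-thinning (mother process) construction
  on a four-shank, 4x4-site electrode geometry: each spatial cluster owns a
  homogeneous Poisson mother train, unit i copies each mother spike with
  probability c * exp(-d_i / lambda), jitters it, and tops up with
  independent Poisson spikes to its target rate. Copy probabilities give
  analytic expected coincidences, i.e. spike-level ground truth for STTC.
* stimulation trials — inhomogeneous-Poisson trial rasters with known
  activated / inhibited / biphasic unit labels for the modulation
  classifier and the population-trajectory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal, stats

from .exceptions import ParameterError
from .spectral import RawTraceSet

__all__ = [
    "SyntheticLFPSpec",
    "SyntheticRasterSpec",
    "SyntheticOptoSpec",
    "generate_power_law_trace",
    "generate_developmental_lfp",
    "generate_correlated_raster",
    "generate_opto_trials",
    "electrode_geometry",
]


def generate_power_law_trace(
    beta: float, duration: float, sampling_rate: float, seed: int = 0
) -> np.ndarray:
    """Gaussian trace with PSD proportional to f^-beta, unit variance.

    Spectral synthesis: shape rfft amplitudes as f^(-beta/2), draw random
    phases (complex Gaussian), invert. beta=0 gives white noise.
    """
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    n = int(round(duration * sampling_rate))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    trace = np.fft.irfft(spec, n=n)
    sd = trace.std()
    return trace / sd if sd > 0 else trace


@dataclass(frozen=True)
class SyntheticLFPSpec:
    duration: float = 120.0
    sampling_rate: float = 1000.0
    burst_rate: float = 6.0  # events per minute
    burst_duration_mean: float = 2.0
    burst_duration_sd: float = 0.5
    burst_amplitude: float = 300.0  # uV
    carrier_band: tuple = (4.0, 20.0)
    background_sigma: float = 20.0  # uV
    spectral_exponent: float = 1.5
    n_channels: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.duration, self.sampling_rate, self.burst_amplitude,
               self.background_sigma, self.n_channels) <= 0:
            raise ParameterError("spec fields must be positive")
        if self.burst_amplitude <= self.background_sigma:
            raise ParameterError("burst_amplitude must exceed background_sigma")


def generate_developmental_lfp(spec: SyntheticLFPSpec):
    """Discontinuous multichannel LFP plus the true inserted burst intervals.

    Background: power-law noise scaled to background_sigma, independent per
    channel. Bursts: flat-topped (Tukey-enveloped) oscillations at a random
    carrier frequency inside carrier_band, at Poisson event times with
    truncated-normal durations (minimum 0.1 s), added to every channel with
    a small per-channel gain jitter. Overlapping insertions are merged in
    the returned ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    data = np.stack(
        [
            spec.background_sigma
            * generate_power_law_trace(
                spec.spectral_exponent, spec.duration, spec.sampling_rate,
                seed=int(rng.integers(2**31 - 1)),
            )
            for _ in range(spec.n_channels)
        ]
    )

    n_bursts = rng.poisson(spec.burst_rate * spec.duration / 60.0)
    t = np.arange(n) / spec.sampling_rate
    truth = []
    gains = 1.0 + 0.05 * rng.standard_normal(spec.n_channels)
    for _ in range(n_bursts):
        dur = float(
            stats.truncnorm.rvs(
                (0.1 - spec.burst_duration_mean) / spec.burst_duration_sd,
                np.inf,
                loc=spec.burst_duration_mean,
                scale=spec.burst_duration_sd,
                random_state=rng,
            )
        )
        start = float(rng.uniform(0, max(spec.duration - dur, 0)))
        f = float(rng.uniform(*spec.carrier_band))
        phase = float(rng.uniform(0, 2 * np.pi))
        i0, i1 = int(start * spec.sampling_rate), int((start + dur) * spec.sampling_rate)
        i1 = min(i1, n)
        seg = np.arange(i0, i1)
        # flat-topped (Tukey) envelope: bursts switch on/off sharply, as
        # discontinuous developmental activity does
        envelope = signal.windows.tukey(seg.size, alpha=0.25)
        wave = spec.burst_amplitude * envelope * np.sin(2 * np.pi * f * t[seg] + phase)
        data[:, seg] += gains[:, None] * wave[None, :]
        truth.append((start, start + dur))

    truth.sort()
    merged = []
    for s, e in truth:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return RawTraceSet(data, spec.sampling_rate), merged


def electrode_geometry(
    n_shanks: int = 4, sites_per_shank: int = 4, site_pitch: float = 100.0,
    shank_pitch: float = 125.0,
):
    """(x, y) site positions (um) of a multi-shank linear probe."""
    xs, ys = [], []
    for s in range(n_shanks):
        for k in range(sites_per_shank):
            xs.append(s * shank_pitch)
            ys.append(k * site_pitch)
    return np.column_stack([xs, ys])


@dataclass(frozen=True)
class SyntheticRasterSpec:
    n_units: int = 32
    rates: float = 1.0  # Hz, scalar or per-unit array (low, neonatal-like)
    correlation_strength: float = 0.4  # copy probability c
    jitter_sd: float = 5.0  # ms
    distance_decay: float = np.inf  # um length constant (inf = no decay)
    duration: float = 600.0
    mother_rate: Optional[float] = None  # Hz; default min unit rate
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.correlation_strength <= 1.0:
            raise ParameterError("correlation_strength must be in [0, 1]")
        if self.n_units < 2 or self.duration <= 0:
            raise ParameterError("need >= 2 units and positive duration")
        if np.any(np.asarray(self.rates) <= 0):
            raise ParameterError("rates must be > 0")


def generate_correlated_raster(spec: SyntheticRasterSpec):
    """Copy-thinning raster on the 4-shank probe with exact ground truth.

    One mother Poisson train per shank (spatial cluster). Unit i, sitting on
    a probe site, copies each mother spike of its cluster with probability
    p_i = c * exp(-d_i / lambda) (d_i = distance to the cluster centroid),
    adds Gaussian jitter, and receives independent Poisson spikes to reach
    its target rate.

    Returns (trains, site_map, copy_prob) where trains is a list of sorted
    spike-time arrays, site_map a DataFrame (unit_id, site_index, x_um,
    y_um, shank, cluster), and copy_prob the per-unit copy probability
    (shared-fraction ground truth: units i, j in one cluster share an
    expected fraction p_i * p_j * r_mother of coincident spikes).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    geom = electrode_geometry()
    n_sites = geom.shape[0]
    sites = np.arange(spec.n_units) % n_sites
    shanks = sites // 4
    rates = np.broadcast_to(np.asarray(spec.rates, dtype=float), (spec.n_units,))

    site_shank = np.arange(n_sites) // 4
    centroids = np.stack([geom[site_shank == s].mean(axis=0) for s in range(4)])
    d = np.linalg.norm(geom[sites] - centroids[shanks], axis=1)
    decay = np.exp(-d / spec.distance_decay) if np.isfinite(spec.distance_decay) else np.ones_like(d)
    p = spec.correlation_strength * decay

    r_mother = spec.mother_rate if spec.mother_rate is not None else float(rates.min())
    if np.any(p * r_mother > rates + 1e-12):
        raise ParameterError("copy rate exceeds target rate for some unit")

    mothers = []
    for s in range(4):
        n_m = rng.poisson(r_mother * spec.duration)
        mothers.append(np.sort(rng.uniform(0, spec.duration, n_m)))

    trains = []
    for u in range(spec.n_units):
        m = mothers[shanks[u]]
        copied = m[rng.random(m.size) < p[u]]
        if copied.size and spec.jitter_sd > 0:
            copied = copied + rng.normal(0, spec.jitter_sd / 1000.0, copied.size)
            copied = copied[(copied >= 0) & (copied < spec.duration)]
        top_rate = rates[u] - p[u] * r_mother
        n_top = rng.poisson(max(top_rate, 0.0) * spec.duration)
        extra = rng.uniform(0, spec.duration, n_top)
        trains.append(np.sort(np.concatenate([copied, extra])))

    site_map = pd.DataFrame(
        {
            "unit_id": np.arange(spec.n_units),
            "site_index": sites,
            "x_um": geom[sites, 0],
            "y_um": geom[sites, 1],
            "shank": shanks,
            "cluster": shanks,
        }
    )
    return trains, site_map, p


@dataclass(frozen=True)
class SyntheticOptoSpec:
    n_units: int = 60
    fraction_inhibited: float = 0.4
    fraction_activated: float = 0.3
    fraction_biphasic: float = 0.0
    n_trials: int = 30
    pre_duration: float = 3.0
    stim_duration: float = 3.0
    post_duration: float = 3.0
    baseline_rate: float = 5.0
    effect_multiplier: float = 3.0
    biphasic_switch: float = 1.5  # s into the stimulus
    seed: int = 0

    def __post_init__(self):
        total = self.fraction_inhibited + self.fraction_activated + self.fraction_biphasic
        if total > 1.0 + 1e-9:
            raise ParameterError("label fractions must sum to <= 1")
        if self.effect_multiplier <= 0 or self.baseline_rate <= 0:
            raise ParameterError("rates and effect multiplier must be > 0")


def _rate_profile(t: np.ndarray, spec: SyntheticOptoSpec, label: str) -> np.ndarray:
    """Instantaneous rate (Hz) at stimulus-relative times t for one unit."""
    r0, m = spec.baseline_rate, spec.effect_multiplier
    rate = np.full_like(t, r0, dtype=float)
    in_stim = (t >= 0) & (t < spec.stim_duration)
    frac = np.clip(t / spec.stim_duration, 0, 1)
    if label == "activated":
        rate[in_stim] = r0 * (1 + (m - 1) * frac[in_stim])
    elif label == "inhibited":
        rate[in_stim] = r0 / (1 + (m - 1) * frac[in_stim])
    elif label == "biphasic":
        down = in_stim & (t < spec.biphasic_switch)
        up = in_stim & (t >= spec.biphasic_switch)
        rate[down] = r0 / (1 + (m - 1) * (t[down] / spec.biphasic_switch))
        rise = (t[up] - spec.biphasic_switch) / (spec.stim_duration - spec.biphasic_switch)
        rate[up] = (r0 / m) * (1 + (m**2 - 1) * rise)
    return rate


def generate_opto_trials(spec: SyntheticOptoSpec):
    """Per-unit, per-trial inhomogeneous-Poisson spike times + true labels.

    Returns (trials, labels): trials[u][k] is an array of spike times
    relative to stimulus onset (spanning [-pre, stim + post)), labels[u] in
    {activated, inhibited, biphasic, unmodulated}. Spikes are drawn by
    thinning a homogeneous Poisson process at the profile's peak rate.
    """
    rng = np.random.default_rng(spec.seed)
    n_i = int(round(spec.fraction_inhibited * spec.n_units))
    n_a = int(round(spec.fraction_activated * spec.n_units))
    n_b = int(round(spec.fraction_biphasic * spec.n_units))
    labels = (
        ["inhibited"] * n_i
        + ["activated"] * n_a
        + ["biphasic"] * n_b
        + ["unmodulated"] * (spec.n_units - n_i - n_a - n_b)
    )

    t0, t1 = -spec.pre_duration, spec.stim_duration + spec.post_duration
    r_max = spec.baseline_rate * spec.effect_multiplier
    trials = []
    for u, label in enumerate(labels):
        unit_trials = []
        for _ in range(spec.n_trials):
            n_cand = rng.poisson(r_max * (t1 - t0))
            cand = np.sort(rng.uniform(t0, t1, n_cand))
            keep = rng.random(n_cand) < _rate_profile(cand, spec, label) / r_max
            unit_trials.append(cand[keep])
        trials.append(unit_trials)
    return trials, labels
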