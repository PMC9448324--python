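"""Conductance-based LIF excitation-inhibition network.

A 400-unit all-to-all network (default 320 excitatory, 80 inhibitory) with
lognormally distributed synaptic weights, AMPA/GABA conductance synapses,
zero-mean Ornstein-Uhlenbeck noise current in every unit, and a shared
external Poisson pool driving the excitatory population. Net inhibition
strength is varied by scaling all excitatory and all inhibitory recurrent
conductances with two grid multipliers; its summary statistic is the ratio
inhibitory/excitatory multiplier.

The model LFP is the sum of the absolute AMPA and GABA currents on the
excitatory units, sampled (by within-bin averaging) at a configurable rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._kernels import pairwise_sttc_mean, run_lif_kernel
from .exceptions import ParameterError, SimulationError

__all__ = [
    "PopulationParams",
    "SynapseConfig",
    "NoiseConfig",
    "ExternalInputConfig",
    "NetworkConfig",
    "RampProtocol",
    "RealizedNetwork",
    "SpikeRaster",
    "LFPProxyTrace",
    "SimulationResult",
    "ReversalRegime",
    "build_network",
    "simulate",
    "net_inhibition_strength",
    "sweep_ei_grid",
    "apply_ramp_protocol",
    "set_gaba_reversal",
    "classify_gaba_reversal",
]

#: OU noise amplitude (pA). Calibrated once so that the grid-central cell
#: (multipliers 0.4 / 0.7) yields excitatory-population rates near 1.5 Hz.
DEFAULT_OU_SIGMA_PA = 487.0

#: Global scale on all recurrent synaptic weights. Calibrated once, jointly
#: with the OU amplitude, so the default network is stable for GABA
#: reversal potentials at least 5 mV below rest but shows runaway
#: excitation when the reversal reaches the resting potential.
DEFAULT_COUPLING_SCALE = 20.0


@dataclass(frozen=True)
class PopulationParams:
    """Single-population neuron parameters (mV, ms, pF, nS)."""

    v_leak: float = -70.0
    v_thresh: float = -52.0
    v_reset: float = -59.0
    t_refract: float = 2.0
    capacitance: float = 500.0
    g_leak: float = 25.0
    tau_ampa: float = 2.0
    tau_gaba: float = 8.0

    def __post_init__(self):
        if not self.v_reset < self.v_thresh:
            raise ParameterError("v_reset must be below v_thresh")
        if self.v_leak > self.v_thresh:
            raise ParameterError("v_leak must not exceed v_thresh")
        for name in ("t_refract", "capacitance", "g_leak", "tau_ampa", "tau_gaba"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant Cm/gL (ms)."""
        return self.capacitance / self.g_leak


def exc_defaults() -> PopulationParams:
    return PopulationParams()


def inh_defaults() -> PopulationParams:
    return PopulationParams(t_refract=1.0, g_leak=20.0, tau_ampa=1.0)


@dataclass(frozen=True)
class SynapseConfig:
    """Synaptic reversal potentials, lognormal weight law, and grid scalers.

    Recurrent weights are lognormal(lognorm_mu, lognorm_sigma) divided by a
    class divisor (AMPA: 50 for both targets; GABA: 12 onto excitatory, 60
    onto inhibitory units), multiplied by a single global coupling_scale,
    and finally by the grid multiplier of their class. The divisors set the
    relative strength of the synapse classes; coupling_scale sets their
    absolute magnitude relative to the leak conductance and is calibrated
    once so the network operates in the inhibition-stabilized regime
    (stable with hyperpolarizing GABA, runaway once the GABA driving force
    vanishes). The external-pool conductance g_ampa_ext is a fixed increment
    per pooled external spike and is not scaled by the grid multipliers.
    """

    e_ampa: float = 0.0
    e_gaba: float = -80.0
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 1.0
    ampa_divisor: float = 50.0
    gaba_divisor_onto_exc: float = 12.0
    gaba_divisor_onto_inh: float = 60.0
    g_ampa_ext: float = 0.234 * 5.0
    coupling_scale: float = DEFAULT_COUPLING_SCALE
    exc_multiplier: float = 0.4
    inh_multiplier: float = 0.7

    def __post_init__(self):
        for name in (
            "ampa_divisor",
            "gaba_divisor_onto_exc",
            "gaba_divisor_onto_inh",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.exc_multiplier <= 0 or self.inh_multiplier <= 0:
            raise ParameterError("grid multipliers must be > 0")
        if self.coupling_scale <= 0:
            raise ParameterError("coupling_scale must be > 0")
        if not (math.isfinite(self.e_ampa) and math.isfinite(self.e_gaba)):
            raise ParameterError("reversal potentials must be finite")
        if self.lognorm_sigma < 0:
            raise ParameterError("lognorm_sigma must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Zero-mean Ornstein-Uhlenbeck current noise (pA, ms)."""

    ou_mean: float = 0.0
    ou_sigma: float = DEFAULT_OU_SIGMA_PA
    ou_tau: float = 5.0

    def __post_init__(self):
        if self.ou_tau <= 0:
            raise ParameterError("ou_tau must be > 0")
        if self.ou_mean != 0.0:
            raise ParameterError("ou_mean must be 0 (zero-mean noise)")
        if self.ou_sigma < 0:
            raise ParameterError("ou_sigma must be >= 0")


@dataclass(frozen=True)
class ExternalInputConfig:
    """Shared external Poisson pool projecting onto excitatory units."""

    n_sources: int = 100
    rate_per_source: float = 1.5

    def __post_init__(self):
        if self.n_sources < 0 or self.rate_per_source < 0:
            raise ParameterError("external input counts/rates must be >= 0")

    @property
    def total_rate(self) -> float:
        return self.n_sources * self.rate_per_source


@dataclass(frozen=True)
class NetworkConfig:
    n_exc: int = 320
    n_inh: int = 80
    exc: PopulationParams = field(default_factory=exc_defaults)
    inh: PopulationParams = field(default_factory=inh_defaults)
    synapses: SynapseConfig = field(default_factory=SynapseConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    ext_input: ExternalInputConfig = field(default_factory=ExternalInputConfig)
    duration: float = 30.0  # s
    dt: float = 0.1  # ms
    seed: int = 0
    lfp_rate: float = 1000.0  # Hz
    lfp_includes_external: bool = True

    def __post_init__(self):
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ParameterError("population sizes must be positive")
        if self.duration <= 0 or self.dt <= 0:
            raise ParameterError("duration and dt must be > 0")
        min_tau = min(self.exc.tau_ampa, self.inh.tau_ampa)
        if self.dt > min_tau / 10.0 + 1e-12:
            raise ParameterError(
                f"dt={self.dt} ms too coarse; must resolve the fastest synaptic "
                f"time constant ({min_tau} ms / 10)"
            )

    @property
    def n_units(self) -> int:
        return self.n_exc + self.n_inh


@dataclass(frozen=True)
class RampProtocol:
    """Repeated ramp-current sweeps injected into one population.

    The current rises linearly from 0 to peak_amplitude (nA) over
    ramp_duration, drops back to 0 instantly, and repeats every
    ramp_duration + interval seconds. Polarity 'inhibitory' injects a
    negative (hyperpolarizing) current.
    """

    peak_amplitude: float = 0.1
    polarity: str = "excitatory"
    ramp_duration: float = 3.0
    interval: float = 6.0
    n_sweeps: int = 60
    target: str = "inhibitory"

    def __post_init__(self):
        if self.peak_amplitude < 0:
            raise ParameterError("peak_amplitude must be >= 0 (sign via polarity)")
        if self.peak_amplitude > 0 and not 0.05 <= self.peak_amplitude <= 0.2:
            warnings.warn(
                "peak_amplitude outside the 0.05-0.2 nA protocol range",
                stacklevel=2,
            )
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ParameterError("polarity must be 'excitatory' or 'inhibitory'")
        if self.target not in ("excitatory", "inhibitory"):
            raise ParameterError("target must be 'excitatory' or 'inhibitory'")
        if self.ramp_duration <= 0:
            raise ParameterError("ramp_duration must be > 0")
        if self.n_sweeps < 1:
            raise ParameterError("n_sweeps must be >= 1")
        if self.interval < 0:
            raise ParameterError("interval must be >= 0")

    @property
    def sweep_period(self) -> float:
        return self.ramp_duration + self.interval

    @property
    def total_duration(self) -> float:
        return self.n_sweeps * self.sweep_period


@dataclass
class SpikeRaster:
    """Unit-labelled spike times over the half-open epoch [0, duration) s.

    spike_times is globally time-sorted; populations[u] gives the label
    ('exc' or 'inh') of unit u.
    """

    spike_times: np.ndarray
    unit_ids: np.ndarray
    populations: np.ndarray
    duration: float

    @property
    def n_units(self) -> int:
        return len(self.populations)

    def train(self, unit: int) -> np.ndarray:
        return np.sort(self.spike_times[self.unit_ids == unit])

    def trains(self) -> list:
        order = np.lexsort((self.spike_times, self.unit_ids))
        uid = self.unit_ids[order]
        t = self.spike_times[order]
        bounds = np.searchsorted(uid, np.arange(self.n_units + 1))
        return [t[bounds[u]:bounds[u + 1]] for u in range(self.n_units)]

    def rates(self) -> np.ndarray:
        counts = np.bincount(self.unit_ids, minlength=self.n_units)
        return counts / self.duration

    def population_rate(self, population: str) -> float:
        mask = self.populations == population
        if not mask.any():
            raise ParameterError(f"no units in population {population!r}")
        return float(self.rates()[mask].mean())


@dataclass
class LFPProxyTrace:
    """Nonnegative model-LFP trace (summed |synaptic currents|, pA)."""

    samples: np.ndarray
    sampling_rate: float


@dataclass
class SimulationResult:
    raster: SpikeRaster
    lfp: LFPProxyTrace
    per_population_rates: dict
    config: NetworkConfig
    protocol: Optional[RampProtocol] = None
    sweep_onsets: Optional[np.ndarray] = None


@dataclass
class RealizedNetwork:
    """Sampled weight matrices, before grid-multiplier scaling.

    w_ampa_base[i, j]: conductance increment (nS) on unit j when excitatory
    unit i spikes, already divided by the AMPA divisor. w_gaba_base[k, j]:
    same for inhibitory unit k (row index k = unit n_exc + k), divided by the
    target-dependent GABA divisor. Self-connections are zero.
    """

    w_ampa_base: np.ndarray
    w_gaba_base: np.ndarray
    config: NetworkConfig

    def scaled_weights(self, exc_multiplier: float, inh_multiplier: float):
        if exc_multiplier <= 0 or inh_multiplier <= 0:
            raise ParameterError("grid multipliers must be > 0")
        return (
            self.w_ampa_base * exc_multiplier,
            self.w_gaba_base * inh_multiplier,
        )


def build_network(config: NetworkConfig) -> RealizedNetwork:
    """Sample the all-to-all lognormal weight matrices once from the seed.

    Weights are drawn from lognormal(lognorm_mu, lognorm_sigma), divided by
    their class divisor, with the diagonal (autapses) zeroed. The grid
    multipliers are applied later so the same sampled tensor serves every
    grid cell.
    """
    syn = config.synapses
    rng = np.random.default_rng(config.seed)
    n, ne, ni = config.n_units, config.n_exc, config.n_inh

    def draw(rows):
        if syn.lognorm_sigma == 0.0:
            return np.full((rows, n), math.exp(syn.lognorm_mu))
        return rng.lognormal(syn.lognorm_mu, syn.lognorm_sigma, size=(rows, n))

    w_ampa = draw(ne) / syn.ampa_divisor * syn.coupling_scale
    w_gaba = draw(ni) * syn.coupling_scale
    w_gaba[:, :ne] /= syn.gaba_divisor_onto_exc
    w_gaba[:, ne:] /= syn.gaba_divisor_onto_inh
    for i in range(ne):
        w_ampa[i, i] = 0.0
    for k in range(ni):
        w_gaba[k, ne + k] = 0.0
    return RealizedNetwork(w_ampa, w_gaba, config)


def _per_neuron_arrays(config: NetworkConfig):
    ne, ni = config.n_exc, config.n_inh
    e, i = config.exc, config.inh

    def cat(a, b):
        return np.concatenate([np.full(ne, a), np.full(ni, b)])

    return {
        "v_leak": cat(e.v_leak, i.v_leak),
        "v_thresh": cat(e.v_thresh, i.v_thresh),
        "v_reset": cat(e.v_reset, i.v_reset),
        "t_ref_steps": np.concatenate(
            [
                np.full(ne, int(round(e.t_refract / config.dt)), dtype=np.int64),
                np.full(ni, int(round(i.t_refract / config.dt)), dtype=np.int64),
            ]
        ),
        "c_m": cat(e.capacitance, i.capacitance),
        "g_leak": cat(e.g_leak, i.g_leak),
        "g_decay_ampa": cat(
            math.exp(-config.dt / e.tau_ampa), math.exp(-config.dt / i.tau_ampa)
        ),
        "g_decay_gaba": cat(
            math.exp(-config.dt / e.tau_gaba), math.exp(-config.dt / i.tau_gaba)
        ),
    }


def _build_stim(config: NetworkConfig, protocol: RampProtocol, n_steps: int):
    """Precompute the pA stimulus waveform and the target-unit mask."""
    if protocol.total_duration > config.duration + 1e-9:
        raise ParameterError(
            f"protocol needs {protocol.total_duration:.1f} s but simulation "
            f"lasts {config.duration:.1f} s"
        )
    dt_s = config.dt / 1000.0
    t = np.arange(n_steps) * dt_s
    phase = t % protocol.sweep_period
    sweep_idx = np.floor(t / protocol.sweep_period)
    in_ramp = (phase < protocol.ramp_duration) & (sweep_idx < protocol.n_sweeps)
    amp_pa = protocol.peak_amplitude * 1000.0
    if protocol.polarity == "inhibitory":
        amp_pa = -amp_pa
    stim = np.where(in_ramp, amp_pa * phase / protocol.ramp_duration, 0.0)
    mask = np.zeros(config.n_units, dtype=np.bool_)
    if protocol.target == "excitatory":
        mask[: config.n_exc] = True
    else:
        mask[config.n_exc:] = True
    onsets = np.arange(protocol.n_sweeps) * protocol.sweep_period
    return stim, mask, onsets


def simulate(
    network: RealizedNetwork,
    config: Optional[NetworkConfig] = None,
    protocol: Optional[RampProtocol] = None,
    noise_seed: Optional[int] = None,
    i_const: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Run the network and return the spike raster plus the LFP proxy.

    noise_seed (default: config.seed) controls the OU noise and the external
    Poisson pool; the weight tensor is fixed by the network object. i_const
    is an optional per-unit constant current (pA), used e.g. for
    single-neuron validation against the closed-form LIF solution.
    """
    config = config or network.config
    dt_s = config.dt / 1000.0
    n_steps = int(round(config.duration / dt_s))
    lfp_decim = max(1, int(round(1000.0 / (config.lfp_rate * config.dt))))
    arr = _per_neuron_arrays(config)
    syn = config.synapses
    w_ampa, w_gaba = network.scaled_weights(syn.exc_multiplier, syn.inh_multiplier)

    if protocol is not None:
        stim, stim_mask, onsets = _build_stim(config, protocol, n_steps)
    else:
        stim = np.zeros(0)
        stim_mask = np.zeros(config.n_units, dtype=np.bool_)
        onsets = None

    if i_const is None:
        i_const = np.zeros(config.n_units)

    ou_decay = math.exp(-config.dt / config.noise.ou_tau)
    ou_kick = math.sqrt(max(0.0, 1.0 - ou_decay**2))
    seed = int(config.seed if noise_seed is None else noise_seed) % (2**31 - 1)

    spk_step, spk_unit, lfp, err = run_lif_kernel(
        config.n_exc,
        arr["v_leak"],
        arr["v_thresh"],
        arr["v_reset"],
        arr["t_ref_steps"],
        arr["c_m"],
        arr["g_leak"],
        arr["g_decay_ampa"],
        arr["g_decay_gaba"],
        np.ascontiguousarray(w_ampa),
        np.ascontiguousarray(w_gaba),
        syn.e_ampa,
        syn.e_gaba,
        syn.g_ampa_ext,
        config.ext_input.total_rate / 1000.0,
        config.noise.ou_sigma,
        ou_decay,
        ou_kick,
        np.asarray(i_const, dtype=np.float64),
        stim,
        stim_mask,
        config.dt,
        n_steps,
        lfp_decim,
        seed,
        config.lfp_includes_external,
    )
    if err >= 0:
        raise SimulationError(
            f"non-finite membrane potential at step {err} (t={err * dt_s:.4f} s)"
        )

    times = spk_step.astype(np.float64) * dt_s
    populations = np.array(
        ["exc"] * config.n_exc + ["inh"] * config.n_inh, dtype=object
    )
    raster = SpikeRaster(times, spk_unit.astype(np.int64), populations, config.duration)
    lfp_trace = LFPProxyTrace(lfp, 1000.0 / (lfp_decim * config.dt))
    rates = {
        "exc": float(np.sum(spk_unit < config.n_exc) / (config.n_exc * config.duration)),
        "inh": float(np.sum(spk_unit >= config.n_exc) / (config.n_inh * config.duration)),
    }
    return SimulationResult(raster, lfp_trace, rates, config, protocol, onsets)


def net_inhibition_strength(exc_multiplier: float, inh_multiplier: float) -> float:
    """Net inhibition strength: inhibitory / excitatory conductance multiplier."""
    if exc_multiplier <= 0:
        raise ParameterError("exc_multiplier must be > 0")
    if inh_multiplier <= 0:
        raise ParameterError("inh_multiplier must be > 0")
    return inh_multiplier / exc_multiplier


def default_grid(n_exc_levels: int = 25, n_inh_levels: int = 26):
    """Grid of conductance multipliers: excitatory 0.1-0.7, inhibitory 0.2-1.2."""
    return (
        np.linspace(0.1, 0.7, n_exc_levels),
        np.linspace(0.2, 1.2, n_inh_levels),
    )


def sweep_ei_grid(
    base_config: NetworkConfig,
    exc_multipliers: Sequence[float],
    inh_multipliers: Sequence[float],
    per_cell_duration: Optional[float] = None,
    seed: Optional[int] = None,
    sttc_lag: float = 1.0,
    sttc_min_spikes: int = 1,
    fit_range=(30.0, 100.0),
    psd_window: float = 10.0,
    psd_overlap: float = 5.0,
    on_error: str = "continue",
):
    """Simulate every (excitatory, inhibitory) multiplier combination.

    The lognormal weight tensor is sampled once from `seed` and rescaled per
    cell; each cell uses its own noise stream. Per cell the table records the
    population rates, the aperiodic 1/f exponent of the LFP proxy fitted over
    `fit_range`, and the mean pairwise STTC at `sttc_lag` over all units with
    at least `sttc_min_spikes` spikes. Failed cells are reported in the
    'error' column and skipped (on_error='raise' propagates instead).

    Returns a pandas DataFrame (one row per cell).
    """
    import pandas as pd

    from .spectral import compute_psd, fit_aperiodic

    exc_multipliers = np.asarray(list(exc_multipliers), dtype=float)
    inh_multipliers = np.asarray(list(inh_multipliers), dtype=float)
    if exc_multipliers.size == 0 or inh_multipliers.size == 0:
        raise ParameterError("multiplier lists must be non-empty")

    seed = base_config.seed if seed is None else int(seed)
    duration = per_cell_duration or base_config.duration
    config = replace(base_config, duration=duration, seed=seed)
    network = build_network(config)

    rows = []
    cell = 0
    for em in exc_multipliers:
        for im in inh_multipliers:
            cell += 1
            row = {
                "exc_mult": em,
                "inh_mult": im,
                "inhibition_strength": net_inhibition_strength(em, im),
                "seed": seed + cell,
            }
            cfg = replace(
                config, synapses=replace(config.synapses, exc_multiplier=em, inh_multiplier=im)
            )
            try:
                res = simulate(network, cfg, noise_seed=seed + cell)
                row["rate_exc_hz"] = res.per_population_rates["exc"]
                row["rate_inh_hz"] = res.per_population_rates["inh"]
                psd = compute_psd(
                    res.lfp.samples,
                    res.lfp.sampling_rate,
                    window=psd_window,
                    overlap=psd_overlap,
                )
                row["exponent_1f"] = fit_aperiodic(psd, fit_range).exponent
                trains = res.raster.trains()
                times = np.concatenate(trains) if trains else np.zeros(0)
                offsets = np.zeros(len(trains) + 1, dtype=np.int64)
                offsets[1:] = np.cumsum([len(t) for t in trains])
                mean_sttc, n_pairs = pairwise_sttc_mean(
                    times, offsets, duration, sttc_lag, sttc_min_spikes
                )
                row["mean_sttc_1s"] = mean_sttc
                row["n_sttc_pairs"] = n_pairs
                row["error"] = ""
            except (SimulationError, ParameterError, ValueError) as exc:
                if on_error == "raise":
                    raise
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def apply_ramp_protocol(
    network: RealizedNetwork,
    config: Optional[NetworkConfig] = None,
    protocol: Optional[RampProtocol] = None,
    noise_seed: Optional[int] = None,
) -> SimulationResult:
    """Run the ramp-stimulation protocol; extends duration to fit all sweeps."""
    protocol = protocol or RampProtocol()
    config = config or network.config
    if config.duration < protocol.total_duration:
        config = replace(config, duration=protocol.total_duration)
    return simulate(network, config, protocol=protocol, noise_seed=noise_seed)


def set_gaba_reversal(config: NetworkConfig, v_rev: float) -> NetworkConfig:
    """Return a copy of config with the GABA reversal potential set to v_rev."""
    if not math.isfinite(v_rev):
        raise ParameterError("v_rev must be finite")
    return replace(config, synapses=replace(config.synapses, e_gaba=v_rev))


@dataclass(frozen=True)
class ReversalRegime:
    label: str  # excitatory | depolarizing | at-rest | hyperpolarizing
    mv_below_rest: float

    def __str__(self):
        if self.label == "hyperpolarizing":
            return f"hyperpolarizing ({self.mv_below_rest:g} mV below rest)"
        return self.label


def classify_gaba_reversal(
    v_rev: float, v_rest: float = -70.0, v_thresh: float = -52.0
) -> ReversalRegime:
    """Classify a GABA reversal potential relative to rest and threshold.

    With zero-mean noise the drive-free fixed point of the membrane is the
    leak potential, so v_rest defaults to the leak value.
    """
    if v_rev > v_thresh:
        return ReversalRegime("excitatory", v_rest - v_rev)
    if v_rev > v_rest:
        return ReversalRegime("depolarizing", v_rest - v_rev)
    if v_rev == v_rest:
        return ReversalRegime("at-rest", 0.0)
    return ReversalRegime("hyperpolarizing", v_rest - v_rev)
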