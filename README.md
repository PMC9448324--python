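# eisim

Simulation and analysis tools for studying how the excitation–inhibition
(E–I) ratio shapes cortical population activity during early development.
The package targets researchers who want to relate net inhibition strength
to two observables that can be measured in developing cortex: the aperiodic
1/f exponent of the field potential and pairwise spike-train correlations.

It provides:

* a conductance-based leaky integrate-and-fire (LIF) network of 400
  all-to-all coupled units (320 excitatory, 80 inhibitory) with lognormal
  synaptic weights, Ornstein–Uhlenbeck current noise, a shared external
  Poisson pool, parametric scaling of all excitatory and inhibitory
  conductances, ramp-current stimulation of interneurons, GABA
  reversal-potential manipulation, and a model LFP (the summed absolute
  AMPA and GABA currents on excitatory cells);
* spike-train statistics: the spike time tiling coefficient (STTC) across
  lags, pair filtering, distance/site-resolved summaries, firing-rate
  modulation indices with signed-rank classification, and PCA population
  trajectories;
* LFP/EEG processing: active-period (burst) detection with dual
  absolute/relative hysteresis thresholds, median-Welch power spectral
  densities, area normalization, aperiodic 1/f-exponent fitting, common
  average referencing, and envelope-based artifact rejection;
* seeded synthetic-data generators with exact ground truth (power-law
  traces, discontinuous neonatal-like LFP, copy-thinning correlated spike
  rasters on a four-shank probe geometry, stimulation-trial rasters);
* an end-to-end pipeline (library functions and an `eisim` command line)
  that sweeps the conductance grid and quantifies both relationships with
  regression fits.

## The model and the statistics

Each unit follows

    Cm dVm/dt = −gL (Vm − VL) − gAMPA (Vm − EAMPA) − gGABA (Vm − EGABA) + Istim + η

with instantaneous (zero-delay) synapses whose conductances decay
exponentially (dg/dt = −g/τ), a refractory clamp at the reset potential,
and zero-mean OU noise η. A presynaptic spike increments the postsynaptic
conductance by the sampled lognormal weight. Net inhibition strength is the
ratio of the inhibitory to the excitatory conductance multiplier.

Pairwise correlation is measured by the spike time tiling coefficient

    STTC = ½ [ (PA − TB) / (1 − PA·TB) + (PB − TA) / (1 − PB·TA) ]

where PA is the proportion of spikes of train A within ±Δt of a spike of
B, and TA the proportion of the recording tiled by ±Δt windows around A's
spikes. The aperiodic 1/f exponent is the negative slope of log10 power
versus log10 frequency of the PSD's aperiodic component, fitted with
iterative down-weighting of oscillatory peaks.

## Worked example

```python
import numpy as np
from eisim.network import NetworkConfig, build_network, simulate
from eisim.spectral import compute_psd, fit_aperiodic
from eisim.spikes import SpikeTrainPair, mean_pairwise_sttc, sttc

config = NetworkConfig(duration=20.0, seed=42)
result = simulate(build_network(config), config)
print(f"excitatory rate: {result.per_population_rates['exc']:.2f} Hz")
print(f"inhibitory rate: {result.per_population_rates['inh']:.2f} Hz")

psd = compute_psd(result.lfp.samples, result.lfp.sampling_rate)
fit = fit_aperiodic(psd, (30.0, 100.0))
print(f"1/f exponent (30-100 Hz): {fit.exponent:.2f}")

mean_sttc, n_pairs = mean_pairwise_sttc(result.raster.trains(), 20.0, lag=1.0)
print(f"mean pairwise STTC (1 s lag): {mean_sttc:.3f} over {n_pairs} pairs")

pair = SpikeTrainPair(np.array([10.0]), np.array([50.0]), 100.0)
print(f"worked STTC example: {sttc(pair, 1.0).value:.3f}")
```

prints

```
excitatory rate: 1.56 Hz
inhibitory rate: 2.94 Hz
1/f exponent (30-100 Hz): 0.90
mean pairwise STTC (1 s lag): 0.281 over 62835 pairs
worked STTC example: -0.020
```

The excitatory population sits near 1.5 Hz, interneurons fire faster, the
LFP proxy shows a clear aperiodic decay in the 30–100 Hz band, and the lone
spikes 40 s apart give the small negative tiling coefficient expected when
two trains tile 2% of the epoch each and never coincide.

Command-line equivalents: `eisim simulate`, `eisim sweep`, `eisim ramp`,
`eisim reversal`, `eisim sttc`, `eisim detect-bursts`, `eisim psd`,
`eisim fit-1f`, `eisim synth`, `eisim fig2` (see `eisim --help`). Every
run writes a `manifest.json` with the seed, config hash and wall time.

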