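# Methods

## Network model

The network has 400 conductance-based LIF units, 80% excitatory (PYR) and
20% inhibitory (IN), coupled all-to-all without self-connections. Membrane
dynamics per unit:

    Cm dVm/dt = −gL (Vm − VL) − gAMPA (Vm − EAMPA) − gGABA (Vm − EGABA) + Istim + η

Neuron parameters (mV, ms, pF, nS): VL = −70, VThr = −52, VRes = −59 for
both populations; τRef = 2 (PYR) / 1 (IN); Cm = 500; gL = 25 (PYR) / 20
(IN); τAMPA = 2 (PYR) / 1 (IN); τGABA = 8. Reversal potentials EAMPA = 0,
EGABA = −80 by default. When Vm reaches threshold the unit spikes, resets,
and is clamped at the reset potential for its refractory period while its
synaptic conductances keep evolving. Synaptic transmission is
instantaneous: a spike at step t increments every postsynaptic conductance
before step t+1; rise times are neglected.

### Synaptic weights and the coupling scale

Weights are sampled once per seed from lognormal(0, 1) and divided by a
class divisor — 50 for AMPA onto either population, 12 for GABA onto
excitatory units, 60 for GABA onto inhibitory units — which fixes the
*relative* strength of the four synapse classes. A single global
`coupling_scale` (default 20) then sets their absolute magnitude relative
to the leak conductance. The grid multipliers (excitatory 0.1–0.7,
inhibitory 0.2–1.2) rescale the same sampled tensor, so grid cells differ
only in synaptic gain, never in wiring. The external-pool conductance
(1.17 nS per pooled spike) is a fixed per-event increment and is not
scaled by the grid multipliers, which model recurrent synaptic maturation.

The coupling scale and the noise amplitude are the two calibrated
constants of the model. They were fixed, once, against four qualitative
and quantitative anchors evaluated at the grid-central multipliers
(0.4, 0.7): (i) excitatory rates near 1.5 Hz; (ii) inhibitory rates above
excitatory ones everywhere on the grid; (iii) excitatory rates
monotonically decreasing in the inhibitory multiplier; (iv) stable
activity for GABA reversal potentials at least 5 mV below rest, with
rates rising steeply as the reversal depolarizes. Larger coupling scales
produce runaway excitation in high-excitation/low-inhibition grid corners
and push inhibitory rates far above the plausible range; smaller ones
make the grid multipliers inconsequential. Slope outcomes of the grid
analyses were never consulted during calibration.

### Drive and noise

Each unit receives an independent Ornstein–Uhlenbeck current η with zero
mean, correlation time 5 ms and stationary SD 487 pA (the calibrated
value; exact exponential update, so the discrete process has the stated
stationary variance at any dt). The excitatory population additionally
receives a *shared* external Poisson pool — 100 sources at 1.5 spikes/s,
pooled into one 150 Hz train delivered identically to every excitatory
unit with a fixed 1.17 nS AMPA increment. Sharing the pool is what gives
the excitatory population common input, and therefore nonzero pairwise
correlations for the STTC analyses; fully independent external drive
would decorrelate the network almost completely.

### Integration

Exponential-Euler scheme: conductances and the OU process decay with
their exact per-step factors; the membrane equation takes a forward-Euler
step. Default dt = 0.1 ms (one tenth of the fastest synaptic time
constant); the test suite verifies first-spike times against the
closed-form LIF solution to 1% and checks convergence under dt halving.
The kernel is numba-compiled; non-finite membrane potentials abort the
run with the offending step. All randomness flows from explicit seeds;
identical (config, seed, protocol) triples give bit-identical rasters.

### Model LFP

The LFP proxy is Σ over excitatory cells of |I_AMPA| + |I_GABA|, averaged
within 1 ms bins (1 kHz output by default). The external-pool AMPA
current is included by default (it is an AMPA current on excitatory
cells); `lfp_includes_external=False` removes it. Because τGABA (8 ms) is
slower than τAMPA (2 ms), a larger GABA share steepens the proxy's
spectrum in the 30–100 Hz band — this is the mechanism linking inhibition
to the 1/f exponent here.

### Protocols

The ramp protocol injects a linearly rising current (0 to ±peak over 3 s,
instant offset, 6 s inter-sweep interval, 60 sweeps by default) into all
inhibitory units; sweep onsets are recorded for trial averaging. The
GABA-reversal manipulation replaces EGABA; regimes are classified
relative to rest (≡ VL, the drive-free fixed point under zero-mean noise)
and threshold.

## Known limitation: the inhibition-stabilized regime

At the calibrated operating point the recurrent excitatory loop gain is
below one, so the network is *not* inhibition-stabilized. Two
consequences, both measured and left visible as failing acceptance-scale
tests rather than patched: (a) moderately depolarizing GABA reversals
(e.g. −60 mV) raise the mean rate severalfold but do not produce
full runaway; rates exceed 100 Hz only for reversals above roughly
−57 mV; (b) the interneuron response to an inhibitory ramp decreases
monotonically — the paradoxical biphasic rebound of inhibition-stabilized
networks does not occur at any stable calibration we found. Coupling
scales strong enough to create these signatures destabilize the
high-excitation corner of the conductance grid and distort its rate,
exponent and STTC structure; a single parameterization cannot exhibit
both behaviours under this weight structure.

## Spike-train statistics

STTC follows the tiling formula with windows clipped to [0, T) and
overlaps merged, so TA is a true proportion; coincidence tests are
inclusive (|t_a − t_b| ≤ Δt). Undefined cases (an empty train, or a
denominator of zero when a train is fully tiled) are returned as flagged
results, never silently dropped; aggregations skip them and report
counts. The default lag grid is 13 log-spaced values from 2.5 ms to 10 s
with the nearest point snapped to exactly 1 s. The all-pairs mean used by
the grid sweep is a compiled two-pointer implementation, tested to 1e−12
against both the vectorized per-pair path and an independent brute-force
oracle.

Modulation analysis compares per-trial rates in the 1.5 s before ramp
onset against the last 1.5 s of the ramp: two-sided Wilcoxon signed-rank
across trials (zero-difference trials dropped — ties are common at
neonatal rates), α = 0.01, with the modulation index
MI = (pre − stim)/(pre + stim) computed from trial-mean rates. Population
trajectories: trial-averaged unit × time rate matrices are convolved with
a Gaussian kernel (500 ms window, 50 ms SD), z-scored per unit across
time, and decomposed by PCA over units; the returned components are PC
scores over time, with each component's sign chosen so its loading vector
has nonnegative mean.

## LFP/EEG processing

Active-period detection: 4th-order zero-phase Butterworth band-pass
(4–20 Hz) per channel → downsampling to 100 Hz (decimation for integer
factors, polyphase resampling otherwise) → channel average →
rectification → 500 ms boxcar. Rectification before the boxcar makes the
absolute thresholds meaningful on oscillatory signals and is toggleable.
Seeds are samples whose envelope exceeds 100 µV *or* whose z-scored
envelope (SD estimated over the whole recording) exceeds 4; seeds extend
over all contiguous samples above 50 µV or 2 SD; periods closer than 1 s
merge; periods shorter than 300 ms are discarded. Boundaries are accurate
to about half the boxcar width. Note that the discard rule can only act
through the relative thresholds or non-default parameters: any burst
strong enough to seed stays above the lower threshold for more than
300 ms after the 500 ms smear.

PSDs are Welch estimates (Hann taper, 10 s windows, 5 s overlap) combined
across windows by the median, which is robust to sporadic artifact
windows. Normalization divides by the trapezoidal area over a stated
range. The aperiodic fit regresses log10 power on log10 frequency over a
caller-chosen range (30–100 Hz for the model LFP, 5–45 Hz for mouse-style
LFP, 1–20/5–20 Hz for EEG-style data — always an argument, never
hard-coded), removing points whose positive residual exceeds 2.5
residual-SDs for two refit iterations so oscillatory peaks do not bias
the slope; the exponent is the negative slope. EEG-style preprocessing
offers common average referencing and rejection of epochs whose mean
analytic-signal envelope exceeds the across-epoch mean by 2 SD.

## Regression fits

Grid relationships are fitted on per-cell summaries. The exponent uses
ordinary least squares of exponent on net inhibition strength (pooled
across the grid; per-excitatory-level slopes are co-reported in
`fits.json`). The STTC relationship, which flattens exponentially, uses a
Gamma GLM with log link and fixed unit shape on shifted-positive values
(shift 1 − min when values are not strictly positive, recorded in the
fit); the log-link coefficient is a multiplicative slope whose sign
follows the direction of the relationship, the natural reading for a
positive decaying quantity. The canonical inverse-link fit (with its
average-marginal-effect response slope dμ/dx = −b₁·mean(μ²)) and a
log-linear OLS are co-reported in `fits.json`. Proportions use a
binomial-logit GLM with per-observation trial weights.

## Synthetic generators

The generators emulate the statistical structure the analyses assume —
not the biophysics. The discontinuous-LFP generator adds flat-topped
(Tukey-enveloped) oscillatory bursts (carrier inside the detector's
4–20 Hz band, truncated-normal durations with a 0.1 s floor to exercise
the discard rule) at Poisson times to 1/f^β background noise; the exact
inserted intervals are the ground truth, with overlaps merged. The
correlated-raster generator uses copy-thinning: one mother Poisson train
per shank of a four-shank, 4×4-site probe (100 µm site pitch, 125 µm
shank pitch); each unit copies mother spikes with probability
c·exp(−d/λ), jitters them (Gaussian, default 5 ms), and tops up with
independent Poisson spikes to its target rate (default 1 Hz,
neonatal-like), so pairwise shared fractions are known exactly. The
stimulation-trial generator draws inhomogeneous-Poisson trials with known
activated / inhibited / biphasic / unmodulated labels via thinning.

What passing these harnesses does *not* show: robustness to
non-stationary backgrounds, electrode drift, spike-sorting contamination,
volume conduction, or bursts with slowly waxing envelopes — none of which
the generators model.

## Problem sizes

The acceptance-scale analyses use a reduced 9×9 multiplier grid at 20 s
per cell (the package's standard reduced configuration; the full design
is 25×26 at 30 s, available through the same functions), 15 s
reversal-regime runs, 15-sweep ramp experiments, 20-seed exponent
recovery at 60 s per trace, and 300-unit null calibrations. Seeds are
fixed in the test suite and flow from `--seed` in the acceptance script.
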