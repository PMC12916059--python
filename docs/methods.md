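# Methods

## Model overview

The network comprises six populations of conductance-based adaptive point
neurons: striatal projection neurons expressing D1 or D2 dopamine
receptors (6000 each), striatal fast-spiking interneurons (FSN, 420), the
arkypallidal (GPe-TA, 264) and prototypic (GPe-TI, 780) subpopulations of
the external pallidum, and the subthalamic nucleus (STN, 408).  STN and
GPe use the adaptive exponential (AdEx) membrane equation; D1/D2 use the
adaptive quadratic equation; FSN uses the quadratic equation with a cubic
recovery current active below V_b = −55 mV.  A spike is registered when v
crosses V_peak, upon which v resets to V_reset and the adaptation current
jumps by b; there is no refractory period.  All per-population constants
(capacitance, reversals, synaptic time constants, thresholds, adaptation
parameters, external-drive rates) are tabulated in `bgdbs.params` and are
the model's reference values.

Synapses are conductance-based with single-exponential kinetics: a
presynaptic event, after its projection's conduction delay (1.0–7.0 ms),
adds the synaptic weight to the target's excitatory or inhibitory
conductance, which otherwise decays with the target population's time
constant.  GPe-TI self-inhibition integrates in a third, dedicated
conductance channel with its own time constant (7 ms); all other
inhibitory inputs to GPe-TI use 5.5 ms.  Connectivity is Bernoulli per
ordered pair at the tabulated probabilities, with no autapses and no
duplicate synapses.  Every neuron receives an independent homogeneous
Poisson excitatory input (zero delay) at a population-specific rate.

## Dopamine depletion

The primary depletion model scales the external-input rate of D2 neurons
only: v_ext(D_d) = v_ext,0 (0.3 D_d + 0.75), with D_d = 0.166 for the
healthy and 0.5 for the Parkinsonian condition.  Elevated D2 activity then
propagates through the D2→D1 and D2→GPe-TI projections, flipping the
striatal D2/D1 rate balance and synchronizing the two beta-generating
loops.  An alternative model additionally multiplies a tabulated set of
projection weights and two connection probabilities by 1 + β_p φ (φ ≤ 0);
the β table includes two striato-striatal rows with positive sign, which
are applied literally (depletion then weakens those connections), and one
row for the pallido-subthalamic projection that is labelled as an
excitatory weight but whose only matching projection in this circuit is
inhibitory — it is applied to that weight.  Alterations are applied to the
healthy base values before wiring; probabilities leaving [0, 1] clamp with
a warning.

## Short-term plasticity

STN→GPe-TI and STN→GPe-TA synapses carry a facilitation/depression model
with two unitless variables.  Between events both relax exponentially
toward 1; at each presynaptic event, with pre-jump values F and D,

* the event transmits weight × D·F,
* F ← F + F (Inc_F − 1)(F_bound − F)/(F_bound − 1)  (bounded above),
* D ← D · Inc_D.

Using the pre-jump values for the transmitted efficacy makes the first
pulse of any train transmit at baseline (efficacy 1), the natural reading
of the at-event delta terms; both jumps use the pre-jump state atomically.
Each plastic synapse is independently assigned one of three classes
(facilitation-dominant, depression-dominant, pseudo-linear; uniform 1/3)
whose time constants and increments are experimentally fitted.  The
relax/jump map under periodic drive contracts to a unique fixed point, so
steady-state per-pulse efficacies are well defined; at 7 ms inter-pulse
interval all three classes equilibrate below 1, depression-dominant lowest
(≈0.1).  Config toggles disable STP globally, per projection, restrict the
network to a single class, or scale all STP time constants by a common
factor (robustness checks use ±25%).

## DBS model

Stimulation is the axon-override mechanism: a fraction α of STN neurons is
recruited; their somatic dynamics are untouched and their spikes still
count in STN rate statistics, but every efferent synapse of a recruited
neuron receives the imposed pulse train (after the normal 2 ms conduction
delay) instead of the somatic spikes, and the synapse's STP state is
driven by that train.  All recruited axons share one pulse train (one
electrode entrains them synchronously); a toggle allows per-neuron Poisson
trains.  Pulse trains are regular (interval t_DBS, default 7 ms = 143 Hz)
or homogeneous Poisson with mean interval t_DBS, active for the whole
simulation.  Recruitment counts round half away from zero
(α = 0.4 → 163 of 408), and raising α retains previously recruited
neurons, adding new ones at random — mimicking the spatial growth of the
activated volume with stimulation amplitude and making intensity sweeps
monotone by construction.

## Numerical scheme

The membrane pair (v, w) advances jointly with classical fixed-step RK4 at
h = 0.04 ms.  Conductances are held fixed within a step and decayed by
their exact per-step exponential factor afterwards: the conductance ODE is
linear with known solution, and removing it from the stages avoids
stiffness.  Event times (spikes, DBS pulses, deliveries) snap to the step
grid; tabulated delays are exact grid multiples except 1.7/1.8 ms, which
snap with ≤ 0.02 ms error.  The threshold/reset check runs once per full
step.  STP states update lazily, per synapse, at event-delivery times via
the closed-form relaxation, so plasticity costs O(events).

The AdEx exponential diverges in finite time, so a fixed-step integrator
must cap it.  The cap is chosen per population so that one capped step
moves v by at most 100 mV: arg_max = ln(100 mV · C_m/(h g_L Δ_T)).  A
capped step lands a bounded distance above V_peak, where the reset takes
over; the supra-threshold trajectory shape is irrelevant because the spike
is the reset.  A much larger cap (e.g. e^30) is catastrophic rather than
conservative: a single RK4 stage then moves v by ~10^10 mV and the stage
combination can throw v to large *negative* values, silently freezing
neurons for hundreds of milliseconds.  This choice is validated by the
step-halving test (population rates change <5% at h = 0.02 ms) and by the
single-neuron engine-versus-reference comparisons.

Initial conditions: v uniform in [E_L, V_th) per neuron (decorrelates
startup), w = 0, conductances 0.  The membrane potentials are not stated
by the underlying study; the first 2000 ms of every simulation is
discarded as transient, which also removes the ~200 ms DBS-onset
transient.  Two independent random streams are used: the wiring stream
(connectivity, STP classes, DBS recruitment) and the noise stream (Poisson
drive, initial conditions, Poisson pulse trains), so paired contrasts
share wiring exactly while varying the manipulated factor.  Identical
configuration and seeds reproduce spike data bit for bit.

## Analysis

Population activity is the instantaneous population rate: total spikes in
1-ms bins.  PSDs use Welch's method with 2000-ms Hann windows, 50% overlap
and mean detrending (0.5 Hz resolution; a full 4-s analysis window gives
three segments, the reduced 2-s window one).  Mean band power over
[f1, f2] is the trapezoidal average of the PSD (beta 12–30 Hz, gamma
30–150 Hz).  Because a finite population of N neurons firing at constant
rate already has flat spectral power ∝ N v₀(1−v₀), reported band powers
subtract the baseline Q of an auxiliary population with i.i.d.
Binomial(N, v₀) counts per bin, with v₀ taken from the analyzed series'
own mean; Q averages 20 auxiliary draws to make its Monte-Carlo error
negligible against the condition differences.  Corrected power can be
slightly negative for sub-binomial variability and is reported as-is.
Beta phase uses an 11–31 Hz 4th-order Butterworth filter applied
forward-backward (zero phase) followed by the analytic-signal angle; the
phase-locking value between STN and D2 is the magnitude of the circular
mean of their phase difference, computed per realization and aggregated as
mean ± SE.  The spectrogram (1000-ms windows, 90% overlap) is
presentation-only.

## Experiments and study design

Drivers reproduce the study conditions: healthy (D_d = 0.166, no DBS),
Parkinsonian (D_d = 0.5), and Parkinsonian with DBS at a chosen fraction,
frequency and regular/Poisson mode.  Every contrast reuses identical
wiring seeds per realization; fraction grids share nested recruitment
sets.  "Within the healthy range" is operationalized as (healthy mean +
1 SE) across realizations, and the therapeutic boundary at each frequency
is the smallest grid fraction whose mean beta power is at or below that
threshold *and stays there for every larger swept fraction*; the D2/D1
boundary is the smallest fraction with mean-rate ratio below 1.  Percent
changes between conditions are computed on realization-mean quantities,
matching single printed numbers per contrast; cells with a ~0 baseline are
reported as undefined rather than infinite.

## Problem sizes

Reference simulations are 6000 ms with the first 2000 ms discarded and
four realizations per condition.  The packaged test suite uses reduced
study conditions — two realizations of 4000 ms (2000 ms analyzed) on the
full 13,872-neuron network — and sweeps the decisive sub-grids of the
fraction/frequency grids (e.g. {0.3, 0.4, 0.5} around the with-STP
therapeutic fraction, {0.04 … 0.16} without STP, {70, 105, 145} Hz ×
{0.3, 0.6} for the frequency spot check).  A 4-s full-network realization
takes roughly half a minute on one core.  The full 19 × 30
frequency-intensity grid is a batch job (`bgdbs sweep-grid` supports grid
subsetting); nothing in the reduced runs changes the model itself.

## What the synthetic benchmarks do and do not show

All inputs are generated by the model itself (there is no external data):
the "experiments" are paired simulations, and the test oracles are
analytic (closed-form STP algebra, binomial white-noise spectra, Rayleigh
statistics for PLV, RK4 order).  Passing them shows the implementation is
faithful to the stated equations and that the network reproduces the
study's emergent phenomenology — murine-range firing rates, beta
elevation and loop locking under depletion, intensity- and
plasticity-dependent DBS suppression.  It does not validate the model
against patient recordings: population spike counts are not local field
potentials, external inputs are uncorrelated Poisson (cortical beta is not
modeled), and the depletion scalar compresses heterogeneous dopamine
effects into one drive parameter.

## Known limitations

No output nuclei (GPi/SNr), thalamus or cortex; no long-term plasticity;
no electrode geometry or field spread (intensity is a recruited fraction);
no charge-balance or waveform effects; point neurons without refractory
dynamics.  Event delivery is grid-snapped, so sub-step spike timing is not
resolved.  The reduced test conditions trade statistical power for
runtime: borderline contrasts (e.g. percent changes in sparsely firing D1)
carry larger realization-to-realization spread than four 6-s runs would.
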