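# Methods

## The model

`btcmodel` implements a neural mass model of the interacting brainstem,
thalamus and cortex (BTC) and uses it to study how cholinergic deficiency
slows the thalamocortical alpha rhythm — the computational analogue of the
EEG slowing observed in Alzheimer's disease.

Eleven lumped populations interact over a fixed, signed, directed graph:

| module    | populations |
|-----------|-------------|
| brainstem | SC (superior colliculus, glutamatergic), PNN (pedunculopontine nucleus, the cholinergic source) |
| thalamus  | TRC (relay nucleus), IN (local inhibitory interneurons), TRN (reticular nucleus) |
| cortex    | PY (pyramidal), eIN (excitatory), fIN (fast GABAergic), sIN (slow GABAergic interneurons) |
| extrinsic | Ret (retinal drive), Cor (adjacent-cortex drive) — Gaussian-noise-driven |

Each population `a` performs the classical two-stage neural mass
computation.  A static sigmoid converts the average membrane potential into
an average firing rate,

    phi_a = 2 e0 / (1 + exp(sigma (V0 - V_a))),

and a critically damped second-order synaptic kernel converts presynaptic
rate into a postsynaptic potential (PSP) `x_a`,

    tau_a^2 x_a'' = A_a tau_a phi_a - 2 tau_a x_a' - x_a.

Membrane potentials are signed sums of afferent PSPs,

    V_a = sum_b C_abe x_b - sum_d C_adi x_d,

so every kernel is positive and inhibition lives exclusively in the minus
sign of the summation.  In particular the cholinergic PNN population emits
one PSP that acts excitatorily on TRC (M1/M3 muscarinic receptors, weight
`C_tde`) and inhibitorily on IN and TRN (M2 receptors, weights `C_idi`,
`C_ndi`).  Ret and Cor are full populations whose "firing rate" is an
independent Gaussian draw `N(mu, eps)` at every step, passed through their
own kernel.

The model output — the analogue of an EEG lead — is the summated
postsynaptic potential `V_t` of the TRC population.

## Simulation protocol

Forward Euler at `dt = 1/256 s` for 120 s from the all-zero state; the
first 20 s are discarded (the transient fully absorbs initialisation), the
remaining 100 s epoch (25 600 samples) is band-passed with a zero-phase
10th-order Butterworth filter (0.5–50 Hz) and analysed:

* **Welch PSD**: Hamming window, 1024-sample (4 s) segments, 50 % overlap
  → a 0.25 Hz frequency grid.  The segment length is chosen so that every
  dominant frequency the experiments report lies exactly on this grid.
* **Dominant frequency**: argmax of the PSD on [0.5, 50] Hz, ties broken
  toward the lower frequency.
* **Relative band power**: power summed over a band's bins divided by power
  summed over [0.5, 50] Hz (alpha = [8, 13) Hz, theta = [4, 8) Hz).  A
  per-bin-mean variant is provided as a cross-check; both give the same
  qualitative sweep shapes.
* **Oscillation amplitude**: mean over successive opposite extrema of half
  the peak-to-trough excursion of the filtered epoch.  The mean Hilbert
  envelope is implemented as an independent cross-check.  Amplitude
  distributions are estimated from batches of independent realizations
  (realization `k` seeded `base + k`) and fitted with a maximum-likelihood
  normal density.

Noise is sampled once per Euler step as `N(mu, sqrt(eps))` without
`1/sqrt(dt)` scaling — the piecewise-constant band-limited-noise convention
of the neural-mass literature, matching a specification of the drive by
mean and variance of a rate rather than by a diffusion coefficient.

## The four deficiency experiments

Cholinergic deficiency is emulated by lowering exactly one weight at a time
from its reference value, everything else untouched:

| sweep  | pathway              | grid            | step |
|--------|----------------------|-----------------|------|
| C_tde  | PNN→TRC (M1/M3, direct)  | 100 → 60    | 1    |
| C_idi  | PNN→IN (M2, direct)      | 18 → 1      | 0.5  |
| C_ndi  | PNN→TRN (M2, direct)     | 10 → 0.5    | 0.25 |
| C_dpe  | PY→PNN (indirect, glutamatergic) | 78 → 38 | 1   |

Grid steps are chosen fine enough to localise the transition points.  For
each grid value one realization supplies the frequency-domain metrics
(every grid point sees the same noise path, which removes realization
jitter from neighbouring points); amplitude distributions are estimated at
the published exemplar weights from realization batches (500 by default,
100 as a documented quick setting).  The *critical value* of a sweep is the
largest grid value whose dominant frequency lies below the 8 Hz alpha/theta
boundary.  The discussion-level PY→TRC sweep is available through the same
generic machinery (`SweepSpec(parameter="C_pte", ...)`) rather than as a
named experiment.

## Parameter provenance and calibration

The kernel, sigmoid and noise constants are the standard neural-mass
values: Jansen–Rit excitatory kinetics (A = 3.25 mV, tau = 10 ms) and
sigmoid (e0 = 2.5 s⁻¹, V0 = 6 mV, sigma = 0.56 mV⁻¹), Wendling-style slow
(22 mV, 20 ms) and fast (10 mV, 2 ms) cortical GABAergic kinetics.
Thalamic GABAergic kinetics and the cholinergic kernel are slower
(tens of ms), reflecting the slow GABA_B-like and muscarinic receptor
dynamics of those pathways; their exact values, together with the
connectivity weights, were fixed by calibration (below).

The connectivity scale is anchored by the conventions of the anatomical
literature on the lateral geniculate nucleus: retinal terminals are a
minority of relay-cell synapses while interneurons receive a large retinal
share, cortical feedback dominates TRN input, and the cholinergic weight
PNN→TRC is set to 100 at the healthy baseline.

Because the complete numeric table for this 11-population circuit is not
available as machine-readable input, the reference configuration was
*calibrated*: target operating points were solved from the deterministic
fixed-point equations, candidate weight sets were screened with a
linearised prediction of the noise-driven output spectrum, and the final
values were selected by direct simulation of all four sweeps.  The
calibrated values live in one place, `src/btcmodel/data/default.yaml`, and
are frozen; the acceptance script and all tests run against this file.

The mechanism the calibration settles on is physiologically transparent.
Two negative-feedback loops close around the relay nucleus: the classical
TRC–TRN loop (fast excitation out, slow GABAergic inhibition back), which
resonates in the alpha range, and a slower corticothalamic loop
TRC→PY→IN→TRC through the thalamic interneurons, which resonates in the
theta range.  Cholinergic tone sets the operating points — and hence the
relative gains — of the two loops.  Weakening any of the four pathway
weights lowers the relay operating point, damping the alpha loop while the
theta pathway persists or strengthens; the spectral peak slides downward,
alpha power gives way to theta power, and the oscillation amplitude
shrinks — the three signatures of EEG slowing.

### What the calibrated configuration reproduces, and where it deviates

With the frozen configuration (reference seed), the healthy baseline is an
alpha rhythm at 8.75 Hz with relative alpha power 0.52 against theta 0.34.
All four deficiency sweeps lower the dominant frequency monotonically (to
within one 0.25 Hz Welch bin) and lower the fitted oscillation amplitude
between the top and the bottom of each grid.  The two interneuron-mediated
sweeps complete the alpha→theta transition inside their published ranges:
`C_idi` crosses the 8 Hz boundary at 8.5 (published ≈ 5) and reaches 7 Hz,
and `C_dpe` crosses at 59 (published ≈ 45) and reaches 7 Hz, both with the
published alpha-fall/theta-rise crossover.  The `C_tde` and `C_ndi` sweeps
slow the rhythm (8.75 → 8 Hz) but remain inside the alpha band over the
published parameter ranges, so their printed critical values (≈ 80, ≈ 2)
are not reproduced, and the published exemplar dominant frequencies are
matched only near the top of each sweep.  The published amplitude means
(11.04 mV at baseline, decreasing to 3.43) are an order of magnitude above
this configuration's (≈ 1.1 mV at baseline): the paper's amplitude scale
could not be recovered without destabilising the frequency structure, so
amplitudes should be compared as trends, not values.  All of these
deviations are visible in the acceptance test suite and in the comparison
sheet emitted by the reproduction run; none are silently corrected.

## Numerical choices

* Euler integration is the product path (matching the reference protocol);
  an RK4 integrator at finer steps exists only inside the test suite as an
  accuracy oracle.
* The integrator advances all realizations of a batch (or all grid values
  of a sweep) through one vectorised loop; a 500-realization batch costs a
  few times one realization, not 500 times.
* A blow-up guard aborts with diagnostics if any |PSP| exceeds 10⁶ mV
  (checked at 64 Hz along the trajectory).
* The sigmoid exponent is clipped at 700 to avoid overflow at extreme
  potentials; the clip is invisible at any physiological value.
* Zero-phase filtering (forward–backward) preserves extremum timing for
  the amplitude statistic; the effective filter order is doubled.
* Reproducibility: a run is a pure function of (configuration, seed);
  identical seeds give bit-identical trajectories on the same call path.
  Across different batch widths, floating-point summation order may differ
  at ~1e-14 relative.

## What the synthetic conditions do and do not show

All experiments run on model-generated data; there is no empirical EEG in
the pipeline.  Passing tests therefore demonstrate that the *mechanism* —
cholinergic operating-point control of a thalamocortical resonator —
produces EEG-slowing signatures robustly and reproducibly; they say nothing
about patient EEG, diagnosis, or the anatomical fidelity of individual
weights.  The published exemplar frequencies and amplitude means are
reported side-by-side with the model's values in the reproduction bundle as
a transparent comparison, with agreement expected at the level of the
qualitative trajectory (and of the 0.25 Hz grid for frequencies near the
baseline), not digit-for-digit.

## Known limitations

* Single cortical column, no conduction delays, no plasticity, no
  conductance-based detail.
* One shared retinal noise stream drives SC, TRC and IN (one Ret
  population, as in the circuit diagram), rather than independent streams.
* The amplitude statistic is one of several defensible operationalisations
  of "oscillation amplitude"; the extremum-based and envelope-based
  statistics agree to a few percent on spindle-like signals but can differ
  more for broadband ones.
* Euler at 1/256 s is part of the reference protocol, and for this
  near-critical configuration it is not a neutral choice: relative to finer
  steps (or an RK4 oracle) the forward-Euler map adds effective
  anti-damping and shifts the alpha centroid downward by up to ~0.7 Hz.
  The calibration was performed against the protocol's discrete map, which
  is therefore the defining object; the test suite verifies that the Euler
  and RK4 maps agree once the step is refined (so the bias is pure
  discretisation, not a drift error) and bounds the step-size sensitivity.
* The fast cortical GABAergic kernel uses tau = 8 ms rather than the 2 ms
  sometimes quoted for somatic inhibition: a 2 ms kernel is marginally
  stable under forward Euler at 1/256 s (dt/tau ≈ 2), so the slowest
  resolvable "fast" kinetics were used, with the kernel's DC gain (A·tau)
  preserved.
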