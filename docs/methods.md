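# Methods

## Model

`betawaves` simulates a two-dimensional lattice of excitatory–inhibitory
(E-I) modules as a rate model with adaptive time scales.  Each module `x`
carries currents `I_E(x,t)`, `I_I(x,t)` obeying

    tau_A(I_A) dI_A/dt = -I_A + I_A_ext + I_AE_syn - I_AI_syn ,   A in {E, I}

with firing rates

    r_A = Phi_A[I_A] + sqrt(Phi_A[I_A]/N_A) * xi_A(t)      (Ito)

where `Phi_A` is the f-I curve of an exponential integrate-and-fire (EIF)
neuron under white-noise input and the `sqrt(Phi/N)` white-noise term is the
finite-size fluctuation of a population of `N_A` neurons.  The stochastic
rate may transiently be negative and is used as-is in the synaptic drive; no
clipping is applied, so the linear fluctuation theory applies exactly.

Synaptic currents follow a rise/decay/latency cascade
(`tau_r`, `tau_d`, `tau_l`; kernel normalized to unit area).  The excitatory
drive on both populations is the delayed lattice convolution

    sum_y C(x-y) r_E(y, t - tau_l_E - D|x-y|)

with a Gaussian connectivity kernel `C(x) ~ exp(-x²/lx² - y²/ly²)`
normalized to sum 1 (truncated at `|x| <= 4 max(lx, ly)` and renormalized;
the dropped weight is below e^-16), and a conduction delay of `D` ms per
grid unit of Euclidean distance.  One grid unit corresponds to 400 um, the
electrode pitch of the 10x10 arrays the analysis side targets.

External drive is an Ornstein–Uhlenbeck process `eta(x,t)` with correlation
time `tau_ext`, mixing a shared ("global") white-noise source with weight
`sqrt(c)` and per-module ("local") sources with weight `sqrt(1-c)`; local
sources may optionally be spread over neighboring modules by a kernel `G`
normalized so that `sum G² = 1`, which preserves the per-module variance.
As written, the stationary variance of `eta` is 1/2; the external current on
population A is `I_A_ext0 + w_A_ext * nu_ext * eta`.  By convention
`w_E_ext = w_EE` and `w_I_ext = 2 w_IE`, so varying the afferent drive moves
the operating point along a line that crosses the oscillatory bifurcation.

Four named parameter presets (`SN`, `SN'`, `ON`, `SN_0`) reproduce the
reference parameter table; `SN` (steady network just below the oscillatory
instability, with fluctuating inputs `nu_ext = 3 Hz`, `tau_ext = 25 ms`,
`c = 0.4`) is the reference configuration throughout.

### Transfer tables

Reference tabulations of `Phi[I]` circulate as separate supplementary data
files and are not bundled here, so the package computes its own default
table: the steady-state
firing rate of a white-noise-driven EIF neuron, obtained by solving the
stationary Fokker–Planck equation with a downward exponential-integrator
sweep (A-stable through the stiff spike-initiation region), then calibrated
by a four-parameter affine map on current and rate so that the two
operating points match the reference values exactly:
`Phi(-6.28 mV) = 5 Hz` with slope `1.46 Hz/mV`, and `Phi(-3.62 mV) = 10 Hz`
with slope `2.30 Hz/mV` (residuals < 1e-12).  Both populations share this
rate table.  The adaptive time constant defaults to the constant
operating-point values (8.74 ms for E, 7.14 ms for I); the linearized
theory only ever uses the operating-point values, so this choice is
invisible to every closed-form result.  User-supplied two-column tables are
accepted everywhere; evaluation uses monotone piecewise-cubic (PCHIP)
interpolation for rates and linear interpolation for time constants, with
clamp-and-warn outside the table domain.

### Geometry and integration

The default lattice is a 24x24 dynamic grid surrounded by a 2-deep frozen
ring (28x28 total) whose rates are clamped at the steady state
(`r_E = 5 Hz`, `r_I = 10 Hz`); offsets reaching beyond the lattice
contribute nothing (those connections simply do not exist).  Measurements
are taken on the central 10x10 window, emulating the recording array.
Periodic boundaries are available as a control and reproduce the same wave
statistics within sampling error.

Integration is first-order Euler–Maruyama with `dt = 0.01 ms`; the OU input
uses an exact exponential update.  A scaled-down mode with `dt = 0.05 ms`
(the coarsest step accepted) is used for the statistical test suite; at
this step the simulated spectra agree with the linear theory within ~10%
(see below), which we accept as the cost of keeping the full statistical
checks inside a routine test run.  State is recorded at 1 kHz (1 ms
frames), matching the analysis frame rate.  The per-simulation RNG is a
single seeded stream; replicate seeds are spawned from a master seed via
`numpy.random.SeedSequence`, and all seeds are recorded in the outputs.
The proxy-LFP is the total excitatory-population input current `I_E`
(recording the synaptic component separately is supported).

### Stimulation

Current steps are injected uniformly into all modules, expressed as an
offset on the shared OU variable (so the current on population A shifts by
`amplitude * w_A_ext * nu_ext`).  Defaults: 50 ms steps every 200 ms.  The
default amplitude used in the stimulation experiments is 0.6, set to the
typical depth of the shared-input dip that precedes planar waves in
unperturbed runs (its per-event spread is ~0.44 around a mean of −0.15)
and inside the distance from the operating point to the oscillatory
boundary along the input line.  Negative steps push the network toward the
oscillatory regime (beta amplitude and synchronized-state occupancy rise,
planar waves become more frequent); positive steps do the opposite.

## Linear theory

Around the fixed point (solved by damped Newton on `(I_E, I_I)` with
analytic Jacobian, tolerance 1e-10 mV, backtracking line search), the loop
gains are `alpha = w_EE Phi_E'`, `beta = w_IE w_EI Phi_E' Phi_I'`,
`gamma = w_II Phi_I'`.  With the synaptic transform
`S~(s) = exp(-s tau_l) / ((1+s tau_r)(1+s tau_d))`, the membrane-filtered
`T~ = S~/(1+tau s)`, and the delayed lattice transform
`C(q,s) = sum_x C(x) exp(-i q.x - s D|x|)`, the characteristic function is

    W(q,s) = [1 - alpha C T~_E][1 + gamma T~_I] + beta C T~_E T~_I .

The oscillatory (Hopf) boundary is obtained parametrically in the
oscillation frequency by solving the two real equations `W(q, i w) = 0`
linearly for `(alpha, beta)`; each returned point is verified by back
substitution (residual < 1e-8, flagged otherwise).  The frequency at a
given `alpha` is found by monotone bracketing on the physical
(`beta > 0`) branch to 1e-3 Hz.  The runaway ("real") instability line is
`beta = [alpha - 1/C(q,0)](1+gamma)`, independent of all kinetics.
Operating points are classified stable / oscillatory / runaway by their
position relative to both lines at `q = 0`, with margins reported as signed
distances in `beta` at fixed `(alpha, gamma)`.

With the reference SN parameters (`gamma = 2`, `D = 1.3 ms`, `l = 2`) the
Hopf line is crossed, when moving from SN toward ON at fixed
`alpha = 1.4016`, at **24.9 Hz** — in the beta band, and consistent with
the harmonic peak near 50 Hz that strongly driven configurations produce.
Frequency decreases along the line as recurrent excitation grows, increases
with `gamma`, and the `D = 0` line is shifted but qualitatively unchanged;
all three trends are covered by tests.

Fluctuation spectra of the proxy-LFP follow from the linearized dynamics
driven by the three independent noise routes (E finite-size, I finite-size,
external OU).  The single-module spectrum is

    S(w) = c S_ext(0,w) + int dq/(2pi)² [ (1-c) S_ext(q,w) + S_N(q,w) ]

integrated over the Brillouin zone with a tensor-trapezoid rule (129²
nodes by default; halving the resolution changes the result by < 1e-10 at
the defaults, and the kernel's lattice transform is evaluated per unique
delay group so the quadrature stays cheap).  Cross-correlations in space
and lag are the inverse Fourier transform of the same densities; the
imaginary residual is reported and is at machine precision.  The theory
assumes a translation-invariant (infinite) lattice; the frozen boundary of
the simulated grid is the main source of the residual simulation-theory
mismatch.  Every closed form is tested against an independent brute-force
route: quadrature of the sampled synaptic kernel, extended-precision
lattice sums, and direct linear solves of the fluctuation system
(agreement 1e-6 relative); the simulated periodogram matches the closed
form within 20% band-averages over 5–80 Hz at small external drive
(`nu_ext = 0.5 Hz`).  At the reference drive `nu_ext = 3 Hz` the response
is visibly nonlinear (broadened peak, harmonic enhancement near twice the
peak frequency), as expected for a network driven across its bifurcation.

## Analysis pipeline

Movies `[nx, ny, nt]` with frame-rate and pitch metadata are the interface;
simulated proxy-LFP and converted recordings are treated identically.
Missing electrodes are filled with the mean of their valid 4-neighbors
before filtering.  Each channel is band-passed 13–30 Hz with a third-order
Butterworth filter applied forward-backward (zero phase; implemented in
second-order sections for numerical robustness), z-scored per trial, and
Hilbert-transformed into amplitude and phase maps.  The first and last
200 ms of every analytic trace are excluded from burst and wave statistics
(Hilbert edge artifacts).

Beta bursts are maximal runs of the amplitude strictly above its own
75th percentile (linear-interpolation quantile, per electrode and trial);
a run still open at the trace end is closed there.  Spectra use Welch
(1 s Hann windows, 50% overlap); spectrograms use a 256 ms window with 90%
overlap.  Spatial correlations are Pearson coefficients of the band-passed
traces, binned by exact pair distance.

Wave classification per 1 ms frame: the phase-gradient map averages
circular phase differences with existing neighbors up to two steps along
each axis (boundary and missing-electrode counts adjusted); gradients are
normalized to unit directionality vectors (zero-gradient electrodes are
excluded — their direction is undefined), whose mean magnitude is
`sigma_g`.  Frames with `sigma_g > 0.5` are planar.  Remaining frames are
radial if the locally averaged directionality field (3x3 neighborhood of
existing electrodes, `N_xy <= 9`) has exactly one critical point — a 2x2
plaquette where the x-component changes sign along x and the y-component
along y, adjacent plaquettes merged (Chebyshev distance 1) and typed
source/sink/saddle by the local Jacobian.  A 5x5 smoothing window is
available but not the default: on a 10x10 array it leaves disordered frames
with a single spurious critical point often enough to inflate the radial
class at the expense of synchronized/random, which is inconsistent with the
small radial proportions in array recordings.  Remaining frames are
synchronized if the Kuramoto order parameter `sigma_p > 0.85`, else random.
Runs of at least 6 identical planar/radial/synchronized frames become
episodes; everything else is a random episode; episodes are annotated with
their flanking episode types.

Wave speed is `v = 2 pi f / <|grad Phi|>` with `f` the spatio-temporal mean
of `dPhi/dt` over the event divided by `2 pi`, converted to cm/s with the
400 um pitch.  The propagation direction is opposite the mean phase
gradient.  Planar-wave averaging aligns events either at wave onset or at
the zero crossing of the array-average phase (mid-event phase divided by
`2 pi f_ref`, `f_ref` the across-event mean frequency), keeps events whose
mean gradient lies within pi/8 of a principal axis, and rotates maps by
quarter turns so all waves propagate identically before averaging.

Transition statistics count planar events by their flanking
synchronized/random episode types; the null draws the following type with
the marginal episode-type proportions, giving a one-sided binomial test
(the exact test used in the reference analysis is unstated; this choice is
calibrated —
under a coin-flip null the p-values are approximately uniform, covered by
a test).  Stimulation comparisons use one-tailed Welch t-tests on per-run
event counts, with identical degenerate samples mapped to p = 0.5.

## Synthetic data

The pattern generator builds phase movies from closed forms — planar
`Phi = 2 pi f t - k.x`, radial `Phi = 2 pi f t - kappa |x - x0|`,
synchronized `Phi = 2 pi f t`, random = the angle of a per-electrode
complex OU process with a 20 ms correlation time (temporally smooth,
marginally uniform, spatially independent) — plus optional i.i.d. phase
and amplitude noise, and reconstructs the LFP as `A cos Phi`.  Ground
truth (labels, closed-form speeds) is returned with the data.  What these
movies share with recordings: grid, pitch, frame rate, band-limited
oscillation, pattern types, optional missing electrodes.  What they do
not: continuous pattern transitions, amplitude-phase coupling, 1/f
background, and spatially correlated disorder — so classifier tests on
them certify the classification rules, not performance on arbitrary real
data.  The burst generator inserts rectangular supra-threshold envelopes
into a smoothed-noise baseline at known times; the surrogate generator
synthesizes stationary Gaussian traces with a prescribed one-sided PSD by
spectral factorization.

A second caution: the smoothed-gradient sigma_g carries a chance-level
floor of a few percent of frames (and occasional >= 6 ms runs) on
spatially uncorrelated data, because a locally averaged noise field on a
10x10 grid sometimes aligns by chance.  Controls that remove spatial
structure (channel shuffling, point-like connectivity) therefore collapse
planar waves to this floor rather than to exactly zero.

One caution established during development: on stationary surrogates of
the linear spectrum, mean burst duration does *not* grow with the input
correlation time (short-tau_ext inputs leave the in-band spectrum
resonance-dominated and hence the envelope correlation long); the growth
of burst duration with tau_ext is a nonlinear-excursion effect and is
accordingly tested on full simulations, where it reproduces cleanly.

## Problem sizes used by the test suite

Statistical checks run scaled down, as the package's standard test
configuration: `dt = 0.05 ms`; reference wave statistics from 3
replicates of 8.5 s (analyzed) on the full 24x24 grid; stimulation
contrasts from one 8.5 s run per condition; spectrum agreement from one
12 s run on a 16x16 grid (central 4x4 window); finite-size scaling from
4 s runs at three population sizes spanning a factor 100; boundary-condition
robustness from a 5.5 s periodic-boundary run.  The acceptance script integrates
the deterministic steady-state check at the reference `dt = 0.01 ms` on a
14x14 dynamic grid (18x18 with the frozen ring), which fully contains the
connectivity kernel of the central module.

## Known limitations

- The adaptive time constant defaults to a constant per population; the
  current-dependence of `tau(I)` matters only far from the operating point.
- The linear spectra assume translation invariance and point-like local
  inputs; input-kernel spread enters simulations but not the closed forms.
- Classification thresholds (`sigma_g > 0.5`, `sigma_p > 0.85`, 6 ms
  minimum episode) are the reference constants; they are exposed as
  parameters but not recalibrated here.
- At the reference drive the network is strongly nonlinear; linear-response
  results are exact only in the small-`nu_ext` limit.
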