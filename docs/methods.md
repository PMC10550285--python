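# Methods

## Model overview

`thetanet` simulates a two-layer spiking network of hippocampal place
cells in an 80 x 80 cm open arena.  The CA3 layer contains 80 x 80 = 6400
excitatory cells whose field centres tile the arena at 1-cm spacing; a
dentate-gyrus (DG) layer of 40 x 40 = 1600 cells mirrors it at 2-cm
spacing.  Each layer has a pool of 250 inhibitory interneurons.  Two
mechanisms generate theta-timescale sequences:

* **Extrinsic sequences.**  CA3 cells are recurrently coupled with
  symmetric Gaussian weights (width sigma = 2 cm) modulated by the
  similarity of preferred heading directions.  Short-term depression
  (STD) of the recurrent synapses penalises input from cells whose fields
  the animal has already crossed, so within each theta cycle activity
  propagates in the direction of movement.
* **Intrinsic sequences.**  CA3 cells on a 40-cm path through the loop
  anchor excite DG cells (gain `C_j`, the Gaussian proximity of the
  presynaptic CA3 field to the path), and DG cells project back to CA3
  cells displaced 4 cm along the loop direction theta_DG.  The resulting
  feedback wave propagates along theta_DG regardless of the running
  direction.

Spikes are generated by the Izhikevich model (excitatory preset
a = 0.035, b = 0.2, c = -60 mV, d = 8, bursting; inhibitory preset
0.02/0.25/-65/2, fast spiking; threshold 30 mV).  Each place cell
receives, besides synaptic input, a box-shaped sensory drive (non-zero
within 5 cm of its field centre) whose amplitude combines positional
(`A_pos`) and directional (`A_dir exp(cos(heading - psi_i) - 1)`)
tuning, multiplied by an entorhinal theta modulation peaking 70 degrees
after the theta peak, and a subtractive theta drive
`7 [1 + cos(2 pi t / 100 ms)] / 2`.  Sensory input passes through
short-term facilitation (STF): the resource `s_F` relaxes to `S0F` with
tau_F = 500 ms and grows towards `S1F` under drive; the effective current
is the raw drive times `s_F^2`.

## Synaptic model and numerics

Synapses are conductance-based (tau_E = 12 ms, tau_I = 10 ms, reversal
potentials 0 / -80 mV) with a 2-ms transmission delay implemented as an
exact 20-step ring buffer at the default dt = 0.1 ms.  Design choices a
maintainer should know:

* **Charge-normalised kernels.**  A delivered spike increments the
  conductance by `W / (N_pre * tau_syn) * efficacy`, so the charge
  injected per spike is `W / N_pre` independent of the synaptic time
  constant.  `N_pre` is the presynaptic population size of each block.
  The overall efficacy constant (default 2.0 for both excitation and
  inhibition) sets the network's operating point in the *sequential*
  regime: weak enough that activity propagates as a wave with a
  resolvable within-cycle temporal gradient (a theta sequence), strong
  enough that the DG feedback engages.  With per-spike currents a few
  times larger the recurrent halo ignites essentially instantaneously
  and all temporal structure inside the theta cycle collapses; much
  weaker and the network falls silent.
* **Semi-implicit conductance integration.**  The synaptic driving-force
  terms `g (V_rev - v)` are linear in `v` and are integrated implicitly
  (`v_{n+1}` solves the linearised update), while the Izhikevich
  quadratic stays explicit.  Forward Euler on the conductance terms is
  unstable once `dt (g_E + g_I) > 2`; inhibitory volleys in this model
  reach exactly that range, and with a fully explicit update the
  resulting numerical oscillation masquerades as runaway network
  activity.  The semi-implicit form is unconditionally stable in the
  conductances and agrees with the explicit update to O(dt^2) when
  conductances are small.
* **STD accounting.**  A spike is transmitted with the depression
  resource available at its emission (before its own depletion), the
  standard release-resource convention; depletion is multiplicative
  (`s_D <- s_D (1 - U_D)`, keeping `s_D` in [0, 1] without clamping; a
  subtractive variant is available as `std_mode="subtractive"`).
  Depression applies to CA3 -> CA3 and CA3 -> DG synapses.  It does
  *not* apply to CA3 -> interneuron synapses: depressing the drive of
  the inhibitory pool removes the network's only fast stabiliser exactly
  when activity is highest, and the network then has a persistent
  high-rate attractor.  This is exposed as `std_to_inhibitory`.
* **Theta routing.**  The subtractive theta drive reaches the place
  cells of CA3.  Interneurons are excluded because the fast-spiking
  parameter set rebound-fires after each theta hyperpolarisation, which
  would make the inhibitory pool a theta pacemaker even in an otherwise
  silent network (with the default routing, a network with no sensory
  and no recurrent input emits no spikes at all).  DG cells are likewise
  driven only synaptically.  Both switches (`theta_to_inhibitory`,
  `theta_to_dg`) are exposed in the configuration.
* **Sensory phase.**  The entorhinal modulation peaks 70 degrees *after*
  the theta peak, i.e. shifted towards the excitable theta trough.  With
  the opposite sign the population spike-phase distribution lands in the
  wrong half of the cycle.

## Parameter presets

Named presets encode the simulation variants: `intrinsic_asymmetry`
(fixed rightward asymmetric weights J_ij, no STD/STF), `extrinsic_std`
(symmetric weights, U_D = 0.9, no facilitation, no directional tuning),
`directional_input` (directional tuning + STF), `dg_loop` (full CA3-DG
model, B_DG = 3000), `dg_lesion` (DG silenced, facilitation replaced by
a constant elevated release level S0F = S1F = 1.25 and raised sensory
amplitudes), `dg_loop_2d` (stronger loop for oblique orientations),
`no_recurrence*` (CA3 recurrence removed, compensated by stronger
spatial input and loop), and `tempotron_readout` (loop gated onto a path
at y = +20 cm).  The parameter table these presets derive from reached
us with merged cells collapsed, so a few cells admit more than one
column alignment; the encoded reading is the one consistent with the
surrounding text, and every scalar can be overridden per run, so any
alternative reading is reproducible from configuration alone.

## Analysis stack

* **Spike phase**: `2 pi (t mod 100 ms) / 100 ms`, zero at the theta
  drive maxima.
* **Phase precession**: for each cell with more than 5 spikes on a
  traversal, animal positions at spike times are projected on the
  running direction and normalised to [0, 1] between the first and last
  spike.  The slope maximises the mean resultant length of
  `phi - a x` over a slope grid (|a| <= 4 pi per traversal, about 1000
  grid points, golden-section refinement); the onset is the circular
  intercept and the reported correlation maps the linear variable to the
  circle at the fitted frequency (circular-circular correlation, signed
  by the slope).
* **Cross-correlograms**: 5-ms bins spanning [-100, 100) ms.  Pair
  pipelines histogram `t_first - t_next`, the lag of the
  first-encountered cell relative to the next cell along the trajectory;
  the fixed-asymmetry and directional-input demonstrations instead use a
  fixed spatial axis ordering, as their comparisons require.
* **Correlation lag**: the correlogram is zero-padded to three times its
  length, band-passed 4-12 Hz (second-order zero-phase Butterworth at
  the 200-Hz bin rate), Hilbert-transformed, and the analytic phase is
  interpolated at lag zero.  Under the lag convention above, a positive
  phase means the first-encountered cell fires earlier in the cycle.
* **Extrinsicity / intrinsicity**: `(r + 1) / 2` of the Pearson
  correlation between a pair's correlograms from opposite running
  directions (Ex), or between one correlogram and the flipped other
  (In); a pair is extrinsic iff Ex > In.  Population pipelines use
  active cells (> 5 spikes) and field-centre distances below 10 cm
  (two 5-cm field radii); averaged correlograms use pairs whose
  projected centre separation is 4 +/- 0.5 cm, each histogram normalised
  to unit mass before averaging.
* **Theta compression**: circular-linear regression (same estimator,
  |a| <= 0.5 rad/cm) of correlation-lag phase against Euclidean
  field-centre distance over all overlapping active pairs.
* **Gradient maps**: per field centre, the sum over the 8 lattice
  neighbours of the unit vector towards the neighbour weighted by the
  difference of mean spike times within one 100-ms cycle (arithmetic
  mean; the window is a single cycle).

## Tempotron readout

The readout neuron sums double-exponential PSPs (tau = 5 ms,
tau_r = 1.25 ms, kernel peak normalised to 1, so V_0 ~ 2.116) and fires
at the first upward crossing of V_theta = 2, after which afferent
arrivals are shunted for the rest of the 100-ms pattern.  Training uses
(+) patterns only: a pattern that fails to fire credits each afferent by
`0.01 * sum_{t_f < t_max} K(t_max - t_f)` with `t_max` the voltage
maximum of the un-shunted trace (earliest tie at the 0.1-ms resolution);
weights are therefore non-decreasing.  Initial weights are zero; the
first presentation of a pattern against a flat (all-zero) trace has no
defined voltage maximum, so it credits every afferent spike at the
kernel peak to bootstrap learning.  Presentation order is shuffled per
epoch under the run seed (budget 100 epochs, early stop when every
pattern fires).  Patterns are the spike
times of the 400 cells in a 20-cm box around the trained location within
one theta cycle; training uses a 1-s standing stimulus split into 10
cycles, each jittered 100 times with N(0, (2 ms)^2) noise (jittered
spikes may leave the cycle window but stay assigned to their pattern).
Detection on a test trajectory counts a jitter realisation as positive
if any of its 10 cycles elicits a readout spike.

## Synthetic fixtures

`thetanet.synthetic` produces toy data with known ground truth: spike
trains with exact phase-position slopes, Poisson trains, theta-locked
pairs with a fixed lag, and lattice records with constructed spike-time
fields.  These exercise every analysis routine independently of the
simulator.  They emulate idealised, noise-free structure; passing those
tests validates the estimators, not the network model.

## Problem sizes and determinism

The bundled test suite runs the headline simulations at the full
6400-cell scale for the compression and precession measurements (2-s
runs) and at half density per axis (1600 CA3 / 400 DG cells, same arena
and length scales) for the multi-trajectory readout protocol; the
per-presynaptic-population charge normalisation makes the mean drive
approximately density-invariant, which is also what `NetworkConfig.scaled`
relies on.  All randomness (preferred directions, inhibitory weights,
jitter, shuffling) derives from explicit seeds; a simulation is bitwise
reproducible given (config, trajectory).

## Known limitations

* The efficacy constant is a genuine degree of freedom of the published
  description; the encoded value reproduces the theta-compression
  slopes and the loop-direction sign flip, but the purely extrinsic
  variant precesses more shallowly (population median about -0.2 rad
  per field size) and the lesion variant compresses more strongly
  (about +0.4 rad/cm) than the printed reference values.  Both
  discrepancies trace to the same mechanism: without facilitation the
  model's within-cycle wave is faster than the reference description
  implies.
* Trajectories are straight constant-speed segments (or standing
  stimuli); curved foraging paths are out of scope.
* DG participation is sparse (hundreds of spikes per 2-s run): the loop
  acts through strong, temporally precise feedback ticks rather than a
  dense secondary place code.  Population statistics that condition on
  *strongly* intrinsic pairs therefore rest on few pairs per run; the
  centre-difference orientation of intrinsic pairs recovers a
  perpendicular loop (90 degrees) but not an oblique one (45 degrees),
  where loop-driven off-track cells fire too few spikes to pass the
  active-cell filter.
* The (+)-pattern-only tempotron becomes permissive once trained to
  full detection: the with-loop readout generalises across all approach
  directions as intended (mean accuracy 1.0), but the loop-free control
  readout also detects most directions (accuracy dips only for headings
  opposing the trained evocation), because any crossing of the trained
  box reactivates the trained afferents densely enough to cross
  threshold regardless of spike order.
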