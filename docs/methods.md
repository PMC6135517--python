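# Methods

This note documents the models, statistics, and design choices behind
`hystnet`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the genuinely open decisions were made.

## 1. The hysteresis statistic for EEG networks

### Functional connectivity

Connectivity between channels *i*, *j* is the phase lag index

> PLI_ij = | ⟨ sign( Δθ_ij(t) ) ⟩_t |,  0 ≤ PLI ≤ 1,

with Δθ_ij the instantaneous phase difference from a Hilbert transform of
the band-filtered signal.  Two conventions are deliberate:

* Δθ is wrapped to (−π, π] before taking its sign.  On unwrapped
  differences, which drift past ±π for any pair of channels with slightly
  different center frequencies, the sign is meaningless.
* sign(0) contributes 0 to the mean; exact zeros are kept, not perturbed.
  This makes PLI insensitive to zero-lag, volume-conduction-like coupling.

Band filtering uses a Hamming-windowed sinc FIR kernel applied in a single
pass with group-delay compensation, i.e. exactly zero phase shift — a
requirement for any phase-difference statistic.  Kernel length is three
cycles of the low band edge (minimum 101 taps, rounded to odd).  The
forward–backward (squared-response) alternative is available behind
`two_pass=True`.  Half a kernel length of samples (capped at 1/8 of the
window) is discarded at window edges before phase extraction, since both
FIR and Hilbert transients corrupt phases there.  Band edges below
max(0.1 Hz, 2/epoch_length) are clamped with a warning: a 2-minute epoch
cannot resolve slower rhythms and the kernel length diverges as lo → 0.

### Surrogate thresholding

Spurious PLI is estimated from 20 segment-swap surrogates per window: per
channel an independent uniform split point is drawn and the two segments
are exchanged — a circular shift that preserves each channel's amplitude
distribution and power spectrum exactly.  Because the FFT-based Hilbert
transform commutes with circular shifts, the pipeline shifts the already
computed phase arrays instead of re-transforming every surrogate; the two
routes are bit-equivalent (tested).  An edge exists where
PLI − median(surrogate PLI) > 0.1.  The threshold is set by the rule of
avoiding isolated nodes in baseline networks; `isolated_node_profile`
exposes the isolated-node count as a function of threshold so the choice
can be audited on any dataset.  Raising the threshold can only remove
edges (tested monotonicity).

### Trajectory and hysteresis area

Per 10-s window the binary network yields a node-degree vector.  A state
(baseline, induction, unconscious, emergence; 120-s epochs) is summarised
by the median over windows of

* topographic similarity — Pearson correlation between the window's degree
  vector and the baseline *mean* degree vector (mean, not median,
  following the bar notation of the defining formula), and
* average node degree.

The four state points, in fixed order baseline → induction → unconscious →
emergence and closed back to baseline, form a quadrilateral whose absolute
shoelace area is the hysteresis size.  The point order is fixed; a
self-intersecting (bow-tie) configuration under-reports the visual area,
so `polygon_self_intersects` flags it.  Windows whose degree vector has
zero variance (empty or complete graphs, possible at extreme thresholds or
very few channels) have no defined topography correlation and are dropped
from the similarity median only.

The frequency sweep uses 2-Hz bins with odd-integer edges
{0.1–1, 1–3, …, 29–31} Hz so that 9–11 Hz is a single bin; the ragged
first bin is labelled as such.

Significance of an observed area is assessed against a permutation null
that reassigns windows to states at random (group sizes preserved) and
recomputes the entire statistic, including the baseline reference, per
permutation.

### Power control analysis

The same reduction run on per-channel band power (3-s Hamming segments,
50% overlap, median over segments of the band-mean power density) instead
of node degree.  Path dependence present in connectivity but absent in
power indicates a network-interaction effect rather than a local-amplitude
effect.  The per-channel peak-frequency spread (variance across channels
of the frequency maximising the median power density within the analysis
band) estimates the frequency-heterogeneity control parameter Δω from
data; it is reported as variance with the SD alongside, since the model
parameter is an SD.  Flat spectra break peak ties to the lowest frequency
with a warning.

### Group statistics

Areas across frequency bins are compared with one-way ANOVA plus
Tukey–Kramer pairwise correction at family α = 0.05 (statsmodels
`pairwise_tukeyhsd`).  A simulation test verifies the type-I error of the
F-test is calibrated near 0.05 under the null.

## 2. The brain network model

78 oscillators on a structural connectome follow a Stuart–Landau-type
system with distance-proportional conduction delays (propagation speed
8.6 m/s; 8.6 mm ↔ 1 ms):

    dr_j/dt = (λ_j − r_j²) r_j + S Σ_k A_jk r_k cos(θ_k(t−τ_jk) − θ_j)
    dθ_j/dt = ω_j + ξ_j + R_j^Z S Σ_k A_jk (r_k/r_j) sin(θ_k(t−τ_jk) − θ_j)

with node synchrony R_j = |(e^{iθ_j} + N⁻¹Σ_k e^{iθ_k})/2| and global
order parameter R = |N⁻¹Σ e^{iθ}|.  Natural frequencies are Gaussian
(center 10 Hz, SD Δω, default 1 Hz, in rad/s internally).  λ_j = 1 for
all nodes.  The feedback R_j^Z (default Z = 4) suppresses gradual cluster
growth: an oscillator can join a synchronized cluster on the
desynchronizing path only below Ω_dec ≈ S R̃² k_j but on the synchronizing
path below Ω_inc ≈ S R̃ k_j; since Ω_dec ≤ Ω_inc with the gap widening as
R̃ → 0, the forward and reverse transitions separate — the hysteresis
mechanism.  `effective_coupling` exposes the identity S_eff = S·R^Z, whose
exponent corresponds to the Hill slope of an anesthetic dose–response
curve.

### Numerics

* Fixed-step Euler–Maruyama, dt = 0.5 ms by default (delays down to ~1 ms,
  10 Hz dynamics); a convergence test verifies that halving dt changes the
  time-averaged R by < 1% at the default operating points.  `simulate`
  refuses a dt exceeding the smallest positive delay.
* Delay history is a ring buffer of depth max(delay steps + 1, 2); the
  minimum of 2 keeps the update synchronous (a depth-1 buffer would make
  nodes see already-updated neighbors within a step).  Cosines/sines of
  the phase history are cached, so delayed coupling needs no trig in the
  inner loop.
* The buffer is pre-filled by backward extrapolation along each node's
  natural frequency, θ(−s) = θ(0) − ωs, r(−s) = r(0), avoiding a startup
  discontinuity; the first max-delay seconds are transient regardless.
* r is floored at 10⁻⁶: the amplitude equation's fixed point keeps r > 0,
  but the r_k/r_j quotient needs the same protection the original
  formulation needs against feedback in the amplitude equation.
* Phases are kept unwrapped in float64; over the longest runs used
  (≤ 10 min simulated) the accumulated phase stays ≪ 2π/ε precision.

### Noise

Describing the noise as a Gaussian frequency perturbation with mean and
SD of 2 Hz leaves its time scaling ambiguous, and the choice is
consequential.  Interpreted as continuous-time
white noise (`noise_scaling="sqrt_dt"`, increment 2π·σ·√dt·N(0,1)), an SD
of 2 Hz implies a phase diffusion of (2π·2)²/2 ≈ 79 rad²/s, which
dominates a 1-Hz natural-frequency spread, suppresses the discontinuous
transition entirely, and pushes the R = 0.5 crossing to S ≈ 30 — far from
the critical couplings of order 2 this model family is known for.
Interpreted as an independent per-step frequency jitter
(`noise_scaling="per_step"`, increment 2π·σ·dt·N(0,1), the literal
discretization θ += dt·(ω + 2πξ) with ξ ~ N(2,2) Hz), the effective
diffusion (2πσ)²·dt/2 vanishes with the step and the explosive transition
survives at S ≈ 2.  The per-step reading is the default; both are
implemented.  The noise mean enters as a uniform frequency offset in
either mode, which cannot affect phase differences and is therefore
dynamically neutral.

### Feedback timescale

R_j in the phase equation can be evaluated instantaneously every step
(`feedback_tau = 0`, the default, matching the equations as written) or
as a low-pass filtered (exponential moving average) node synchrony with
time constant `feedback_tau`.  The choice is consequential, and the two
settings trade off two families of phenomena:

* With instantaneous R_j, finite-size fluctuations of the node synchrony
  transiently raise R_j^Z and nucleate synchronized clusters on the way
  up.  The bistable band at the Z = 4, Δω = 1 operating point is then
  shallow and metastable: per-sweep leg gaps of ~0.1–0.2 in R at 4-s
  dwell per coupling step, smeared further by configuration-to-configuration
  transition jitter when ensemble-averaged.  The power-space loop is then
  negligible next to the connectivity-space loop (area ratios 0.0–0.1
  across seeds).  The matched-strength similarity ordering of the two
  legs, however, is not resolvable: with a narrow band the legs traverse
  statistically equivalent states, and the measured gap (~±0.05) flips
  sign from seed to seed.
* Filtering R_j over a few carrier cycles (e.g. `feedback_tau = 0.5` s)
  suppresses fluctuation-seeded nucleation and the band becomes wide and
  robust (s_dec ≈ 2.2 < s_inc ≈ 3.5–4.3 on the default synthetic
  connectome, leg gaps ~0.5).  But the same memory changes *which* nodes
  seed clusters on the synchronizing path, and the trajectory-space
  geometry degrades: the similarity ordering of the legs inverts and the
  power loop grows to a substantial fraction of the connectivity loop
  (the bistable amplitudes r² ≈ 1 + S·k·⟨cos⟩ differ between branches).

No single feedback timescale was found that yields both the deep bistable
band and a clockwise matched-strength similarity ordering on the
synthetic connectome (nor did degree-heterogeneous, hub-weighted variants
of the connectome change this); instantaneous feedback is the default as
the literal reading of the model, and the filtered mode is a documented,
tested extension for studying strongly hysteretic regimes.

## 3. Coupling sweeps

Quasi-static sweeps step S up 0 → 50 and back down on a shared grid
(default 60 points, logarithmically dense at the low end where the
transition lives), carrying the oscillator state across steps within a
leg and re-randomizing it only at each leg's start.  Per step the system
relaxes for `t_transient` seconds (discarded) and R is averaged over
`t_measure` seconds.  Continuation is essential: re-randomizing at every
step (the `continuation=False` control) destroys the bistable band.  The
critical couplings are the first linearly interpolated crossings of
R = 0.5 along each leg's direction of traversal (robust to any threshold
in 0.1–0.9 for a sharp transition; tested), reported as `s_inc` (up leg)
and `s_dec` (down leg).  Hysteresis size is reported both as
`s_inc − s_dec` and as ∫|R_up − R_down| dS; the area is the headline
number since it does not require both crossings to exist.  Note the two
conventions for naming the legs: here the up leg (increasing S,
resynchronization) defines `s_inc` and the down leg `s_dec`; with
feedback on, `s_dec ≤ s_inc` whenever both exist.

`scan_feedback` and `scan_domega` repeat sweeps over configurations with
fresh natural-frequency draws and initial phases (configuration index
seeds substreams), reporting means and dispersions; the full-scale default
of 200 configurations is configurable down for desk-scale runs.

`model_trajectory` projects a recorded sweep into the EEG analysis plane:
each S step's measurement window of node signals x_j = r_j cos θ_j is
treated as an EEG window (Hilbert phases, PLI, surrogate correction,
binary network, degrees; per-node mean squared signal for power), the
topographic reference being the maximally coupled windows at the top of
the grid.  Because degree and power live on different scales, the strength
axis is normalized by its maximum over the run before the closed
up-then-down path's shoelace area is computed, making the
connectivity-space and power-space areas directly comparable.

## 4. Synthetic data

The generator provides everything the pipeline consumes, with ground
truth serialized as JSON sufficient to regenerate any dataset bit-exactly.

**Connectome.**  Nodes are placed uniformly (minimum separation 6 mm — it
also keeps every positive delay above dt) in an ellipsoid with axes
140 × 109 × 90 mm, brain-like proportions.  Edges are drawn independently
with probability ∝ exp(−d/30 mm), the prefactor calibrated by bisection to
a target mean degree of 10 (within ±10%, else regenerate), and the graph
must be connected.  The distance-decay rule reproduces the strong
short-range bias of DTI-derived cortical networks; it does not reproduce
their rich-club organisation, modular structure, or heavy-tailed hub
degrees, and the degree distribution is near-binomial.

**Four-state EEG.**  The oscillator network itself generates the carriers:
it is integrated through baseline → induction → unconscious → emergence
with continuation across states at the state coupling schedule (defaults
in `DEFAULT_S_STATE`), at Z = 4, Δω = 1 Hz.  Node signals r_j cos θ_j are
RMS-normalized per state and channel, so the amplitude schedule (default:
constant 1) is the *sole* control of band power — connectivity hysteresis
and power changes are independently injectable, which is precisely the
dissociation the power control analysis must detect.  Signals are scaled
to 40 µV RMS, optionally blurred across graph neighbors (zero-lag mixing,
to which PLI should be insensitive), and summed with a 1/f amplitude
noise floor at 0.4 relative RMS.  Channels map to the first
`n_channels` ≤ N nodes.  What the generator does not emulate: volume
conduction through a realistic forward model, artifacts, non-stationary
drug pharmacokinetics, or spatially correlated noise — so passing
end-to-end tests demonstrates statistical correctness of the pipeline,
not field-readiness for any specific recording system.

The injected hysteresis is the gap |S_induction − S_emergence| in the
coupling schedule; a zero-gap schedule with all four couplings equal is
the negative control, whose trajectory area should be indistinguishable
from the permutation null.

The area–gap response is graded only within the synchronization
transition zone.  Once both mid-state couplings saturate into their
attractors, the induction point collapses onto baseline and the
emergence point onto unconscious, the four-state quadrilateral
degenerates toward two point-pairs, and the area *falls* again — the
recovery-surface monotonicity test therefore spans gaps inside the
graded zone (and the saturation itself is a documented feature, not a
defect).

## 5. Problem sizes in the shipped tests

The full-scale study conditions (200 configurations, 2-minute sweeps) are
the library defaults.  The test suite and the acceptance script exercise
the same code at reduced scale — fewer configurations per scan point,
coarser coupling grids restricted to the range containing the
transitions, and shorter dwell times per step — chosen as the smallest
sizes at which the Monte-Carlo dispersion of the quantities under test is
comfortably below the effect sizes being asserted.  The exact sizes are
parameters at the top of the relevant test functions and of
`scripts/acceptance.py`.

## 6. Known limitations

* The binary-network statistics inherit the fixed 0.1 threshold; datasets
  with very different SNR may need the isolated-node diagnostic to re-base
  it.
* The shoelace area of a bow-tie quadrilateral under-reports the visual
  area (flagged, not corrected).
* Euler–Maruyama at fixed step is first-order; dt-halving convergence is
  verified at the default operating points only.
* The synthetic connectome is a geometric stand-in, not a DTI atlas; the
  model's printed critical couplings on a real atlas will differ from
  those on the synthetic graph.
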