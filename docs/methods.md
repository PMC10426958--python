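# Methods

## Model

Each brain region is a Jansen-Rit neural mass: three interacting
populations (pyramidal cells, excitatory and inhibitory interneurons)
whose postsynaptic potentials `y0, y1, y2` (mV) and their derivatives
`y3, y4, y5` (mV/ms) obey six first-order ODEs. Voltage converts to firing
rate through the sigmoid `S[v] = 2 v_max / (1 + exp(r (v0 − v)))`. The
default parameters are the standard alpha-regime set: A = 3.25 mV,
B = 22 mV, a = 0.1 ms⁻¹, b = 0.05 ms⁻¹, C1 = 135, C2 = 108, C3 = C4 =
33.75, v_max = 0.0025 ms⁻¹, r = 0.56 mV⁻¹, v0 = 6 mV. Time is in ms
throughout.

The extrinsic input to region *i* is `p_i + η_i(t) + g Σ_j w_ji S[v_j(t −
d_ji)]`, with `v = y1 − y2` the pyramidal membrane potential (also the
recorded output), `w` the streamline-count matrix normalized by its
maximum (so a given `g` is comparable across subjects), and delays
`d = length / speed` with conduction speed 15 mm/ms, rounded to
integration steps. Cortical defaults are `p = 0.09 ms⁻¹`,
`η = 2.2×10⁻⁸ ms⁻¹`; the driver (thalamic) regions receive elevated noise
`η_th = 0.022 ms⁻¹` in the high-noise condition, representing arousal-
system and sensory-relay afferences.

### Node regimes

As constant input grows, an isolated node passes from a damped fixed point
through a fold of limit cycles into a slow (~2.5–3.5 Hz), high-amplitude
(~10 mV peak-to-peak) oscillation, and then into the ~10.5 Hz alpha limit
cycle. With the 0.01-wide drive grid used in the tests the isolated-node
onsets land at p = 0.12 (slow cycle; the fold sits near p ≈ 0.1136, just
above the 0.11 grid point) and p = 0.14 (alpha). Embedded in a coupled
network, inter-regional input adds to the effective drive and shifts both
onsets one to two grid steps down (to 0.11 / 0.12 at g = 6 on the default
synthetic connectome) — when comparing onset values, the coupling context
matters at exactly this granularity. In a network, `g` itself acts as a
bifurcation parameter; records are split into a *prebifurcation* (damped)
and *postbifurcation* (self-oscillating) regime either at a fixed
threshold (default g = 7, the convention for the empirical-scale
connectomes this workflow mirrors) or automatically, at the first coupling
whose repetition-averaged cortical peak-to-peak amplitude exceeds an
oscillation tolerance (default 2 mV — an order of magnitude above
noise-driven damped fluctuations, well below any limit cycle). `auto` is
the principled choice for synthetic connectomes, whose absolute coupling
scale differs from tractography data.

## Integration

Stochastic Heun (predictor–corrector) at dt = 0.1 ms, mirroring common
whole-brain-simulator defaults. The per-step input — drive, one Gaussian
noise draw per node scaled by η, and the delayed coupling term read from a
ring buffer of sigmoid-transformed outputs — is computed once per step and
held fixed across both Heun stages. The noise is interpreted as
piecewise-constant over the step with std η (no √dt scaling); absolute η
values are therefore tied to dt = 0.1 ms, which is fixed. Initial state is
zero with the delay history pre-filled with S[0]; the initialization
transient (4 s for 60-s runs, 2 s for 10-s runs) is discarded before any
metric. Output is decimated from the 10 kHz integration rate to 1000 Hz by
polyphase FIR low-pass (linear-trend padding, which avoids boundary ripple
on signals sitting at a nonzero fixed point). Halving dt moves the
noise-free limit-cycle spectral peak by < 2% (tested). Simulations are
bit-reproducible given the configuration and seed; the kernel is
numba-compiled and draws its noise from a seeded generator inside the
loop, so no large noise arrays are materialized.

## Fixed points

Equilibria of an uncoupled node reduce to a scalar equation in
`v = y1 − y2`: sign changes of the self-consistency mismatch are bracketed
on a dense grid over v ∈ [−80, 120] mV and polished with Brent's method
(residual ≤ 1e-12), which is more robust in the bistable range than damped
multi-start iteration; stability comes from the eigenvalues of the 6-D
Jacobian. The node is bistable over part of the drive range (a
high-voltage stable branch coexists with the resting branch);
`fixed_point` returns the lowest-output stable root, which is the
attractor reached from the zero initial state in the damped regime — the
simulator-independent oracle the convergence tests use (‖state − root‖ <
1e-6 after the transient).

## Metrics

* **Band-pass:** 4th-order Butterworth, applied forward–backward
  (zero-phase), alpha band 8–12 Hz.
* **Phase:** analytic-signal (Hilbert) angle; 1 s at each end flagged as
  edge region and excluded from phase statistics (capped at a quarter of
  the record for short signals).
* **PLV:** `|⟨exp(i(φ_i − φ_j))⟩_t|`, symmetric, unit diagonal, invariant
  to common phase offsets.
* **FC fit (r_PLV):** Pearson r between strictly-upper-triangle entries of
  simulated and reference PLV matrices, both restricted to cortical
  regions. A constant FC vector (functional disconnection at low coupling
  and low noise) is reported as undefined rather than an error.
* **dFC:** PLV per 4-s window at 50% overlap; the dFC matrix holds Pearson
  correlations between the windowed upper-triangle patterns; its window
  count obeys `floor((T − w)/(w(1−overlap))) + 1`.
* **KSD:** two-sample Kolmogorov–Smirnov statistic between the
  off-diagonal upper-triangle dFC correlation values of two records (the
  always-1 diagonal is uninformative and excluded).
* **Spectra:** Welch PSD (4-s segments); the reported peak is the argmax
  of the node-averaged spectrum.
* **SNR:** mean post-transient half peak-to-peak amplitude of the driver
  nodes divided by η. "Amplitude" conventions differ across the
  literature (RMS, envelope); values here are internally consistent but
  may differ from other reports by a constant factor.
* **Relative power:** mean total PSD area over cortical nodes / over
  driver nodes.

## Synthetic data

`generate_connectome` draws uniform 3-D positions in a 150-mm box, wires
region pairs with probability 0.75 (drivers: ×1.03), gives edges
log-normal weights damped by `exp(−distance/60 mm)`, joins any stray
components through their closest pair, and then rescales driver
rows/columns by a single factor (solved by fixed-point iteration) so the
driver-group mean strength is 0.48 × the global mean — the hub profile of
the thalamus in tractography-based network analyses (normalized strength
0.111 vs 0.231 globally, near-average degree 0.851 vs 0.827). Lengths are
Euclidean distances, giving multi-millisecond delays at 15 mm/ms. Defaults
produce 26 regions (20 cortical, 6 driver nuclei); cohorts derive
per-subject seeds from a master seed via `SeedSequence`.

What the generator deliberately does *not* emulate: cortical geometry and
folding, atlas-faithful parcellation sizes, distance-dependent weight
noise beyond the exponential decay, and the log-tailed degree
heterogeneity of real connectomes. Passing tests therefore demonstrate
the *mechanism* — driver noise activating a damped cortex reshapes FC
toward the connectome-implied pattern — not a quantitative fit to any
empirical dataset.

`generate_pseudo_empirical` simulates a hidden reference run (default:
high driver noise, coupling g*), computes cortical alpha PLV and dFC, adds
Gaussian measurement noise (default sd 0.02) to the FC off-diagonals,
clips to [0,1] and symmetrizes, and stores the generating truth for
recovery tests.

## Experiments and their scales

`g_sweep` runs the full subject × condition × coupling × repetition
factorial; every record's seed derives deterministically from
(master seed, subject, condition, grid index, repetition), so any cell is
reproducible in isolation. Divergent simulations are flagged, not fatal.
The test suite uses desk scales chosen as the smallest sizes at which each
effect is stable: a 5-subject cohort, couplings 0–6, 10-s simulations with
2-s transients for the noise-condition factorial; 60-s simulations with
4-s transients and 3 repetitions for coupling recovery (see below); the
full-scale protocol (g up to 60, 60-s runs, 10 subjects) is available
through the same interfaces.

### Which metric identifies the coupling

In the driver-noise prebifurcation regime the static FC fit r_PLV(g) is
flat (≈0.92–0.99 on the default synthetic cohort) across the whole damped
range: damped cortical nodes inherit the same connectome-shaped
phase-locking pattern at any coupling strength, so static FC cannot
localize g — the same plateau that makes the working-point *regime*, not
its exact coupling, the scientifically meaningful object. The temporal
variability of windowed FC does depend on coupling, so the dFC/KSD working
point (argmin KSD) is the identifying criterion for parameter recovery; it
needs long records (60 s → 28 windows → 378 dFC correlations) for the KS
statistic to resolve. With 20-s records (8 windows, 28 values) the KS
granularity swamps the effect.

## Statistics

Two-way repeated-measures ANOVA on complete balanced designs (pingouin
backend), reporting F, degrees of freedom, generalized eta squared,
Greenhouse–Geisser epsilon (always), the GG-corrected p whenever Mauchly's
test rejects sphericity (for the interaction: whenever either parent
factor does; with two levels sphericity holds trivially), plus
Shapiro-Wilk normality diagnostics per cell. Paired comparisons use the
Wilcoxon signed-rank test with Benjamini–Hochberg adjustment across each
comparison family; effect size is paired Cohen's d (mean of differences /
sd of differences; a constant nonzero difference yields signed infinity,
all-zero differences are flagged degenerate). Calibration on simulated
10-subject designs: type-I error ≈ 5%, power ≥ 95% for strong effects
(tested with 200 replicates).

## Known limitations

* Absolute coupling and noise scales are convention-bound (weight
  normalization, noise discretization); comparisons across conventions
  need rescaling.
* The single-node driver variant is built by sum/weighted-mean merging of
  the parceled nuclei, an approximation to re-parcellating tractography.
* PLV/dFC estimator variance at 10-s desk scale is substantial; the
  cohort-level tests assert directions and majorities, not point values.
* No empirical data path is bundled; `read_connectome` accepts any
  delimited-text connectome, but all shipped results are synthetic.
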