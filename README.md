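# thalnet

Whole-brain network modelling of the thalamus' role in resting-state
functional connectivity.

## The problem

Resting-state functional connectivity (FC) — the pattern of statistical
dependence between regional brain signals — is a widely used biomarker, but
the mechanisms that generate it are not settled. One hypothesis is that a
small set of *driver* regions, foremost the thalamus with its arousal
(reticular activating system) and sensory-relay afferences, injects strong
noisy input that pushes otherwise damped cortical populations into
functional interaction. `thalnet` implements the in-silico machinery to
test this hypothesis: brain network models built from structural
connectomes, with variants that parcel, collapse or remove the driver
region, heterogeneous noisy drive, and FC/dynamical-FC scoring against
reference connectivity.

It is written for computational neuroscientists who want a compact,
fully-scripted version of this modelling workflow that runs on synthetic
connectomes calibrated to the network statistics of tractography data.

## The model

Each region is a Jansen-Rit cortical column: pyramidal cells, excitatory
and inhibitory interneurons, with mean postsynaptic potentials evolving as

    ẏ₀ = y₃                 ẏ₃ = A·a·S[y₁−y₂] − 2a·y₃ − a²·y₀
    ẏ₁ = y₄                 ẏ₄ = A·a·(input + C₂·S[C₁y₀]) − 2a·y₄ − a²·y₁
    ẏ₂ = y₅                 ẏ₅ = B·b·C₄·S[C₃y₀] − 2b·y₅ − b²·y₂

with the sigmoid rate function S[v] = 2·v_max / (1 + e^{r(v₀−v)}). Regions
couple through the structural connectome:

    input_i(t) = p_i + η_i(t) + g · Σ_j w_ji · S[y₁ʲ(t−d_ji) − y₂ʲ(t−d_ji)]

where `p_i` is the mean intrinsic drive, `η_i(t)` Gaussian noise redrawn
each integration step, `g` the global coupling factor, `w_ji` streamline
weights (normalized by their maximum) and `d_ji` = tract length / 15 mm/ms
conduction delays. Depending on its total input a node is a damped
oscillator relaxing to a fixed point (*prebifurcation*) or a self-sustained
limit cycle (*postbifurcation*); between the damped and ~10 Hz alpha
regimes lies a slow, high-amplitude limit cycle.

Evaluation metrics: alpha-band (8–12 Hz) phase-locking-value FC; Pearson
correlation `r_PLV` between the upper triangles of simulated and reference
FC (cortical regions only); sliding-window dynamical FC (4-s windows, 50%
overlap) compared by the Kolmogorov–Smirnov distance (KSD) between
dFC-correlation distributions; spectral peaks, driver SNR and
cortex/driver relative power. Group statistics: two-way repeated-measures
ANOVA with Greenhouse–Geisser correction and paired Wilcoxon tests with
Benjamini–Hochberg FDR.

Because the subject data such analyses are normally built on (tractography
connectomes, MEG FC) cannot be shipped, the `synthetic` module generates
connectomes whose driver regions reproduce the characteristic thalamic hub
profile — near-average degree, roughly half-average node strength — and
*pseudo-empirical* FC/dFC targets simulated at hidden parameters, so every
downstream claim is testable end to end.

## Worked example

Score one synthetic subject under high vs low thalamic noise and find the
prebifurcation working point:

```python
import numpy as np, thalnet as tn
from thalnet.synthetic import ConnectomeGenSpec, ReferenceRun, \
    generate_connectome, generate_pseudo_empirical
from thalnet.experiments import Condition, g_sweep, split_regimes, working_point

sc = generate_connectome(ConnectomeGenSpec(seed=1))   # 20 cortical + 6 thalamic
target = generate_pseudo_empirical(sc, ReferenceRun(g=4.0), noise_sd=0.02, seed=2)

conditions = [Condition(driver_eta=0.022), Condition(driver_eta=2.2e-8)]
cfg = tn.SimulationConfig(duration=10_000, transient=2_000, seed=3)
table = g_sweep([sc], conditions, np.arange(0.0, 7.0), 1, cfg, [target])

wp = working_point(split_regimes(table), metric="r_plv", regime="pre")
print(wp[["condition", "g", "r_plv", "ksd", "peak_hz"]].to_string(index=False))
```

prints

```
    condition   g    r_plv  ksd  peak_hz
parceled-high 1.0 0.933154 0.75     0.75
 parceled-low 1.0 0.108487 1.00     1.75
```

With high thalamic noise (η_th = 0.022) the damped cortex is driven into a
connectome-shaped interaction pattern and the FC fit is high
(r_PLV ≈ 0.93); with low noise (η_th = 2.2×10⁻⁸) the nodes barely interact
and the fit collapses (r_PLV ≈ 0.11). The sub-alpha spectral peak reflects
the 1/f-like spectrum of damped nodes processing noise.

A command-line interface wraps the same library:

```sh
thalnet simulate --connectome SC_DIR --g 4 --eta-driver 0.022 --duration 10 --out run.h5
thalnet fc --result run.h5 --out fc.txt
thalnet sweep-g --subjects 3 --g-max 10 --out sweep.csv
```

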