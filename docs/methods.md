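# Methods

## Model structure

Every network entity X is an interconverting pair (X_inactive, X_active)
with a conserved total normalised to 1, so concentrations are occupancy
fractions (nM-equivalent arbitrary units) and time is in hours. The state
therefore has 2 × 17 = 34 dimensions. Four kinds of additive terms build
each entity's rate:

- **basal interconversion** — first-order activation `k_act·[X_i]` and
  deactivation `k_inact·[X_a]` for every entity, so the unstimulated cell
  relaxes to a non-trivial resting state and nodes without an activating
  interaction still cycle;
- **activation edges** — the source's active form converts the target's
  inactive form to active;
- **inhibition edges** — the source's active form converts the target's
  active form back to inactive;
- **stimulus couplings** — TNFα activates TNFR1 at `k_stim_tnfa·dose·[TNFR1_i]`
  (dose in ng/ml) and TPL deactivates NFκB at `k_stim_tpl·dose·[NFκB_a]`
  (dose in nM), both held constant while applied.

Edge rate laws are bilinear mass action `k·[src_a]·[sub]` for
receptor-proximal and other fast couplings (14 edges), Michaelis–Menten
`V·[src_a]·[sub]/(Km+[sub])` for enzyme-like (de)activations (10 edges) and
Hill `V·[src_a]·[sub]ⁿ/(Kmⁿ+[sub]ⁿ)` with n = 2 for the JNK→Caspase3
activation, the one place a sharper nonlinearity is wanted; all laws are
Michaelian in the substrate (the species being converted) and linear in the
modulating source, and Hill with n = 1 reduces identically to
Michaelis–Menten. Rate-law kinds and the whole edge list are overridable
through the network config (TSV/JSON edge-list round trip in
`tnfnet.network`).

The default topology had to reconcile an over-determined description: the
interaction lists recoverable from prose and the curated branch table imply
more edges than the stated totals (17 entities / 25 interactions / 34
species) admit. The shipped network keeps all structurally load-bearing
paths — the NFκB⊣PTEN⊣PI3K→AKT branch, the four pAKT regulators (PI3K,
JNK, Bcl2 positive; CAPP negative), the NFκB-controlled XG and Bcl2 arms,
the ceramide→{C1P, CAPP} arm, the MKK4/7–ROS–JNK positive feedback loop,
the RAF→ERK1/2⊣JNK arm and all five inhibitor-affected edges — and routes
receptor-driven Caspase3 activation through Caspase8
(TNFR1→Casp8→Casp3), the canonical initiator, which also supplies the
17th entity. NFκB's protection of Caspase3 is carried indirectly through
PTEN→PI3K→AKT⊣Casp3 rather than as a separate lumped edge; the price of the
exact 17/25 counts is that a handful of long branches through
PI3K→ERK1/2, PI3K→Ceramide and the AKT→RAF / AKT⊣MKK4/7 couplings are not
present in the default enumeration.

### Parameters (81)

| group | count | defaults |
|---|---|---|
| basal k_act / k_inact per entity | 34 | 0.02–0.5 / 0.05–1.0 h⁻¹ |
| mass-action edge constants | 14 | 0.15–3 h⁻¹ |
| Michaelis–Menten (V, Km) | 20 | V 0.3–3 h⁻¹, Km 0.3–0.4 |
| Hill (V, Km, n) | 3 | 0.3 h⁻¹, 0.45, 2 |
| stimulus couplings | 2 | 0.04 (ng/ml)⁻¹h⁻¹, 0.25 nM⁻¹h⁻¹ |
| marker scalings s_pAKT, s_pJNK, s_Casp3 | 3 | 1/resting active level |
| inhibitor constants | 5 | printed values, nM⁻¹ |

The kinetic defaults are the synthetic ground truth. They were chosen once
so that the simulated study conditions reproduce the qualitative biology
the analysis is about: under 100 ng/ml TNFα, NFκB activity roughly doubles
and Caspase3 stays near its resting level (early dip, FC ≈ 1.05 at 24 h);
under 60 nM TPL, NFκB collapses, pAKT falls, pJNK rises and Caspase3 climbs
through the late phase to FC ≈ 1.8; the combination sits between. Marker
scaling constants are frozen at the reciprocal resting active levels of a
converged pre-equilibration, which makes model fold change exactly 1 at the
unstimulated steady state.

## Simulation

`scipy.integrate.solve_ivp` (LSODA) with rtol 1e-8 / atol 1e-10 integrates
the RHS; halving the tolerances moves marker FC by < 1e-4 relative. The
initial condition is the unstimulated steady state: a 500 h relaxation from
the all-inactive state followed by a Newton polish on the active fractions
(inactive forms follow from conservation), verified by ‖RHS‖ < 1e-8; a
warm-start guess (e.g. the previous parameter set's rest state in a fit
sweep) short-circuits the relaxation when the Newton solve converges from
it. Protocols integrate in two phases: TPL and any inhibitor on from
−1 h (the pre-treatment offset) to 0, then all inputs on from 0 to the
horizon. Sub-tolerance negative excursions of the integrator are clipped
to zero inside the rate laws; a state genuinely negative beyond tolerance
aborts with the last successful time.

Inhibition is phenomenological: each affected edge is multiplied by
1/(1 + K·[I]) with K in nM⁻¹ and the dose constant (no decay). Wortmannin
attenuates PI3K→AKT, MKK4/7→JNK and NFκB→XG; SP600125 attenuates Bcl2→AKT
and MKK4/7→JNK. The attenuation acts on the NFκB→XG edge itself rather
than on XG directly — with a single lumped edge the two readings are
equivalent up to the constant's value.

## Synthetic data

The generator emulates a barcoded phospho-flow experiment: per marker,
condition and time point it draws `n_replicates` (default 3) MFI values
`MFI_t = MFI_DN + (MFI_Neg − MFI_DN)·FC_model(t)·(1 + ε)`,
ε ~ N(0, c_rel) with c_rel = 0.10, clipped from below at the background
MFI_DN = 100 (MFI_Neg = 1000; both cancel in the FC transform). The 12
measured time points are 0, 1, 2, 4, 6, 8, 12, 16, 18, 20, 22, 24 h — the
10 h and 14 h points are deliberately absent and appended by cubic-spline
interpolation of the replicate means (σ interpolated the same way), flagged
`augmented`, reproducing the spline-augmented calibration design.

Per-point uncertainties follow a standard error model with two modes:

- `"sample"` (default): sample SD of the replicates / √n, floored at
  c_abs = 0.05 FC units so zero-spread points cannot blow up the χ² weights;
- `"model"`: the exact noise-model SD of the replicate mean,
  c_rel·|FC|/√n.

The distinction matters for calibration statistics: with estimated
triplicate SEs the normalised residual (mean − truth)/SE is t-distributed
with 2 degrees of freedom, whose second moment diverges, so "χ² at the
truth ≈ number of residuals" holds only under the model-σ mode (measured:
mean χ²/N ≈ 1.015 over 200 realisations with model σ, ≈ 1.14 with sample
SEs and the floor). Tests of that property use the model mode; fitted
analyses default to the sample mode, as an experimenter would.

What the generator does **not** emulate: per-cell fluorescence
distributions, barcoding/gating artefacts, non-Gaussian or autocorrelated
measurement error, biological run-to-run drift, and cell-to-cell
variability (the model is deterministic). Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated noise
model, not robustness to everything real cytometry data can do.

## Calibration

Residuals (yᵉ − y(t;P))/σ are stacked over markers, time points (augmented
ones included) and the three conditions, and minimised with
`scipy.optimize.least_squares` (trust-region reflective) in log₁₀
parameter space — bounds default to ±2 decades around nominal — from
`n_starts` log-uniform random starting points. The σ exponent is
configurable (`sigma_power=2` reproduces a σ²-weighted variant of the
objective). A failed simulation inside the objective contributes a 1e12
penalty and a warning instead of aborting the sweep. An identical-start
mode exists but cannot produce a spread of fits for a deterministic
optimiser, hence randomized starts are the default. Ensemble selection
keeps the ⌈fraction·N⌉ lowest-χ² fits (ties by start id; default fraction
3%), and `ensemble_summary` reports per-parameter median/IQR/Tukey-whisker
statistics on log₁₀ values.

On identifiability: for an identifiable (sub)model every converged start of
a single dataset lands on that dataset's optimum, so whiskers across starts
have near-zero width and need not cover the truth (the optimum is biased by
the particular noise realisation). The recovery test therefore builds its
ensemble from best fits across independent noise realisations, where
truth-in-whiskers is a genuine property; multi-start spread only becomes
informative for sloppy, high-dimensional fits.

## Flux, branch and AUC analyses

Fluxes are evaluated analytically from the stored rate terms along the
trajectory (never by numerical differentiation), so each species'
derivative equals the signed sum of its term fluxes to rounding error; the
decomposition test demands residual < 1e-9 relative. Contribution sign is +
if the term increases the active form. Basal and stimulus terms are
reported alongside interaction edges but excluded from capacities.

Node capacity is C_k = Σ|out-edge flux| / Σ|in-edge flux| (the literal
all-edges reading of the printed sums would make C_k identical for every
node; an out/total-network-flux alternative is available via `mode=`).
Zero inbound flux yields NaN, never infinity. Branch capacity multiplies
|J|·C over consecutive edges with C evaluated at each edge's end node, and
S = R_comb/(R_a + R_b) − 1 with a denominator guard of 1e-12 × the largest
R on the grid; undefined points are flagged NaN, not interpolated. Branch
enumeration runs on the unsigned digraph (networkx simple paths, default
cutoff 8 edges), re-annotates original signs, and orders paths
lexicographically.

AUCs are trapezoidal on the stored grid without resampling, windows
anchored at 0. The contribution regression is no-intercept OLS (optional
intercept available), fitted per condition pooling windows and replicates
by default (a per-window mode exists). The normalisation of the relative
contributions divides by the regression-reproduced average
a·⟨AUC_pJNK⟩ + b·⟨AUC_pAKT⟩, which makes A_pJNK + A_pAKT = 1 an algebraic
identity per window; dividing by the observed ⟨AUC_casp3⟩ (mode
`denominator="observed"`) reproduces the sum only up to the regression
residual, because no-intercept residuals are not orthogonal to a constant.
⟨·⟩ averages over whatever replicate axis the AUC records carry (parameter
sets, experimental replicates, or both), recorded in the result metadata.
The apoptosis calibration is an ordinary degree-4 polynomial least-squares
fit; predictions are clipped to [0, 100] % and inputs outside the fitted
AUC range are flagged as extrapolations rather than rejected.

## Pipeline and reproducibility

The `tnfnet` CLI chains synth → simulate → fit → flux → branches → auc. A
single seed fans out as seed + stage index; every artifact carries the
configuration hash (computed over everything but the output directory) and
the seed, and reruns with the same config and seed are byte-identical in
all numeric outputs. The default pipeline sizes (12 + 2 time points, 3
replicates, 8 fit starts over a 3-parameter free subset, 5-member ensemble
for the AUC stage) keep a full run under a minute on one core; all knobs
scale up through `RunConfig`.

## Known limitations

- The default topology is a reconciliation, not a transcription: some
  curated long branches are absent (see Model structure), and per-edge
  rate-law assignments beyond the stated mix are this package's choice.
- The synthetic ground truth is a plausible parameterisation, not a fitted
  one; analyses that depend on the actual fitted constants (absolute
  synergism curves, the apoptosis calibration coefficients) are
  reproducible in procedure but not in numeric value.
- Fitting the full 76-dimensional kinetic space is supported but expensive;
  recovery guarantees in the test suite are for identifiable low-dimensional
  subsets.
- Deterministic ODEs: no cell-to-cell variability, no stochastic
  extensions, no TNFR2 arm, no SBML import/export.
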