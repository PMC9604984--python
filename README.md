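# tnfnet

Kinetic analysis of the signalling cross-talk that sets the apoptotic
response of TNFα-stimulated cells.

TNFα drives both survival signalling (NFκB, PI3K/pAKT) and apoptotic
signalling (ceramide/pJNK, caspases) from the same receptor, and the
phenotype — what fraction of a population dies — depends on how these arms
trade fluxes over a full day, not on any single snapshot. `tnfnet` provides
a tested re-implementation of a data-driven analysis of this trade-off in a
monocytic cell line: an ODE model of the TNFα → {NFκB, pAKT, pJNK, Caspase3}
network, its calibration to flow-cytometry fold-change time courses, and the
downstream analyses (reaction-flux decomposition, branch synergism, AUC
correlation) that turn fitted trajectories into mechanistic statements. A
synthetic-data generator emulating the triplicate fold-change measurements
makes every stage testable against a known ground truth.

It is intended for systems biologists who want to run, perturb or extend
this style of analysis on their own network variants and datasets.

## The model and the analyses

**Network / ODEs.** Each of the 17 entities (TNFR1, NFκB, PTEN, PI3K, AKT,
Bcl2, XIAP/Gadd45β, ceramide, C1P, CAPP, MKK4/7, ROS, JNK, RAF, ERK1/2,
Caspase8, Caspase3) interconverts between an inactive and an active form
(34 species). The 25 signed interactions act by mass-action,
Michaelis–Menten or Hill kinetics: activation edges convert the target's
inactive form to active at a rate set by the source's active level,
inhibition edges do the converse. TNFα (ng/ml) and triptolide (TPL, nM; an
NFκB transactivation blocker) enter as external stimuli; TPL and kinase
inhibitors are applied 1 h before TNFα, mirroring the experimental
pre-treatment. The parameter schema has 81 entries, including 3 marker
scaling constants and 5 phenomenological inhibitor constants
(Wortmannin: K = 0.001, 0.02, 5·10⁻⁵ nM⁻¹ on PI3K→AKT, MKK4/7→JNK,
NFκB→XG; SP600125: 2·10⁻⁴, 5·10⁻³ nM⁻¹ on Bcl2→AKT, MKK4/7→JNK), each
attenuating its edge by 1/(1 + K·[I]).

**Measurement model.** A marker's relative fold change is
FC = (MFI_t − MFI_DN)/(MFI_Neg − MFI_DN), with MFI_Neg the unstimulated 0 h
control and MFI_DN the cells-only background; the model-side equivalent is
FC = s·[active marker]. The generator draws triplicate MFI readouts with
multiplicative Gaussian noise and spline-augments the curves at 10 h and
14 h, as in the calibration design it emulates.

**Calibration.** χ²(P) = Σ ((yᵉ − y(t;P))/σ)² pooled over pAKT, pJNK,
Caspase3 and the three conditions, minimised by trust-region-reflective
least squares in log₁₀ parameter space from many random starts; the best
fraction (default 3%) of starts forms the ensemble whose per-parameter
boxplot statistics summarise identifiability.

**Flux and branch analysis.** Every RHS term evaluated along a trajectory
is a reaction flux; each species' derivative is exactly the signed sum of
its term fluxes. A branch is a simple path from TNFR1 or NFκB to pAKT or
pJNK; its relative capacity is R = Π |J_edge|·C_end-node with
C_k = out-flux(k)/in-flux(k), and the extent of synergism between stimuli
is S = R_combined/(R_TNFα + R_TPL) − 1 (S > 0 super-additive).

**AUC correlation.** Marker accumulation is the trapezoidal AUC of FC over
0–8, 0–12, 0–24 h. Accumulated Caspase3 is regressed without intercept as
AUC_casp3 = a·AUC_pJNK + b·AUC_pAKT across ensemble trajectories; the
normalised relative contributions A_pJNK + A_pAKT sum to 1 per window. A
degree-4 polynomial calibrates ensemble-average AUC_casp3 against measured
apoptosis percentages, turning simulated Caspase3 accumulation into a
phenotype prediction (clipped to [0, 100] %, extrapolation flagged).

## Worked example

```python
import numpy as np
from tnfnet import build_network, assemble_odes, default_protocols, run_protocol
from tnfnet.params import default_truth
from tnfnet.flux import edge_fluxes, decompose_node, dominant_contributors
from tnfnet.branches import enumerate_branches, synergism_trace

net = build_network()                      # 17 entities, 25 interactions
sys = assemble_odes(net, default_truth())
trajs = {l: run_protocol(sys, p) for l, p in default_protocols().items()}
for label, traj in trajs.items():
    fc = traj.markers["Casp3"]
    print(f"{label:9s} Casp3 FC:  2h={fc[2]:.2f}  8h={fc[8]:.2f}  24h={fc[24]:.2f}")

fx = {l: edge_fluxes(sys, t) for l, t in trajs.items()}
dec = decompose_node("AKT", sys, fx["TNFa"], trajs["TNFa"])
for lbl, integral in dominant_contributors(dec)[:2]:
    print(f"pAKT contributor {lbl}: {integral:.3f}")

b = next(x for x in enumerate_branches(net, "NFkB", "AKT")
         if x.nodes == ("NFkB", "PTEN", "PI3K", "AKT"))
tr = synergism_trace(b, fx)
print(f"{b}: S(2h)={tr.s[2]:.2f}  S(24h)={tr.s[24]:.2f}")
```

prints

```
TNFa      Casp3 FC:  2h=0.87  8h=1.04  24h=1.05
TPL       Casp3 FC:  2h=1.38  8h=1.72  24h=1.84
TNFa+TPL  Casp3 FC:  2h=1.10  8h=1.41  24h=1.43
pAKT contributor PI3K>AKT: 24.334
pAKT contributor CAPP>AKT: 19.000
NFkB-|PTEN-|PI3K->AKT: S(2h)=2.05  S(24h)=2.14
```

Under TNFα alone, survival signalling holds Caspase3 near its resting level
(FC ≈ 1 throughout, after an early dip); arresting NFκB with TPL
de-represses the apoptotic arm and Caspase3 climbs through the late phase.
The flux decomposition identifies PI3K as the dominant positive and CAPP as
the dominant negative regulator of pAKT, and the NFκB⊣PTEN⊣PI3K→pAKT branch
carries strong positive synergism between the two stimuli (time-integrated
|contribution| in FC-equivalents·h; S dimensionless).

The same stages are available from the shell:

```sh
tnfnet --seed 1 --out out/ run          # synth -> simulate -> fit -> flux -> branches -> auc
tnfnet --out out/ branches --source NFkB --target AKT
```

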