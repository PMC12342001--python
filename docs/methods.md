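# Methods

## Model

The liver is a set of reaction nodes, one per enzyme or lumped pathway
step. At temperature T, node *j* minimizes the dimensionless Gibbs free
energy of its component set over its reaction extents, holding the rest
of the system fixed; the network's operating point is the fixed point at
which every node is optimal given the others — a Nash equilibrium rather
than a single global optimum, which lets pathways compete for shared
substrates (adenylates, NADH, oxygen, glutathione).

Activities are ideal: the chemical potential of species *i* is
ΔG⁰f,i/RT + ln x_i with x_i its mole fraction within the node's
component set, and x·ln x → 0 as x → 0 so species may be fully consumed.
The solver minimizes the *extensive* form Σ n_i (g_i + ln x_i); for
reactions that change total mole number only this form reproduces
mass-action equilibria, which the tests verify against closed-form
constants and brute-force grid minimization. The intensive per-mole form
is exposed separately (`mixture_gibbs`). Standard energies are carried
to temperature through

ΔG⁰(T)/RT = ΔG⁰(T₀)/RT₀ + (ΔH⁰(T₀)/R)·(T−T₀)/(T·T₀), T₀ = 298 K.

Note the (T−T₀) numerator: under this correction an exothermic reaction
becomes *more* favorable as the system warms toward and past T₀, which
is the temperature sensitivity that makes gradual warming productive in
this model.

### Solver

Each node's problem is convex (ideal-mixture Gibbs energy in amounts,
affine in extents), solved by SLSQP with analytic gradients followed by
a coordinate-wise bounded 1-D polish. The polish matters: equilibria
such as the proton buffer sit a tiny extent away from a log singularity
at a nonnegativity boundary, far below the resolution of a linearly
scaled gradient step. A solution is accepted only if it does not
increase the objective relative to the zero-extent start (always
feasible); on failure one seeded random restart is tried, else the node
stays put.

Nodes are swept sequentially in a fixed order (Gauss–Seidel successive
substitution on the shared state); the node carrying the
CO₂/bicarbonate chemistry goes last so each sweep ends
acid-base-consistent. The outer loop compares the cumulative step fluxes
(transport edges when the network has them, otherwise all extents)
between sweeps and stops below a 2-norm tolerance of 10⁻³. Extent
budgets — per-reaction rate caps × a Q₁₀ temperature factor × the step
length — apply to the whole step, not per sweep, so iterating to the
fixed point cannot multiply throughput. Every update is a stoichiometric
extent move of a balanced reaction, so element and charge totals are
conserved to machine precision by construction.

### Protons and pH

Reactions that consume or produce H⁺ at physiological mole fractions
(~10⁻⁹) would otherwise acquire enormous ideal-mixing entropy terms that
flip pathway directions. The package therefore uses the transformed
(pH-buffered) convention standard in biochemical thermodynamics: the
proton carries a reference potential that exactly cancels its mixing
term at pH 7.4, it is excluded from node objectives (`Species.buffered`),
and every fixture reaction target is thereby a physiological driving
force at the pH 7.4 operating point. After each step an analytic
carbonic-anhydrase rebalance absorbs the step's acid load into the
CO₂/bicarbonate pair (conserving hydrogen and charge exactly) and
resets the tracked H⁺ amounts to the Henderson–Hasselbalch value
pH = pK′ + log₁₀([HCO₃⁻]/[CO₂]) with pK′ = 6.1. Reported pH is
−log₁₀ of the tracked molar H⁺ concentration, consistent with that
buffer state. pH dynamics therefore come from CO₂ accumulation (Krebs
flux, metabolic acid) against bicarbonate stores and perfusate gas
exchange — the clinically meaningful channel.

## Reduced network

The bundled network is a synthetic, deliberately small stand-in for a
whole-organ reconstruction: 3 compartments (extracellular, cytosol,
mitochondrion), 9 nodes, ~30 reactions including transport edges, all
element- and charge-balanced (charge rides as a pseudo-element in one
balance matrix). It contains lumped glycolysis (glucose → 2 lactate,
+2 ATP), lactate-fed Krebs cycle (NAD⁺-coupled, 1 substrate-level ATP),
oxidative phosphorylation (NADH + ½O₂, 2.5 ATP), purine degradation with
superoxide-releasing xanthine-oxidase steps, the textbook
SOD/catalase/glutathione-peroxidase triad written verbatim, glutathione
transport and reductase regeneration, the committed malonyl step
(irreversible) plus an ATP-consuming fatty-acid synthesis lump,
mevalonate synthesis as the bile proxy, an adenylate node (adenylate
kinase + maintenance ATPase load), and the CO₂/bicarbonate buffer with
perfusate gas exchange.

Two structural choices are load-bearing. First, the Krebs lump carries
no direct O₂; oxygen is consumed in the oxphos node. This keeps the
electron-leak H₂O₂ source (2 % of O₂ consumed — an exact per-step
identity) on the same 10⁻⁵ nmol/cell scale as the glutathione economy,
so that supplementation is the operative control on the peroxide
balance. Second, committed pathway steps (PDH, Krebs, oxphos, ACC, FAS,
mevalonate, the maintenance ATPase) are irreversible; reversible lumped
biosynthesis with large H⁺ stoichiometries would otherwise act as
unphysical acid buffers near equilibrium.

### Fixture thermodynamics

Formation energies are synthetic fixture data. A few species carry
literature-scale anchors (water −237.2/−285.8, CO₂ −394.4/−393.5
kJ/mol, …; large cofactors carry arbitrary fixed anchors since only
reaction deltas matter); every other species is derived by walking a
chain of target reaction energies, one unknown per target. The targets
are physiological driving forces in the pH-buffered convention
(`physiological_delta`); hallmarks hold exactly by construction:
glutathione-peroxidase ΔH = −196 kJ/mol, ATP hydrolysis −30 kJ/mol,
NADH oxidation −220 kJ/mol. Scavenging equilibria (SOD −116, GPx −100,
catalase −190 kJ/mol) and the buffer target (−6.9 kJ/mol) were
calibrated once so that the baseline protocol lands in its physiological
operating ranges — all six plausibility criteria pass, end-of-perfusion
mitochondrial [H₂O₂] sits inside the normal 10⁻⁹–10⁻⁸ M band, cold-storage
superoxide sits at the 10⁻¹⁴–10⁻¹⁵ M order, and the constant
mid-thermic policy is viable — and then frozen.

### Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| intracellular volume | 1/9 | nmol/(cell·mM) | amount ↔ concentration; implied by the perfusate table |
| leak_fraction | 0.02 | — | share of consumed O₂ diverted to superoxide in MP |
| xo_scs_rate | 2×10⁻⁷ | nmol/cell/h | forced xanthine-oxidase extent in cold storage |
| Q₁₀ | 2.0 | — | rate-cap temperature scaling, referenced to 37 °C |
| outer eps | 10⁻³ | — | transport-flux fixed-point tolerance |
| atten threshold / scale | 3×10⁻⁸ / 5×10⁻⁸ | M | onset and softness of cytochrome-oxidase dysfunction |
| pK′ | 6.1 | — | CO₂/bicarbonate Henderson–Hasselbalch constant |
| GSH bounds | [2.22, 25.2]×10⁻⁵ | nmol/cell | supplement search window |
| H₂O₂ band | [10⁻⁹, 10⁻⁸] | M | normal mitochondrial range |

Rate caps (nmol/cell/h at 37 °C): glycolysis 0.05, Krebs 0.04, oxphos
6×10⁻⁴, maintenance ATPase 0.1, GSH uptake 6×10⁻⁵, catalase 2×10⁻⁷,
and smaller values for the remaining steps; they were sized so the
constant 16 °C baseline is viable while constant 37 °C is not, giving
the warming optimizer a genuine trade-off.

## Protocol engine

A phase advances in hourly steps (configurable). Per step: set
temperature; (SCS) apply the forced xanthine-oxidase extents, clipped to
substrate availability; relax to the Nash equilibrium; (MP) measure the
step's useful O₂ consumption U, apply the electron-leak extent
D/2 with D = f/(1−f)·U so that superoxide-forming O₂ D equals
f = 2 % of total consumption U + D exactly, then let the scavenging
nodes re-equilibrate; rebalance acid-base; record biomarkers. Perfusate
O₂ and CO₂ are reset to medium set-points each MP step (continuous
oxygenator); medium exchanges and gas refreshes are boundary fluxes,
logged outside the conservation ledger. Oxidative-stress feedback:
above [H₂O₂] = 3×10⁻⁸ M the oxphos rate capacity is multiplied by
1/(1 + excess/5×10⁻⁸), a smooth monotone stand-in for
cytochrome-c-oxidase dysfunction.

The six physiological-plausibility criteria are evaluated on phase-net
fluxes: glycolysis makes net ATP; Krebs ATP per glucose consumed lies in
[0, 2]; oxphos makes ATP; the malonyl step never runs backward; fatty-acid
synthesis consumes ATP; net glutathione disulfide is produced.

## Optimizers

Both searches are plain seeded Monte Carlo with full-simulation
evaluation and recorded traces. Policy proposals add a half-normal
increment (scale 4 °C) to a random suffix of the schedule, clamped to
[16, 37] °C — monotone by construction; acceptance needs a strict R
increase over the incumbent plus physiology and viability. Weights
default to each metric normalized by its baseline-perfusion magnitude.
The GSH search samples uniformly in [L, best-so-far]; because
over-supplementation can scavenge H₂O₂ below the band's lower edge, the
feasible set is an interval and the search keeps the smallest feasible
point rather than assuming feasibility at the upper bound (resolution
10⁻⁶ nmol/cell, default budget 200 iterations for the policy search).
The two optimizations are decoupled: peroxide scavenging turns over
~10⁻¹² kJ/cell against ~10⁻⁸ kJ/cell for ATP synthesis, four orders of
magnitude apart, so supplementation cannot move the optimal warming
rate.

## What the synthetic network does and does not show

The generator emulates the *structure* of the study — pathway
competition, the two superoxide routes, glutathione economics, pH and
lactate viability pressure — with thermodynamically self-consistent but
synthetic formation data and a ~30-reaction topology. Absolute fluxes,
concentrations, and the published whole-organ table values are
network-dependent and are reproduced directionally (signs, bands,
orders of magnitude, monotone trends), not numerically. Passing tests
therefore demonstrate the method's contracts and qualitative physiology on this
fixture, not quantitative predictions for a real liver. Known
limitations: no kinetic rate laws (equilibrium-seeking steps under rate
caps), no proton-motive coupling (pH-buffered convention), a single
intracellular volume, NADH accumulates as a reduced-equivalent sink at
high Krebs flux, and immune/inflammatory signaling is out of scope with
[H₂O₂] serving as the inflammation marker.

## Problem sizes

Default studies: 6 SCS steps + 8 MP steps per protocol; 200-iteration
policy search (~3 min on one CPU); 15–25-iteration GSH searches;
6-point perturbation sweeps. These sizes exercise every contract while
keeping a full study under a few minutes.
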