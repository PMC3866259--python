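# Methods

## Model structure

The simulator couples a continuum description of the tumor
microenvironment to a discrete cellular automaton on the same uniform
3D lattice (node-centered, spacing Δl = 0.1 dimensionless units ≈ one
cell diameter; default domain 40³ nodes, tumor seeded at the center).
Each simulation step: rebuild the region masks (viable Ω_V, necrotic
Ω_N, host Ω_H, neo-vessel Σ_C) from the cell population → solve
pressure → velocity → nutrient → TAF → MDE → adaptive Δt → advance ECM
→ angiogenesis and therapy hooks → update every cell in a freshly
shuffled order. The circular pressure/nutrient coupling is resolved by
lagging: each elliptic solve uses the most recent other field, starting
from n ≡ 1, p ≡ 0, f ≡ 1. Quasi-steady treatment of the diffusing
factors is justified by the separation of time scales between molecular
diffusion and cell cycling.

## Discretization and solvers

All elliptic problems use the 7-point finite-difference Laplacian.
Dirichlet conditions (n = 1, p = 0, d = dose) are imposed on the
outermost node layer and eliminated into the right-hand side; zero-flux
conditions use the node-centered finite-volume form, in which wall
cells carry half volumes and half face areas. The flux matrix is
symmetric, so every system is SPD and solved by conjugate gradients
(tolerance 1e-8 on the residual max-norm relative to max(1, ‖b‖∞),
10,000 iteration cap, warm-started from the previous step). Both
boundary treatments converge at second order on manufactured solutions
(sin·sin·sin for Dirichlet, cos·cos·cos for zero-flux), and the
iterative solutions agree with dense direct solves of the identical
assembled systems to 1e-8 on small grids. After each solve, nutrient,
ECM and drug are clamped to their physical ranges ([0,1], resp.
[0,dose]); TAF and MDE are floored at 0.

The ECM equation has no spatial coupling and is advanced pointwise by
one Heun (2nd-order TVD Runge–Kutta) step per timestep. The timestep is
Δt = (Δl/4)·min(1/max|V_i|, 1/max|u⃗_i|) over sprout-tip speeds V_i and
Darcy velocities, with an infinite bound when a speed set is empty or
zero and a hard cap (default 0.05 day; desk-scale runs described below
use 0.1 day) guarding the quiescent case.

## Parameters

Rates are dimensionless per simulated day. The registry holds the full
published table; choices that the source table leaves open:

* λ_pm (MDE secretion) is listed as {50, 100, 150}; default 50.
* λ_a (apoptotic volume loss) is listed as a range 0–1.3e-4; default
  1e-4. The TC division vector is [1−λ_a, λ_a].
* C_s = 1e-4 converts live-cell counts to tumor volume.
* The 6-entry nutrient-uptake vector maps positionally to
  [CSC, PC, TC, quiescent, endothelial, host] = [0.2, 0.5, 0.33, 0.67,
  1, 1]; host uptake applies to unoccupied non-necrotic nodes and can
  be disabled (`host_uptake`). Necrotic debris consumes nothing.
* Survival thresholds map as θ_a = [CSC 0.1, PC 0.17, TC 0.25] (CSCs
  most hypoxia-tolerant) and θ_d = [CSC 0.375, PC 0.27, TC 0.25] (CSCs
  most drug-resistant).
* Relative proliferation ages A_p = [CSC 1, PC 0.4, TC 1, EC 0.2]
  multiply a base cycle time of 3 days (PCs are the fast transit
  compartment at 1.2 days; stem and terminal cells cycle slowly). The
  3-day base is this package's calibration of a constant the source
  model never states: it reproduces compact, sub-millimeter tumors over
  30-day spans. With a 1-day base the growth front advances ≈1.3 lattice
  sites/day and a single founder fills any desk-scale domain within two
  weeks, which erases every cohort contrast the 30-day protocols are
  designed to measure.
* Generation bookkeeping: a same-type daughter inherits the parent's
  post-division generation count; a type switch (CSC→PC on the PC+PC
  outcome, or a cross-type daughter) starts at generation 0 of the new
  type's budget.
* Drug constants reuse the nutrient diffusion and vascular-transfer
  constants, but cellular uptake is scaled by `drug_uptake_scale`
  (default 20), giving a penetration depth of ~4 cell layers. This
  encodes the pharmacological premise that a chemotherapeutic is bound
  and consumed far faster than nutrient turns over: treatment kills
  from the rim inward and interior cells are poorly exposed. With
  unscaled (nutrient-like) uptake the drug equilibrates near the dose
  across the whole desk-scale domain and the first treatment step kills
  100% of cells, which contradicts both the 85%-kill stop rule and the
  relapse-from-interior-CSCs behavior the model exists to produce.
* Therapy cycle modifiers while a course is active: CSC ×0.5 (volume
  loss activates stem-cell cycling), PC ×1.0, TC ×2.0; restored exactly
  on stop. A zero-dose course has no effect of any kind.
* Motion weights include the stay option in the normalization (the stay
  weight q₀ = n/f at the current node competes with the m ≤ 6 free
  neighbors), and the ECM denominator is floored at 1e-6.
* Hypoxia tolerance: a cell must sit below its θ_a continuously for 2
  days before necrosis; any recovery resets the clock. Quiescent cells
  resume cycling when adjacent space frees.

## Heterogeneity semantics

Every CSC stores a heritable self-renewal mean μ_p ∈ [0, 1]. At each
division the symmetric-renewal probability p is drawn from the Gaussian
G(μ_p, σ) truncated to [0, 1] (σ = 0.1 by default; rejection sampling),
and the remaining outcome mass 1−p is distributed over the
CSC-preserving asymmetric outcomes (CSC+PC, CSC+TC) proportionally to
[K_CCP, K_CT]. The CSC-eliminating PC+PC conversion operates only under
the fixed four-outcome kinetics of the non-heterogeneity experiments:
heritable self-renewal ability modulates how often a stem cell renews,
not whether the lineage survives. (With the conversion included, a
low-mean cohort is a near-critical branching process whose stem
compartment dies out in most replicates by day 30, which would make
cohort CSC-fraction ratios degenerate rather than finite.) A CSC
daughter samples a fresh μ_p from G(parent μ_p, σ), so lineages drift
and selection acts on self-renewal. Cohorts are initialized with a
single CSC whose μ_p equals the cohort mean.

## Angiogenesis

The microenvironment equations only need the Σ_C indicator and the
sprout-tip speeds, so the vasculature model is deliberately minimal and
off by default: the outermost node layer proxies pre-existing vessels;
where TAF exceeds 0.2 a tip forms with probability 0.05 per step; tips
hop to orthogonal neighbors with probability ∝ exp(κ·Δc/Δl)/max(f, ε)
(κ = 10), laying down vessel nodes monotonically. All constants are
configuration knobs; disabling the module zeroes every Σ_C-dependent
term and the simulator runs unchanged.

## Gompertz analytics

ŷ(t) = y0·e^{k(1−e^{−b(t−t0)})} is fitted by bounded trust-region least
squares from five deterministic starting points, keeping the best
objective. The triple (y0, k, t0) is structurally non-identifiable
(sliding t0 along the fitted curve rescales y0 and k without changing
the curve), so fitted parameters are normalized to the gauge t0 = first
sample time; PP = y0·e^k and TtP are invariant under this
normalization. TtP is reported at a relative tolerance ε (default 0.01)
because the Gompertz asymptote is unreachable in finite time:
TtP = t0 − ln(−ln(1−ε)/k)/b, with TtP = t0 when the target level is
already met. AAI counts a cell as surface if at least one of its six
in-domain neighbors is free, and uses raw cell counts, not C_s-scaled
volumes. Degenerate records (fewer than 5 samples, constant volume) are
rejected rather than fitted.

## Synthetic experiments: what they emulate, and limits

The seeding fixtures mirror the published designs: ~20 pure CSCs, 200
unsorted cells with exactly 8 CSCs (4%), or a single CSC with cohort
mean μ ∈ {0.25, 0.5, 0.75}. Unsorted non-CSCs split 50/50 into PC/TC
(their in-vivo composition is unspecified). Initial clusters are the
nodes nearest the domain center.

Desk-scale protocol sizes (chosen for single-CPU runtimes of minutes):
the heterogeneity cohort experiment runs on a 30³ lattice with five
seeds per cohort and a 0.1-day timestep cap; the qualitative therapy
checks use 16³ lattices. At these scales tumors stay three-dimensional
but small (10³–10⁴ cells), which has real consequences:

* Nutrient gradients across such small domains stay above every
  survival threshold, so hypoxic necrosis — and with it TAF release and
  the necrotic pressure sink — is essentially inactive in the desk
  runs (it is exercised by unit tests instead).
* A single-CSC lineage at low μ is a near-critical branching process;
  by day 30 many replicates have lost their CSC compartment entirely.
  Cohort-mean CSC fractions at small replicate counts are therefore
  heavy-tailed, and fold-change ratios between cohorts are far noisier
  than the underlying biology.
* Because the slow-cycling CSC compartment delays early expansion while
  PC-rich progeny grow fastest, low-μ tumors can transiently exceed
  high-μ tumors in volume at day 30 at this scale; the high-μ growth
  advantage emerges through lineage exhaustion on longer horizons than
  a desk lattice can hold.

Passing tests at these scales therefore demonstrate mechanism
correctness (solver accuracy, lineage kinetics, enrichment direction,
reproducibility), not quantitative agreement of every published fold at
full scale.

## Numerical and degenerate-input choices

Empty-source elliptic problems short-circuit to the zero field. An
all-zero reaction coefficient with a nonzero source raises (singular
zero-flux system). Probability vectors are validated to sum to 1 within
1e-9. Cells are updated strictly sequentially in a seeded random
permutation per step, so occupancy conflicts cannot arise; a consistency
checker aborts with a diagnostic if an invariant is ever violated. All
randomness flows from a single master seed through named substreams
(fixture, automaton, angiogenesis), making whole runs byte-reproducible.

## Known limitations

No cell mechanics or shape, no intracellular signaling, no stromal
compartment, no vessel flow/pruning or anti-angiogenic therapy, no
pharmacokinetic decay between doses, and a sharp (threshold) drug kill
rather than a dose–response curve. The angiogenesis scheme is a
placeholder sufficient to feed the PDE terms, not a validated vascular
model.
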