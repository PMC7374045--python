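# Methods

`tmesim` simulates a block of tumor tissue as a population of immobile
cells, each carrying a stochastic synchronous Boolean network (BN), coupled
through steady-state cytokine fields on a periodic 3D voxel grid.  This
note documents the model, its numerical choices, the defaults and why, what
the built-in synthetic data do and do not emulate, and known limitations.

## Cells as stochastic Boolean networks

Each cell type has one BN over `n` binary nodes split into *receptor* nodes
(written by the environment) and *regulatory* nodes (updated by logic
rules).  All regulatory nodes of all cells update synchronously from a
frozen snapshot of the previous state:

    x_j(t+1) = F_j(x_{j1}(t), ..., x_{jk}(t)).

Stochasticity follows the random-BN convention: each step, with probability
`1 − (1−q)^n` the state is replaced by its XOR with a Bernoulli(q) flip
vector; otherwise all rules fire.  Any `q > 0` makes the chain ergodic with
a unique stationary distribution; `bn_core` exposes an exact
transition-matrix oracle for networks of up to 12 regulatory nodes, used
throughout the tests.

Choices:

* **q = 0.01 for every gene and every cell type** (one knob; exposed in the
  model constructor).
* **Receptor nodes are excluded from the flip** — the environment overwrites
  them immediately after every update, so flipping them would have no
  observable effect; the branch probability therefore uses the number of
  flippable (regulatory) nodes.  This is an interpretation; a
  `perturb_receptors` flag restores the inclusive behavior.
* **Clamps (mutations, interventions) are re-applied after the flip**, so a
  clamped node is a fixed point of the composite update for every
  realization — mutations are permanent.
* Rule files use the BoolNet plain-text convention (`target, factors`) with
  `!`, `&`, `|`, parentheses, constants `0/1`, precedence NOT > AND > OR;
  parsing and serialization round-trip exactly.

## Cytokine fields

Each cytokine `m` obeys a diffusion–degradation balance; on the timescale
of one BN step diffusion is assumed equilibrated, so we solve the screened
Poisson steady state per step:

    0 = D ΔC − γ_D C + h⁻³ Σ_{i∈v} η_i,    η_i = 1 (node OFF) or R (ON),

with the 7-point periodic Laplacian on voxels of spacing `h`.  Because the
operator is diagonal in the discrete Fourier basis the solve is a single
FFT round-trip — exact to floating point (all active cytokines are solved
in one batched transform).  Receptor bits are set by a strict threshold:
`x_R = 1` iff the cell's local-voxel concentration exceeds `K` (equality
resolves to inactive).

Units are nondimensional: lengths in cell diameters (`h = 1` by default, so
`λ = sqrt(D/γ_D) ≲ h` degenerates to contact-like signaling), time in BN
steps, concentrations in units of the basal single-cell source.  The demo
model uses `λ = 2.5` cell diameters and `γ_D = 1` for every cytokine; only
`λ/h` and `K` relative to source magnitudes matter.  Useful intuition: a
uniform tissue of density ρ secreting at rate η̄ produces a background field
`C ≈ ρ·η̄/γ_D`; thresholds are meaningful where they straddle the basal
(η̄≈1) and active (η̄≈R) background levels.

## Tissue architecture

Cell positions form a point process in a periodic box of edge `L` at total
density ρ with cancer fraction `r_C`.  Cancer cells follow a Thomas
process: Poisson parent centers of intensity `ρ_cc = s·ρ_C`, Poisson(1/s)
offspring per center, isotropic Gaussian scatter.  The kernel width σ is
fixed by capping the expected within-σ cluster density at `ρ_max = 8ρ`:

    σ = (3 μ P₁ / (4π ρ_max))^{1/3},   μ = 1/s,  P₁ = P(‖Z‖≤1) ≈ 0.1987.

Stromal cells are a void process: uniform candidates thinned inside the
exclusion radius `R_ex` of the *same* centers.  The candidate intensity is
compensated by the Boolean-model void probability `exp(−ρ_cc·(4/3)πR_ex³)`
so the *realized* stromal density equals `ρ_S` — appropriate because
cell fractions come from deconvolution of realized tissue.  Counts are
Poisson-realized by default; a fixed-N mode draws exactly `round(ρL³)`
cells for reproducible tests.  All distances are minimum-image.

## Simulation loop and ensemble readouts

Per step: (1) assemble per-voxel sources from the current secretion-node
states; (2) solve every sensed cytokine's steady state (cytokines nobody
senses are flagged inert and skipped); (3) write receptor bits; (4) update
every cell's BN with perturbation and clamps.  One BN step = one diffusion
solve; no sub-stepping.

Ensemble readouts average the last `K` steps of `M` independent runs, each
with fresh Bernoulli(0.5) initial regulatory states (receptors start 0) and
a fresh tissue draw.  The cancer expression profile `Ḡ(θ)` collects the
per-node ON fractions — receptors included, since their ON fraction is the
most direct signature of the communication parameters.  Phenotype scores
are trailing-window means (50 steps by default) of the fraction of cells
with the phenotype node ON.  Reference run lengths are `M=20, T=400,
K=200`; the desk-scale experiments below use shorter runs, justified by the
measured plateau onset of ~20–30 steps.

## Sensitivity analysis

Latin hypercube sampling (scipy's `qmc.LatinHypercube`: one jittered point
per equal-probability stratum per dimension; log-scaled parameters are
stratified in log space) generates parameter sets; each is simulated with a
small ensemble and the outputs averaged.  PRCC between a parameter and an
output is computed by rank-transforming all columns (average ranks on
ties), regressing both the target's and the output's ranks on all other
sampled parameters' ranks, and correlating the residuals; p-values use the
t transform with `n − 2 − (d−1)` degrees of freedom.

The stellate/cancer interplay experiments are expressed purely as
`ParameterSpace` configurations (`demo.table_protocol_space`): secretion
rates frozen or sampled in `[2, 10]` per protocol, with the stellate
fraction `r_PSC`, the clustering `s` and the KRAS-mutant fraction always
sampled.  Freezing thresholds at the demo defaults in these protocols
mirrors the design of varying only secretion strengths.

## Calibration

Per sample, the cost is `C_p(θ) = 1 − Spearman(Ḡ(θ), G_target(p))` over
mapped genes (average ranks; an all-constant profile scores the worst value
2).  Simulated annealing minimizes it: W = 60 Metropolis steps per
temperature, Gaussian proposals with per-dimension scale `σ₀·T·range`
(σ₀ = 1) reflected into bounds, geometric cooling `T ← 0.8 T` from
`T₀ = 0.5` to `T_min` (default 0.01, ≈18 stages).  Mutation fractions `α_g` enter θ only for
genes present in the sample's mutation record; absent genes are fixed at
`α_g = 0` and dropped from the space.

The cost is stochastic (reduced ensembles, `M_cal = 3` short runs per
evaluation), which has three consequences handled explicitly:

* the incumbent's cached cost is refreshed at each temperature change, so a
  single lucky evaluation cannot stall the chain (full re-evaluation each
  step is available but doubles the budget);
* the lowest recorded cost is biased low, so the top 5 accepted candidates
  are re-screened with a doubled ensemble before declaring a winner;
* the reported final cost is re-evaluated with a larger ensemble
  (`4·M_cal` runs of doubled length).

## Synthetic data (what passing tests show)

The fixtures generate everything the pipeline consumes: random toy BNs
(≤12 nodes, exact-oracle-compatible), a two-cell PCC/PSC demo model, and
synthetic cohorts (Dirichlet cell fractions; mutation bits drawn at the
cohort prevalences 0.93/0.73/0.30/0.32 for KRAS/TP53/CDKN2A/SMAD4; target
expression = the demo model's own simulated profile at per-sample
parameters jittered around a recorded truth, plus bounded uniform noise
that preserves rank structure).

The demo networks are a structural stand-in written for this package, not
a transcription of any published rule set: EGF/bFGF autocrine loops feeding
a KRAS–PI3K growth axis that represses the p53 arm, TGFb-driven (and
self-sustaining) stellate activation, activated stellates secreting bFGF
(the cancer→stellate→cancer relay) and VEGF (deliberately sensed by no
modeled cell, as a null output).  Demo defaults: `L=10, ρ=0.25` (≈250
cells), `r_C=0.6`, `s=0.07`, `R=5`, `K_PCC=0.6`, `K_PSC=0.4` — thresholds
sit between the all-basal background (~ρ) and actively sourced fields, the
regime where communication, rather than saturation, decides phenotypes.

Because targets are self-generated, calibration tests demonstrate
*parameter recovery and optimizer correctness*, not fidelity to tumor
biology; cohort-scale conclusions about real samples require the real
deconvolved inputs, which this package only consumes.  Likewise the
synthetic cohort reproduces only the rank structure the cost sees, not the
distributional shape of real expression data.

## Desk-scale problem sizes

The bundled experiments run on one CPU core: plateau (10 runs × 100
steps), interplay PRCCs (200 LHS sets × 5 runs × 100 steps per protocol),
calibration benchmark (10 samples; SA at the default schedule, ~1,080
evaluations of 3 × 50-step runs; best-of-20 random baseline re-scored
identically with a 24-run ensemble),
perturbation screens (5 fractions × 15 replicates × 100 steps).  These
sizes were chosen once against the measured plateau onset and kept fixed.

## Known limitations

* No cell division, death, motility, or mechanics; positions and counts
  are frozen for a simulation (signaling-timescale snapshot).
* No cytokine uptake and no transient diffusion; spatially uniform D and
  γ_D.
* Synchronous updates only; no asynchronous/continuous-time semantics.
* The σ(ρ_max) closed form satisfies the stated density cap but other
  constant conventions are possible.
* PRCC is a rank-linear partialing; strongly non-monotone,
  interaction-driven responses (threshold crossings) depress its
  magnitude — visible in the demo's single-loop protocols.
* The exact stationary oracle is O(4^n) and limited to 12 regulatory nodes.
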