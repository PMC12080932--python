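# Model and methods

`thrombosim` simulates platelet deposition and thrombus growth in small
vessels by coupling four solvers on one cubic lattice. This note records
the model equations, the tunable parameters and their defaults, the
numerical choices, what the synthetic donor generator does and does not
emulate, and the known limitations.

## Domains and lattice conventions

Two voxelized vessels are built from analytic shapes:

* **venous case** — a straight vessel, 0.5 mm long, 0.12 mm diameter,
  with a reactive collagen patch 0.25 mm long centered axially and
  covering half the circumference (in 2D: the bottom wall);
* **arterial case** — a 1 mm vessel of 0.12 mm inlet diameter with a
  smooth axisymmetric constriction over the central 0.5 mm that removes
  75% of the flow area at the apex. The wall radius follows
  `r(x) = R sqrt(1 - f w(x))` with a C¹ cosine bump `w`; collagen covers
  the constricted wall. The profile shape is a modeling choice (only the
  end areas are constrained); a cosine avoids staircase corners at the
  constriction edges.

Flow is along +x. Axial node columns sit at `x_i = i Δx` with
`floor(L/Δx)+1` columns; transverse coordinates are staggered half a
spacing so the nominal wall falls exactly on the half-link where
full-way bounce-back places the no-slip plane. In 2D the domain is the
axial–radial center plane (a plane channel of height equal to the local
diameter). One platelet occupies one lattice node.

## Blood flow (lattice Boltzmann)

Blood is incompressible and Newtonian (ν = 3.1 × 10⁻⁶ m²/s). The LB
solver uses a two-relaxation-time collision operator with the "magic"
parameter Λ = 3/16, which pins the bounce-back wall to the half-link for
any relaxation time; the even relaxation time τ_LB sets the viscosity
and is chosen per case (0.8 venous, 0.65 arterial, 1.2 for the fast
re-solves of desk-scale growth runs) to balance compressibility error
(δρ < 1%) against relaxation cost. The inlet imposes the Poiseuille
profile whose wall shear rate is prescribed (u_max = γ_w R/2 in both the
2D channel and the 3D pipe), with inlet density extrapolated from the
first interior column; the outlet fixes the reference pressure (ρ = 1)
with extrapolated velocity. Bound platelets become bounce-back nodes;
re-solves warm-start from the previous distributions and nodes freed by
detachment are re-seeded at local equilibrium.

Convergence is declared when the relative L2 velocity change per 100
steps falls below 10⁻⁶ (10⁻⁵ for the quasi-static in-run re-solves,
which start very close to the solution; the warm-started field is then
within ~10⁻⁴ of the fully converged one).

Two safeguards handle heavy occlusion, where a velocity inlet is
otherwise singular: (i) the imposed profile is throttled once the
estimated peak lattice velocity through the narrowest inlet-connected
cross-section (sealed pockets are excluded by a connectivity fill)
exceeds a cap; once the narrowest conveying section pinches to two
nodes or fewer the vessel counts as occluded and the exact stagnant
solution is returned (a 1–2-node tortuous thread is below the
resolution at which lattice flow through it means anything); (ii) if
the iteration diverges the throttle is halved and the field restarted
from equilibrium, and a residual stalled in a small bounded oscillation
(< 10⁻³ relative) is accepted as converged. Physically the throttle
mimics the finite pressure head available to drive flow through a
nearly occluded vessel.

The local shear rate is `γ = sqrt(2 S:S)` from centered differences of
the velocity; against walls a one-sided quadratic fit through the node,
its neighbor and the zero-velocity half-link is used (exact for
parabolic profiles).

## Agonist transport (finite volume)

ADP and thromboxane A2 obey convection–diffusion equations with release
sources, solved by an explicit, conservative first-order upwind scheme
(positivity-preserving under the CFL bound the solver computes).
Boundary conditions: zero concentration at the inlet (advective-only
face), convective outflow at the outlet, no flux through walls. Bound
platelets are treated as a porous aggregate: their nodes stay in the
transport domain with zero velocity, so intra-clot transport is
diffusion-dominated and granule release from buried platelets
accumulates inside the deposit — this is what produces the elevated
intra-clot agonist levels seen in the field snapshots.

Diffusivities (literature small-molecule values): D_ADP = 2.4 × 10⁻⁶,
D_TXA2 = 2.1 × 10⁻⁶ cm²/s. Release: a platelet whose activation crosses
the threshold releases its dense-granule ADP content Q_ADP
(default 1500 μM per cell volume) with first-order rate k_rel = 0.1 s⁻¹
and synthesizes TXA2 at q_TXA2 = 0.15 μM/s while bound. These
release magnitudes are not independently measurable at this scale; they
were chosen once so that relative scenario effects are meaningful —
intra-clot ADP reaches the μM scale where the P2Y12 axis responds, and
the ADP loop dominates the TP (TXA2) loop, matching the observed
potency ordering of inhibiting either pathway.

## Platelet signaling (donor-specific networks)

Each platelet's cytosolic calcium is predicted 1 s at a time by a
feed-forward network with 14 inputs: the six agonist concentrations
(ADP μM, convulxin nM, thrombin nM, U46619 μM-equivalents, iloprost nM,
GSNO μM) and the platelet's own calcium at lags 1, 2, 4, 8, 16, 32, 64
and 128 s (basal-padded before entry). The architecture is two hidden
layers of 12 tanh units with a linear output (the alternative
single-hidden-layer reading of "two-layer, 12-node" is a config
option). Agonist inputs pass through log1p before standardization — a
monotone reparameterization that lets one network resolve dose grids
spanning two decades.

Collagen contact enters as convulxin at an effective 10 nM; local TXA2
as U46619 at 15 × [TXA2]. A platelet counts as collagen-contacting only
if bound directly to a collagen node (GPVI is a contact receptor).
Scenario transforms are applied last: `no-adp`/`no-txa2`/`no-both` zero
the corresponding inputs (clopidogrel/aspirin idealized as complete
inhibition); `gsno` and `iloprost` add a constant endothelial
antagonist dose (1 μM and 10 nM — the top of the PAS dose grid);
`tf` supplies intra-clot thrombin from a reduced generation curve
(lag phase, then a saturating rise whose plateau and speed grow with
the wall tissue-factor density), applied to bound platelets over the
collagen patch span, where the wall-derived TF lies.

Activation integrates supra-basal calcium, `ξ(t) = ∫([Ca]ᵢ - [Ca]₀)dt`,
exactly as written — negative excursions subtract; ξ is not rectified.
Adhesiveness follows the Hill map
`F(ξ) = α_min + (α_max - α_min) ξⁿ/(ξⁿ + ξ₅₀ⁿ)` with α_min = 0.01,
α_max = 1, n = 2; crossing ξ_crit triggers irreversible dense-granule
release. ξ₅₀ and ξ_crit are not free: they are calibrated cohort-wide
(below).

## Platelet motion and bonding (lattice KMC)

Rejection-free KMC with a rate catalog: per mobile platelet, directional
hops `D_p/Δx² + max(0, u·ê)/Δx` (effective RBC-augmented diffusivity
D_p = 2.5 × 10⁻⁷ cm²/s, upwind convection at the local velocity);
attachment when adjacent to collagen or bound platelets,
`k_att⁰ F W(γ)`; slip-bond detachment `k_det⁰ (1/F) exp(γ/γ_c)`.
The vWF factor `W(γ) = 1 + (W_max - 1) σ((γ - γ_vWF)/s_vWF)` (rescaled
so W(0) = 1) switches on across the pathological-shear window with
midpoint 4000 s⁻¹, width 500 s⁻¹ and plateau W_max = 150: W must
outgrow the ~1/γ near-wall residence time for capture to concentrate at
the stenotic apex. Platelet–platelet attachment uses the pair maximum
F_eff = max(F_p, F_q), so an activated deposit recruits passive flowing
platelets — with 1 s signaling resolution a transiting platelet cannot
itself activate, and this is the recruitment pathway that makes
secondary agonist release matter.

Bond prefactors are calibrated so that (a) a quiescent collagen surface
at venous shear acquires a monolayer within about a minute, (b) passive
(F = α_min) platelet–platelet tethers are transient — they must release
faster than stagnation-zone corners can accumulate them, or unactivated
paving creeps along the wall — and (c) detachment of activated
platelets is negligible below 1000 s⁻¹. γ_c = 3000 s⁻¹ keeps passive
apex bonds alive long enough for contact activation while detachment
still grows steeply into pathological shear.

Insertion: a Poisson stream at the inlet with the flux-weighted
near-wall-excess density `φ(r) = 1 + (E-1) e^{-(R-r)/δ}` (E = 4,
δ = 6 μm — the margination imposed by unresolved red cells), normalized
so the mixing-cup concentration equals the bulk platelet count
1.5 × 10⁵ μL⁻¹ exactly. 2D domains count a slab one lattice spacing
deep. Desk-scale runs may restrict simulated insertions to a near-wall
band (default 18 μm; matrix runs 12 μm): a platelet inserted farther
than a couple of diffusion lengths from the wall cannot reach it within
the domain, so skipping it changes nothing but cost. A blocked inlet
node is redrawn from the same density so transient occupancy does not
bias the inlet flux.

Event selection is rate-proportional with exponential waiting times;
platelet ids are never recycled and the insert/attach/detach/exit log
replays the deposited count exactly. A platelet whose last bound
neighbor detaches cascades back to the mobile state. The production
event loop is a numba kernel over flat node arrays; a test cross-checks
it against the pure-Python execution of the same source on identical
seeds (this guards against a control-flow miscompilation observed with
`continue`/`break` inside `while` loops, which the kernel therefore
avoids).

## Coupling schedule

Master horizon 0.1 s: the KMC event loop runs within each horizon with
the scheduled insertion stream merged in; transport is sub-stepped at
its stable dt (skipped while fields and sources are identically zero);
signaling updates every platelet each 1 s (the NN feedback grid);
the flow re-solves after 20 net new deposits, or at 1 s boundaries when
the deposit changed — re-solves are skipped while fewer than 10 nodes
changed, bounding the quasi-static lag at a few voxels. Runs are
bit-reproducible from (config, seed), and scenario runs sharing a seed
consume the random streams identically until the first signaling
divergence, which makes paired scenario comparisons low-variance.

## Synthetic donors and calibration

The generator stands in for human pairwise-agonist-scanning (PAS) data:
256 s calcium traces at 1 s resolution under singles (3 doses: 0.1×,
1×, 10× the cohort-median EC50; convulxin additionally at the 10 nM
effective collagen-contact dose, since every platelet on collagen
experiences exactly that input) and all pairwise dose combinations of
the six agents, plus a basal record. Each activating agonist
contributes `R_a(dose) g_a(t)` with a Hill dose response and a
unit-peak rise/decay kernel; co-applied activators add a synergy term
`S_ab min(R_a, R_b) g_ab(t)`; iloprost and GSNO multiply the
supra-basal response by IC50 factors. Donor heterogeneity comes from
documented log-normal spreads around cohort medians; GSNO sensitivity
is given a wide spread (some donors barely respond to nitric oxide,
some are silenced). The effective collagen response at the 10 nM
contact dose is pinned to a stratified log-grid of total ratio 4.2 —
through the response-kernel integral this maps to first-release times
spanning roughly 60–240 s once the threshold is calibrated. ADP is made
the dominant secondary mediator (higher amplitude and potency than the
TP axis), consistent with the potency ordering of P2Y12 vs TXA2
inhibition.

Per donor, the network is trained by teacher forcing (scikit-learn
MLP, Adam, fixed epochs and seed — fully deterministic) on all but a
20% held-out split of the pairwise conditions. Lag features receive
small Gaussian jitter (0.03 μM) during training; without it the network
is accurate one step ahead but drifts in closed loop. Fidelity is
measured in free-running rollout and normalized by the donor's full PAS
dynamic range (per-condition ranges would let noise-scale flat traces
dominate the score); the requirement is mean NRMSE < 0.15, and trained
cohorts come in at 0.01–0.04. A deterministic closed-loop correction
round follows (lag features from the network's own rollouts, generator
targets), which removes the compounding bias teacher forcing leaves on
long response plateaus; with it, the network's collagen-driven release
times agree with the generator's within ~5% per donor.

Calibration then fixes one cohort-wide (ξ₅₀, ξ_crit): each donor is
rolled out under constant collagen contact, ξ(t) integrated, and
ξ_crit bisected so the fastest donor releases at 60 s; ξ₅₀ = ξ_crit/2
(so a platelet at the release threshold has F ≈ 0.8 and recruits).
Donors that cannot cross within 6 minutes abort calibration with the
achievable range reported.

An "oracle mode" donor bypasses the network and integrates the
generator's own response kernels against each platelet's agonist
history (piecewise-constant drive increments); it is used to verify
that the trained surrogate is a faithful drop-in replacement in full
simulations.

### What the generator does not emulate

Synthetic donors reproduce the *structure* of PAS data — six-input dose
dependence, pairwise synergy, inhibitor suppression, donor-to-donor
spread — not any real individual's biology. Passing cohort-level tests
therefore shows that the pipeline propagates signaling heterogeneity
into thrombus-growth heterogeneity as designed; it does not validate
the magnitudes of any real donor's responses, nor intra-donor platelet
subpopulations (all of a donor's platelets share one model).

## Desk-scale problem sizes

Study-condition lattices are 3 μm (one platelet per node). The scenario
matrix (10 donors × 7 scenarios, paired seeds) runs the venous case in
2D at 8 μm spacing and 180 s duration; the stenotic spatial check runs
90 s at 6 μm (the 8 μm lattice leaves only ~7 nodes across the apex
gap, too coarse to resolve the high-shear window against the deposit).
These sizes keep full-matrix behavior checks to minutes while
preserving the mechanisms under test; the 3 μm benchmarks (flow,
geometry) are retained where the quantitative targets live. At 8 μm a
platelet is represented by a coarser voxel than its physical diameter;
deposited counts are therefore comparable only within a lattice, which
paired-seed scenario ratios respect.

## Known limitations

* 2D center-plane hemodynamics at desk scale; 3D is supported but only
  exercised coarsely.
* No explicit red cells (margination enters through the inlet excess
  and the effective platelet diffusivity), no fibrin mechanics, no
  platelet shape change, no pulsatility.
* The adhesion/detachment rate forms are declared interfaces with
  calibrated constants, not measured kinetics; the vWF switch is a
  smooth phenomenological factor.
* Thrombin appears only through the reduced intra-clot generation
  curve (a parameterized lag/rise/plateau surrogate isolated behind one
  function, so a full coagulation ODE model can be dropped in).
* Complete (100%) inhibition is assumed for the pharmacological
  scenarios; graded inhibition would be a config extension.
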