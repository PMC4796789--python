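# Methods

## Model overview

`cldend` simulates intracellular chloride in dendrites represented as
graphs of cylindrical compartments: a chain (or tree) of shaft cylinders
with spines — a thin neck cylinder capped by a head cylinder — hanging off
it. Two engines share this representation:

* a **deterministic** solver for the coupled Cl⁻ concentration / membrane
  dynamics (diffusion, extrusion, synaptic flux, reversal potentials,
  optionally passive voltage), and
* a **stochastic** engine that treats Cl⁻ as discrete particles hopping
  between volume elements under an exact spatial Gillespie SSA.

All internal units are μm, ms, mM, nS, mV, pA; F = 96485.332 C/mol and
R = 8.3145 J/(mol·K) live in `cldend.units`, together with the worked unit
check that 20 pA into 1 μm³ for 1 ms raises [Cl⁻]_i by 0.207 mM.

## Deterministic engine

**Diffusion.** Fick's law on the compartment graph: the flux between
neighbors i, j is J = D_Cl·A_ij·(C_j − C_i)/d_ij, with A_ij the coupling
cross-section (for a spine, the neck cross-section π r_neck² on both the
shaft–neck and neck–head edges) and d_ij the center-to-center distance.
Volume-normalizing gives a graph Laplacian L with L_ij = D·A_ij/(V_i·d_ij);
the step C ← (I − Δt·L)⁻¹C is backward Euler, factorized once with sparse
LU. Two properties make this scheme well suited here:

* it is unconditionally stable, so thin spine necks (which give jump rates
  ≈ 2 ms⁻¹ out of a 0.04 μm³ neck) do not constrain Δt;
* it conserves mass to machine precision (Σ V_i C_i is an exact invariant
  of the discrete update), and on a uniform interior lattice the second
  moment of the profile grows at exactly 2·D·Δt per step independent of
  Δt, so the free-diffusion metrics carry no time-step bias.

Ends are sealed (zero flux): boundary compartments simply lack a neighbor.

**Radial shells.** Optionally each shaft compartment is split into a
cylindrical core plus N equal-thickness concentric shells (default N = 4
when enabled). Radial exchange uses the interface area 2π r L over the
shell spacing; axial exchange couples matching shells of adjacent
compartments with annulus cross-sections; spines attach to the outermost
shell. Shells are **off by default**: the axial metrics are computed from
radially uniform initial conditions and are insensitive to the radial
discretization (verified by a dedicated test at 1% tolerance). Shells
cannot be combined with the passive cable (voltage is a per-compartment
membrane quantity); the solver raises in that case.

**Extrusion.** KCC2-like transport is a first-order relaxation
d[Cl⁻]/dt = −([Cl⁻] − Cl_rest)/τ_Cl with τ_Cl = 3000 ms and
Cl_rest = 5 mM, applied as its exact exponential over each step, on a
per-compartment mask (uniform, distal-thirds, spines-only, spines + parent
shafts, or off).

**Synapses.** Each GABA_A synapse has a double-exponential conductance
g(t) = g_max·N·(e^(−t/τ₂) − e^(−t/τ₁)), τ₁ = 0.5 ms rise, τ₂ = 6 ms decay,
normalized so the per-event peak equals g_max; events superpose linearly
(integrated as the standard two-state exponential form). The conductance
splits into parallel Cl⁻ and HCO3⁻ branches by the fractional conductance
P = 0.25: I_Cl = (1−P)·g·(V−E_Cl), I_HCO3 = P·g·(V−E_HCO3), with positive
I_Cl meaning Cl⁻ influx. Only the Cl⁻ branch moves mass:
Δ[Cl⁻]_i = I_Cl·Δt/(F·V). HCO3⁻ pools are held constant.

**Reversals.** E_Cl and E_HCO3 are Nernst potentials at 308.15 K; E_GABA
is the conductance-weighted mean (1−P)·E_Cl + P·E_HCO3, recomputed every
step from the instantaneous local [Cl⁻]_i. At the resting concentrations
(5/133.5 and 16/26 mM) this gives E_Cl = −87.2 mV, E_HCO3 = −12.9 mV,
E_GABA = −68.64 mV. The weighted-mean convention (rather than GHK) is a
deliberate choice: it is the form consistent with a two-branch conductance
model, and it reproduces the resting E_GABA from the resting
concentrations exactly.

**Voltage.** By default the membrane potential is clamped at
V_rest = −70 mV, so the synaptic driving force changes only through E_Cl.
This is the right default for the plasticity experiments here, whose
outcome is dominated by the Cl⁻ load rather than by millivolt-scale
voltage excursions, and it avoids committing to passive parameters the
scenario definitions do not pin down. A passive cable is available
(`CableParams`: R_m = 20 kΩ·cm², C_m = 1 μF/cm², R_a = 150 Ω·cm, backward
Euler with synaptic conductances folded into the system matrix); these
defaults are conventional placeholder values for a passive dendrite, not
measurements, and are labeled as such. `implicit_spine_factors` returns
the area factor F for absorbing spines into the shaft membrane (C_m×F,
R_m/F); the head contributes its lateral plus distal-cap area by default
(`include_head_cap=False` gives the lateral-only convention).

**Time steps.** Default Δt = 0.5 ms for pure-diffusion runs and 0.05 ms
for synaptic runs (to resolve the 0.5 ms conductance rise). The solver
checks recorded states for negative concentrations and raises a
`SolverError` advising a smaller step — reachable only through the
explicit synaptic source term, since diffusion and pump steps are
positivity-preserving.

## Stochastic engine

`voxelize` partitions a morphology into volume elements (shaft slices at
≤ target_dx, one voxel per spine head/neck) with per-particle jump rates
k_ij = D_Cl·A_ij/(V_i·d_ij) — the diffusion coefficient is the only
physical parameter. Cylinder voxels stand in for tetrahedral mesh
elements: the SSA operates on any volume partition, and the jump rates
depend only on areas, volumes and distances, so the stochastic physics is
preserved while the meshing dependency is removed.

`ssa_run` is the direct-method SSA: waiting times are exponential in the
total propensity Σ_i n_i·k_i^out, and the jump category is sampled
proportionally to propensity. A Fenwick tree over per-voxel propensities
gives O(log n) selection and update per event (the same logarithmic-class
idea used by large reaction–diffusion simulators); the kernel is compiled
with numba, and a 100-replicate × 10⁴-particle ensemble on a 100 μm graph
(≈4×10⁸ events) runs in under a minute. Runs are bit-reproducible per
seed. Particle number is conserved exactly. `to_concentration` maps counts
to mM through a configurable particles-per-(mM·μm³) factor; the diffusion
metrics themselves need only mass weights, so comparisons between engines
are conversion-free.

The deterministic reference for engine-agreement tests is the matrix
exponential of the same jump generator (`expm_multiply`), i.e. the exact
expected occupancy of the identical Markov process — the comparison
isolates stochastic sampling error from discretization differences.

## Diffusion metrics

The axial profile at time t is built from **shaft compartments only**
(spine content is excluded; a flag folds it in at its attachment position
— for uniform-diameter shafts the two conventions give identical variance
for the total distribution, and shaft-only is the convention adopted
throughout). Weights are baseline-subtracted concentration × compartment
volume, clipped at zero (clipped mass is reported) and normalized to 1 —
a true displacement distribution of the released ions. Then

* ⟨x²⟩(t) = Σ C_n(x)(x − r_m)², r_m = Σ C_n(x)·x (the centroid);
* D_app(t) = (⟨x²⟩(t) − ⟨x²⟩₀)/(2t) — the 1-D convention, which makes
  D_app = D_Cl exact for free axial diffusion;
* λ = sqrt(D_Cl/D_app) at the end of the run (4000 ms for the standard
  focal-release experiment); D_app ≤ 0 returns λ = ∞ as the
  blocked-diffusion sentinel.

`max_slope_profile` reports, per shaft compartment, the maximum
finite-difference temporal slope of [Cl⁻]_i over a window — the measure of
how sharply the synaptic Cl⁻ transient rises at increasing distance from
the synaptic zone (it decays monotonically away from the zone: the
dendrite low-pass filters the transient).

## Standard experiments and problem sizes

* **Density sweep**: 700 μm × 1 μm cylinder at 1 μm resolution, spines at
  {0, 2, 5, 10, 15}/μm with head 0.6 × 0.55 μm and neck 0.2 × 1.25 μm,
  focal release 5→10 mM in the central 1 μm, 4000 ms at Δt = 0.5 ms.
  Spine placement is uniform i.i.d. with count = round(density × length)
  (several spines may share a shaft compartment); seeds make placements
  reproducible, and sweep statistics average ≥ 3 seeds.
* **Pump layouts**: same release, pump off / uniform / distal-thirds /
  spines-only / spines+shafts. A uniform pump rescales the deviation field
  by e^(−t/τ) without changing the normalized profile, so it leaves λ
  unchanged (the suite checks < 2%); only nonuniform layouts distort the
  profile, and far less than spines do.
* **Ionic plasticity**: 200 μm × 1 μm cylinder, 11 shaft synapses evenly
  spread over 89–111 μm (0.5/μm), synchronous 10 Hz × 30 pulses at
  g_max = 1 nS, uniform pump, Δt = 0.05 ms; probes at 110 and 190 μm,
  spatial profiles at t = 3000 ms (end of the train). The volume-matched
  smooth control widens the diameter by π d'²/4 = π d²/4 + ρ·V_spine
  (1 μm + 2 spines/μm → 1.22 μm; + 5/μm → 1.50 μm).
* **Branched trees**: SWC morphologies (hand-written fixtures, generated
  cylinders, or the procedural `synthetic_tree_swc` archetypes — labeled
  synthetic; they are not reconstructions), spines attachable tree-wide,
  metrics along the longest root-to-tip path with path distance as the
  axial coordinate.
* **Engine agreement**: 100 μm graph, 10⁴ particles, up to 100 replicates;
  ensemble-mean shaft variance within 3 SE of the exact expectation.

These sizes are the package's standard desk-scale conditions; the unit
tests run reduced variants (shorter cylinders/horizons) of the same
scenarios, and the full-scale versions live in the acceptance suite.

## What the synthetic generator does and does not emulate

The generator reproduces the *geometric* determinants of dendritic Cl⁻
dynamics — shaft caliber, spine density and spine head/neck proportions,
branching — and the canonical physiological parameters (D_Cl = 2 μm²/ms,
τ_Cl = 3 s, resting gradients). It does not emulate: heterogeneity of real
spine shapes (all spines share one geometry per run), GABAergic synapses
on spines (all synapses target shafts), active conductances or spiking,
electrodiffusion (ionic fluxes do not feel the local field), Cl⁻ buffering
or organelle stores, or immobile-charge effects. Passing tests therefore
demonstrate the geometric trapping mechanism and its consequences for
E_GABA dynamics under these idealizations, not a quantitative match to any
particular measured dendrite.

## The spine-density effect, quantitatively

For spines exchanging rapidly with the shaft (neck equilibration here is
~10 ms, far shorter than the 4000 ms observation window), two-phase
homogenization gives

    D_app/D_Cl  →  V_shaft / (V_shaft + ρ·V_spine)   per unit length,

i.e. the shaft-resident fraction of the diffusing ions. With the canonical
spine (V_spine ≈ 0.195 μm³) on a 1 μm shaft (0.785 μm³/μm) this predicts
reductions of 33.2% at 2 spines/μm and 78.8% at 15 spines/μm; the solver
computes 33.1% and 78.5% at 4000 ms, and the tests assert the monotone λ
trend on this basis. This closed form serves as an independent oracle for
the sweep, alongside the SSA/deterministic cross-validation.

## Numerical conventions and degenerate inputs

* Seeded `numpy.random.default_rng` everywhere; identical seeds give
  bit-identical morphologies, trains, and SSA runs.
* Cylinder discretization: ceil(L/dx) compartments, last one shortened so
  total length is exact; a single-compartment cylinder is valid.
* Spine attachment with density 0 returns a graph-isomorphic copy;
  negative densities, nonpositive dimensions, malformed SWC records
  (reported with line numbers), disconnected graphs, zero-mass profiles,
  and t = 0 in D_app all raise explicit errors.
* Float ties in nearest-compartment lookups resolve to the lower index
  (`argmin` semantics).

## Known limitations

* The paper-style "20–70%" reduction range is not reproduced under the
  canonical spine geometry; the model's own volume-balance arithmetic
  (above) yields 33–79%, and the package reports its computed values.
* The stochastic engine covers diffusion only (no extrusion/synapses), by
  design.
* SWC import collapses a type-1 soma to one equivalent cylinder and treats
  all neurite types as dendrite.
* The passive cable is first-order accurate in Δt and intended for
  qualitative voltage behavior; active channels are out of scope.
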