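# Methods

`chemocycle` simulates the response of a vascularized solid tumor to
sequential chemotherapy cycles. One cycle couples four submodels — blood flow
in a discrete capillary network, interstitial fluid flow in the tissue, drug
transport and cellular uptake, and cell-kill plus regrowth bookkeeping — and
the cycle loop iterates them over a dosing schedule. This note describes the
model, the numerical choices, the default parameter set and why each value
was chosen, and what the synthetic geometry does and does not represent.

## Model

### Intravascular flow

The vasculature is a graph of straight segments. Each segment carries
Poiseuille flow `Q = πD⁴ΔP/(128 μ_app L)` with the apparent viscosity
`μ_app = μ_plasma · μ_rel(D, H)` given by the empirical in-vitro law for
blood in microvessels (diameter- and hematocrit-dependent, anchored at the
reference hematocrit 0.45, singular at D = 1.1 µm). Hematocrit is constant at
0.45 on all segments (configurable per segment); red-cell phase separation at
bifurcations is out of scope. Nodal pressures solve a sparse linear system:
at every interior node the segment flows balance the node's share of the
transvascular (Starling) leakage

    Q_t = πDL·L_p·(P_b − P_i − σ_s(π_b − π_i)),

evaluated with the segment-midpoint blood pressure and the interstitial
pressure sampled at the midpoint, split equally between the two endpoint
nodes. Inlets and outlets carry Dirichlet pressures, default 3330 Pa and
1330 Pa. The inlet value was chosen so the maximum intravascular pressure of
the solved network matches the ~3.3 kPa scale reported for comparable
microvascular simulations; both are configuration keys.

### Interstitial flow

The tissue is a porous medium: `v_i = −κ∇P_i`, `∇·v_i = φ_B − φ_L`, with
`φ_B = L_p(S/V)(P_b − P_i − σ_s(π_B − π_i))` the capillary source and
`φ_L = L_PL(S/V)_L (P_i − P_L)` the lymphatic sink, clamped at zero (no
lymphatic backflow; the clamp is implemented as a small active-set iteration
and is inactive in the default configuration, where P_L = 0). Lymphatics
function only in normal tissue. The elliptic problem is discretized with a
conservative five-point finite-volume stencil, harmonic-mean interface κ, and
Dirichlet `P_i = 0` on the outer boundary; the domain is two tumor diameters
wide so the far boundary is passive. The sparse system is solved directly.
The network and tissue solves exchange `P_i` at segment midpoints and the
cell-averaged blood pressure field, iterated to a fixed point (tolerance
0.1 Pa on max |ΔP_i|, cap 50 iterations; 3–6 iterations in practice).

On the default geometry this produces the classic solid-tumor phenotype:
elevated core interstitial pressure (~1.1 kPa vs ~0.1 kPa in normal tissue)
with a steep drop across the tumor rim, peak intravascular velocities of
order 10⁻² m/s in the thoroughfare channels, and a median tumor interstitial
fluid velocity of ~0.03 µm/s.

### Vessel-to-grid mapping and source regularization

Each segment's wall area `πDL` is distributed over the grid cells its
centerline crosses, proportional to the intersected length (exact geometric
clipping; total wall area is conserved to round-off). The resulting surface
density field is then regularized with a Gaussian of 25 µm — the scale of a
capillary's perivascular exchange territory. Without this (Krogh-territory)
lumping, a coarse grid lets freshly extravasated drug wash straight back
through the wall of its own cell; physically, re-entry is rare (the wall
Biot number P·δ/D is ≪ 1 at the true wall scale). The regularization
conserves the field total exactly.

### Drug transport

Three species per cell — free (C_F), bound (C_B), internalized (C_INT) —
follow a convection–diffusion–reaction system: upwind advection by the
Darcy velocity, Fickian diffusion of free drug, receptor binding at rate
`(1/φ)K_ON·C_rec·C_F`, dissociation `K_OFF·C_B`, internalization
`K_INT·C_B`. Binding sites are conserved, `C_rec = C_rec0 − C_B − C_INT`
(floored at zero); a constant-receptor mode is not provided because site
conservation is what produces dose-saturation effects. Plasma concentration
decays as `C_P = C_0·exp(−t/K_d)` per bolus, `K_d = t½/ln 2`, with
superposition across boluses. Transvascular exchange uses the Patlak form

    Φ_B = φ_B(1−σ_f)C_P + (PS/V)(C_P − C_F)·Pe/(e^Pe − 1),
    Pe  = φ_B(1−σ_f)/(PS/V),

with the Pe → 0 limit handled analytically; lymphatic removal is
`Φ_L = φ_L C_F`. The outer boundary is no-flux for the drug (it is far from
the tumor and carries negligible concentration), so the global mass balance
of `C_F + C_B + C_INT` closes against the integrated `Φ_B − Φ_L` alone; the
reaction terms cancel identically in this sum, which fixes the bookkeeping
convention for the accessible-volume factor φ (it appears inside the binding
rate, not as a weight on the conserved density).

**Time integration.** The binding term is stiff (rates up to ~10 s⁻¹ against
a 24 h horizon) and receptor-saturation fronts make generic stiff integrators
refactorize constantly. The default integrator is therefore purpose-built:
variable-step BDF2 with a backward-Euler startup, on a geometric step ladder
(0.5 s initial step, growth 1.08, cap at horizon/60; the ladder restarts at
each bolus). At each step the local C_B/C_INT unknowns are eliminated in
closed form — the implicit bound-drug equation is linear in C_B for given
C_F — leaving one N-cell Newton problem whose matrix is the constant
transport operator plus a diagonal state modification. The factorization
persists across steps and is redone only when the frozen-matrix iteration
stalls. The scheme preserves non-negativity (projected Newton plus an
M-matrix transport solve) and the monotonicity of C_INT (an induction over
the BDF2 recurrence, since its history weights satisfy a₁ − 1 = a₂), and
closes the global mass balance to Newton tolerance (~10⁻¹³ relative in
practice). Against an independent well-mixed stiff-ODE reference, all three
species stay within 1% at the default ladder; a generic method-of-lines path
(scipy BDF with an analytic sparse Jacobian) is retained as `method="bdf"`
for cross-validation and agrees with the default path to <0.1% on C_INT.

### Pharmacodynamics

The surviving fraction per cell is `S_F = exp(−ω·C_INT)` at the end of the
delivery phase (end-of-phase C_INT rather than an AUC basis; C_INT has
plateaued well before 24 h at the default uptake rate, and the AUC is
reported alongside). The aggregate killed fraction is one minus the
area-weighted mean of S_F over the region mask; the same formula on the
normal-tissue mask is the cycle's side effect. ω for doxorubicin is not
tabulated; it is calibrated **once** so that the baseline full-dose
first-cycle tumor FKC on the default seeded geometry equals 0.3678, giving
ω = 59.788581 m³/mol, frozen in the defaults. This is a calibration, not a
literature constant.

### Treatment cycles

Per injection event: solve coupled flow on the current geometry; run the
delivery phase (24 h by default, capped by the following break); compute
tumor FKC and normal-tissue FKC; update the cell counts
`N ← N(1 − FKC)`; regrow over the drug-free remainder of the break with the
Gompertz law

    n(t) = N·exp{ln(N_∞/N)·[1 − e^(−b·t)]},

tumor at full rate b = 0.0283 month⁻¹ (N₀ = 5×10⁹, N_∞ = 3.1×10¹²), healthy
tissue at b/2 with its baseline N₁ = 4.64×10¹² as carrying capacity; then
rescale the tumor radius by `(N_new/N_old)^(1/3)` (the planar grid is the
mid-plane slice of a spherical tumor whose cell number tracks volume) and
rebuild the masks. The capillary network structure is held fixed across
cycles; segments left outside the shrinking tumor adopt normal-tissue wall
parameters. Dose fractions scale the plasma peak linearly. The cumulative
side effect is `1 − N_healthy/N₁`. Histories record, per cycle, the kill and
regrowth in percentage points of N₀ (the convention of the reference cycle
chain), the per-cycle surviving fraction, and the radius.

Regimen builders: MTD = dose 1.0 every 0.5 month; LDC/metronomic = 0.2 every
0.1 month; chemo-switching = repeating block [1.0, 0.5-month break, five 0.2
doses at 0.1-month spacing]. Events landing exactly on the horizon are
included — this reproduces the reference comparisons, in which the "75-day"
MTD arm contains six events (cumulative dose 6.0 C_p) against 5.2 C_p for
the other two arms, which is what makes MTD's side effects the largest.

## Synthetic vasculature: what it emulates and what it does not

The real study geometry (a vascular network segmented from a histology
image) is not available, so a seeded generator builds a stand-in with the
architectural features that drive delivery physics:

* a jittered capillary lattice spanning a 2 mm × 2 mm window, trimmed to a
  target surface density of 20 000 m⁻¹ measured over a 40 µm slab;
* an **angiogenic rim**: tumor-rim density 2.5× normal tissue, with the
  tumor core (inside 0.6 R_t) rarefied to 0.15 of the rim density — the
  compressed, poorly-perfused center of solid tumors;
* two **thoroughfare channels** (40 µm feeding/draining vessels) routed
  around the core, which set the physiological peak-velocity scale;
* inlets on the left boundary, outlets on the right, pruned to one perfused
  component; the realized surface density lands within a few percent of
  target (hard-checked to ±10%).

Identical seeds give identical networks. The generator does not attempt
tortuosity statistics, diameter-flow correlations (Murray's law), red-cell
phase separation, or angiogenic remodeling between cycles; conclusions that
depend on those features do not transfer. Passing trend tests on this
geometry show that the *model* responds in the reported directions under a
plausible tumor architecture — not that any particular patient geometry
would.

## Default parameters

Tissue (per region, tumor / normal; surfaced under `tissue:` in the config):
hydraulic conductivity L_p 2.1×10⁻¹¹ / 2.7×10⁻¹² m Pa⁻¹s⁻¹; Darcy κ
3.1×10⁻¹⁴ / 6.4×10⁻¹⁵ m² Pa⁻¹s⁻¹; osmotic reflection 0.82 / 0.91; π_b
2660 Pa; π_i 2000 / 1330 Pa; lymph coefficient 0 / 1.042×10⁻⁶ Pa⁻¹s⁻¹.
These are the standard porous-tumor modelling values. Two region factors
scale the drug interaction: normal vessels pass drug at 0.1× the tumor-wall
permeability (non-leaky continuous endothelium vs angiogenic vessels), and
normal tissue carries 0.2× the binding-site density — the healthy:tumor cell
*density* ratio of 0.2 applied to binding sites, since sites scale with
cells.

Drug (doxorubicin-like): diffusivity 3.4×10⁻¹⁰ m²/s, association rate
15 m³ mol⁻¹s⁻¹, plasma half-life 6 min (the baseline sweep states are 0.5×/
1×/~3× diffusivity, 0.1×/1×/10× affinity, 0.5×/1×/2× half-life);
dissociation 10⁻³ s⁻¹ (slow DNA-intercalation off-rate), cellular uptake
10⁻² s⁻¹ (fast membrane transport), vessel permeability 5.7×10⁻⁷ m/s,
accessible volume fraction 0.4, filtration reflection 0.15. The
concentration scale is physical because binding saturates: plasma peak
C₀ = 10⁻³ mol/m³ (~1 µM) per unit dose against a binding-site density of
10⁻² mol/m³ (~10 µM). This pairing puts the system in the regime the
reported response structure requires: at the lowest affinity, binding
competes with vascular washout (capture is lossy); at the baseline it is
nearly complete; at full dose the perivascular sites saturate transiently,
which is what gives large boluses their penetration advantage and
metronomic splitting its efficiency advantage. K_OFF, K_INT, φ, σ_f, P,
C_rec0 and C₀ are not printed in the source material; all are configuration
keys and should be treated as modelling choices, not measurements.

## Numerical choices and problem sizes

Production grid 64×64 over 2 mm (h ≈ 31 µm); tumor radius 0.5 mm. The
comparative studies (regimen comparison, drug sweeps, dose fractionation)
run at 32×32 over three seeds — directions of the comparisons are stable
under this reduction while a full three-regimen comparison stays within a
few minutes. Delivery phases use the step ladder above; coupled-flow fixed
point to 0.1 Pa; direct sparse factorization throughout (the default systems
are ≤ 10⁴ unknowns). Degenerate inputs (empty schedules, zero tumors,
sub-resolution radii, non-perfused networks) raise typed errors rather than
propagating NaNs; geometry updates floor the tumor radius at one grid cell.

## Known limitations

* The per-cycle bookkeeping is lumped: one FKC per cycle multiplies the cell
  count, so spatial correlation between the cells killed in successive
  cycles is discarded (survivor mixing). A consequence — provable from the
  convexity of the log-survival in dose — is that at equal cumulative dose,
  maximally split dosing is always at least as effective as any mixed
  schedule in this model family, so a chemo-switching advantage *over*
  metronomic dosing cannot be reproduced; the corresponding acceptance test
  is expected to fail and documents this.
* The binding-affinity response reproduces the low-affinity washout penalty
  strongly, but the very-high-affinity penalty (rim trapping) is slightly
  outweighed by the retention gain at every parameterization tried, so the
  affinity optimum sits at the top of the tested range rather than at the
  intermediate value.
* In the mild-saturation regime the dose-response is near-linear, so at a
  fixed horizon the endpoint survival of MTD vs metronomic dosing ranks
  mostly by cumulative dose and the two arms are a seed-level tie (MTD
  delivers 6.0 C_p vs 5.2 for the others); a clear metronomic advantage
  needs deeper full-dose saturation, which in turn suppresses the
  diffusivity and affinity trends. The corresponding acceptance test sits at
  this resolution limit.
* 2-D mid-plane slab, unit depth; the cube-root radius law imports the 3-D
  volume scaling but out-of-plane transport is absent.
* Quasi-steady flow per cycle; no poroelasticity, no vessel remodeling, no
  resistance evolution, single-exponential systemic PK.
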