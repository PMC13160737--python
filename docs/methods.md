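# Methods

## Physical model

The package treats one sarcoplasmic-reticulum (SR) element of amphibian
skeletal muscle as a sealed cylinder of radius a_ΔSR/2 = 15 nm and length
l/2 = 1.8 µm, the half-sarcomere distance from the terminal cisterna (CSR,
face F2 at x = 0) to the midpoint of the longitudinal SR (LSR, closed face
F1 at x = L). The lateral membrane (F3) carries SERCA-mediated re-uptake.
The state variable is total luminal Ca²⁺ (free plus calsequestrin-bound),
which evolves by Fickian diffusion with a concentration-dependent effective
coefficient:

- **Rapid-buffer approximation.** Calsequestrin binding
  (Ca²⁺ + Casq ⇌ Casq–Ca²⁺, K_d) is assumed to equilibrate instantly
  relative to diffusion. Free, bound and total Ca²⁺ are then algebraically
  linked at every point: bound is the smaller root of
  b² − (C + B_T + K_d)b + C·B_T = 0 and free the positive root of
  f² + (B_T − C + K_d)f − K_d·C = 0 (C total Ca²⁺, B_T total buffer). Both
  roots are evaluated in subtraction-free form, so the free↔total round trip
  holds to ~10⁻¹⁵ relative and the conversions are safe to apply per node
  per time step.
- **Effective diffusivity.** With the buffer immobile (anchored
  calsequestrin, D_Casq = 0), the concentration-weighted average diffusivity
  of total Ca²⁺ is D*(C) = D_Ca · free(C)/C. Its removable singularity at
  C = 0 is filled with the limit D_Ca·K_d/(K_d + B_T), keeping D*
  continuous. Note this weighted-average form is adopted as stated for the
  model being reproduced; it differs from the textbook rapid-buffer
  reduction D_Ca/(1 + dB/df), which would use the local buffering slope
  rather than the free/total ratio. The difference vanishes without buffer
  and stays within the same order of magnitude at these concentrations.
- **Boundary fluxes.** The release efflux density on F2 is either constant,
  J(t) = J₀, or depletion-scaled, J(t) = J₀·c_free(0,t)/c_free(0,0), with
  the face value taken as the area average over F2. The cytosolic
  concentration (~50 nM against 3.6 mM luminal) is treated as zero in the
  driving-force ratio. SERCA influx is a constant density on F3; both fluxes
  move free Ca²⁺, and because bound Ca²⁺ cannot cross the membrane they
  enter the total-Ca²⁺ balance at the same magnitude.

A consequence worth stating explicitly: in depletion-scaled mode the efflux
is proportional to the CSR face free concentration, so the percent declines
of the efflux and of CSR free Ca²⁺ over any window are identical by
construction. The test suite asserts this identity.

## Parameters

All constants are kept in SI units; mol m⁻³ is numerically mM. Defaults
(overridable via a flat YAML config whose keys are the field names; unknown
keys are an error):

| parameter | default | units | meaning |
|---|---|---|---|
| `sarcomere_length_l` | 3.6e-6 | m | sarcomere length (element length = l/2) |
| `fiber_diameter_a` | 100e-6 | m | muscle fibre diameter |
| `surface_capacitance_Cs` / `tubular_capacitance_Ct` | 1.0e-2 / 5.0e-2 | F m⁻² | their ratio fixes the tubular membrane area |
| `junction_fraction_xi` | 0.3 | – | fraction of tubular membrane in triad junctions |
| `sr_volume_fraction_Vsr_star` | 0.12 | – | SR volume / fibre volume |
| `sr_element_diameter_a_dsr` | 3.0e-8 | m | SR element diameter |
| `D_ca_free` | 3e-10 | m² s⁻¹ | free Ca²⁺ diffusivity |
| `casq_total` | 6.1 | mM | total calsequestrin (1:1 sites) |
| `ca_free_initial` | 3.6 | mM | resting free luminal Ca²⁺ |
| `Kd` | 1.1 | mM | calsequestrin dissociation constant |
| `J_efflux_0` | −2.7375e-6 | mol m⁻² s⁻¹ | initial release efflux density |
| `J_serca_influx` | 3.6880e-10 | mol m⁻² s⁻¹ | SERCA influx density |

Two derivation paths are exposed for provenance rather than used in runs:
the initial efflux follows from a whole-fibre T–SR release flux of
−3.0 µmol m⁻² s⁻¹ through the geometric factor 2·A_TSR/(π a² V_SR*), and the
SERCA density from a background flux of 9.70×10⁻⁸ mol m⁻² s⁻¹ spread over
the n ≈ (a_SR/a_ΔSR)² elements. The tubular membrane area defaults to the
published figure of 5,733 µm² (so the junctional area is exactly 1,720 µm²);
the closed form (C_T/C_S)·π·a·l evaluates ~1.4% lower (5,655 µm²) and is
available behind `use_printed_tubular_area=False`. The published constants
were derived from the larger area, so it is kept as the default.

Note a deliberate redundancy: `J_efflux_0 = −2.7375e-6` is the primary
simulation constant, although the geometric derivation from −3.0 µmol m⁻²
s⁻¹ reproduces it only to ~0.007%. Re-deriving it instead from a whole-fibre
flux of −2.7375 µmol m⁻² s⁻¹ (i.e. applying the geometric factor once more)
gives −2.4978e-6 and lowers every decline statistic by the same ~9% — the
2-s no-buffer decline moves from 57.1% to 53.8%. The reported numbers are
sensitive to this single convention choice and the package fixes it as the
first, direct reading.

## Discretisation and time integration

- **Grids.** Production runs use a uniform 1D axial finite-volume grid
  (default spacing 10 nm → 181 nodes), with control volumes π r² Δx (half
  cells at the ends) and the lateral SERCA flux folded in as the equivalent
  volumetric source 2 J_in/r. A structured node-centred 2D axisymmetric
  (r, z) grid with cylindrical measure (default H_max = 10 nm → 3×181
  nodes) serves to verify radial uniformity; its control volumes tile
  π r² L exactly at any resolution. With no radial forcing the 2D scheme
  collapses algebraically onto the 1D one, and the two solutions agree to
  ~10⁻¹⁵.
- **Operator.** Conservative form ∇·(D*∇C) by default, with the face
  diffusivity the arithmetic mean of the node values (the fields vary by
  <1% per cell, so the choice of mean is immaterial); a non-conservative
  D*·∇²C variant (node-local coefficient) exists for sensitivity checks
  only. The conservative form makes the discrete mass balance an identity.
- **Time stepping.** `scipy.integrate.solve_ivp` BDF with a supplied
  Jacobian sparsity pattern (grid neighbours plus the F2-face coupling
  introduced by the depletion-scaled efflux). The implicit modified-Newton
  iteration handles the D*(C) nonlinearity. Defaults rtol = 10⁻⁸,
  atol = 10⁻¹² mol m⁻³; the decline percentages are stable to ≥4
  significant figures under these tolerances and under halving the grid
  spacing. The 1,000 output points are equally spaced sampling times only.
- **Degenerate inputs.** Negative concentrations abort the run (beyond
  atol); a zero-buffer run bypasses the buffer algebra entirely
  (D* ≡ D_Ca, free ≡ total); a two-node grid is the smallest accepted.
- **Determinism.** No randomness anywhere; identical configurations
  reproduce outputs byte-identically.

## Validation oracles

Three independent references, all in `srlumen.oracle_validation`:

1. the classical Fourier cosine-series solution of the constant-flux,
   sealed-end rod (truncated when terms fall below 10⁻¹⁶ of the initial
   concentration) — the implicit solver matches it to <10⁻⁴ relative;
2. the well-mixed single-compartment ODE, with closed-form linear
   (constant-efflux) and exponential (decaying-efflux) solutions — inflating
   D_Ca by 10⁶ drives the PDE onto this trajectory to <10⁻⁵;
3. a forward-Euler conservative solver stepped at 0.25·Δx²/max D* — the
   implicit solver matches it to <10⁻³ in the nonlinear case.

Mass balance (domain content vs time-integrated boundary fluxes) holds to
better than 10⁻⁷ relative on all production runs.

## Design choices that were genuinely open

- **Axis orientation:** x = 0 at the CSR release face, increasing toward
  the LSR midpoint. Display routines that want the opposite orientation can
  flip the exported matrices; the numbers are the interface, not figures.
- **Efflux sign convention:** densities are signed along the outward
  normal; the depletion-scaled law keeps the sign of J₀ and scales its
  magnitude — the only reading under which the efflux magnitude declines as
  the face depletes.
- **Face average vs point value** for the depletion scaling: area average
  over F2 (identical to the corner node in 1D; radial spreads are ~10⁻⁶ of
  axial ones in 2D, so the distinction never matters numerically).
- **LSR−CSR difference** is reported as value at F1 minus value at F2,
  positive during release.
- **2D instead of 3D:** all boundary conditions and data are axisymmetric,
  so the azimuthal dimension carries no information; the axisymmetric
  solver is exact for this class and orders of magnitude cheaper.
- **Decline measurement:** percent declines are evaluated between t = 0 and
  the end of the window (20 ms or 2 s), not at the penultimate sample.

## Limitations

- 1:1 calsequestrin stoichiometry only. Real calsequestrin binds tens of
  Ca²⁺ ions cooperatively; at the default concentrations the 1:1 buffer is
  ~77% saturated and its capacity factor d(total)/d(free) is only ≈1.30, so
  buffering can slow the free-Ca²⁺ decline by at most ~30% relative. Claims
  of much larger protective effects require cooperative binding, which is
  outside this model.
- No RyR gating kinetics, no Ca²⁺-dependent SERCA rate law, no
  electrodiffusion, no luminal buffers other than calsequestrin, no
  heterogeneous calsequestrin anchoring.
- The cytosolic side is not modelled; the release driving force uses the
  luminal face concentration alone.
- Geometry is a single straight element; branched SR network topology is
  not represented.
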