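# Methods

`dialysim` simulates a hollow-fiber hemodialyzer at the module scale. The
fiber bundle is not resolved fiber by fiber; instead the device volume is
treated as **two interpenetrating porous media** — the blood side (the
fiber lumina) and the dialysate side (the shell space between fibers) —
that occupy the same mesh and exchange water and solute through the
membrane, represented by volumetric source terms.

## 1. Model

### 1.1 Geometry

Five housing shapes share the same membrane area (A = 1.7 m²), total
volume (V_tot = 307 cm³) and porosities (lumen 0.29, shell 0.51):

| shape | description |
|---|---|
| `long_cyl` | commercial long cylindrical unit |
| `short_cyl` | 2× the diameter, 1/4 the length |
| `thick_rect` | rectangular cross-flow housing, near-square section |
| `flat_rect` | rectangular cross-flow housing, 16:1 wide and thin |
| `coaxial_cyl` | two axial chambers divided by a partition disc, joined by a peripheral annular gap |

The axial length of the long cylinder is not an input; it is recovered
from the blood-side pressure drop through the exact 1-D axial Darcy
relation (the lumen flow is purely axial because its transverse
permeability is zero):

    L² = Δp_B · K_z · V_tot / (μ_B · Q_B)

With Δp_B = 9833 Pa, K_z = 3.4·10⁻¹⁰ m², μ_B = 3.5·10⁻³ Pa·s and
Q_B = 300 mL/min this gives L = 0.2422 m and D = 4.02 cm, inside the
typical commercial envelope. The same inversion with 3347 Pa and 8132 Pa
fixes the rectangular (L = 0.1413 m) and coaxial (L = 0.2202 m) lengths.
A consistency check recomputes the lumen membrane area from volume,
porosity and fiber dimensions (d_i = 200 µm, wall 30 µm) and rejects
constraint sets that disagree by more than 10%.

### 1.2 Flow

Each compartment obeys Darcy flow, `u = −(K/μ)∇p`, with an anisotropic
diagonal permeability `K = diag(K_t, K_t, K_z)` aligned with the fiber
axis:

* blood: K_z = 3.4·10⁻¹⁰ m², K_t = 0 (flow confined to the lumina);
* dialysate: K_z = 3.4·10⁻¹⁰ m², K_t = 3.2·10⁻¹¹ m².

Substituting into continuity with the ultrafiltration source gives an
anisotropic Poisson problem for each pressure field:

    −∇·( (K/μ) ∇p ) = S_M / ρ,   S_M = ± (A/V_tot) ρ L_p (p_B − p_D − p_onc)

with hydraulic permeability L_p = 6.6·10⁻¹¹ m s⁻¹ Pa⁻¹ and oncotic
pressure p_onc (zero for the saline validation protocol). The + sign
applies on the dialysate side, − on the blood side.

### 1.3 Membrane exchange

The transmembrane solute flux combines convection through the membrane
with diffusion down the concentration difference:

    j = L_p (p_B − p_D − p_onc)(1 − σ) · (C_B + C_D)/2  +  U (C_B − C_D)

with σ = 0 for urea. The overall coefficient is three resistances in
series, 1/U = 1/k_B + 1/k_M + 1/k_D, where

* k_B = Sh_B·D_B/d_i with Sh_B = 4 (laminar duct value),
* k_M = 1.1·10⁻⁵ m/s (membrane permeability for urea),
* k_D = Sh_D·D_D/d_h with the cross-flow fiber-bundle correlation
  Sh_D = 9.85 (1 + 1.41 Re_t^0.38), evaluated cell by cell from the local
  transverse dialysate speed; Re_t uses the bundle hydraulic diameter
  d_h = d_o·ε/(1−ε) = 2.706·10⁻⁴ m. At Re_t = 0 the correlation returns
  the purely axial value 9.85, so the "larger of axial/cross-flow" rule
  is automatic.

Exchange terms enter the transport equations as volumetric sources
scaled by the area density A/V_tot.

### 1.4 Solute transport

Each side carries a steady advection–diffusion equation for the urea
concentration,

    ∇·(u C) − ∇·(ε D ∇C) = S_C,

with porosity-scaled diffusivity (blood D = 7.4·10⁻¹⁰, dialysate
1.8·10⁻⁹ m²/s) and S_C = ∓(A/V_tot)·j.

### 1.5 Metrics

* clearance CL = (Q_B,in·C_B,in − Q_B,out·C_B,out)/C_B,in;
* per-side pressure drop = area-weighted mean inlet-face pressure minus
  the imposed outlet pressure (manifolds outside the domain);
* ⟨Sh_D⟩ = volume-weighted mean of the local shell Sherwood number;
* UF% = 100 · ∫j_conv / ∫j, the convective share of solute transport.

## 2. Numerics

* **Discretisation.** Cell-centred finite volumes on structured
  orthogonal meshes (Cartesian boxes or cylinders, periodic in θ);
  two-point flux approximation with harmonic face mobilities; first-order
  upwind advection and central diffusion. The coaxial partition disc is
  modelled as dialysate-blocked internal faces; the blood, confined to the
  fiber lumina, passes through it.
* **Boundary conditions.** Inlet ports impose the total flow with uniform
  flux density over the port faces; outlet ports impose pressure through
  half-cell transmissibilities; all other boundary faces are impermeable
  walls. Solute inlets impose the advective influx Q·C_in with zero inlet
  diffusive flux (Danckwerts form, which makes the discrete inflow exact
  in the balance checks); outlets are pure advective outflow.
* **Linear solves.** Direct sparse LU (`scipy.sparse.linalg.splu`). The
  pressure matrix of a side is constant across coupling steps and across
  ultrafiltration probes (the outlet pressure and the frozen opposite-side
  pressure enter only the right-hand side), so one factorisation serves
  every solve.
* **Implicit/explicit source split.** The own-side part of each membrane
  source is taken implicitly (it adds a positive diagonal, keeping the
  pressure system SPD and giving the transport system a discrete maximum
  principle: concentrations stay within the two inlet values); the frozen
  opposite-side part goes to the right-hand side.
* **Coupling.** The two sides are solved alternately, exchanging frozen
  pressure and concentration fields; the first blood step sees zero
  dialysate fields. Convergence is declared when both sides' outlet flow
  and mixing-cup outlet concentration change by less than 0.5% between
  consecutive steps (typically 5–9 steps per side).
* **Ultrafiltration tuning.** Within each blood step the blood outlet
  pressure is adjusted so the net transmembrane water flow equals the
  prescribed Q_UF (10 mL/min by default). Q_UF is affine in the outlet
  pressure for a linear Darcy system, so a secant step from two probe
  solves on the same factorisation lands on the root exactly.
* **Resolutions.** Per-shape study meshes of roughly 13k–20k cells
  (e.g. 10×24×72 for the long cylinder); a `level` scale factor
  coarsens or refines all directions together.

## 3. Parameters

| quantity | value |
|---|---|
| membrane area A | 1.7 m² |
| total volume V_tot | 307 cm³ |
| fiber inner diameter / wall | 200 µm / 30 µm |
| porosities (lumen / shell) | 0.29 / 0.51 |
| K_z (both), K_t (shell) | 3.4·10⁻¹⁰, 3.2·10⁻¹¹ m² |
| L_p, k_M, σ | 6.6·10⁻¹¹ m s⁻¹Pa⁻¹, 1.1·10⁻⁵ m/s, 0 |
| blood: ρ, μ, D | 1000, 3.5·10⁻³, 7.4·10⁻¹⁰ (SI) |
| dialysate: ρ, μ, D | 1000, 7.62·10⁻⁴, 1.8·10⁻⁹ (SI) |
| operating point | Q_B 300, Q_D 500, Q_UF 10 mL/min, C_B,in 20 mol/m³ |

The in-vitro validation protocol replaces the blood with saline: both
sides carry the dialysate properties (including the aqueous solute
diffusivity in the lumen) and p_onc = 0.

## 4. Assumptions and limitations

* Darcy drag only (no inertial/Forchheimer correction); laminar,
  steady, isothermal, single solute; constant properties.
* The porous-medium description cannot resolve individual fiber wakes or
  channelling; shell-side mixing enters only through the Sh_D(Re_t)
  correlation.
* Port geometry is idealised: circular nozzles (default 8 mm) and slits
  (default 5 mm) are mapped onto boundary-face patches; a port narrower
  than the local face spacing falls back to the nearest face column.
  Single-nozzle and coaxial cases are sensitive to these assumed sizes,
  which the study they reproduce does not print.
* First-order upwinding adds numerical diffusion; clearances rise by a
  fraction of a percent from the study meshes to 1.5× refinement.
* The effectiveness-NTU model in `reference.py` is used only as an
  independent oracle (uniform U, no ultrafiltration), never inside the
  simulator.
* With the parameter set above, the counter-flow effectiveness bound
  caps the blood-property clearance of the commercial configuration near
  240 mL/min; see the README's reproduction notes for how the computed
  values relate to the published comparison table.
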