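# fabricopt

Forward and inverse optimality problems of trabecular bone adaptation at the
homogenised representative-volume-element (RVE) level.

Trabecular bone adapts its mass and architecture to mechanical load. At the
continuum scale a ~5 mm RVE is described by two morphological variables: the
bone volume fraction ρ (BV/TV, typically 5–45%) and the fabric tensor **M**,
a positive-definite symmetric tensor normalised to tr **M** = d that captures
the orientation anisotropy of the trabecular network. `fabricopt` implements
the fabric–elasticity and fabric–yield constitutive models built on these two
variables and solves the two optimisation problems they induce:

* **Forward problem** — given a stress tensor **S**, find the fabric **M̄**
  and the minimal density ρ̄ at which a mechanostat set-point is met. The
  optimal fabric always aligns with the principal stresses (Wolff's law as a
  theorem, not an assumption).
* **Inverse problem** — given ρ and **M**, find the stress direction(s) of
  maximal admissible intensity, octant by octant in principal-stress space.
  The inversion is not unique: all stationary octants are reported.

Three mechanostat criteria are supported:

| criterion | stimulus | symmetry |
|---|---|---|
| CFE | normalised complementary free energy ½**S**:𝔼**S**/f(ρ) | even in **S** |
| GYC | quadric yield value √(**S**:𝔽**S**) + **F**:**S** | tension ≠ compression |
| PSE | principal strains vs. set amplitudes (E⁺, E⁻) | tension ≠ compression |

## The model

The stiffness is the multiplicative density–fabric form

    𝕊(ρ, M) = ρᵏ (λ₀ M⊗M + 2μ₀ M⊗̄M),

orthotropic with symmetry planes normal to the fabric eigenvectors; its exact
inverse is the compliance 𝔼(ρ,M) built from **M**⁻¹ and the engineering
constants (ε₀, ν₀). The quadric yield tensors use **M**⁻² and the uniaxial
yield stresses σ₀⁺, σ₀⁻ with shape factor ζ₀ and density exponent p. Stress
intensity is measured by the pyramidal norm λ_S = tr|**S**|/d, and every
solution is reported through the density-to-stress-intensity ratio
λ_ρ = f(ρ)/λ_S, which decouples magnitude from direction.

Default constants are the representative trabecular-bone values ε₀ = 10 GPa,
ν₀ = 0.25, k = 2, σ₀⁺ = 54 MPa, σ₀⁻ = 72 MPa, ζ₀ = 0.3, p = 2, with
set-points ψ̂*ₛ = 0.2592 MPa, yₛ = 1, E⁺ = 0.0054, E⁻ = 0.0072.

## Worked example

Optimal fabric for a triaxial compressive stress with principal ratios
(σ₁/σ₃, σ₂/σ₃) = (0.5, 0.75):

```sh
fabricopt forward --criterion cfe --stress "-0.5,-0.75,-1"
```

```json
{
  "criterion": "cfe",
  "S_hat": [-0.6666666666666666, -1.0, -1.3333333333333333],
  "m_bar": [0.7332024939786854, 1.0081914061900514, 1.258606099831263],
  "lambda_rho_bar": 0.016867390593795096,
  "criterion_value": 7.374469792299337e-05,
  "residual": 2.710505431213761e-20,
  "status": "optimal"
}
```

The optimal fabric eigenvalues (0.733, 1.008, 1.259) order themselves with
the stress magnitudes — the strongest trabecular direction follows the
largest compressive stress. `lambda_rho_bar` ≈ 0.0169 means a stress
intensity of λ_S MPa requires f(ρ̄) = 0.0169·λ_S, e.g. λ_S = 36 MPa needs
ρ̄ = √0.607 ≈ 0.78; intensities above 1/0.0169 ≈ 59 MPa exceed even fully
dense bone (`status` would become `infeasible_density`).

The inverse problem for the fabric (0.7, 1.0, 1.3) at ρ = 0.3:

```sh
fabricopt inverse --criterion all --fabric "0.7,1.0,1.3" --rho 0.3
```

reports the stationary stress direction of every octant for the three
criteria; the global optimum lies in the all-compressive octant (`"---"`)
with λ_ρ = 0.00678 and admissible intensity λ_S = 13.27 MPa, and the CFE and
PSE stress ratios coincide to machine precision (they share the same
anisotropic Hooke law).

The same functionality is available programmatically
(`fabricopt.solve_forward`, `fabricopt.solve_inverse`,
`fabricopt.compare_inverse_criteria`, `fabricopt.run_forward_sweep`, ...),
and `fabricopt sweep` regenerates whole solution surfaces as CSV tables.

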