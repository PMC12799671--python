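# Methods

## Constitutive models

The elastic model is the multiplicative density–fabric stiffness

    𝕊(ρ, M) = f(ρ) (λ₀ M⊗M + 2μ₀ M⊗̄M),      f(ρ) = ρᵏ,

with fabric normalised to tr M = d and the Lamé pair (λ₀, μ₀) tied to the
engineering constants by λ₀ = ε₀ν₀/((1+ν₀)(1−(d−1)ν₀)), μ₀ = ε₀/(2(1+ν₀)).
Its inverse, the compliance, replaces M by M⁻¹ and (λ₀, 2μ₀) by
(−ν₀/ε₀, (1+ν₀)/ε₀). Density scales but never reshapes the anisotropy — the
property that lets every optimisation be posed at ρ = 1 and the density be
recovered afterwards from λ_ρ = f(ρ)/λ_S.

The yield model is the tension/compression-asymmetric quadric
y(S) = √(S:𝔽S) + F:S with F = (f₀/ρᵖ)M⁻², 𝔽 built from M⁻² with
coefficients F₀², ζ₀, and f₀ = (1/σ₀⁺ − 1/σ₀⁻)/2, F₀ = (1/σ₀⁺ + 1/σ₀⁻)/2.
The isotropic degeneration fixes the shear yield stress
τ₀ = (1/F₀)√(1/(2(1+ζ₀))) — 38.27 MPa at the default constants, which the
constructor verifies to 1e−3 relative (the printed precision).

Fourth-order tensors are stored as symmetric matrices in the orthonormal
second-order tensor basis (Mandel convention: off-diagonal basis tensors
carry the √2). Double contraction is then an ordinary matrix–vector product,
𝕊𝔼 = I holds as an exact matrix identity (verified to 1e−9 over random
draws), and no Voigt-factor bookkeeping exists anywhere in the code.

## Reduced dimensions

A vanishing principal stress forces the corresponding fabric eigenvalue to
zero and the problem is projected onto the active subspace, with the trace
normalisations of fabric and stress adapted to the active rank d′. The
reduced model's Lamé pair is re-derived at d′ from (ε₀, ν₀) — the exact
restriction, i.e. the inverse of the restricted compliance. In 1D this makes
the axial stiffness exactly ε₀ (λ₀ = 0, 2μ₀ = ε₀), which is what produces
the uniaxial benchmark values (72 MPa ↔ 0.72% strain at 10 GPa). An
alternative reading — carrying the 3D λ₀ formally into the reduced systems —
is algebraically inconsistent with those 1D values and was not adopted; the
only observable consequence is the location of the 2D mixed-quadrant
no-solution boundary of the inverse CFE problem (m₂/m₃ = ν₀ here).

The σᵢ → 0 limit is *not* continuous into the projected problem: the
optimal fabric eigenvalue shrinks linearly with σᵢ, so the ratio σᵢ/mᵢ
survives in the limiting stationarity system and the limit sits a few parts
in 10³ away from the exact-zero solution (tested explicitly). This is a
property of the model's boundary singularity, not of the solver.

## Forward solvers

CFE and GYC are convex minimisations over the fabric simplex
{mᵢ > 0, Σmᵢ = d}. The solver first minimises through the softmax
reparameterisation m = d·exp(z)/Σexp(z) (positivity and trace enforced
exactly) with analytic gradients and multi-start BFGS (8 starts, seeded,
default seed 0), then polishes by Newton root-finding on the Lagrange
stationarity system ∂criterion/∂mᵢ = λ, Σmᵢ = d. The reported residual is
the largest violation of that system (typically ≪ 1e−12; tolerance 1e−10).
Exactly degenerate stress eigenvalues are grouped to a shared fabric
eigenvalue before solving — the transverse-isotropy tie-break that makes the
hydrostatic direction return exactly isotropic fabric.

PSE involves no minimisation: the d+1 equations "strain along each principal
direction equals ±E_set, trace = d" are solved by Newton's method with
multi-start; sign selection follows sign(σᵢ). Inconsistent sign patterns are
reported as `no_solution`, never silently dropped.

The multiplier is recovered from the stationarity equations at the optimum.
Uniqueness (convexity) is exercised by multi-seed agreement tests to 1e−6.

## Inverse solvers

The pyramidal constraint tr|Ŝ| = d is non-smooth; fixing an octant sign
vector s turns it into the linear constraint Σsᵢσᵢ = d with sᵢσᵢ ≥ 0, and
each of the 2^d octants is solved separately:

* **CFE** — closed form: the stationary direction is σ ∝ Ks with K the
  stiffness normal block in the fabric eigenbasis; if the point leaves the
  octant cone the octant has no interior solution and its minimum belongs to
  a lower-dimensional face.
* **GYC** — SLSQP minimisation on the octant simplex (bounds let the
  iterate hit faces exactly), multi-start from the centre, the corners and
  seeded Dirichlet draws, followed by a Newton polish of the interior KKT
  system. A minimum with a weight below the interior tolerance (1e−6) is
  classified `no_solution`.
* **PSE** — fully explicit: each of the 2^d strain corners diag(±E_set)
  maps through Hooke's law to a candidate stress; λ_ρ = 1/λ_S at ρ = 1.
  A corner's stress octant need not match the corner's own sign pattern, so
  both are recorded.

All octant solutions are returned; the global one minimises λ_ρ, with exact
ties (the ± pairs of the even CFE, mirrored PSE corners under symmetric set
strains) broken toward the compressive octant.

For criterion comparisons the three set-points are calibrated to a common
isotropic contractile strain of 0.72%: each scalar criterion is evaluated at
the stress 𝕊(1,I)(−0.0072·I) (= −144·I MPa in 3D at the defaults), giving
ψ̂*ₛ = 1.5552 MPa and yₛ = 1.5562 (the calibrated yield set-point exceeds 1 by
construction), and the PSE compressive amplitude is the strain itself. All
three criteria then share λ_ρ = 1/144 at the isotropic fabric in 3D.

## Octant census of the inverse GYC problem

Over the package's default fabric-ratio domain m₁/m₃, m₂/m₃ ∈ [0.3, 1]
(matching the generator's eigenvalue-ratio range), a 15×15 sweep finds
interior stationary yield minima in seven octants: six robust families
(−−−, +++, −−+, −++, +−+, ++−; the octant +−− never has one) plus a thin
sliver of −+− confined to m₂/m₃ ≳ 0.93. Near the transverse-isotropy line
m₂ = m₃ the octants −+− and −−+ are exchanged by swapping the two nearly
degenerate fabric axes, so the sliver is the mirror continuation of the
−−+ family rather than an independent solution branch; it disappears for
domains with ratio lower bounds ≳ 0.6. The census was verified against a
dense barycentric grid search (the sliver minima are strictly interior,
below every octant-face minimum, with KKT residuals ~1e−10). Counts of
"octants with solutions" therefore depend on the sampled fabric domain; the
physically robust statements — the compressive octant carries the global
optimum everywhere, and +−− is always empty — do not.

## Brute-force oracle

An independent check, used only by tests and the `selftest` command:
exhaustive evaluation on the barycentric lattice of the relevant simplex
(default 60 subdivisions; interior points only, cutoff 1e−6 against the
boundary singularity) followed by one Nelder–Mead refinement from the best
lattice point (derivative-free, hence independent of the production
solvers' gradient machinery). For the convex criteria the lattice stage is
within one cell of the optimum and the refinement reaches ~1e−9; solver and
oracle are required to agree to 1e−3 in eigenvalues over 50 random
instances per criterion for both problems. PSE, having no variational
formulation, is checked instead by substituting solutions back through the
compliance and requiring the prescribed strains exactly.

## Random instances

The fixture generator draws fabric eigenvalue ratios uniformly in [0.3, 1]
(covering the realistic trabecular degree-of-anisotropy range up to ≈ 3),
uniformly random orientations (QR of Gaussian matrices), stress directions
with random magnitudes in [0.2, 1], random signs and orientations normalised
to unit pyramidal intensity, and densities uniform in the trabecular range
[0.05, 0.45]. Everything is keyed to a single integer seed and is
bit-reproducible. These fixtures probe the solvers across the model's
operating envelope; they do not emulate measurement noise, fabric–density
correlations, or non-orthotropic micro-architectures, so passing tests
certify the optimality machinery, not the constitutive models' fidelity to
any particular bone specimen.

## Numerical choices

* Stationarity residual tolerance 1e−10; simplex feasibility 1e−12;
  optimiser criterion tolerance 1e−12 (all configurable via
  `SolverOptions` / the YAML `solver:` section).
* Automatic dimension reduction below |σᵢ|/max|σⱼ| = 1e−12.
* Constructor consistency checks: Lamé/engineering 1e−9 relative; τ₀ 1e−3
  relative (printed precision).
* Sweeps default to 41×41 ratio grids; the domain orderings
  (|σ₁/σ₃| ≤ |σ₂/σ₃| ≤ 1, m₁/m₃ ≤ m₂/m₃ ≤ 1) are enforced by construction.
* Problem sizes in the test-suite property batches: 50 random instances per
  oracle comparison at lattice resolution 60, 1000 draws for the
  stiffness–compliance identity, 15×15 fabric grids for the octant census.

## Known limitations

* Single load case only: no time averaging of non-proportional stress
  histories, and no whole-bone finite-element adaptation loop — solutions
  apply at a single RVE.
* Fabric is an input (eigenvalues/eigenvectors); no image-based fabric
  measurement (MIL/MSL/GST) is included, though the power-law
  renormalisation between fabric conventions is (`normalise_fabric`).
* Small-strain symmetric tensors throughout; no finite-strain kinematics.
* The criteria are singular as fabric or stress eigenvalues approach zero;
  solutions near rank change carry the boundary-layer behaviour described
  above.
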