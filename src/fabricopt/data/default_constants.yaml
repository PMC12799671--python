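# Representative trabecular-bone constants (fully dense isotropic tissue).
elastic:
  eps0: 10000.0     # Young's modulus [MPa]
  nu0: 0.25         # Poisson's ratio [-]
  mu0: 4000.0       # shear modulus [MPa], consistent with eps0, nu0
  k: 2              # density exponent of f(rho) = rho^k
  d: 3
yield:
  sigma0_plus: 54.0   # uniaxial tensile yield stress [MPa]
  sigma0_minus: 72.0  # uniaxial compressive yield stress [MPa]
  zeta0: 0.30         # quadric shape factor [-]
  tau0: 38.27         # shear yield stress [MPa], consistent with the above
  p: 2                # density exponent of fhat(rho) = rho^p
setpoints:
  psi_set: 0.2592     # normalised CFE set-point [MPa]
  y_set: 1.0          # yield/damage set-point [-]
  E_set_plus: 0.0054  # homeostatic tensile strain [-]
  E_set_minus: 0.0072 # homeostatic compressive strain magnitude [-]
solver:
  n_starts: 8
  seed: 0
  tol_residual: 1.0e-10
  tol_simplex: 1.0e-12
  tol_criterion: 1.0e-12
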