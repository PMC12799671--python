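"""Forward optimality problem: optimal fabric for a given stress direction.

Given a normalised stress direction ``S_hat`` (``tr|S_hat| = d``), each
mechanostat criterion defines the fabric a bone RVE should adopt to carry
that stress with the least material:

* CFE -- minimise the normalised complementary free energy
  ``psi_hat(S_hat; 1, M)`` over the fabric simplex ``{m_i > 0, sum m_i = d}``;
  the density-to-stress-intensity ratio is
  ``lambda_rho = sqrt(psi_hat / psi_set)``.
* GYC -- minimise the quadric yield value ``y(S_hat; 1, M)`` over the same
  simplex; ``lambda_rho = y / y_set``.  Tension and compression give
  different optima.
* PSE -- no minimisation: fabric eigenvalues and ``lambda_rho`` solve the
  system requiring the strain along each principal stress direction to
  equal the homeostatic amplitude ``+E_set_plus`` (tensile) or
  ``-E_set_minus`` (compressive).

In all three cases the optimal fabric commutes with the stress tensor, so
the solvers work on eigenvalue vectors in the stress eigenbasis.  Stress
eigenvalues that vanish force the corresponding fabric eigenvalue to zero
and the problem is projected onto the active subspace ("dimension
reduction"), with the trace normalisations adapted to the active rank.

If a stress intensity ``lambda_S`` is supplied the minimal density follows
from ``rho = (lambda_rho * lambda_S)**(1/k)`` (exponent ``p`` for GYC);
intensities beyond ``1/lambda_rho`` are infeasible even at full density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.optimize import minimize, root

from .constitutive import (
    DomainError,
    ElasticConstants,
    FabricTensor,
    InfeasibleDensityError,
    SetPoints,
    StressState,
    TOL_REDUCE,
    YieldConstants,
    cfe_aligned,
    cfe_grad_m,
    default_elastic,
    default_yield,
    gyc_aligned,
    gyc_grad_m,
    recover_density,
    strain_aligned,
)

logger = logging.getLogger("fabricopt")

Criterion = Literal["cfe", "gyc", "pse"]


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls shared by the forward and inverse solvers."""

    n_starts: int = 8
    seed: int = 0
    tol_residual: float = 1e-10
    tol_simplex: float = 1e-12
    tol_criterion: float = 1e-12
    reduce_threshold: float = TOL_REDUCE
    interior_tol: float = 1e-6


@dataclass(frozen=True)
class ForwardProblem:
    """A forward problem: stress direction in, optimal fabric out."""

    criterion: Criterion
    S_hat: StressState
    lambda_S: float | None = None
    set_points: SetPoints = field(default_factory=SetPoints)
    elastic: ElasticConstants = field(default_factory=default_elastic)
    yield_constants: YieldConstants = field(default_factory=default_yield)
    options: SolverOptions = field(default_factory=SolverOptions)

    @property
    def d(self) -> int:
        return self.S_hat.d


@dataclass(frozen=True)
class ForwardSolution:
    """Solution of a forward problem.

    ``M_bar`` reports fabric eigenvalues paired with the stress
    eigendirections (no forced ordering); dropped (zero-stress) axes carry a
    zero fabric eigenvalue in ``m_full``.  ``lambda_rho_bar`` is the ratio
    ``f(rho)/lambda_S`` at the optimum; ``rho_bar`` is only set when the
    problem supplied an intensity.  ``residual`` is the largest violation of
    the Lagrange stationarity system at the returned point.
    """

    M_bar: FabricTensor
    m_full: np.ndarray
    active: np.ndarray
    lambda_rho_bar: float
    rho_bar: float | None
    multiplier: float
    criterion_value: float
    residual: float
    status: str


# ---------------------------------------------------------------------------
# dimension reduction
# ---------------------------------------------------------------------------

def reduce_dimension(problem: ForwardProblem) -> tuple[ForwardProblem, np.ndarray]:
    """Project a problem onto the span of its nonzero-stress eigendirections.

    Returns the reduced problem (with ``tr M = d'`` and the stress direction
    renormalised to ``tr|S_hat| = d'``) and the boolean mask of active axes.
    A vanishing stress eigenvalue implies a vanishing fabric eigenvalue, so
    the dropped axes simply carry ``m_i = 0`` in the mapped-back solution.
    """
    sig = problem.S_hat.sigma
    scale = np.abs(sig).max()
    if scale == 0:
        raise DomainError("all stress eigenvalues are zero")
    active = np.abs(sig) >= problem.options.reduce_threshold * scale
    if active.all():
        return problem, active
    sig_red = sig[active]
    axes_red = problem.S_hat.axes[active]
    d_red = int(active.sum())
    S_red = StressState(sigma=d_red * sig_red / np.abs(sig_red).sum(), axes=axes_red)
    reduced = replace(problem, S_hat=S_red)
    return reduced, active


def _groups(sig: np.ndarray, tol: float = 1e-12) -> list[np.ndarray]:
    """Indices of stress eigenvalues equal within tolerance.

    Exactly degenerate stress eigenvalues share a fabric eigenvalue
    (transverse isotropy of the fabric model), so the solvers treat each
    group as a single unknown.
    """
    scale = max(np.abs(sig).max(), 1.0)
    groups: list[list[int]] = []
    for i, s in enumerate(sig):
        for g in groups:
            if abs(sig[g[0]] - s) <= tol * scale:
                g.append(i)
                break
        else:
            groups.append([i])
    return [np.asarray(g) for g in groups]


def _expand(values: np.ndarray, groups: list[np.ndarray], d: int) -> np.ndarray:
    out = np.empty(d)
    for v, g in zip(values, groups):
        out[g] = v
    return out


# ---------------------------------------------------------------------------
# simplex minimisation with stationarity polish (CFE and GYC)
# ---------------------------------------------------------------------------

def _minimise_on_simplex(
    value: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    sig: np.ndarray,
    d: int,
    opts: SolverOptions,
) -> tuple[np.ndarray, float, float]:
    """Minimise a criterion over the fabric simplex {m_i > 0, sum m_i = d}.

    Uses the softmax reparameterisation ``m = d exp(z)/sum exp(z)`` (which
    enforces positivity and the trace constraint exactly) with multi-start
    quasi-Newton descent, then polishes the result by Newton root-finding on
    the Lagrange stationarity system.  Returns (m, multiplier, residual).
    """
    groups = _groups(sig)
    g_sizes = np.array([len(g) for g in groups], dtype=float)
    n = len(groups)
    sig_g = np.array([sig[g[0]] for g in groups])

    def m_of_z(z: np.ndarray) -> np.ndarray:
        e = g_sizes * np.exp(z - z.max())
        return d * e / e.sum()

    def fun(z: np.ndarray) -> tuple[float, np.ndarray]:
        mg = m_of_z(z)
        m = _expand(mg, groups, d)
        v = value(m)
        gm = grad(m)
        gg = np.array([gm[g[0]] * len(g) for g in groups])
        # chain rule through the softmax map
        jac = gg * mg - mg * (gg @ mg) / d
        return v, jac

    rng = np.random.default_rng(opts.seed)
    best_z, best_v = None, np.inf
    for s in range(max(opts.n_starts, 1)):
        z0 = np.zeros(n) if s == 0 else rng.normal(0.0, 0.7, n)
        res = minimize(fun, z0, jac=True, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        if res.fun < best_v:
            best_v, best_z = res.fun, res.x
    mg = m_of_z(best_z)

    # polish: grad_i(m) - lam = 0 on group representatives, sum m = d
    def system(x: np.ndarray) -> np.ndarray:
        m_groups, lam = x[:n], x[n]
        m = _expand(m_groups, groups, d)
        gm = grad(m)
        return np.concatenate(
            [[gm[g[0]] - lam for g in groups], [float(m_groups @ g_sizes) - d]]
        )

    m_full = _expand(mg, groups, d)
    lam0 = float(np.mean(grad(m_full)))
    sol = root(system, np.concatenate([mg, [lam0]]), method="hybr", tol=1e-13)
    m_pol, lam = sol.x[:n], float(sol.x[n])
    if np.all(m_pol > 0) and np.max(np.abs(system(sol.x))) <= np.max(
        np.abs(system(np.concatenate([mg, [lam0]])))
    ):
        mg = m_pol
    else:
        lam = lam0
    m = _expand(mg, groups, d)
    residual = float(np.max(np.abs(system(np.concatenate([mg, [lam]])))))
    return m, lam, residual


# ---------------------------------------------------------------------------
# criterion-specific solvers
# ---------------------------------------------------------------------------

def _finish(
    problem: ForwardProblem,
    active: np.ndarray,
    m_red: np.ndarray,
    lambda_rho: float,
    multiplier: float,
    criterion_value: float,
    residual: float,
    exponent: float,
    status: str = "optimal",
) -> ForwardSolution:
    d = problem.d
    m_full = np.zeros(d)
    m_full[active] = m_red
    rho_bar = None
    if problem.lambda_S is not None and status in ("optimal", "reduced_dimension"):
        try:
            rho_bar = recover_density(lambda_rho, problem.lambda_S, exponent)
        except InfeasibleDensityError:
            status = "infeasible_density"
    if status == "optimal" and not active.all():
        status = "reduced_dimension"
    M_bar = _fabric_on_active(problem, active, m_red)
    return ForwardSolution(
        M_bar=M_bar,
        m_full=m_full,
        active=active,
        lambda_rho_bar=lambda_rho,
        rho_bar=rho_bar,
        multiplier=multiplier,
        criterion_value=criterion_value,
        residual=residual,
        status=status,
    )


def _fabric_on_active(
    problem: ForwardProblem, active: np.ndarray, m_red: np.ndarray
) -> FabricTensor:
    """Fabric tensor on the active subspace, eigenvalues in stress-axis order."""
    return FabricTensor(m=m_red, axes=problem.S_hat.axes[active])


def solve_forward_cfe(problem: ForwardProblem) -> ForwardSolution:
    """Optimal fabric minimising the normalised CFE for a stress direction."""
    reduced, active = reduce_dimension(problem)
    sig = reduced.S_hat.sigma
    d = reduced.d
    c = reduced.elastic.at_dimension(d)
    if d == 1:
        m = np.ones(1)
        psi = cfe_aligned(sig, m, c)
        lam_rho = float(np.sqrt(psi / problem.set_points.psi_set))
        return _finish(problem, active, m, lam_rho, 0.0, psi, 0.0,
                       problem.elastic.k)
    m, lam, residual = _minimise_on_simplex(
        lambda m: cfe_aligned(sig, m, c),
        lambda m: cfe_grad_m(sig, m, c),
        sig, d, problem.options,
    )
    psi = cfe_aligned(sig, m, c)
    lam_rho = float(np.sqrt(psi / problem.set_points.psi_set))
    return _finish(problem, active, m, lam_rho, lam, psi, residual,
                   problem.elastic.k)


def solve_forward_gyc(problem: ForwardProblem) -> ForwardSolution:
    """Optimal fabric minimising the quadric yield value for a stress direction."""
    reduced, active = reduce_dimension(problem)
    sig = reduced.S_hat.sigma
    d = reduced.d
    yc = reduced.yield_constants
    if d == 1:
        m = np.ones(1)
        y = gyc_aligned(sig, m, yc)
        lam_rho = y / problem.set_points.y_set
        return _finish(problem, active, m, lam_rho, 0.0, y, 0.0, yc.p)
    m, lam, residual = _minimise_on_simplex(
        lambda m: gyc_aligned(sig, m, yc),
        lambda m: gyc_grad_m(sig, m, yc),
        sig, d, problem.options,
    )
    y = gyc_aligned(sig, m, yc)
    lam_rho = y / problem.set_points.y_set
    return _finish(problem, active, m, lam_rho, lam, y, residual, yc.p)


def solve_forward_pse(problem: ForwardProblem) -> ForwardSolution:
    """Fabric and lambda_rho realising the homeostatic principal strains.

    Solves, in the shared eigenbasis,

        strain_i(S_hat; 1, m) = lambda_rho * E_i_set,   sum_i m_i = d,

    where ``E_i_set`` is ``+E_set_plus`` for tensile and ``-E_set_minus``
    for compressive principal stresses (Heaviside selection by sign).
    """
    reduced, active = reduce_dimension(problem)
    sig = reduced.S_hat.sigma
    d = reduced.d
    c = reduced.elastic.at_dimension(d)
    sp = problem.set_points
    e_set = np.where(sig > 0, sp.E_set_plus, -sp.E_set_minus)

    groups = _groups(sig)
    g_sizes = np.array([len(g) for g in groups], dtype=float)
    n = len(groups)

    def system(x: np.ndarray) -> np.ndarray:
        m = _expand(x[:n], groups, d)
        lam_rho = x[n]
        eqs = strain_aligned(sig, m, c) - lam_rho * e_set
        return np.concatenate([[eqs[g[0]] for g in groups], [m.sum() - d]])

    e_iso = strain_aligned(sig, np.ones(d), c)
    x0 = np.concatenate([np.ones(n), [float(np.mean(np.abs(e_iso) / np.abs(e_set)))]])
    rng = np.random.default_rng(problem.options.seed)
    best = None
    for s in range(max(problem.options.n_starts, 1)):
        start = x0 if s == 0 else x0 * np.concatenate(
            [np.exp(rng.normal(0, 0.3, n)), [np.exp(rng.normal(0, 0.3))]]
        )
        sol = root(system, start, method="hybr")
        res = float(np.max(np.abs(system(sol.x))))
        if np.all(sol.x[:n] > 0) and sol.x[n] > 0:
            if best is None or res < best[1]:
                best = (sol.x, res)
    if best is None or best[1] > 1e-8:
        m_full = np.zeros(problem.d)
        return ForwardSolution(
            M_bar=FabricTensor.isotropic(d),
            m_full=m_full, active=active, lambda_rho_bar=np.nan, rho_bar=None,
            multiplier=np.nan, criterion_value=np.nan,
            residual=np.inf if best is None else best[1], status="no_solution",
        )
    x, residual = best
    m = _expand(x[:n], groups, d)
    m = d * m / m.sum()
    lam_rho = float(x[n])
    return _finish(problem, active, m, lam_rho, lam_rho, lam_rho, residual,
                   problem.elastic.k)


_SOLVERS = {"cfe": solve_forward_cfe, "gyc": solve_forward_gyc, "pse": solve_forward_pse}


def solve_forward(problem: ForwardProblem) -> ForwardSolution:
    """Dispatch to the solver for the problem's criterion."""
    try:
        return _SOLVERS[problem.criterion](problem)
    except KeyError:
        raise DomainError(f"unknown criterion {problem.criterion!r}") from None
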