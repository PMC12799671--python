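"""Inverse optimality problem: optimal stress for a given density and fabric.

For a bone RVE with known volume fraction ``rho`` and fabric ``M``, the
inverse problem asks which stress tensor of a given pyramidal intensity
``lambda_S = tr|S|/d`` the RVE carries best -- equivalently, which stress
direction minimises the mechanostat criterion on the norm surface
``tr|S_hat| = d``.  The surface is a union of 2^d simplices, one per sign
pattern (octant) of the principal stresses; fixing the sign vector ``s``
turns the non-smooth constraint into the linear one ``sum_i s_i sigma_i = d``
with ``s_i sigma_i >= 0``, and the solvers treat each octant separately:

* CFE -- the quadratic ``psi_hat`` has the closed-form per-octant stationary
  point ``sigma = d K s / (s' K s)`` with ``K`` the normal-stress stiffness
  block in the fabric eigenbasis; octants whose stationary point leaves the
  cone have no interior solution.  Solutions come in +/- pairs.
* GYC -- the yield value (a norm plus a linear term) is minimised per
  octant numerically; boundary minima (a vanishing stress eigenvalue) are
  reported as ``no_solution`` for that octant, matching the empty regions
  of the solution surfaces.
* PSE -- fully explicit: each of the 2^d homeostatic strain corners
  ``diag(+/-E_set)`` maps through Hooke's law to a candidate stress.

The optimal intensity for a given density is ``lambda_S = fhat(rho) /
lambda_rho`` (elastic scaling ``f`` for PSE), and the global solution is
the octant with the smallest ``lambda_rho``.  Multiple octants may be
stationary -- the inversion is not univocal -- so all octant solutions are
returned, never silently one.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, root

from .constitutive import (
    DomainError,
    ElasticConstants,
    FabricTensor,
    SetPoints,
    YieldConstants,
    cfe_aligned,
    default_elastic,
    default_yield,
    gyc_aligned,
    gyc_grad_sigma,
    stiffness_normal_block,
)
from .forward import Criterion, SolverOptions

logger = logging.getLogger("fabricopt")


@dataclass(frozen=True)
class InverseProblem:
    """An inverse problem: density and fabric in, optimal stress out."""

    criterion: Criterion
    M: FabricTensor
    rho: float | None = None
    set_points: SetPoints = field(default_factory=SetPoints)
    elastic: ElasticConstants = field(default_factory=default_elastic)
    yield_constants: YieldConstants = field(default_factory=default_yield)
    octants: Sequence[tuple[int, ...]] | None = None
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.rho is not None and not 0.0 < self.rho <= 1.0:
            raise DomainError(f"density must lie in (0, 1], got {self.rho}")

    @property
    def d(self) -> int:
        return self.M.d

    def octant_list(self) -> list[tuple[int, ...]]:
        if self.octants is not None:
            return [tuple(o) for o in self.octants]
        return [o for o in itertools.product((-1, 1), repeat=self.d)]


@dataclass(frozen=True)
class OctantSolution:
    """Stationary stress direction of one octant (or its absence).

    ``sigma_hat`` holds principal values in the fabric eigenvalue order;
    the full tensor shares the fabric eigenvectors.  ``lambda_rho`` is the
    criterion-over-set-point ratio; ``status`` is ``"stationary"`` when an
    interior stationary point exists in the octant and ``"no_solution"``
    otherwise (the octant minimum then sits on a lower-dimensional face).
    """

    signs: tuple[int, ...]
    sigma_hat: np.ndarray | None
    lambda_rho: float
    criterion_value: float
    status: str
    residual: float = np.nan
    #: PSE only: the sign pattern of the generating strain corner (a strain
    #: corner's stress need not lie in the octant of the same sign pattern)
    corner: tuple[int, ...] | None = None

    @property
    def is_stationary(self) -> bool:
        return self.status == "stationary"


@dataclass(frozen=True)
class InverseSolution:
    """All octant solutions plus the global (minimal lambda_rho) one."""

    per_octant: list[OctantSolution]
    global_solution: OctantSolution
    lambda_S: float | None
    M: FabricTensor

    def stationary(self) -> list[OctantSolution]:
        return [o for o in self.per_octant if o.is_stationary]


def _global(per_octant: list[OctantSolution]) -> OctantSolution:
    stationary = [o for o in per_octant if o.is_stationary]
    if not stationary:
        raise DomainError("no octant admits a stationary solution")
    # exact ties (CFE's +/- pairs, PSE with symmetric set strains) break
    # toward the compressive octant
    return min(stationary, key=lambda o: (o.lambda_rho, sum(o.signs)))


def _wrap(
    problem: InverseProblem, per_octant: list[OctantSolution], scaling: str
) -> InverseSolution:
    best = _global(per_octant)
    lambda_S = None
    if problem.rho is not None:
        f = (
            problem.yield_constants.fhat(problem.rho)
            if scaling == "yield"
            else problem.elastic.f(problem.rho)
        )
        lambda_S = f / best.lambda_rho
    return InverseSolution(
        per_octant=per_octant, global_solution=best, lambda_S=lambda_S, M=problem.M
    )


# ---------------------------------------------------------------------------
# CFE: closed-form per-octant stationary point
# ---------------------------------------------------------------------------

def solve_inverse_cfe(problem: InverseProblem) -> InverseSolution:
    """Per-octant CFE-optimal stress directions and the global optimum.

    In each octant the stationarity system is
    ``sigma_i = lam (lambda0 (sum_l m_l s_l) m_i + 2 mu0 s_i m_i^2)``
    together with ``sum_i s_i sigma_i = d`` -- the stress is the (scaled)
    image of the sign vector under the stiffness normal block.
    """
    m = problem.M.m
    d = problem.d
    K = stiffness_normal_block(m, problem.elastic)
    sp = problem.set_points
    out: list[OctantSolution] = []
    for signs in problem.octant_list():
        s = np.asarray(signs, dtype=float)
        Ks = K @ s
        denom = float(s @ Ks)
        sigma = d * Ks / denom
        if np.all(s * sigma > problem.options.interior_tol * d / 100.0):
            psi = cfe_aligned(sigma, m, problem.elastic.at_dimension(d))
            lam = d / denom
            residual = float(np.max(np.abs(sigma - lam * Ks)))
            out.append(
                OctantSolution(
                    signs=tuple(signs), sigma_hat=sigma,
                    lambda_rho=math.sqrt(psi / sp.psi_set),
                    criterion_value=psi, status="stationary", residual=residual,
                )
            )
        else:
            out.append(
                OctantSolution(signs=tuple(signs), sigma_hat=None,
                               lambda_rho=np.inf, criterion_value=np.nan,
                               status="no_solution")
            )
    return _wrap(problem, out, scaling="yield")


# ---------------------------------------------------------------------------
# GYC: per-octant constrained minimisation with stationarity polish
# ---------------------------------------------------------------------------

def _gyc_octant_minimum(
    m: np.ndarray,
    signs: np.ndarray,
    yc: YieldConstants,
    opts: SolverOptions,
) -> tuple[np.ndarray, float, bool, float]:
    """Minimise y(s*w; 1, m) over the octant simplex {w >= 0, sum w = d}.

    Returns (w, value, interior, kkt_residual).  SLSQP with bounds lets the
    minimiser hit octant faces exactly, which is how boundary (no-solution)
    octants are detected.
    """
    d = m.size
    fun = lambda w: gyc_aligned(signs * w, m, yc)
    jac = lambda w: gyc_grad_sigma(signs * w, m, yc) * signs
    cons = [{"type": "eq", "fun": lambda w: w.sum() - d,
             "jac": lambda w: np.ones(d)}]
    bounds = [(0.0, None)] * d
    starts = [np.full(d, 1.0)]
    for i in range(d):
        w0 = np.full(d, 0.1)
        w0[i] = d - 0.1 * (d - 1)
        starts.append(w0)
    rng = np.random.default_rng(opts.seed)
    for _ in range(max(opts.n_starts - len(starts), 0)):
        w0 = rng.dirichlet(np.ones(d)) * d
        starts.append(w0)
    best = None
    for w0 in starts:
        res = minimize(fun, w0, jac=jac, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"ftol": 1e-14, "maxiter": 500})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:  # pragma: no cover - SLSQP essentially always succeeds here
        return np.full(d, np.nan), np.inf, False, np.inf
    w = np.maximum(best.x, 0.0)
    w = d * w / w.sum()
    interior = bool(w.min() > opts.interior_tol)
    kkt = np.inf
    if interior:
        # polish the interior stationary point: grad = lam * ones, sum w = d
        def system(x: np.ndarray) -> np.ndarray:
            ww, lam = x[:d], x[d]
            return np.concatenate([jac(ww) - lam, [ww.sum() - d]])

        g = jac(w)
        sol = root(system, np.concatenate([w, [float(g.mean())]]), method="hybr",
                   tol=1e-13)
        if np.all(sol.x[:d] > 0):
            w = sol.x[:d]
        kkt = float(np.max(np.abs(system(np.concatenate([w, [jac(w).mean()]])))))
    return w, fun(w), interior, kkt


def solve_inverse_gyc(problem: InverseProblem) -> InverseSolution:
    """Per-octant yield-optimal stress directions and the global optimum."""
    m = problem.M.m
    d = problem.d
    yc = problem.yield_constants
    sp = problem.set_points
    out: list[OctantSolution] = []
    for signs in problem.octant_list():
        s = np.asarray(signs, dtype=float)
        w, y, interior, kkt = _gyc_octant_minimum(m, s, yc, problem.options)
        if interior:
            out.append(
                OctantSolution(signs=tuple(signs), sigma_hat=s * w,
                               lambda_rho=y / sp.y_set, criterion_value=y,
                               status="stationary", residual=kkt)
            )
        else:
            out.append(
                OctantSolution(signs=tuple(signs), sigma_hat=None,
                               lambda_rho=np.inf, criterion_value=np.nan,
                               status="no_solution")
            )
    return _wrap(problem, out, scaling="yield")


# ---------------------------------------------------------------------------
# PSE: explicit corner enumeration
# ---------------------------------------------------------------------------

def solve_inverse_pse(problem: InverseProblem) -> InverseSolution:
    """Stress states realising the 2^d homeostatic strain corners.

    Each corner strain ``diag(e)`` with ``e_i in {+E_set_plus, -E_set_minus}``
    maps to the stress ``sigma_i = lambda0 m_i (m . e) + 2 mu0 m_i^2 e_i``
    (at rho=1); ``lambda_rho = 1 / lambda_S(sigma)``.  No iteration needed.
    """
    m = problem.M.m
    d = problem.d
    K = stiffness_normal_block(m, problem.elastic)
    sp = problem.set_points
    out: list[OctantSolution] = []
    for corner in itertools.product((1, -1), repeat=d):
        e = np.array(
            [sp.E_set_plus if c > 0 else -sp.E_set_minus for c in corner]
        )
        sigma = K @ e
        lam_S = float(np.abs(sigma).sum() / d)
        if lam_S <= 0:
            out.append(
                OctantSolution(signs=tuple(corner), sigma_hat=None,
                               lambda_rho=np.inf, criterion_value=np.nan,
                               status="degenerate", corner=tuple(corner))
            )
            continue
        sigma_hat = sigma / lam_S
        signs = tuple(int(np.sign(x)) if x != 0 else 0 for x in sigma)
        out.append(
            OctantSolution(signs=signs, sigma_hat=sigma_hat,
                           lambda_rho=1.0 / lam_S, criterion_value=lam_S,
                           status="stationary", residual=0.0,
                           corner=tuple(corner))
        )
    if problem.octants is not None:
        wanted = {tuple(o) for o in problem.octants}
        out = [o for o in out if o.signs in wanted]
    return _wrap(problem, out, scaling="elastic")


_SOLVERS = {"cfe": solve_inverse_cfe, "gyc": solve_inverse_gyc, "pse": solve_inverse_pse}


def solve_inverse(problem: InverseProblem) -> InverseSolution:
    """Dispatch to the solver for the problem's criterion."""
    try:
        return _SOLVERS[problem.criterion](problem)
    except KeyError:
        raise DomainError(f"unknown criterion {problem.criterion!r}") from None


# ---------------------------------------------------------------------------
# criterion comparison with a common calibration
# ---------------------------------------------------------------------------

def calibrate_set_points(
    elastic: ElasticConstants,
    yield_constants: YieldConstants,
    contractile_strain: float = 0.0072,
    d: int = 3,
    E_set_plus: float | None = None,
) -> SetPoints:
    """Set-points making the three criteria agree at the isotropic state.

    Each scalar criterion is evaluated at the stress produced by the
    isotropic contractile strain ``-contractile_strain * I`` through the
    fully dense isotropic Hooke law; the PSE compressive amplitude is the
    contractile strain itself.  With this calibration all three inverse
    solutions share ``lambda_rho`` at ``M = I``.
    """
    c = elastic.at_dimension(d)
    e = -contractile_strain * np.ones(d)
    sigma = stiffness_normal_block(np.ones(d), c) @ e
    psi_set = cfe_aligned(sigma, np.ones(d), c)
    y_set = gyc_aligned(sigma, np.ones(d), yield_constants)
    return SetPoints(
        psi_set=psi_set,
        y_set=y_set,
        E_set_plus=E_set_plus if E_set_plus is not None else contractile_strain,
        E_set_minus=contractile_strain,
    )


@dataclass(frozen=True)
class InverseComparison:
    """Side-by-side inverse solutions of the three criteria."""

    cfe: InverseSolution
    gyc: InverseSolution
    pse: InverseSolution
    set_points: SetPoints
    stress_ratio_deviation: float

    def lambda_rho(self) -> dict[str, float]:
        return {
            name: getattr(self, name).global_solution.lambda_rho
            for name in ("cfe", "gyc", "pse")
        }


def compare_inverse_criteria(
    M: FabricTensor,
    rho: float | None = None,
    set_points: SetPoints | None = None,
    elastic: ElasticConstants | None = None,
    yield_constants: YieldConstants | None = None,
    options: SolverOptions | None = None,
    check: bool = True,
) -> InverseComparison:
    """Run the three inverse solvers with a common calibration and compare.

    The CFE and PSE stress ratios in the all-negative octant are identical
    (both derive from the same anisotropic Hooke law); with ``check=True``
    a deviation beyond 1e-6 raises.
    """
    elastic = elastic or default_elastic()
    yield_constants = yield_constants or default_yield()
    options = options or SolverOptions()
    if set_points is None:
        set_points = calibrate_set_points(elastic, yield_constants, d=M.d)
    kw = dict(M=M, rho=rho, set_points=set_points, elastic=elastic,
              yield_constants=yield_constants, options=options)
    cfe = solve_inverse_cfe(InverseProblem(criterion="cfe", **kw))
    gyc = solve_inverse_gyc(InverseProblem(criterion="gyc", **kw))
    pse = solve_inverse_pse(InverseProblem(criterion="pse", **kw))
    neg = tuple([-1] * M.d)
    dev = np.nan
    cfe_neg = next(o for o in cfe.per_octant if o.signs == neg)
    pse_neg = next(o for o in pse.per_octant if o.corner == neg)
    if cfe_neg.is_stationary and pse_neg.is_stationary:
        r_cfe = cfe_neg.sigma_hat / cfe_neg.sigma_hat[-1]
        r_pse = pse_neg.sigma_hat / pse_neg.sigma_hat[-1]
        dev = float(np.max(np.abs(r_cfe - r_pse)))
        if check and dev > 1e-6:
            raise AssertionError(
                f"CFE/PSE stress-ratio identity violated: deviation {dev:.2e}"
            )
    return InverseComparison(cfe=cfe, gyc=gyc, pse=pse, set_points=set_points,
                             stress_ratio_deviation=dev)
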