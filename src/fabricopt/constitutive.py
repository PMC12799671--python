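"""Fabric-based constitutive models for trabecular bone at the RVE level.

Trabecular bone at the scale of a ~5 mm representative volume element (RVE)
is described by two morphological variables: the bone volume fraction
``rho`` (BV/TV, in [0, 1]) and the fabric tensor ``M``, a positive-definite
symmetric second-order tensor normalised to ``tr M = d`` that captures the
orientation anisotropy of the trabecular network.

This module provides

* the material-constant containers (:class:`ElasticConstants`,
  :class:`YieldConstants`, :class:`SetPoints`),
* the tensor-state containers (:class:`FabricTensor`, :class:`StressState`),
* assembly of the fabric-based fourth-order stiffness/compliance and yield
  tensors in an orthonormal second-order tensor basis (Mandel convention),
* the three mechanostat criterion evaluations: normalised complementary
  free energy density (CFE), the generalised quadric yield criterion (GYC),
  and the principal-strain response (PSE),
* the density recovery map ``rho = (lambda_rho * lambda_S)**(1/exponent)``.

The stiffness model is the multiplicative density-fabric form

    S(rho, M) = f(rho) * (lambda0 M (x) M + 2 mu0 M (s) M),

with ``f(rho) = rho**k``, ``(x)`` the tensor dyadic and ``(s)`` the
symmetrised tensor product; its inverse is the compliance

    E(rho, M) = (1/f(rho)) * (-(nu0/eps0) M^-1 (x) M^-1
                              + ((1+nu0)/eps0) M^-1 (s) M^-1).

The quadric yield criterion is ``y(S) = sqrt(S:FF S) + F:S`` with
``F = (f0/fhat(rho)) M^-2`` and
``FF = (F0^2/fhat(rho)^2) (-zeta0 M^-2 (x) M^-2 + (zeta0+1) M^-2 (s) M^-2)``,
``fhat(rho) = rho**p``; it is asymmetric in tension and compression
whenever the uniaxial yield stresses differ (f0 > 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("fabricopt")

# ---------------------------------------------------------------------------
# Numerical tolerances (shared package-wide defaults)
# ---------------------------------------------------------------------------

#: relative tolerance for the Lame/engineering consistency check
TOL_CONSISTENCY = 1e-9
#: relative tolerance for the printed shear yield stress tau0
TOL_TAU0 = 1e-3
#: absolute tolerance on trace normalisations and orthonormality
TOL_TRACE = 1e-12
#: threshold (relative to the largest magnitude) below which a stress
#: eigenvalue is treated as zero and the problem dimension is reduced
TOL_REDUCE = 1e-12


class DomainError(ValueError):
    """An input violates a model-domain restriction."""


class InfeasibleDensityError(DomainError):
    """The requested stress intensity exceeds what full density can bear."""


# ---------------------------------------------------------------------------
# Material constants
# ---------------------------------------------------------------------------

def lame_from_engineering(eps0: float, nu0: float, d: int) -> tuple[float, float]:
    """Lame pair (lambda0, mu0) from Young's modulus and Poisson's ratio.

    In dimension ``d`` the isotropy relations read

        lambda0 = eps0 * nu0 / ((1 + nu0) * (1 - (d - 1) * nu0))
        mu0     = eps0 / (2 * (1 + nu0))

    For ``d = 1`` the Poisson effect is void and the pair degenerates to
    ``(0, eps0 / 2)`` so that the axial stiffness is ``eps0``.
    """
    if eps0 <= 0:
        raise DomainError(f"Young's modulus must be positive, got {eps0}")
    if d == 1:
        return 0.0, eps0 / 2.0
    if d not in (2, 3):
        raise DomainError(f"dimension must be 1, 2 or 3, got {d}")
    bound = 1.0 / (d - 1)
    if not 0.0 <= nu0 < bound:
        raise DomainError(
            f"Poisson's ratio {nu0} outside admissible range [0, 1/(d-1)) = [0, {bound})"
        )
    lam0 = eps0 * nu0 / ((1.0 + nu0) * (1.0 - (d - 1) * nu0))
    mu0 = eps0 / (2.0 * (1.0 + nu0))
    return lam0, mu0


@dataclass(frozen=True)
class ElasticConstants:
    """Elastic constants of the fabric-elasticity model at rho=1, M=I.

    Parameters
    ----------
    eps0
        Young's modulus of the fully dense isotropic tissue [MPa].
    nu0
        Poisson's ratio [-], in [0, 1/(d-1)).
    mu0, lambda0
        Lame constants [MPa]; must satisfy the isotropy relations for
        (eps0, nu0, d) within ``TOL_CONSISTENCY``.
    k
        Density exponent of the power law ``f(rho) = rho**k``.
    d
        Native spatial dimension the constants refer to (default 3).
    """

    eps0: float
    nu0: float
    mu0: float
    lambda0: float
    k: float = 2.0
    d: int = 3

    def __post_init__(self) -> None:
        lam_ref, mu_ref = lame_from_engineering(self.eps0, self.nu0, self.d)
        scale = max(abs(lam_ref), abs(mu_ref))
        if abs(self.mu0 - mu_ref) > TOL_CONSISTENCY * scale or (
            abs(self.lambda0 - lam_ref) > TOL_CONSISTENCY * scale
        ):
            raise DomainError(
                "Lame constants inconsistent with (eps0, nu0, d): expected "
                f"(lambda0, mu0) = ({lam_ref:.6g}, {mu_ref:.6g}), got "
                f"({self.lambda0:.6g}, {self.mu0:.6g})"
            )
        if self.mu0 <= 0 or self.lambda0 < 0:
            raise DomainError("mu0 must be positive and lambda0 nonnegative")

    @classmethod
    def from_engineering(
        cls, eps0: float, nu0: float, k: float = 2.0, d: int = 3
    ) -> "ElasticConstants":
        lam0, mu0 = lame_from_engineering(eps0, nu0, d)
        return cls(eps0=eps0, nu0=nu0, mu0=mu0, lambda0=lam0, k=k, d=d)

    def f(self, rho: float) -> float:
        """Density scaling function ``f(rho) = rho**k``."""
        return float(rho) ** self.k

    def f_inv(self, value: float) -> float:
        """Inverse of the density scaling function."""
        return float(value) ** (1.0 / self.k)

    def at_dimension(self, d: int) -> "ElasticConstants":
        """Constants of the rank-``d`` reduced model (same eps0, nu0, k).

        The Lame pair is re-derived at the active dimension so that the
        reduced stiffness is the exact inverse of the reduced compliance
        (plane-stress-like restriction; in 1D the axial stiffness is eps0).
        """
        if d == self.d:
            return self
        return ElasticConstants.from_engineering(self.eps0, self.nu0, k=self.k, d=d)


def default_elastic(d: int = 3) -> ElasticConstants:
    """Representative trabecular-bone elastic constants (10 GPa, nu 0.25, k=2)."""
    return ElasticConstants.from_engineering(10000.0, 0.25, k=2.0, d=d)


@dataclass(frozen=True)
class YieldConstants:
    """Constants of the compact quadric (tension/compression asymmetric) yield model.

    ``f0 = (1/sigma0_plus - 1/sigma0_minus)/2`` shifts the quadric and makes
    the criterion asymmetric; ``F0 = (1/sigma0_plus + 1/sigma0_minus)/2`` sets
    its mean size; ``zeta0`` shapes the surface.  The shear yield stress of
    the degenerate isotropic model is ``tau0 = (1/F0) sqrt(1/(2(1+zeta0)))``.
    """

    sigma0_plus: float
    sigma0_minus: float
    zeta0: float
    p: float = 2.0
    tau0: float | None = None

    def __post_init__(self) -> None:
        if self.sigma0_plus <= 0 or self.sigma0_minus <= 0:
            raise DomainError("uniaxial yield stresses must be positive")
        if self.zeta0 <= -1:
            raise DomainError("zeta0 must exceed -1")
        if self.tau0 is not None:
            ref = self.tau0_consistent
            if abs(self.tau0 - ref) > TOL_TAU0 * ref:
                raise DomainError(
                    f"tau0={self.tau0} inconsistent with the other constants "
                    f"(expected {ref:.4f})"
                )

    @property
    def f0(self) -> float:
        """Asymmetry coefficient [1/MPa]."""
        return 0.5 * (1.0 / self.sigma0_plus - 1.0 / self.sigma0_minus)

    @property
    def F0(self) -> float:
        """Mean inverse strength [1/MPa]."""
        return 0.5 * (1.0 / self.sigma0_plus + 1.0 / self.sigma0_minus)

    @property
    def tau0_consistent(self) -> float:
        """Shear yield stress implied by F0 and zeta0 [MPa]."""
        return (1.0 / self.F0) * math.sqrt(1.0 / (2.0 * (1.0 + self.zeta0)))

    def fhat(self, rho: float) -> float:
        """Density scaling of the yield properties, ``fhat(rho) = rho**p``."""
        return float(rho) ** self.p

    def fhat_inv(self, value: float) -> float:
        return float(value) ** (1.0 / self.p)

    def h(self, rho: float, elastic: ElasticConstants) -> float:
        """Ratio ``h(rho) = fhat(rho)/f(rho)`` of yield to elastic density scaling."""
        return self.fhat(rho) / elastic.f(rho)


def default_yield() -> YieldConstants:
    """Compact quadric yield constants for trabecular bone (54/72 MPa, zeta 0.3)."""
    return YieldConstants(sigma0_plus=54.0, sigma0_minus=72.0, zeta0=0.30, p=2.0,
                          tau0=38.27)


@dataclass(frozen=True)
class SetPoints:
    """Homeostatic set-points of the three mechanostat criteria.

    psi_set
        Normalised CFE set-point [MPa]; the default 0.2592 corresponds to a
        uniaxial strain of 0.72% at a 10 GPa modulus.
    y_set
        Yield/damage level; usually in (0, 1], but a set-point calibrated
        to a common homeostatic strain state may exceed 1.
    E_set_plus, E_set_minus
        Homeostatic strain amplitudes in tension and compression
        (both positive magnitudes; defaults 0.0054 and 0.0072, the uniaxial
        yield strains of the compact quadric model at 10 GPa).
    """

    psi_set: float = 0.2592
    y_set: float = 1.0
    E_set_plus: float = 0.0054
    E_set_minus: float = 0.0072

    def __post_init__(self) -> None:
        if min(self.psi_set, self.y_set, self.E_set_plus, self.E_set_minus) <= 0:
            raise DomainError("all set-points must be strictly positive")


# ---------------------------------------------------------------------------
# Fabric and stress states
# ---------------------------------------------------------------------------

def _check_orthonormal(axes: np.ndarray, tol: float = 1e-12) -> None:
    d = axes.shape[0]
    gram = axes @ axes.T
    if not np.allclose(gram, np.eye(d), atol=max(tol, 1e-10)):
        raise DomainError("axes rows must form an orthonormal set")


@dataclass(frozen=True)
class FabricTensor:
    """Normalised fabric tensor given by eigenvalues and eigenvector rows.

    Eigenvalues are positive and sum to the spatial dimension ``d``
    (``tr M = d``); ``axes[i]`` is the unit eigenvector of ``m[i]``.
    The eigenvalue order is preserved as given (solvers pair fabric
    eigenvalues with stress eigendirections, which need not be sorted).
    """

    m: np.ndarray
    axes: np.ndarray
    d: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "d", m.size)
        if np.any(m <= 0):
            raise DomainError(f"fabric eigenvalues must be positive, got {m}")
        if abs(m.sum() - self.d) > 1e-9:
            raise DomainError(f"fabric eigenvalues must sum to d={self.d}, got {m.sum()}")
        # axes rows are eigenvectors; they may live in a higher-dimensional
        # ambient frame when the tensor is a reduced-rank restriction
        if axes.ndim != 2 or axes.shape[0] != self.d or axes.shape[1] < self.d:
            raise DomainError("axes must be a matrix of d eigenvector rows")
        _check_orthonormal(axes)

    @classmethod
    def from_eigenvalues(
        cls,
        m: Sequence[float],
        axes: np.ndarray | None = None,
        normalise: bool = False,
    ) -> "FabricTensor":
        m = np.asarray(m, dtype=float)
        d = m.size
        if normalise:
            if np.any(m <= 0):
                raise DomainError("fabric eigenvalues must be positive")
            m = d * m / m.sum()
        if axes is None:
            axes = np.eye(d)
        return cls(m=m, axes=np.asarray(axes, dtype=float))

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "FabricTensor":
        M = np.asarray(M, dtype=float)
        vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
        return cls(m=vals, axes=vecs.T)

    @classmethod
    def isotropic(cls, d: int = 3) -> "FabricTensor":
        return cls(m=np.ones(d), axes=np.eye(d))

    @property
    def DA(self) -> float:
        """Degree of anisotropy, largest over smallest eigenvalue."""
        return float(self.m.max() / self.m.min())

    def matrix(self) -> np.ndarray:
        return self.axes.T @ np.diag(self.m) @ self.axes

    def inverse_matrix(self) -> np.ndarray:
        return self.axes.T @ np.diag(1.0 / self.m) @ self.axes

    def ascending(self) -> "FabricTensor":
        order = np.argsort(self.m)
        return FabricTensor(m=self.m[order], axes=self.axes[order])


def normalise_fabric(
    raw_eigenvalues: Sequence[float], exponent: float = 1.0, d: int | None = None
) -> np.ndarray:
    """Power-transform and trace-normalise raw fabric eigenvalues.

    ``m_i = d * m~_i**n / sum_j m~_j**n`` -- the power transform relates
    fabric tensors measured by different morphometric methods (MIL, MSL,
    GST); the trace normalisation makes the result density-independent.
    """
    raw = np.asarray(raw_eigenvalues, dtype=float)
    if np.any(raw <= 0):
        raise DomainError(f"raw fabric eigenvalues must be positive, got {raw}")
    if d is None:
        d = raw.size
    powered = raw**exponent
    return d * powered / powered.sum()


@dataclass(frozen=True)
class StressState:
    """Symmetric second-order tensor with its spectral decomposition.

    Used for stresses [MPa] and (with unit-free entries) strains.  The
    stress intensity is the pyramidal norm ``lambda_S = tr|S| / d`` (sum of
    absolute eigenvalues over the active dimension) and the direction is
    ``S_hat = S / lambda_S`` with ``tr|S_hat| = d``.
    """

    sigma: np.ndarray
    axes: np.ndarray
    d: int = field(init=False)

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "d", sigma.size)
        if axes.ndim != 2 or axes.shape[0] != self.d or axes.shape[1] < self.d:
            raise DomainError("axes must be a matrix of d eigenvector rows")
        _check_orthonormal(axes)

    @classmethod
    def from_matrix(cls, S: np.ndarray) -> "StressState":
        S = np.asarray(S, dtype=float)
        if S.ndim == 0 or S.size == 1:
            return cls(sigma=np.atleast_1d(S).astype(float), axes=np.eye(1))
        if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
            raise DomainError("stress tensor must be symmetric")
        vals, vecs = np.linalg.eigh(0.5 * (S + S.T))
        return cls(sigma=vals, axes=vecs.T)

    @classmethod
    def from_principal(
        cls, sigma: Sequence[float], axes: np.ndarray | None = None
    ) -> "StressState":
        sigma = np.asarray(sigma, dtype=float)
        if axes is None:
            axes = np.eye(sigma.size)
        return cls(sigma=sigma, axes=np.asarray(axes, dtype=float))

    def matrix(self) -> np.ndarray:
        return self.axes.T @ np.diag(self.sigma) @ self.axes

    @property
    def lambda_S(self) -> float:
        """Stress intensity ``tr|S| / d`` [MPa]."""
        return float(np.abs(self.sigma).sum() / self.d)

    @property
    def signs(self) -> np.ndarray:
        """Sign vector of the principal values, entries in {-1, 0, +1}."""
        scale = np.abs(self.sigma).max()
        if scale == 0:
            return np.zeros(self.d, dtype=int)
        return np.sign(np.where(np.abs(self.sigma) < TOL_REDUCE * scale, 0.0, self.sigma)).astype(int)

    def normalised(self) -> "StressState":
        """The direction S_hat with ``tr|S_hat| = d``."""
        lam = self.lambda_S
        if lam == 0:
            raise DomainError("cannot normalise the zero stress tensor")
        return StressState(sigma=self.sigma / lam, axes=self.axes)

    @property
    def sigma_hat(self) -> np.ndarray:
        return self.normalised().sigma


# ---------------------------------------------------------------------------
# Fourth-order tensors in the orthonormal (Mandel) basis
# ---------------------------------------------------------------------------

def mandel_basis(d: int) -> list[np.ndarray]:
    """Orthonormal basis of symmetric d x d tensors (Mandel convention).

    Normal basis tensors ``e_i (x) e_i`` come first; off-diagonal tensors
    ``(e_i (x) e_j + e_j (x) e_i)/sqrt(2)`` follow, so double contraction of
    symmetric tensors is the Euclidean dot product of their coordinates.
    """
    basis = [np.outer(np.eye(d)[i], np.eye(d)[i]) for i in range(d)]
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for i in range(d):
        for j in range(i + 1, d):
            B = np.zeros((d, d))
            B[i, j] = B[j, i] = inv_sqrt2
            basis.append(B)
    return basis


def sym_to_mandel(X: np.ndarray) -> np.ndarray:
    """Coordinates of a symmetric tensor in the Mandel basis."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[0]
    return np.array([np.tensordot(B, X) for B in mandel_basis(d)])


def mandel_to_sym(v: np.ndarray, d: int) -> np.ndarray:
    """Symmetric tensor from its Mandel coordinates."""
    v = np.asarray(v, dtype=float)
    return sum(vi * B for vi, B in zip(v, mandel_basis(d)))


@dataclass(frozen=True)
class FourthOrderTensor:
    """Symmetric fourth-order tensor stored as a Mandel-basis matrix.

    The matrix has size ``d(d+1)/2``; double contraction with a symmetric
    second-order tensor is a plain matrix-vector product on Mandel
    coordinates, so inverses and positive-definiteness are exact matrix
    notions (no Voigt factor bookkeeping).
    """

    matrix: np.ndarray
    d: int

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Double contraction with a symmetric tensor, returned as a tensor."""
        return mandel_to_sym(self.matrix @ sym_to_mandel(X), self.d)

    def quadratic(self, X: np.ndarray) -> float:
        """The scalar ``X : T X``."""
        v = sym_to_mandel(X)
        return float(v @ self.matrix @ v)

    def inverse(self) -> "FourthOrderTensor":
        return FourthOrderTensor(matrix=np.linalg.inv(self.matrix), d=self.d)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)


def _dyad_dyad(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mandel matrix of the tensor dyadic ``A (x) B`` (X -> (X:B) A)."""
    return np.outer(sym_to_mandel(A), sym_to_mandel(B))


def _sym_prod(A: np.ndarray) -> np.ndarray:
    """Mandel matrix of the symmetrised product ``A (s) A`` (X -> A X A)."""
    d = A.shape[0]
    basis = mandel_basis(d)
    cols = [sym_to_mandel(A @ B @ A) for B in basis]
    return np.column_stack(cols)


def build_stiffness(
    rho: float, M: FabricTensor, c: ElasticConstants
) -> FourthOrderTensor:
    """Fabric-based stiffness ``f(rho) (lambda0 M(x)M + 2 mu0 M(s)M)`` [MPa]."""
    if not 0.0 < rho <= 1.0:
        raise DomainError(f"density must lie in (0, 1], got {rho}")
    c = c.at_dimension(M.d)
    Mm = M.matrix()
    mat = c.f(rho) * (c.lambda0 * _dyad_dyad(Mm, Mm) + 2.0 * c.mu0 * _sym_prod(Mm))
    return FourthOrderTensor(matrix=0.5 * (mat + mat.T), d=M.d)


def build_compliance(
    rho: float, M: FabricTensor, c: ElasticConstants
) -> FourthOrderTensor:
    """Fabric-based compliance, the exact inverse of the stiffness [1/MPa]."""
    if not 0.0 < rho <= 1.0:
        raise DomainError(f"density must lie in (0, 1], got {rho}")
    c = c.at_dimension(M.d)
    Mi = M.inverse_matrix()
    mat = (1.0 / c.f(rho)) * (
        -(c.nu0 / c.eps0) * _dyad_dyad(Mi, Mi)
        + ((1.0 + c.nu0) / c.eps0) * _sym_prod(Mi)
    )
    return FourthOrderTensor(matrix=0.5 * (mat + mat.T), d=M.d)


def build_yield_tensors(
    rho: float, M: FabricTensor, yc: YieldConstants
) -> tuple[np.ndarray, FourthOrderTensor]:
    """Second- and fourth-order yield tensors (F [1/MPa], FF [1/MPa^2])."""
    if not 0.0 < rho <= 1.0:
        raise DomainError(f"density must lie in (0, 1], got {rho}")
    Mi2 = M.axes.T @ np.diag(1.0 / M.m**2) @ M.axes
    F = (yc.f0 / yc.fhat(rho)) * Mi2
    mat = (yc.F0**2 / yc.fhat(rho) ** 2) * (
        -yc.zeta0 * _dyad_dyad(Mi2, Mi2) + (yc.zeta0 + 1.0) * _sym_prod(Mi2)
    )
    return F, FourthOrderTensor(matrix=0.5 * (mat + mat.T), d=M.d)


# ---------------------------------------------------------------------------
# Criterion evaluations -- full-frame paths
# ---------------------------------------------------------------------------

def cfe_value(
    S: StressState,
    rho: float,
    M: FabricTensor,
    c: ElasticConstants,
    normalised: bool = True,
) -> float:
    """Complementary free energy density ``0.5 S:E(rho,M) S`` [MPa].

    With ``normalised=True`` the value is divided by ``f(rho)``, which turns
    the CFE into a density-independent strain metric of the tissue.
    """
    E = build_compliance(rho, M, c)
    value = 0.5 * E.quadratic(S.matrix())
    if normalised:
        value /= c.f(rho)
    return value


def gyc_value(S: StressState, rho: float, M: FabricTensor, yc: YieldConstants) -> float:
    """Quadric yield criterion value ``sqrt(S:FF S) + F:S`` (dimensionless).

    Positively homogeneous of degree one in stress; equals 1 on the yield
    surface.  Asymmetric in tension/compression whenever ``f0 > 0``.
    """
    F, FF = build_yield_tensors(rho, M, yc)
    Sm = S.matrix()
    return math.sqrt(max(FF.quadratic(Sm), 0.0)) + float(np.tensordot(F, Sm))


def pse_strain(
    S: StressState, rho: float, M: FabricTensor, c: ElasticConstants
) -> StressState:
    """Strain tensor ``E = E(rho, M) S`` (dimensionless).

    When the stress is diagonal in the fabric eigenbasis the strain is
    diagonal in that same basis (orthotropic decoupling of normal and
    shear components).
    """
    E = build_compliance(rho, M, c)
    return StressState.from_matrix(E.apply(S.matrix()))


def recover_density(lambda_rho: float, lambda_S: float, exponent: float) -> float:
    """Density from the ratio lambda_rho and the stress intensity lambda_S.

    ``rho = (lambda_rho * lambda_S)**(1/exponent)``; the product is the value
    of the density function, so intensities with ``lambda_rho * lambda_S > 1``
    exceed what fully dense tissue can carry and raise
    :class:`InfeasibleDensityError`.
    """
    if lambda_rho <= 0:
        raise DomainError(f"lambda_rho must be positive, got {lambda_rho}")
    if lambda_S < 0:
        raise DomainError(f"lambda_S must be nonnegative, got {lambda_S}")
    product = lambda_rho * lambda_S
    if product > 1.0 + 1e-12:
        raise InfeasibleDensityError(
            f"no density can carry this stress intensity: lambda_rho * lambda_S = "
            f"{product:.6g} > 1 (requires lambda_S <= 1/lambda_rho)"
        )
    return min(product, 1.0) ** (1.0 / exponent)


# ---------------------------------------------------------------------------
# Criterion evaluations -- aligned fast paths
#
# When stress and fabric commute (share an eigenbasis) every criterion is a
# function of the eigenvalue vectors alone; the solvers and the oracle work
# in this representation.  sig and m are eigenvalue arrays of equal length.
# ---------------------------------------------------------------------------

def cfe_aligned(sig: np.ndarray, m: np.ndarray, c: ElasticConstants) -> float:
    """Normalised CFE at rho=1 for commuting stress/fabric eigenvalues."""
    A = float(np.sum(sig / m))
    B = float(np.sum(sig**2 / m**2))
    return 0.5 * (-(c.nu0 / c.eps0) * A**2 + (1.0 + c.nu0) / c.eps0 * B)


def cfe_grad_m(sig: np.ndarray, m: np.ndarray, c: ElasticConstants) -> np.ndarray:
    """Gradient of the aligned CFE with respect to the fabric eigenvalues."""
    A = np.sum(sig / m)
    return (c.nu0 / c.eps0) * A * sig / m**2 - (1.0 + c.nu0) / c.eps0 * sig**2 / m**3


def gyc_aligned(sig: np.ndarray, m: np.ndarray, yc: YieldConstants) -> float:
    """Quadric yield value at rho=1 for commuting stress/fabric eigenvalues."""
    C = float(np.sum(sig / m**2))
    D = float(np.sum(sig**2 / m**4))
    Q = yc.F0**2 * (-yc.zeta0 * C**2 + (yc.zeta0 + 1.0) * D)
    return math.sqrt(max(Q, 0.0)) + yc.f0 * C


def gyc_grad_m(sig: np.ndarray, m: np.ndarray, yc: YieldConstants) -> np.ndarray:
    """Gradient of the aligned yield value w.r.t. the fabric eigenvalues."""
    C = np.sum(sig / m**2)
    D = np.sum(sig**2 / m**4)
    Q = yc.F0**2 * (-yc.zeta0 * C**2 + (yc.zeta0 + 1.0) * D)
    sqrtQ = math.sqrt(max(Q, 1e-300))
    return (2.0 * yc.F0**2 / sqrtQ) * (
        yc.zeta0 * C * sig / m**3 - (yc.zeta0 + 1.0) * sig**2 / m**5
    ) - 2.0 * yc.f0 * sig / m**3


def gyc_grad_sigma(sig: np.ndarray, m: np.ndarray, yc: YieldConstants) -> np.ndarray:
    """Gradient of the aligned yield value w.r.t. the stress eigenvalues."""
    C = np.sum(sig / m**2)
    D = np.sum(sig**2 / m**4)
    Q = yc.F0**2 * (-yc.zeta0 * C**2 + (yc.zeta0 + 1.0) * D)
    sqrtQ = math.sqrt(max(Q, 1e-300))
    dQ = yc.F0**2 * (-2.0 * yc.zeta0 * C / m**2 + 2.0 * (yc.zeta0 + 1.0) * sig / m**4)
    return dQ / (2.0 * sqrtQ) + yc.f0 / m**2


def strain_aligned(sig: np.ndarray, m: np.ndarray, c: ElasticConstants) -> np.ndarray:
    """Principal strains ``E(1, M) S`` for commuting stress/fabric eigenvalues."""
    A = np.sum(sig / m)
    return -(c.nu0 / c.eps0) * A / m + (1.0 + c.nu0) / c.eps0 * sig / m**2


def stiffness_normal_block(m: np.ndarray, c: ElasticConstants) -> np.ndarray:
    """Normal-stress block of the stiffness at rho=1 in the fabric eigenbasis.

    ``K_ij = lambda0 m_i m_j + 2 mu0 m_i^2 delta_ij`` with the Lame pair taken
    at the active dimension ``len(m)``.
    """
    c = c.at_dimension(m.size)
    return c.lambda0 * np.outer(m, m) + 2.0 * c.mu0 * np.diag(m**2)
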