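"""Brute-force reference minimisers for validating the optimality solvers.

These are dense-grid searches over the same feasible sets the solvers use:
the fabric simplex ``{m_i > 0, sum m_i = d}`` for the forward problem and
the per-octant stress simplex ``{s_i sigma_i >= 0, sum s_i sigma_i = d}``
for the inverse problem.  The best lattice point is refined by one
derivative-free (Nelder-Mead) local pass, keeping the oracle independent of
the gradient-based machinery in the production solvers.  Cost grows as
``resolution**(d-1)``; this is deliberate test plumbing, not a production
path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize


@dataclass(frozen=True)
class GridSpec:
    """Resolution and bounds of the brute-force lattice.

    ``resolution`` is the number of subdivisions per barycentric coordinate;
    ``bounds`` is the lower cutoff on eigenvalue weights (the criteria are
    singular at the simplex boundary); ``seed`` fixes any randomised
    refinement for determinism.
    """

    resolution: int = 60
    bounds: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 10:
            raise ValueError("resolution must be at least 10")
        if self.bounds <= 0:
            raise ValueError("bounds must be positive")


def _simplex_lattice(resolution: int, d: int) -> np.ndarray:
    """Interior lattice of the simplex {w_i > 0, sum w_i = d}, scaled to trace d."""
    R = resolution
    if d == 1:
        return np.array([[1.0]])
    if d == 2:
        i = np.arange(1, R)
        pts = np.column_stack([i, R - i]).astype(float)
    elif d == 3:
        pts = np.array(
            [[i, j, R - i - j] for i in range(1, R) for j in range(1, R - i)],
            dtype=float,
        )
    else:
        raise ValueError("oracle supports d in {1, 2, 3}")
    return d * pts / R


def _refine(
    fn: Callable[[np.ndarray], float], w0: np.ndarray, d: int
) -> tuple[np.ndarray, float]:
    """Nelder-Mead refinement in softmax coordinates from the best lattice point."""
    if d == 1:
        return np.array([1.0]), fn(np.array([1.0]))

    def m_of_z(z: np.ndarray) -> np.ndarray:
        e = np.exp(z - z.max())
        return d * e / e.sum()

    z0 = np.log(w0 / w0.sum())
    res = minimize(
        lambda z: fn(m_of_z(z)), z0, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    w = m_of_z(res.x)
    v = fn(w)
    if v <= fn(w0):
        return w, v
    return w0, fn(w0)


def grid_min_over_fabric(
    criterion_fn: Callable[[np.ndarray], float],
    spec: GridSpec,
    d: int,
) -> tuple[np.ndarray, float]:
    """Brute-force minimum of a criterion over the fabric simplex.

    ``criterion_fn`` maps a fabric eigenvalue vector (summing to ``d``) to a
    scalar.  Returns the refined argmin and its value; for a convex
    criterion the result is within one grid cell of the true minimum before
    refinement and at Nelder-Mead accuracy after it.
    """
    lattice = _simplex_lattice(spec.resolution, d)
    lattice = lattice[np.all(lattice > spec.bounds, axis=1)]
    values = np.array([criterion_fn(w) for w in lattice])
    best = lattice[int(np.argmin(values))]
    return _refine(criterion_fn, best, d)


def grid_min_over_stress(
    criterion_fn: Callable[[np.ndarray], float],
    signs: np.ndarray,
    spec: GridSpec,
    d: int,
) -> tuple[np.ndarray, float]:
    """Brute-force minimum over the octant stress simplex.

    ``criterion_fn`` maps a principal-stress vector to a scalar; the search
    runs over ``sigma = signs * w`` with ``w`` on the simplex, i.e. the part
    of the pyramidal norm surface ``tr|S_hat| = d`` in the given octant.
    Returns the refined ``sigma`` argmin and its value.
    """
    signs = np.asarray(signs, dtype=float)
    fn = lambda w: criterion_fn(signs * w)
    w, v = grid_min_over_fabric(fn, spec, d)
    return signs * w, v
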