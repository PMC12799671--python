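"""Parameter-sweep drivers, fixture generation and tabular output.

The sweeps regenerate the solution surfaces of the optimality problems as
tables: the forward sweep scans principal stress ratios over the butterfly
domain ``|sigma_1/sigma_3| <= |sigma_2/sigma_3| <= 1`` (one sign pattern of
``sigma_3`` at a time), the inverse sweep scans fabric eigenvalue ratios
``m1/m3 <= m2/m3 <= 1`` and solves every requested octant.  Rows are plain
records, collected into a pandas DataFrame whose CSV round-trips at full
precision.  Per-point failures are recorded in the ``status`` column and
never abort a sweep.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constitutive import (
    ElasticConstants,
    FabricTensor,
    SetPoints,
    StressState,
    YieldConstants,
    default_elastic,
    default_yield,
)
from .forward import (
    Criterion,
    ForwardProblem,
    SolverOptions,
    solve_forward,
)
from .inverse import InverseProblem, calibrate_set_points, solve_inverse

logger = logging.getLogger("fabricopt")


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a forward or inverse sweep.

    Forward mode scans stress ratios ``(sigma_1/sigma_3, sigma_2/sigma_3)``
    over ``ratio_range`` restricted to the butterfly domain; ``sign_patterns``
    selects the sign of the reference eigenvalue ``sigma_3``.  Inverse mode
    scans fabric ratios ``(m1/m3, m2/m3)`` with ``m1/m3 <= m2/m3`` over
    ``fabric_range``; ``octants`` selects the sign patterns searched.
    """

    mode: Literal["forward", "inverse"]
    criterion: Literal["cfe", "gyc", "pse", "all"] = "all"
    d: int = 3
    steps: int = 41
    ratio_range: tuple[float, float] = (-1.0, 1.0)
    fabric_range: tuple[float, float] = (0.3, 1.0)
    sign_patterns: tuple[int, ...] = (-1, 1)
    octants: Sequence[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if self.steps < 2:
            raise ValueError("steps must be at least 2")
        if self.fabric_range[0] <= 0:
            raise ValueError("fabric ratios must be positive")

    def criteria(self) -> list[Criterion]:
        if self.criterion == "all":
            return ["cfe", "gyc", "pse"]
        return [self.criterion]


def run_forward_sweep(
    spec: SweepSpec,
    set_points: SetPoints | None = None,
    elastic: ElasticConstants | None = None,
    yield_constants: YieldConstants | None = None,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Solve one forward problem per stress-ratio grid point.

    Returns a DataFrame with columns ``criterion, s1_ratio, s2_ratio,
    sign_pattern, m1_over_m3, m2_over_m3, lambda_rho, criterion_value,
    residual, status``, sorted by grid coordinates.
    """
    elastic = elastic or default_elastic(spec.d)
    yield_constants = yield_constants or default_yield()
    set_points = set_points or SetPoints()
    options = options or SolverOptions()
    ratios = np.linspace(*spec.ratio_range, spec.steps)
    rows = []
    for criterion in spec.criteria():
        for s3_sign in spec.sign_patterns:
            for r1, r2 in itertools.product(ratios, ratios):
                if abs(r1) > abs(r2):
                    continue
                sigma = s3_sign * np.array([r1, r2, 1.0][: spec.d])
                if np.abs(sigma).sum() == 0:
                    continue
                S_hat = StressState.from_principal(
                    spec.d * sigma / np.abs(sigma).sum()
                )
                row = {
                    "criterion": criterion,
                    "s1_ratio": r1,
                    "s2_ratio": r2,
                    "sign_pattern": s3_sign,
                    "m1_over_m3": np.nan,
                    "m2_over_m3": np.nan,
                    "lambda_rho": np.nan,
                    "criterion_value": np.nan,
                    "residual": np.nan,
                    "status": "error",
                }
                try:
                    sol = solve_forward(
                        ForwardProblem(
                            criterion=criterion, S_hat=S_hat,
                            set_points=set_points, elastic=elastic,
                            yield_constants=yield_constants, options=options,
                        )
                    )
                    m = sol.m_full
                    row.update(
                        m1_over_m3=m[0] / m[-1] if m[-1] > 0 else np.nan,
                        m2_over_m3=m[1] / m[-1] if spec.d > 2 and m[-1] > 0 else np.nan,
                        lambda_rho=sol.lambda_rho_bar,
                        criterion_value=sol.criterion_value,
                        residual=sol.residual,
                        status=sol.status,
                    )
                except Exception as exc:  # per-point failures never abort
                    logger.debug("forward sweep point (%s, %s) failed: %s", r1, r2, exc)
                rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["criterion", "sign_pattern", "s1_ratio", "s2_ratio"], kind="stable"
    )
    df = df.reset_index(drop=True)
    _log_summary("forward", df)
    return df


def run_inverse_sweep(
    spec: SweepSpec,
    rho: float | None = None,
    set_points: SetPoints | None = None,
    elastic: ElasticConstants | None = None,
    yield_constants: YieldConstants | None = None,
    options: SolverOptions | None = None,
    calibrated: bool = True,
) -> pd.DataFrame:
    """Solve one inverse problem per fabric-ratio grid point and octant.

    Returns a DataFrame with columns ``criterion, m1_over_m3, m2_over_m3,
    octant, s1_hat, s2_hat, s3_hat, lambda_rho, criterion_value, status,
    is_global`` (one row per octant per grid point).
    """
    elastic = elastic or default_elastic(spec.d)
    yield_constants = yield_constants or default_yield()
    options = options or SolverOptions()
    if set_points is None:
        set_points = (
            calibrate_set_points(elastic, yield_constants, d=spec.d)
            if calibrated
            else SetPoints()
        )
    ratios = np.linspace(*spec.fabric_range, spec.steps)
    rows = []
    for criterion in spec.criteria():
        for r1, r2 in itertools.product(ratios, ratios):
            if spec.d == 3 and r1 > r2:
                continue
            raw = np.array([r1, r2, 1.0][-spec.d:]) if spec.d < 3 else np.array([r1, r2, 1.0])
            M = FabricTensor.from_eigenvalues(raw, normalise=True)
            try:
                sol = solve_inverse(
                    InverseProblem(
                        criterion=criterion, M=M, rho=rho,
                        set_points=set_points, elastic=elastic,
                        yield_constants=yield_constants, octants=spec.octants,
                        options=options,
                    )
                )
            except Exception as exc:
                logger.debug("inverse sweep point (%s, %s) failed: %s", r1, r2, exc)
                rows.append({
                    "criterion": criterion, "m1_over_m3": r1, "m2_over_m3": r2,
                    "octant": "", "s1_hat": np.nan, "s2_hat": np.nan,
                    "s3_hat": np.nan, "lambda_rho": np.nan,
                    "criterion_value": np.nan, "status": "error",
                    "is_global": False,
                })
                continue
            for oct_sol in sol.per_octant:
                sig = oct_sol.sigma_hat
                pad = [np.nan] * (3 - spec.d)
                svals = (list(sig) + pad) if sig is not None else [np.nan] * 3
                rows.append({
                    "criterion": criterion,
                    "m1_over_m3": r1,
                    "m2_over_m3": r2,
                    "octant": "".join("+" if s > 0 else "-" for s in oct_sol.signs),
                    "s1_hat": svals[0],
                    "s2_hat": svals[1],
                    "s3_hat": svals[2],
                    "lambda_rho": oct_sol.lambda_rho,
                    "criterion_value": oct_sol.criterion_value,
                    "status": oct_sol.status,
                    "is_global": oct_sol is sol.global_solution,
                })
    df = pd.DataFrame(rows).sort_values(
        ["criterion", "m1_over_m3", "m2_over_m3", "octant"], kind="stable"
    )
    df = df.reset_index(drop=True)
    _log_summary("inverse", df)
    return df


def _log_summary(mode: str, df: pd.DataFrame) -> None:
    counts = df["status"].value_counts().to_dict()
    lam = df["lambda_rho"].replace([np.inf, -np.inf], np.nan).dropna()
    logger.info(
        "%s sweep: %d rows, statuses %s, lambda_rho in [%.4g, %.4g]",
        mode, len(df), counts,
        lam.min() if len(lam) else np.nan,
        lam.max() if len(lam) else np.nan,
    )


def generate_fixtures(
    seed: int, n: int, d: int = 3
) -> list[tuple[FabricTensor, StressState, float]]:
    """Reproducible random (fabric, unit-intensity stress, density) triples.

    Fabric eigenvalue ratios are drawn uniformly in [0.3, 1] (realistic
    trabecular anisotropy) with random orthonormal axes; stresses have
    random principal values with random sign patterns and orientations,
    normalised to unit pyramidal intensity; densities cover the trabecular
    volume-fraction range 5-45%.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        ratios = np.sort(rng.uniform(0.3, 1.0, d - 1)) if d > 1 else np.array([])
        m = np.concatenate([ratios, [1.0]])
        m = d * m / m.sum()
        Q = _random_rotation(rng, d)
        M = FabricTensor(m=m, axes=Q)
        mags = rng.uniform(0.2, 1.0, d)
        signs = rng.choice([-1.0, 1.0], d)
        sigma = mags * signs
        sigma = d * sigma / np.abs(sigma).sum()
        S = StressState(sigma=sigma, axes=_random_rotation(rng, d))
        rho = float(rng.uniform(0.05, 0.45))
        out.append((M, S, rho))
    return out


def _random_rotation(rng: np.random.Generator, d: int) -> np.ndarray:
    A = rng.normal(size=(d, d))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    return Q
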