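"""YAML configuration for material constants, set-points and solver options.

The packaged default file reproduces the representative trabecular-bone
constants (10 GPa modulus, Poisson 0.25, yield stresses 54/72 MPa, shape
factor 0.3, density exponents 2).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .constitutive import ElasticConstants, SetPoints, YieldConstants
from .forward import SolverOptions

DEFAULT_CONFIG_NAME = "default_constants.yaml"


def default_config_path() -> Path:
    return Path(str(importlib.resources.files("fabricopt") / "data" / DEFAULT_CONFIG_NAME))


def load_config(path: str | Path | None = None) -> dict:
    """Load a config file into constant/set-point/solver objects.

    Returns a dict with keys ``elastic``, ``yield``, ``setpoints``,
    ``solver``; missing sections fall back to the packaged defaults.
    """
    if path is None:
        path = default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    el = raw.get("elastic", {})
    elastic = ElasticConstants.from_engineering(
        eps0=float(el.get("eps0", 10000.0)),
        nu0=float(el.get("nu0", 0.25)),
        k=float(el.get("k", 2.0)),
        d=int(el.get("d", 3)),
    )
    if "mu0" in el:
        got, want = float(el["mu0"]), elastic.mu0
        if abs(got - want) > 1e-9 * want:
            raise ValueError(f"config mu0={got} inconsistent with eps0, nu0 (want {want})")
    yl = raw.get("yield", {})
    yield_constants = YieldConstants(
        sigma0_plus=float(yl.get("sigma0_plus", 54.0)),
        sigma0_minus=float(yl.get("sigma0_minus", 72.0)),
        zeta0=float(yl.get("zeta0", 0.30)),
        p=float(yl.get("p", 2.0)),
        tau0=float(yl["tau0"]) if "tau0" in yl else None,
    )
    sp = raw.get("setpoints", {})
    set_points = SetPoints(
        psi_set=float(sp.get("psi_set", 0.2592)),
        y_set=float(sp.get("y_set", 1.0)),
        E_set_plus=float(sp.get("E_set_plus", 0.0054)),
        E_set_minus=float(sp.get("E_set_minus", 0.0072)),
    )
    so = raw.get("solver", {})
    solver = SolverOptions(
        n_starts=int(so.get("n_starts", 8)),
        seed=int(so.get("seed", 0)),
        tol_residual=float(so.get("tol_residual", 1e-10)),
        tol_simplex=float(so.get("tol_simplex", 1e-12)),
        tol_criterion=float(so.get("tol_criterion", 1e-12)),
    )
    return {
        "elastic": elastic,
        "yield": yield_constants,
        "setpoints": set_points,
        "solver": solver,
    }
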