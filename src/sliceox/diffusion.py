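"""Steady-state oxygen reaction-diffusion solvers for brain tissue.

Two geometries are covered, both with Michaelis-Menten oxygen consumption
``cmro2 * p / (p + km)``:

* a planar slab, modeling an acute brain slice in an interface chamber with a
  single dominant oxygen supply at the surface (Dirichlet boundary) and a
  zero-flux boundary at the pO2 minimum (the slice "core"), and
* a Krogh cylinder, modeling perivascular tissue supplied by a single central
  capillary (Dirichlet at the lumen wall) with a closed outer boundary, the
  classical idealization of the tissue territory of one capillary.

Pressures are in mmHg, lengths in um, the diffusion constant in um^2/s and
the volumetric consumption rate (CMRO2) in oxygen partial-pressure
equivalents, mmHg/s.  The discretization is a node-centered second-order
finite-difference scheme on a uniform 1-um grid; the cylindrical operator is
written in flux form so that the discrete solution conserves oxygen exactly
(influx through the lumen-side face balances the summed shell consumption).
The nonlinear systems are solved by Picard iteration on the linearized
consumption term, which preserves positivity of every iterate (fully hypoxic
cores pose no special case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "ValidationError",
    "SolverError",
    "SliceModelParams",
    "KroghParams",
    "OxygenField",
    "solve_planar_steady_state",
    "solve_cylindrical_steady_state",
    "cylindrical_flux_balance",
]

#: Convergence threshold on the largest node update per iteration (mmHg).
NEWTON_TOL = 1e-6
#: Hard cap on iterations before declaring failure.
NEWTON_MAXITER = 10_000


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class SolverError(RuntimeError):
    """Raised when the steady-state iteration fails to converge.

    Carries the residual infinity-norm of the last iterate in
    :attr:`last_residual`.
    """

    def __init__(self, message: str, last_residual: float):
        super().__init__(f"{message} (last residual {last_residual:.3e})")
        self.last_residual = last_residual


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


def _check_grid_multiple(span: float, step: float, what: str) -> int:
    n = span / step
    if abs(n - round(n)) > 1e-9 * max(1.0, n):
        raise ValidationError(
            f"{what} ({span} um) must be an integer multiple of the grid step ({step} um)"
        )
    return int(round(n))


@dataclass(frozen=True)
class SliceModelParams:
    """Physical constants and geometry of the planar slice model.

    Parameters
    ----------
    surface_po2
        Dirichlet value at the slice surface (supply pO2), mmHg.
    domain_depth
        Depth of the pO2 minimum, i.e. the zero-flux boundary, um.  Must be
        an integer multiple of ``layer_thickness``.
    diffusion_constant
        Fick diffusion constant of oxygen in tissue, um^2/s.
    km
        Michaelis constant of oxygen consumption, mmHg.
    layer_thickness
        Grid spacing of the layered discretization, um.
    """

    surface_po2: float
    domain_depth: float
    diffusion_constant: float = 1600.0
    km: float = 3.0
    layer_thickness: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("surface_po2", self.surface_po2)
        _check_positive("domain_depth", self.domain_depth)
        _check_positive("diffusion_constant", self.diffusion_constant)
        _check_positive("km", self.km)
        _check_positive("layer_thickness", self.layer_thickness)
        _check_grid_multiple(self.domain_depth, self.layer_thickness, "domain_depth")

    @property
    def n_nodes(self) -> int:
        return _check_grid_multiple(self.domain_depth, self.layer_thickness, "domain_depth") + 1

    def grid(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.layer_thickness


@dataclass(frozen=True)
class KroghParams:
    """Geometry and constants of the Krogh-cylinder perivascular model.

    All radii are measured from the cylinder axis; ``capillary_radius`` is the
    lumen (vessel-compartment) radius and ``outer_radius`` the closed outer
    boundary of the tissue cylinder.  The vessel compartment is represented as
    a Dirichlet boundary held at ``capillary_po2`` (no intravascular
    gradient).
    """

    outer_radius: float
    capillary_po2: float
    cmro2: float
    capillary_radius: float = 3.0
    shell_thickness: float = 1.0
    diffusion_constant: float = 1600.0
    km: float = 3.0

    def __post_init__(self) -> None:
        _check_positive("capillary_radius", self.capillary_radius)
        _check_positive("capillary_po2", self.capillary_po2)
        _check_positive("shell_thickness", self.shell_thickness)
        _check_positive("diffusion_constant", self.diffusion_constant)
        _check_positive("km", self.km)
        if self.outer_radius <= self.capillary_radius:
            raise ValidationError(
                f"outer_radius ({self.outer_radius}) must exceed "
                f"capillary_radius ({self.capillary_radius})"
            )
        if self.cmro2 < 0 or not np.isfinite(self.cmro2):
            raise ValidationError(f"cmro2 must be >= 0, got {self.cmro2!r}")
        _check_grid_multiple(
            self.outer_radius - self.capillary_radius, self.shell_thickness, "tissue annulus"
        )

    @property
    def n_nodes(self) -> int:
        span = self.outer_radius - self.capillary_radius
        return _check_grid_multiple(span, self.shell_thickness, "tissue annulus") + 1

    def grid(self) -> np.ndarray:
        return self.capillary_radius + np.arange(self.n_nodes) * self.shell_thickness


@dataclass
class OxygenField:
    """A converged steady-state pO2 field on a 1-D grid.

    ``positions`` are depths (planar) or radii (cylindrical) in um;
    ``po2`` the node pressures in mmHg; ``boundary_value`` the Dirichlet
    supply pressure at ``positions[0]``.
    """

    geometry: str  # "planar" | "cylindrical"
    positions: np.ndarray
    po2: np.ndarray
    boundary_value: float
    iterations: int = 0
    residual: float = 0.0

    @property
    def minimum(self) -> float:
        return float(self.po2.min())

    @property
    def edge_po2(self) -> float:
        """pO2 at the closed (zero-flux) boundary — the field minimum."""
        return float(self.po2[-1])

    def sample(self, positions: np.ndarray | list[float]) -> np.ndarray:
        """Linearly interpolate the field at arbitrary positions."""
        pos = np.asarray(positions, dtype=float)
        lo, hi = self.positions[0], self.positions[-1]
        if np.any(pos < lo - 1e-9) or np.any(pos > hi + 1e-9):
            raise ValidationError(f"sample positions must lie within [{lo}, {hi}] um")
        return np.interp(pos, self.positions, self.po2)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"position_um": self.positions, "po2_mmHg": self.po2})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "geometry": self.geometry,
                "boundary_value_mmHg": self.boundary_value,
                "position_um": self.positions.tolist(),
                "po2_mmHg": self.po2.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _picard_tridiag(
    p: np.ndarray,
    linear_system_fn,
    residual_fn,
    what: str,
) -> tuple[np.ndarray, int, float]:
    """Picard iteration on the linearized consumption term.

    Each iterate freezes the saturable factor ``q = cmro2 / (p + km)`` and
    solves the resulting *linear* diffusion-uptake system exactly.  That
    system is an M-matrix, so every iterate is strictly positive — no
    clamping is needed and fully hypoxic cores (pressures underflowing to
    ~0) are handled without special cases.  Under-relaxation (0.5) kicks in
    only if the update grows between iterations.

    ``p`` holds all nodes including the fixed Dirichlet node 0; only
    ``p[1:]`` are unknowns.  Convergence: max node update < ``NEWTON_TOL``.
    """
    last_update = np.inf
    relax = 1.0
    for it in range(1, NEWTON_MAXITER + 1):
        ab, rhs = linear_system_fn(p)
        p_new = p.copy()
        p_new[1:] = solve_banded((1, 1), ab, rhs)
        update = float(np.abs(p_new[1:] - p[1:]).max())
        if update > last_update:
            relax = 0.5
        p[1:] += relax * (p_new[1:] - p[1:])
        last_update = update
        if update < NEWTON_TOL:
            return p, it, float(np.abs(residual_fn(p)).max())
    raise SolverError(
        f"{what} solver failed to converge", float(np.abs(residual_fn(p)).max())
    )


def solve_planar_steady_state(
    params: SliceModelParams,
    cmro2: float,
    initial: np.ndarray | None = None,
) -> OxygenField:
    """Solve D p'' = cmro2 * p/(p+Km) on [0, domain_depth].

    Boundary conditions: p(0) = surface pO2 (Dirichlet), dp/dx = 0 at the
    domain depth (zero flux at the pO2 minimum).  ``initial`` optionally
    warm-starts the Newton iteration with a previously converged field of the
    same shape.
    """
    if cmro2 < 0 or not np.isfinite(cmro2):
        raise ValidationError(f"cmro2 must be >= 0, got {cmro2!r}")
    x = params.grid()
    n = x.size
    ps = float(params.surface_po2)
    if cmro2 == 0.0:
        return OxygenField("planar", x, np.full(n, ps, dtype=float), ps)

    D, km, h = params.diffusion_constant, params.km, params.layer_thickness
    c = D / h**2

    def residual(p: np.ndarray) -> np.ndarray:
        F = np.empty(n - 1)
        F[:-1] = c * (p[:-2] - 2.0 * p[1:-1] + p[2:]) - cmro2 * p[1:-1] / (p[1:-1] + km)
        # ghost-node reflection at the zero-flux boundary
        F[-1] = 2.0 * c * (p[-2] - p[-1]) - cmro2 * p[-1] / (p[-1] + km)
        return F

    def linear_system(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = cmro2 / (p[1:] + km)
        ab = np.zeros((3, n - 1))
        ab[0, 1:] = c  # superdiagonal
        ab[1, :] = -2.0 * c - q
        ab[2, :-1] = c  # subdiagonal
        ab[2, -2] = 2.0 * c
        rhs = np.zeros(n - 1)
        rhs[0] = -c * ps
        return ab, rhs

    p0 = np.full(n, ps, dtype=float) if initial is None else np.asarray(initial, dtype=float).copy()
    p0[0] = ps
    p0[1:] = np.maximum(p0[1:], 0.0)
    p, its, res = _picard_tridiag(p0, linear_system, residual, "planar")
    return OxygenField("planar", x, p, ps, its, res)


def solve_cylindrical_steady_state(
    params: KroghParams,
    initial: np.ndarray | None = None,
) -> OxygenField:
    """Solve D (1/r) d/dr(r dp/dr) = cmro2 * p/(p+Km) on [r_c, R].

    Dirichlet boundary p(r_c) = capillary pO2 at the lumen wall; zero flux at
    the closed outer radius R.  The operator is discretized in flux form on
    annular control volumes so that the converged solution conserves oxygen:
    the diffusive influx through the face at r_c + h/2 equals the summed
    consumption of the tissue shells it feeds (see
    :func:`cylindrical_flux_balance`).
    """
    r = params.grid()
    n = r.size
    pc, M = float(params.capillary_po2), float(params.cmro2)
    if M == 0.0:
        return OxygenField("cylindrical", r, np.full(n, pc, dtype=float), pc)

    D, km, h = params.diffusion_constant, params.km, params.shell_thickness
    r_ip = r + h / 2.0  # outward faces
    r_im = r - h / 2.0  # inward faces
    R = params.outer_radius
    # control volumes per radian per unit length: full annuli for interior
    # nodes, a half cell [R - h/2, R] for the outer node
    vol = r * h
    vol_last = h * (R - h / 4.0) / 2.0

    def residual(p: np.ndarray) -> np.ndarray:
        F = np.empty(n - 1)
        flux_out = D * r_ip[1:-1] * (p[2:] - p[1:-1]) / h
        flux_in = D * r_im[1:-1] * (p[1:-1] - p[:-2]) / h
        F[:-1] = (flux_out - flux_in) - M * p[1:-1] / (p[1:-1] + km) * vol[1:-1]
        F[-1] = D * r_im[-1] * (p[-2] - p[-1]) / h - M * p[-1] / (p[-1] + km) * vol_last
        return F

    def linear_system(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = M / (p[1:] + km)
        ab = np.zeros((3, n - 1))
        ab[0, 1:] = D * r_ip[1:-1] / h
        ab[1, :-1] = -D * (r_ip[1:-1] + r_im[1:-1]) / h - q[:-1] * vol[1:-1]
        ab[1, -1] = -D * r_im[-1] / h - q[-1] * vol_last
        ab[2, :-2] = D * r_im[2:-1] / h
        ab[2, -2] = D * r_im[-1] / h
        rhs = np.zeros(n - 1)
        rhs[0] = -D * r_im[1] / h * pc
        return ab, rhs

    p0 = np.full(n, pc, dtype=float) if initial is None else np.asarray(initial, dtype=float).copy()
    p0[0] = pc
    p0[1:] = np.maximum(p0[1:], 0.0)
    p, its, res = _picard_tridiag(p0, linear_system, residual, "cylindrical")
    return OxygenField("cylindrical", r, p, pc, its, res)


def cylindrical_flux_balance(params: KroghParams, f: OxygenField) -> tuple[float, float]:
    """Diffusive influx at the lumen-side face vs. summed shell consumption.

    Returns ``(influx, consumption)`` per radian per unit cylinder length
    (mmHg um^2 / s).  The two agree to the Newton tolerance by construction
    of the flux-form discretization.
    """
    h = params.shell_thickness
    r = f.positions
    p = f.po2
    D, km, M = params.diffusion_constant, params.km, params.cmro2
    influx = D * (r[0] + h / 2.0) * (p[0] - p[1]) / h
    vol = r[1:-1] * h
    vol_last = h * (params.outer_radius - h / 4.0) / 2.0
    consumption = float(
        np.sum(M * p[1:-1] / (p[1:-1] + km) * vol) + M * p[-1] / (p[-1] + km) * vol_last
    )
    return float(influx), consumption
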