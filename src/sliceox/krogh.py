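"""Perivascular oxygenation maps and hypoxia-boundary extraction.

Builds on the Krogh-cylinder solver to answer the question: out to which
radius can a single capillary at a given luminal pO2 keep its tissue
territory above the hypoxia threshold (~8 mmHg, where oxidative metabolism
fails)?  Because the outer boundary is closed, the field minimum sits at the
cylinder edge, so the "minimal tissue pO2" of a cylinder is its edge value.

The scan configuration defaults reproduce the reference operating point of a
27-um supplied radius at capillary pO2 20 mmHg under a baseline CMRO2 of
34.4 mmHg/s: lumen radius 2.5 um with 0.5-um shells (the lumen radius of
cortical capillaries is not tightly constrained; 2-4 um are all plausible,
and the default is recorded here and in the docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import (
    KroghParams,
    ValidationError,
    solve_cylindrical_steady_state,
)

__all__ = [
    "KroghScanConfig",
    "HypoxiaBoundary",
    "TissueOxygenationMap",
    "minimal_ptio2",
    "hypoxia_boundary_radius",
    "oxygenation_map",
]

#: boundary_curve sentinel: even the largest scanned radius stays above threshold
BEYOND_SCAN_RANGE = "beyond_scan_range"
#: boundary_curve sentinel: even the smallest scanned radius falls below threshold
BELOW_SCAN_RANGE = "below_scan_range"


@dataclass(frozen=True)
class KroghScanConfig:
    """Scan grid and physical constants for hypoxia-boundary searches."""

    radius_min: float = 10.0
    radius_max: float = 35.0
    radius_step: float = 1.0
    capillary_radius: float = 2.5
    shell_thickness: float = 0.5
    diffusion_constant: float = 1600.0
    km: float = 3.0
    hypoxia_threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_min >= self.radius_max:
            raise ValidationError("radius_min must be below radius_max")
        if self.radius_step <= 0:
            raise ValidationError("radius_step must be positive")
        if self.capillary_radius >= self.radius_min:
            raise ValidationError("capillary_radius must be below radius_min")

    def radii(self) -> np.ndarray:
        n = int(round((self.radius_max - self.radius_min) / self.radius_step))
        return self.radius_min + np.arange(n + 1) * self.radius_step


@dataclass(frozen=True)
class HypoxiaBoundary:
    """Largest scanned radius still supplied above the hypoxia threshold.

    ``radius`` is NaN when ``status`` is a sentinel: ``beyond_scan_range``
    (all scanned radii supplied — e.g. zero consumption) or
    ``below_scan_range`` (even the smallest scanned radius hypoxic).
    """

    radius: float
    status: str  # "within" | BEYOND_SCAN_RANGE | BELOW_SCAN_RANGE

    @property
    def within_scan(self) -> bool:
        return self.status == "within"


@dataclass
class TissueOxygenationMap:
    """Edge (minimal) pO2 over a capillary-pO2 x cylinder-radius grid.

    ``min_po2[i, j]`` is the edge pO2 for ``capillary_po2_grid[i]`` and
    ``radius_grid[j]``; ``boundary_curve[i]`` the per-capillary-pO2 hypoxia
    boundary.
    """

    capillary_po2_grid: np.ndarray
    radius_grid: np.ndarray
    min_po2: np.ndarray
    boundary_curve: list[HypoxiaBoundary]
    hypoxia_threshold: float
    cmro2: float

    def to_frame(self) -> pd.DataFrame:
        pc, r = np.meshgrid(self.capillary_po2_grid, self.radius_grid, indexing="ij")
        return pd.DataFrame(
            {
                "capillary_po2_mmHg": pc.ravel(),
                "radius_um": r.ravel(),
                "min_po2_mmHg": self.min_po2.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def boundary_to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "hypoxia_threshold_mmHg": self.hypoxia_threshold,
                "cmro2_mmHg_per_s": self.cmro2,
                "capillary_po2_mmHg": self.capillary_po2_grid.tolist(),
                "boundary_radius_um": [
                    b.radius if b.within_scan else None for b in self.boundary_curve
                ],
                "status": [b.status for b in self.boundary_curve],
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def plot(self, ax=None):
        """Optional heat-map rendering (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(
            self.capillary_po2_grid, self.radius_grid, self.min_po2.T, shading="nearest"
        )
        within = [b.within_scan for b in self.boundary_curve]
        if any(within):
            ax.plot(
                self.capillary_po2_grid[within],
                [b.radius for b in self.boundary_curve if b.within_scan],
                "k-",
                lw=2,
            )
        ax.set_xlabel("capillary pO2 (mmHg)")
        ax.set_ylabel("cylinder radius (um)")
        plt.colorbar(im, ax=ax, label="minimal tissue pO2 (mmHg)")
        return ax


def _edge_po2(capillary_po2: float, cmro2: float, radius: float,
              config: KroghScanConfig, warm=None) -> tuple[float, np.ndarray]:
    kp = KroghParams(
        outer_radius=radius,
        capillary_po2=capillary_po2,
        cmro2=cmro2,
        capillary_radius=config.capillary_radius,
        shell_thickness=config.shell_thickness,
        diffusion_constant=config.diffusion_constant,
        km=config.km,
    )
    f = solve_cylindrical_steady_state(kp, initial=warm)
    return f.edge_po2, f.po2


def minimal_ptio2(kp: KroghParams) -> float:
    """Minimal tissue pO2 of a Krogh cylinder — its edge value (mmHg)."""
    return solve_cylindrical_steady_state(kp).edge_po2


def hypoxia_boundary_radius(
    capillary_po2: float,
    cmro2: float,
    config: KroghScanConfig | None = None,
) -> HypoxiaBoundary:
    """Largest scanned cylinder radius with edge pO2 above the threshold.

    Scans the configured radius range (default 10-35 um in 1-um steps) and
    returns the largest radius whose edge pO2 strictly exceeds the hypoxia
    threshold (default 8 mmHg; strict comparison — edge pO2 > threshold
    counts as supplied).  Boundaries outside the scan range are reported via
    the sentinels of :class:`HypoxiaBoundary` rather than extrapolated.
    """
    config = config or KroghScanConfig()
    radii = config.radii()
    if radii.size == 0:
        raise ValidationError("empty radius scan range")
    best: float | None = None
    for r in radii:
        edge, _ = _edge_po2(capillary_po2, cmro2, float(r), config)
        if edge > config.hypoxia_threshold:
            best = float(r)
    if best is None:
        return HypoxiaBoundary(float("nan"), BELOW_SCAN_RANGE)
    if best == radii[-1]:
        return HypoxiaBoundary(float("nan"), BEYOND_SCAN_RANGE)
    return HypoxiaBoundary(best, "within")


def oxygenation_map(
    capillary_po2_grid,
    radius_grid,
    cmro2: float,
    config: KroghScanConfig | None = None,
) -> TissueOxygenationMap:
    """Edge-pO2 map over a capillary-pO2 x radius grid with boundary curve.

    The boundary curve is computed from the map's own columns, cell-by-cell
    consistent with :func:`hypoxia_boundary_radius` on the same grid.
    """
    config = config or KroghScanConfig()
    pc_grid = np.asarray(capillary_po2_grid, dtype=float)
    r_grid = np.asarray(radius_grid, dtype=float)
    for name, g in (("capillary_po2_grid", pc_grid), ("radius_grid", r_grid)):
        if g.size == 0:
            raise ValidationError(f"{name} must be non-empty")
        if g.ndim != 1 or (g.size > 1 and np.any(np.diff(g) <= 0)):
            raise ValidationError(f"{name} must be 1-D and strictly ascending")
    if r_grid[0] <= config.capillary_radius:
        raise ValidationError("radius_grid must start above the capillary radius")

    min_po2 = np.empty((pc_grid.size, r_grid.size))
    for i, pc in enumerate(pc_grid):
        for j, r in enumerate(r_grid):
            min_po2[i, j], _ = _edge_po2(float(pc), cmro2, float(r), config)

    boundary: list[HypoxiaBoundary] = []
    thr = config.hypoxia_threshold
    for i in range(pc_grid.size):
        above = min_po2[i] > thr
        if not above.any():
            boundary.append(HypoxiaBoundary(float("nan"), BELOW_SCAN_RANGE))
        elif above[-1]:
            boundary.append(HypoxiaBoundary(float("nan"), BEYOND_SCAN_RANGE))
        else:
            boundary.append(HypoxiaBoundary(float(r_grid[above][-1]), "within"))
    return TissueOxygenationMap(
        capillary_po2_grid=pc_grid,
        radius_grid=r_grid,
        min_po2=min_po2,
        boundary_curve=boundary,
        hypoxia_threshold=thr,
        cmro2=cmro2,
    )
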