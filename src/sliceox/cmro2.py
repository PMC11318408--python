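"""Inverse estimation of CMRO2 from tissue-pO2 depth profiles.

The forward model is the planar slice reaction-diffusion solution
(:mod:`sliceox.diffusion`); CMRO2 is the single adjustable parameter and is
recovered by bounded scalar least squares against the measured (depth, pO2)
records.  Two acquisition designs are supported:

* multi-step profiles (one electrode stepped through the slice, typically
  every 20 um), where the shallowest measurement serves as the Dirichlet
  supply value and is excluded from the residual set;
* three-point profiles (stationary electrodes at e.g. 40 / 100 / core um),
  where the chamber supply pO2 must be supplied explicitly.

Time-resolved CMRO2 during a spreading depolarization is obtained by fitting
each time sample of a three-electrode recording as an independent steady
state (quasi-steady-state assumption), and the cumulative metabolic cost of
an event is summarized as the area under the above-baseline excess over a
fixed horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar

from .diffusion import (
    OxygenField,
    SliceModelParams,
    ValidationError,
    solve_planar_steady_state,
)

__all__ = [
    "DepthProfile",
    "Cmro2Fit",
    "Cmro2Series",
    "FitConfig",
    "fit_cmro2",
    "fit_cmro2_timeseries",
    "excess_cmro2_auc",
]


@dataclass(frozen=True)
class DepthProfile:
    """Measured or simulated (depth, pO2) records, surface toward the core.

    ``depths`` must be strictly increasing, start at or below the surface
    supply and end at ``core_depth`` (the pO2 minimum / zero-flux boundary).
    ``surface_po2`` optionally records the chamber supply value used as the
    Dirichlet boundary for three-point fits.
    """

    depths: np.ndarray
    po2: np.ndarray
    core_depth: float
    surface_po2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "po2", np.asarray(self.po2, dtype=float))
        if self.depths.ndim != 1 or self.depths.shape != self.po2.shape:
            raise ValidationError("depths and po2 must be 1-D arrays of equal length")
        if self.depths.size < 3:
            raise ValidationError(
                f"a depth profile needs at least 3 records (three-point design), "
                f"got {self.depths.size}"
            )
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if self.depths[0] < 0:
            raise ValidationError("first depth must be >= 0")
        if abs(self.depths[-1] - self.core_depth) > 1e-9:
            raise ValidationError(
                f"last depth ({self.depths[-1]}) must equal core_depth ({self.core_depth})"
            )
        if np.any(self.po2 < 0):
            raise ValidationError("po2 records must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path, surface_po2: float | None = None) -> "DepthProfile":
        df = pd.read_csv(path, comment="#")
        return cls(
            depths=df["depth_um"].to_numpy(),
            po2=df["po2_mmHg"].to_numpy(),
            core_depth=float(df["depth_um"].iloc[-1]),
            surface_po2=surface_po2,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"depth_um": self.depths, "po2_mmHg": self.po2}).to_csv(path, index=False)


@dataclass
class Cmro2Fit:
    """Result of a single steady-state CMRO2 fit.

    ``converged`` is true only when the optimizer terminated normally and the
    estimate is interior to ``search_bounds``; a boundary hit is reported
    distinctly via ``boundary_hit``.
    """

    estimate: float
    sse: float
    n_points: int
    converged: bool
    boundary_hit: bool
    search_bounds: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "cmro2_mmHg_per_s": self.estimate,
            "sse_mmHg2": self.sse,
            "n_points": self.n_points,
            "converged": self.converged,
            "boundary_hit": self.boundary_hit,
            "search_bounds_mmHg_per_s": list(self.search_bounds),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class Cmro2Series:
    """Time-resolved CMRO2 estimates with a pre-onset baseline.

    ``window`` is the (start, end) of the pre-onset interval whose median
    estimate defines ``baseline``; the window end doubles as the event onset
    for AUC summaries unless an explicit ``onset`` is stored.
    """

    times: np.ndarray
    estimates: np.ndarray
    baseline: float
    window: tuple[float, float]
    onset: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.times.size != self.estimates.size:
            raise ValidationError("times and estimates must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "cmro2_mmHg_per_s": self.estimates})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "time_s": self.times.tolist(),
                "cmro2_mmHg_per_s": self.estimates.tolist(),
                "baseline_mmHg_per_s": self.baseline,
                "baseline_window_s": list(self.window),
                "onset_s": self.onset,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass(frozen=True)
class FitConfig:
    """Configuration of steady-state and time-resolved CMRO2 fits.

    surface_po2
        Chamber supply pO2 used as the Dirichlet boundary of three-point
        fits, mmHg.  Required; there is no sensible universal default.
    smoothing_window_s
        Length of the centered moving average applied to the pO2 channels
        before per-sample fitting; 0 disables smoothing.
    baseline_window
        (start, end) in seconds of the pre-onset interval defining the
        baseline CMRO2 as the median estimate.
    stride
        Fit every ``stride``-th time sample (downsampling of the series).
    """

    surface_po2: float
    smoothing_window_s: float = 1.0
    baseline_window: tuple[float, float] = (0.0, 30.0)
    stride: int = 1
    bounds: tuple[float, float] = (0.0, 500.0)
    xtol: float = 1e-3

    def __post_init__(self) -> None:
        if self.surface_po2 <= 0:
            raise ValidationError("surface_po2 must be strictly positive")
        if self.smoothing_window_s < 0:
            raise ValidationError("smoothing_window_s must be >= 0")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if not 0 <= self.bounds[0] < self.bounds[1]:
            raise ValidationError("bounds must satisfy 0 <= low < high")


def _minimize_sse(
    depths: np.ndarray,
    observed: np.ndarray,
    params: SliceModelParams,
    bounds: tuple[float, float],
    xtol: float,
    warm: list,
) -> tuple[float, float, bool]:
    """Bounded scalar least squares for CMRO2; returns (estimate, sse, ok)."""

    def objective(m: float) -> float:
        f = solve_planar_steady_state(params, m, initial=warm[0])
        warm[0] = f.po2
        return float(np.sum((f.sample(depths) - observed) ** 2))

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xtol}
    )
    return float(res.x), float(res.fun), bool(res.success)


def fit_cmro2(
    profile: DepthProfile,
    params: SliceModelParams | None = None,
    *,
    surface_po2: float | None = None,
    use_shallowest_as_surface: bool = False,
    bounds: tuple[float, float] = (0.0, 500.0),
    xtol: float = 1e-3,
    diffusion_constant: float = 1600.0,
    km: float = 3.0,
    layer_thickness: float = 1.0,
) -> Cmro2Fit:
    """Estimate CMRO2 from a depth profile by bounded scalar least squares.

    The estimate minimizes the unweighted sum of squared differences between
    the forward planar steady state and the measured pO2 at the recorded
    depths.  For multi-step profiles set ``use_shallowest_as_surface=True``:
    the shallowest record then provides the Dirichlet supply value and is
    excluded from the residual set, and the model domain spans from its depth
    to the core.  Otherwise the supply pO2 must be given via ``surface_po2``
    (or ``profile.surface_po2`` / ``params.surface_po2``).

    Deterministic for fixed inputs (golden-section/Brent line search on the
    bounded interval, tolerance ``xtol`` in mmHg/s).
    """
    if use_shallowest_as_surface:
        dirichlet = float(profile.po2[0])
        x0 = float(profile.depths[0])
        fit_depths = profile.depths[1:] - x0
        fit_po2 = profile.po2[1:]
        if fit_depths.size < 2:
            raise ValidationError("multi-step fit needs >= 2 residual points below the surface")
    else:
        dirichlet = surface_po2
        if dirichlet is None:
            dirichlet = profile.surface_po2
        if dirichlet is None and params is not None:
            dirichlet = params.surface_po2
        if dirichlet is None:
            raise ValidationError(
                "surface_po2 is required for three-point fits "
                "(chamber supply value from configuration)"
            )
        x0 = 0.0
        fit_depths = profile.depths.copy()
        fit_po2 = profile.po2

    domain = profile.core_depth - x0
    if params is not None:
        diffusion_constant = params.diffusion_constant
        km = params.km
        layer_thickness = params.layer_thickness
        if abs(params.domain_depth - profile.core_depth) > 1e-9 and not use_shallowest_as_surface:
            raise ValidationError(
                f"params.domain_depth ({params.domain_depth}) must equal "
                f"profile.core_depth ({profile.core_depth})"
            )
    model = SliceModelParams(
        surface_po2=float(dirichlet),
        domain_depth=domain,
        diffusion_constant=diffusion_constant,
        km=km,
        layer_thickness=layer_thickness,
    )
    warm = [None]
    estimate, sse, ok = _minimize_sse(fit_depths, fit_po2, model, bounds, xtol, warm)
    # bounded Brent cannot land exactly on a bound; flag near-boundary fits
    margin = max(10 * xtol, 1e-6 * (bounds[1] - bounds[0]))
    boundary_hit = estimate <= bounds[0] + margin or estimate >= bounds[1] - margin
    return Cmro2Fit(
        estimate=estimate,
        sse=sse,
        n_points=int(fit_depths.size),
        converged=ok and not boundary_hit,
        boundary_hit=boundary_hit,
        search_bounds=bounds,
    )


def fit_cmro2_timeseries(traces, config: FitConfig, *, core_depth: float | None = None,
                         diffusion_constant: float = 1600.0, km: float = 3.0,
                         layer_thickness: float = 1.0) -> Cmro2Series:
    """Quasi-steady time-resolved CMRO2 from a multi-electrode recording.

    ``traces`` is a :class:`sliceox.sd_traces.TraceSet` (or any object with
    ``time`` in s, a ``po2`` mapping of depth (um) -> mmHg trace, and
    ``sampling_rate``).  Each (optionally smoothed, optionally strided) time
    sample is fitted independently as a steady state — valid on time scales
    longer than the diffusive equilibration time L^2/D (~16 s for a 160-um
    domain), which is documented rather than corrected.  The baseline is the
    median estimate over ``config.baseline_window``.
    """
    if not getattr(traces, "po2", None):
        raise ValidationError("trace set has no pO2 channels")
    time = np.asarray(traces.time, dtype=float)
    if time.size == 0:
        raise ValidationError("empty trace")
    dt = np.diff(time)
    if dt.size == 0 or np.any(np.abs(dt - dt[0]) > 1e-6 * dt[0]):
        raise ValidationError("time base must be strictly uniform")
    depths = np.array(sorted(traces.po2), dtype=float)
    core = float(core_depth if core_depth is not None else depths.max())

    channels = np.vstack([np.asarray(traces.po2[d], dtype=float) for d in sorted(traces.po2)])
    if channels.shape[1] != time.size:
        raise ValidationError("pO2 channels must match the time base length")
    if np.any(~np.isfinite(channels)):
        raise ValidationError("pO2 channels contain missing samples")

    if config.smoothing_window_s > 0:
        w = max(1, int(round(config.smoothing_window_s * traces.sampling_rate)))
        if w > 1:
            channels = uniform_filter1d(channels, size=w, axis=1, mode="nearest")
    # negative excursions from noise are clamped: the forward model is >= 0
    channels = np.maximum(channels, 0.0)

    model = SliceModelParams(
        surface_po2=config.surface_po2,
        domain_depth=core,
        diffusion_constant=diffusion_constant,
        km=km,
        layer_thickness=layer_thickness,
    )
    idx = np.arange(0, time.size, config.stride)
    estimates = np.empty(idx.size)
    warm = [None]
    for j, i in enumerate(idx):
        est, _, _ = _minimize_sse(
            depths, channels[:, i], model, config.bounds, config.xtol, warm
        )
        estimates[j] = est

    t = time[idx]
    lo, hi = config.baseline_window
    pre = (t >= lo) & (t <= hi)
    if not np.any(pre):
        raise ValidationError("baseline window contains no fitted samples")
    baseline = float(np.median(estimates[pre]))
    return Cmro2Series(times=t, estimates=estimates, baseline=baseline,
                       window=(float(lo), float(hi)), onset=float(hi))


def excess_cmro2_auc(series: Cmro2Series, horizon: float = 300.0,
                     onset: float | None = None) -> float:
    """Cumulative above-baseline CMRO2 over ``[onset, onset + horizon]``.

    Trapezoidal integral of ``max(estimate - baseline, 0)`` in mmHg (i.e.
    mmHg/s x s); negative excess is clipped at zero.  ``onset`` defaults to
    the series' stored onset (the end of its baseline window).
    """
    if onset is None:
        onset = series.onset if series.onset is not None else series.window[1]
    end = onset + horizon
    if series.times[-1] < end - 1e-9:
        raise ValidationError(
            f"series ends at {series.times[-1]:.1f} s, {end - series.times[-1]:.1f} s "
            f"short of the {horizon:.0f}-s horizon after onset {onset:.1f} s"
        )
    if series.times[0] > onset + 1e-9:
        raise ValidationError("series starts after the event onset")
    excess = np.clip(series.estimates - series.baseline, 0.0, None)
    # exact endpoints by linear interpolation
    grid = np.concatenate(([onset], series.times[(series.times > onset) & (series.times < end)], [end]))
    vals = np.interp(grid, series.times, excess)
    return float(np.trapezoid(vals, grid))
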