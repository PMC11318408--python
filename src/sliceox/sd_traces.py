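"""Spreading-depolarization trace analysis.

Converts ion-sensitive-electrode voltages to extracellular potassium via the
Nernst decade relation, detects SD onset on the DC (near-zero-frequency)
local-field-potential channel, and extracts the per-event scalar features
used to characterize SD episodes: DC amplitude and duration, the peak
potassium rise and its decay landmarks (time to 50% and to 10% of the peak
rise), and the per-depth pO2 minima with a core-hypoxia flag.

A small unit helper converts vaporizer output (vol% isoflurane in the gas
phase) to the aqueous concentration via the water/gas partition coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import ValidationError

__all__ = [
    "NernstCalibration",
    "TraceSet",
    "OnsetConfig",
    "FeatureConfig",
    "SdFeatures",
    "voltage_to_potassium",
    "potassium_to_voltage",
    "detect_sd_onset",
    "extract_sd_features",
    "isoflurane_vol_percent_to_mM",
    "ideal_nernst_slope",
]

GAS_CONSTANT = 8.31446  # J / (mol K)
FARADAY = 96485.33  # C / mol


def ideal_nernst_slope(temperature_k: float = 309.15) -> float:
    """Ideal monovalent-cation Nernst slope in mV per decade at ``temperature_k``."""
    return 1000.0 * np.log(10.0) * GAS_CONSTANT * temperature_k / FARADAY


@dataclass(frozen=True)
class NernstCalibration:
    """Decade-form calibration of a K+-selective electrode.

    Real electrodes are calibrated empirically, so the slope is configurable;
    the default is the spec'd ideal slope at 36 degC (~61.36 mV/decade).
    """

    baseline_k: float = 3.0  # mM
    slope: float = 61.36  # mV per decade
    temperature: float = 309.15  # K

    def __post_init__(self) -> None:
        if self.baseline_k <= 0:
            raise ValidationError("baseline_k must be strictly positive")
        if self.slope <= 0:
            raise ValidationError("slope must be strictly positive")


def voltage_to_potassium(
    v_mv, calib: NernstCalibration, reference_mv: float | None = None
) -> np.ndarray:
    """Convert electrode voltage (mV) to [K+]o (mM).

    ``[K+]o = baseline_k * 10**((v - v_ref) / slope)``, with ``v_ref`` the
    voltage at which the electrode reads the baseline concentration.  When
    ``reference_mv`` is omitted, the median of the supplied trace is used —
    callers analyzing events should pass the median of a pre-onset baseline
    window instead.
    """
    v = np.atleast_1d(np.asarray(v_mv, dtype=float))
    if v.size == 0:
        raise ValidationError("empty voltage trace")
    ref = float(np.median(v)) if reference_mv is None else float(reference_mv)
    return calib.baseline_k * 10.0 ** ((v - ref) / calib.slope)


def potassium_to_voltage(
    k_mm, calib: NernstCalibration, reference_mv: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`voltage_to_potassium` (exact algebraic inverse)."""
    k = np.atleast_1d(np.asarray(k_mm, dtype=float))
    if k.size == 0:
        raise ValidationError("empty potassium trace")
    if np.any(k <= 0):
        raise ValidationError("potassium concentrations must be strictly positive")
    return reference_mv + calib.slope * np.log10(k / calib.baseline_k)


@dataclass
class TraceSet:
    """Uniformly sampled multi-channel SD recording.

    ``po2`` maps electrode depth (um) to the pO2 trace at that depth; the
    deepest channel is taken to be the slice core.  Exactly one of ``k``
    (already-converted mM) or ``k_voltage`` (raw electrode mV) is required.
    """

    time: np.ndarray
    dc: np.ndarray
    sampling_rate: float
    po2: dict[float, np.ndarray] = field(default_factory=dict)
    k: np.ndarray | None = None
    k_voltage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dc = np.asarray(self.dc, dtype=float)
        if self.time.size == 0:
            raise ValidationError("empty trace set")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.k is None and self.k_voltage is None:
            raise ValidationError("one of k (mM) or k_voltage (mV) is required")
        dt = np.diff(self.time)
        if dt.size and np.any(np.abs(dt - 1.0 / self.sampling_rate) > 1e-6 / self.sampling_rate):
            raise ValidationError("time base must be strictly uniform at sampling_rate")
        for name, ch in self._channels():
            if np.asarray(ch).size != self.time.size:
                raise ValidationError(f"channel {name} length differs from time base")

    def _channels(self):
        yield "dc", self.dc
        if self.k is not None:
            yield "k", self.k
        if self.k_voltage is not None:
            yield "k_voltage", self.k_voltage
        for d, ch in self.po2.items():
            yield f"po2_{d}", ch

    @property
    def core_depth(self) -> float:
        if not self.po2:
            raise ValidationError("trace set has no pO2 channels")
        return max(self.po2)

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time_s": self.time, "dc_mV": self.dc}
        if self.k_voltage is not None:
            cols["k_mV"] = np.asarray(self.k_voltage, dtype=float)
        if self.k is not None:
            cols["k_mM"] = np.asarray(self.k, dtype=float)
        for d in sorted(self.po2):
            cols[f"po2_{d:g}um_mmHg"] = np.asarray(self.po2[d], dtype=float)
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraceSet":
        df = pd.read_csv(path, comment="#")
        time = df["time_s"].to_numpy(dtype=float)
        if time.size < 2:
            raise ValidationError("trace CSV needs at least two samples")
        po2 = {}
        for col in df.columns:
            if col.startswith("po2_") and col.endswith("um_mmHg"):
                po2[float(col[len("po2_"):-len("um_mmHg")])] = df[col].to_numpy(dtype=float)
        return cls(
            time=time,
            dc=df["dc_mV"].to_numpy(dtype=float),
            sampling_rate=1.0 / float(time[1] - time[0]),
            po2=po2,
            k=df["k_mM"].to_numpy(dtype=float) if "k_mM" in df else None,
            k_voltage=df["k_mV"].to_numpy(dtype=float) if "k_mV" in df else None,
        )


@dataclass(frozen=True)
class OnsetConfig:
    """SD-onset detector settings (threshold crossing on the DC channel)."""

    baseline_window_s: float = 30.0
    sd_multiplier: float = 5.0
    absolute_floor_mv: float = 2.0
    sustain_s: float = 2.0


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings."""

    hypoxia_threshold: float = 8.0  # mmHg
    post_window_s: float = 300.0  # window after onset for minima / peaks
    dc_half_fraction: float = 0.5  # DC duration = full width at this fraction
    baseline_window_s: float = 30.0  # pre-onset window for DC / K baselines
    onset: float | None = None  # supply to skip detection


@dataclass
class SdFeatures:
    """Per-event scalar descriptors of one SD episode."""

    onset: float
    dc_amplitude: float  # mV, baseline-to-trough magnitude
    dc_duration: float  # s, full width at half the negative amplitude
    delta_k: float  # mM, K peak minus baseline
    t1_50: float  # s from K peak to 50% decay of the rise
    t2_50: float  # s from K peak to 10% decay of the rise
    min_po2: dict[float, float]  # mmHg per depth channel
    hypoxia: bool  # core minimum below threshold
    threshold: float = 8.0
    t1_50_censored: bool = False
    t2_50_censored: bool = False

    def to_dict(self) -> dict:
        return {
            "onset_s": self.onset,
            "dc_amplitude_mV": self.dc_amplitude,
            "dc_duration_s": self.dc_duration,
            "delta_k_mM": self.delta_k,
            "t1_50_s": self.t1_50,
            "t2_50_s": self.t2_50,
            "min_po2_mmHg": {f"{d:g}": v for d, v in self.min_po2.items()},
            "hypoxia": self.hypoxia,
            "hypoxia_threshold_mmHg": self.threshold,
            "t1_50_censored": self.t1_50_censored,
            "t2_50_censored": self.t2_50_censored,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_tsv_row(self) -> pd.DataFrame:
        flat = {k: v for k, v in self.to_dict().items() if not isinstance(v, dict)}
        for d, v in self.min_po2.items():
            flat[f"min_po2_{d:g}um_mmHg"] = v
        return pd.DataFrame([flat])


def detect_sd_onset(
    dc, sampling_rate: float, config: OnsetConfig | None = None
) -> float | None:
    """Detect SD onset on a DC trace; ``None`` means "no SD detected".

    The onset is the first time (s, relative to the trace start) at which
    the DC falls below ``baseline mean - max(sd_multiplier x baseline SD,
    absolute floor)`` and stays below for at least ``sustain_s``.  The
    baseline window (default the first 30 s) must precede the event.
    """
    config = config or OnsetConfig()
    x = np.asarray(dc, dtype=float)
    if x.size == 0:
        raise ValidationError("empty DC trace")
    nb = int(round(config.baseline_window_s * sampling_rate))
    if x.size <= nb:
        raise ValidationError(
            f"trace ({x.size / sampling_rate:.1f} s) shorter than the "
            f"{config.baseline_window_s:.0f}-s baseline window — no pre-event baseline"
        )
    base = x[:nb]
    drop = max(config.sd_multiplier * float(np.std(base)), config.absolute_floor_mv)
    threshold = float(np.mean(base)) - drop
    ns = max(1, int(round(config.sustain_s * sampling_rate)))
    below = x < threshold
    # sustained run of >= ns samples, searched after the baseline window
    run = 0
    for i in range(nb, x.size):
        run = run + 1 if below[i] else 0
        if run >= ns:
            return (i - run + 1) / sampling_rate
    return None


def _crossing_time(t: np.ndarray, x: np.ndarray, level: float, rising: bool) -> float:
    """First sub-sample crossing of ``level``; assumes a crossing exists."""
    if rising:
        idx = np.nonzero(x >= level)[0]
    else:
        idx = np.nonzero(x <= level)[0]
    i = idx[0]
    if i == 0:
        return float(t[0])
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(t[i])
    frac = (level - x0) / (x1 - x0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extract_sd_features(
    traces: TraceSet,
    calib: NernstCalibration | None = None,
    config: FeatureConfig | None = None,
    onset_config: OnsetConfig | None = None,
) -> SdFeatures | None:
    """Extract per-event SD features; ``None`` means "no SD detected".

    DC amplitude is the baseline-to-trough magnitude; DC duration the full
    width of the negative deflection at half (configurable fraction) of that
    amplitude, with sub-sample linear interpolation of the crossings.  The
    potassium rise is measured against the median over the pre-onset
    baseline window; its decay landmarks t1_50/t2_50 are the times from the
    K peak until decay to 50% / 10% of the rise.  A potassium trace that
    never recovers to a landmark within the recording is reported as
    censored (NaN landmark, censored flag), never fabricated.
    """
    config = config or FeatureConfig()
    calib = calib or NernstCalibration()
    t = traces.time
    fs = traces.sampling_rate

    onset = config.onset
    if onset is None:
        onset = detect_sd_onset(traces.dc, fs, onset_config)
        if onset is None:
            return None
        onset += float(t[0])

    pre = (t >= onset - config.baseline_window_s) & (t < onset)
    post = (t >= onset) & (t <= onset + config.post_window_s)
    if not pre.any():
        raise ValidationError("no samples in the pre-onset baseline window")
    if not post.any():
        raise ValidationError("no samples in the post-onset window")

    # --- DC shift ---
    dc_base = float(np.median(traces.dc[pre]))
    dc_post = traces.dc[post]
    t_post = t[post]
    i_trough = int(np.argmin(dc_post))
    dc_amplitude = max(dc_base - float(dc_post[i_trough]), 0.0)
    half = dc_base - config.dc_half_fraction * dc_amplitude
    t_out = _crossing_time(t_post[: i_trough + 1], dc_post[: i_trough + 1], half, rising=False)
    after = dc_post[i_trough:]
    if np.any(after >= half):
        t_ret = _crossing_time(t_post[i_trough:], after, half, rising=True)
        dc_duration = t_ret - t_out
    else:
        dc_duration = float("nan")  # DC never recovers within the trace

    # --- potassium ---
    if traces.k is not None:
        k = np.asarray(traces.k, dtype=float)
    else:
        v = np.asarray(traces.k_voltage, dtype=float)
        k = voltage_to_potassium(v, calib, reference_mv=float(np.median(v[pre])))
    k_base = float(np.median(k[pre]))
    k_post = k[post]
    i_peak = int(np.argmax(k_post))
    delta_k = max(float(k_post[i_peak]) - k_base, 0.0)

    decay = k_post[i_peak:]
    t_decay = t_post[i_peak:] - t_post[i_peak]
    t1_50 = t2_50 = float("nan")
    t1_cens = t2_cens = True
    lvl50 = k_base + 0.5 * delta_k
    lvl10 = k_base + 0.1 * delta_k
    if np.any(decay <= lvl50):
        t1_50 = _crossing_time(t_decay, decay, lvl50, rising=False)
        t1_cens = False
    if np.any(decay <= lvl10):
        t2_50 = _crossing_time(t_decay, decay, lvl10, rising=False)
        t2_cens = False

    # --- pO2 minima ---
    min_po2 = {d: float(np.min(np.asarray(ch, dtype=float)[post])) for d, ch in traces.po2.items()}
    hypoxia = bool(traces.po2) and min_po2[traces.core_depth] < config.hypoxia_threshold

    return SdFeatures(
        onset=float(onset),
        dc_amplitude=dc_amplitude,
        dc_duration=dc_duration,
        delta_k=delta_k,
        t1_50=t1_50,
        t2_50=t2_50,
        min_po2=min_po2,
        hypoxia=hypoxia,
        threshold=config.hypoxia_threshold,
        t1_50_censored=t1_cens,
        t2_50_censored=t2_cens,
    )


def isoflurane_vol_percent_to_mM(
    percent: float,
    partition_coefficient: float = 0.5424,
    molar_volume_l_per_mol: float = 22.414,
    decimals: int | None = None,
) -> float:
    """Aqueous isoflurane concentration (mM) from gas-phase vol%.

    ``mM = percent/100 * (1000 / molar_volume) * partition_coefficient``.
    The default molar volume is the STP value 22.414 L/mol, which reproduces
    the conventional 0.24 / 0.72 mM figures for 1% / 3%; the 310 K ideal-gas
    molar volume (~25.4 L/mol) would give ~0.21 / 0.64 mM instead — a known
    convention discrepancy, documented rather than resolved here.  Full
    precision (0.2420 / 0.7260 mM) is returned unless ``decimals`` is given;
    reported values are then truncated toward zero, the only 2-decimal
    reporting rule consistent with both conventional figures (round-half
    would turn 0.726 into 0.73).
    """
    if percent < 0:
        raise ValidationError("isoflurane percent must be >= 0")
    mm = percent / 100.0 * (1000.0 / molar_volume_l_per_mol) * partition_coefficient
    if decimals is not None:
        scale = 10.0**decimals
        return np.trunc(mm * scale + 1e-12) / scale
    return mm
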