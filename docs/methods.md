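# Methods

## Steady-state oxygen transport

Both geometries solve a reaction–diffusion balance with saturable
(Michaelis–Menten) uptake, `D ∇²p = M p/(p+Km)`, under one Dirichlet supply
boundary and one closed (zero-flux) boundary. The model assumes a
homogeneous consumption rate M (CMRO2), a constant diffusion constant, no
convective transport, and no hemoglobin — appropriate for superfused slices
and for the classic single-capillary tissue-cylinder idealization. CMRO2 is
carried throughout in oxygen partial-pressure equivalents (mmHg/s); no
conversion to molar units is attempted, so D and M need no solubility
factor.

Defaults: D = 1600 µm²/s, Km = 3 mmHg, grid spacing 1 µm (planar layers and
cylindrical shells alike). The planar domain runs from the slice surface to
the pO2 minimum (zero-flux depth, typically 160 µm); the cylindrical domain
from the capillary lumen wall r_c to the closed outer radius R, with the
vessel represented as a Dirichlet boundary (no intravascular gradient).

### Discretization and solver

Node-centered second-order finite differences; the cylindrical operator is
discretized in flux form on annular control volumes (faces at r ± h/2), so
the converged solution conserves oxygen exactly: the diffusive influx
through the lumen-side face equals the summed shell consumption to solver
tolerance (`cylindrical_flux_balance` exposes both sides; they agree to
~1e-7 relative).

The nonlinearity is handled by Picard iteration: each sweep freezes
q = M/(p+Km) and solves the resulting linear diffusion–uptake system with a
banded direct solve. Because that linear system is an M-matrix, every
iterate is strictly positive — deeply hypoxic cores (pressures
underflowing toward 0) need no clamping or special casing, and the
objective seen by the inverse fit stays smooth in M. A Newton scheme with
positivity clamping was tried first and rejected: near fully hypoxic
solutions the clamped line search can stall with a tiny step but a large
residual, which either false-converges or fails outright. Convergence:
largest node update < 1e-6 mmHg, iteration cap 10⁴ (typical: 20–30
iterations; a `SolverError` carrying the last residual is raised on
failure). Halving the grid step changes no node by more than 0.1 mmHg at
default parameters, and the planar solution agrees node-wise to < 1e-3 mmHg
with an adaptive collocation solve of the same boundary-value problem.

## CMRO2 estimation

`fit_cmro2` minimizes the unweighted SSE between the forward solution and
the measured pO2 over M ∈ [0, 500] mmHg/s (bounded Brent, tolerance 1e-3
mmHg/s). The SSE is unimodal in M for forward-generated profiles (verified
by sweep), which justifies scalar line search; fits landing at a search
bound are flagged (`boundary_hit`) rather than silently returned.

Two acquisition designs:

* **multi-step** (one electrode, ~20-µm steps): the shallowest record is
  the Dirichlet supply value and is excluded from the residual set; the
  model domain spans from its depth to the core.
* **three-point** (stationary electrodes, e.g. 40/100/core µm): the chamber
  supply pO2 must be supplied in configuration. No universally valid
  default exists — interface chambers differ — so the value is required,
  not defaulted (the demo configuration uses 150 mmHg).

Time-resolved CMRO2 treats every (optionally 1-s moving-average-smoothed,
optionally strided) time sample as an independent steady state. This
quasi-steady assumption is justified on time scales longer than the
diffusive equilibration time L²/D ≈ 16 s for a 160-µm domain; the resulting
lag during the fastest phase of SD is a documented approximation, not
corrected. The baseline is the median estimate over a configured pre-onset
window, and the cumulative metabolic cost of an event is the trapezoidal
integral of max(estimate − baseline, 0) over a 5-min (configurable)
horizon, with exact endpoint interpolation; negative excess is clipped so
post-event undershoot cannot cancel the transient.

## Perivascular oxygenation maps

`oxygenation_map` scans capillary pO2 (default 20–55 mmHg) × outer radius
(default 10–35 µm, 1-µm steps) and records the edge pO2 — the field
minimum, since the outer boundary is closed. The hypoxia boundary per
capillary pO2 is the largest scanned radius whose edge pO2 strictly exceeds
the threshold (default 8 mmHg; "supplied" means > 8). Boundaries are
reported on the scan grid without sub-grid interpolation, and positions
outside the scan are reported by explicit sentinels (`beyond_scan_range`,
`below_scan_range`) rather than extrapolated. The map stores raw solver
output without clipping.

The capillary lumen radius is not a well-constrained quantity (cortical
capillary lumina of roughly 2–4 µm are all defensible). The scan default is
2.5 µm with 0.5-µm shells, chosen once so that the reference operating
point — capillary pO2 20 mmHg, baseline CMRO2 34.4 mmHg/s — yields a
27-µm supplied radius, the canonical figure for this configuration; at a
3-µm lumen the same scan gives 29 µm. The value is a configuration entry
(`KroghScanConfig.capillary_radius`), not a constant.

## SD trace features

* **Nernst conversion**: [K⁺]o = 3 mM · 10^(Δv/s) with a configurable
  empirical slope (default: ideal monovalent slope at 36 °C, 61.36
  mV/decade); Δv is taken against the median over a 30-s pre-onset window.
* **Onset detection**: first DC sample below baseline mean −
  max(5·baseline SD, 2 mV) that stays below for ≥ 2 s; a trace shorter than
  the baseline window (e.g. started mid-event) is a validation error, and
  "no crossing" is a distinct no-SD result, not an error.
* **DC duration**: the field reports SD durations without a standard
  definition; here it is the full width at half the negative amplitude
  (configurable fraction), with sub-sample linear interpolation of both
  crossings.
* **Decay landmarks**: T1_50/T2_50 are times from the [K⁺]o peak to 50% /
  10% of the rise above baseline (the names are conventional even though
  T2_50 refers to the 10% landmark). A trace that never reaches a landmark
  reports it censored (NaN + flag) rather than fabricated.
* **Isoflurane conversion**: mM = %/100 · (1000/22.414) · 0.5424. The STP
  molar volume is used because it underlies the conventional 0.24/0.72 mM
  figures for 1%/3% (the 310-K molar volume would give ~0.21/0.64). Note
  the exact values are 0.2420 and 0.7260 mM; the conventional 2-decimal
  pair is reproduced by truncation toward zero, which is therefore the
  reporting rule when rounding is requested — full precision is always
  retained internally.

## Synthetic data

The generator emulates the landmark statistics of real recordings, not
their biophysics. Scenario defaults are the observed condition medians
where such exist: baseline CMRO2 34.4 mmHg/s rising 2.7-fold, DC duration
43 s, Δ[K⁺]o 22.6 mM with decay landmarks 20 s / 65 s. The DC amplitude
default (15 mV) and the per-channel noise SDs (pO2 1 mmHg, DC 0.2 mV,
K-electrode 0.2 mV) are placeholders at realistic orders of magnitude — no
published medians exist for them — and are exposed in configuration.

Waveforms: CMRO2(t) = baseline + excess · kernel with a smooth rise
(τ_rise = 10 s) and slow exponential decay (τ_decay = 120 s), so elevated
consumption outlasts DC recovery as observed. The DC pulse is a
sigmoid-edged negative rectangle (edge 0.5 s — SD fronts are steep) whose
half-amplitude width equals the configured duration exactly. The [K⁺]o
transient rises over 2 s and decays as a single stretched/compressed
exponential exp(−(s/τ)^β) with τ and β solved in closed form from the two
landmarks. This family was chosen because it covers *every* landmark pair
t2 > t1: the default pair (20 s, 65 s; ratio 3.25) lies in the
sub-exponential regime t2/t1 < log 0.1/log 0.5 ≈ 3.32, which no convex
mixture of exponentials (bi-exponential decay of any amplitude split) can
represent — the 50→10% decay is *faster* than any single exponential
through the 50% point. pO2 channels are exact quasi-steady forward
solutions of the planar model under CMRO2(t) (so the cross-module round
trip is exact at zero noise), plus i.i.d. Gaussian noise from per-channel
substreams of one root seed.

Paired cohorts share slice-level lognormal multipliers (default log-SD 0.3)
on baseline CMRO2 and Δ[K⁺]o between the control and treated episode of a
slice — the repeated-measures structure the paired statistics exploit. The
default fast path draws per-episode feature values directly (episode-level
lognormal factor, default log-SD 0.1), which makes thousands of replicate
cohorts affordable for calibration studies; `synthesize=True` instead
generates full trace sets and measures them with the real extraction code
(used at small n to confirm the two paths agree in distribution).

Because the generator shares the planar forward model with the estimator,
round-trip tests demonstrate correctness of the inverse machinery and the
extraction logic — not that real tissue satisfies the model. Features of
real data deliberately not emulated: SD propagation, electrode drift,
non-Gaussian artifacts, depth-dependent consumption, and any coupling of
[K⁺]o to CMRO2 beyond their common onset.

## Statistics

Wilcoxon signed-rank, two-sided, zeros dropped, average ranks for ties; the
exact null (complete enumeration via characteristic-polynomial convolution
on doubled ranks) is used for n ≤ 25 and a tie-corrected,
continuity-corrected normal approximation above, with the mode labeled in
every result. The two-sided p is P(min(W⁺, W⁻) ≤ observed), which for
tie-free data coincides with the standard doubled one-tail definition.
Bonferroni adjustment is min(1, m·p) with m = 2 by default (each treatment
level vs control, not vs each other). Summaries are median (25th, 75th
percentile) with quantiles by linear interpolation between order
statistics; the definition is fixed and recorded so summaries are
software-independent. At n = 13 the exact test's attainable size at
α = 0.05 is 0.048, so calibrated type-I rates sit just under the nominal
level.

## Pipeline

A pydantic-validated YAML config drives the run; all randomness descends
from one root seed through named substreams, and re-running a config
reproduces every output byte-identically. Every table carries the
config hash on a leading comment line; `report.json` embeds the full
configuration, hash, seed and library versions. Stages (depth-profile
design comparison, episodes/features, oxygenation maps, paired statistics)
are isolated: a failure is recorded in the report's `errors` block without
aborting independent stages.

## Problem sizes

Default analyses are desk-scale by construction: planar solves use ≤ 321
nodes and cylindrical solves ≤ 66, a depth-profile fit costs ~30 forward
solves, a full 36 × 26 oxygenation map ~1 s, and a 420-s episode at 10 Hz
with per-sample fits a few seconds (stride and sampling rate are the knobs;
the bundled demo uses stride 5). Validation studies in the test suite use
200 noisy replicates per operating point and 2000 replicate cohorts for
type-I calibration.

## Known limitations

* Homogeneous CMRO2: depth- or compartment-dependent consumption is out of
  scope; joint fitting of Km or D is deliberately not offered (they are
  fixed constants of the model).
* The quasi-steady series lags genuinely fast transients (≈ L²/D).
* The Krogh picture ignores blood flow, oxygen extraction along the
  capillary, and hemoglobin buffering; the lumen radius default is a
  calibrated convention (see above), not a measurement.
* Transient (time-dependent) diffusion and 2-D/3-D vascular geometries are
  not modeled.
* The synthetic cohort's variance components are plausibility choices
  informed by published interquartile ranges, not fitted quantities.
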