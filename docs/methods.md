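# Methods

This note records the models, defaults and numerical choices behind
`aquapos`, and what the synthetic experiments do and do not demonstrate.

## Coordinates and geodesy

All positioning runs in a local east–north tangent plane (meters)
anchored at the centroid of the receiver array, using an equirectangular
projection on a spherical Earth (R = 6 371 000 m) with an exact analytic
inverse. At array scales (≤ 5 km) the plane distance agrees with the
great-circle distance to well under 0.1%, far below the timing-induced
position error and the ±3–5 m accuracy of a handheld reference GPS, so
no ellipsoidal machinery is warranted. Depth is positive-down (surface
z = 0). Great-circle distances use the haversine formula.

## Receiver power budget

Autonomy is the closed-form energy budget `hours = V × Ah / W` for the
battery bank alone (solar recharge deliberately excluded: the budget is
the guarantee *after* a panel failure). For the reference unit —
2 × 12 V / 10 Ah, 0.65 W average, 1 W worst-case draw — this gives
369 h and 240 h respectively. Hours are reported both exact and rounded
to integers (round-half-to-even).

## Simulator

The simulator is the package's source of study conditions, not a test
fixture:

* **Tags.** Continuous pingers emit every `period` s (default 3 s,
  first emission at t₀ = 0); coded tags draw i.i.d. uniform delays on
  [30, 90] s. Signal collisions between coded tags are not modelled.
* **Detection range.** p(d) = 1 / (1 + exp(k (d − d₅₀))), with d₅₀
  solved so that p(270 m) = 0.75 — the conservative receiver spacing at
  which three quarters of emissions are recorded. The steepness
  k = 0.02 m⁻¹ is a free shape parameter (only the single anchor point
  is empirically constrained); it gives d₅₀ ≈ 325 m and a ~110 m-wide
  10–90% roll-off, a plausible shape for 69–70 kHz tags in coastal
  water.
* **Clocks.** Receivers are GPS-disciplined; residual error is modelled
  as optional per-receiver bias plus Gaussian per-detection jitter,
  default sd 10⁻⁴ s (≈ 0.15 m of range error). This magnitude is a
  calibration knob, not an empirical value; real acoustic arrival
  timing (multipath, detector latency) is noisier, so absolute accuracy
  numbers from the simulator are optimistic while all *geometric*
  effects (inside vs outside the mesh, rate-vs-distance decay) are
  preserved.
* **Tracks.** Stationary, constant-speed waypoint drift (default
  9.2 km/h, the towed-test boat speed), or a sampled CTCRW path.
* **False detections.** Poisson impostors uniform in time at a
  configurable rate per receiver-hour, flagged in a truth column.
* **Reproducibility.** All randomness flows through one injected
  `numpy` Generator; a fixed config + seed reproduces the detections
  CSV byte for byte.

The default towed-test scenario (600 s: ~4 interior waypoint legs, then
a straight run out to ~540 m from the centre) mirrors the two-phase
field protocol — accuracy inside the array, maximum operating distance
outside it — at a duration that keeps a full pipeline run under a
minute.

## Grouping and multilateration

Detections are clustered per tag by a greedy earliest-first rule: a
group opens at the earliest unconsumed detection and absorbs later
detections from unused receivers within `max_baseline/c + guard`
(guard default 0.05 s) of the opener; a repeated receiver opens the
next group. Ties break on (arrival time, receiver id). Groups smaller
than the mode's minimum (3 for 2-D, 4 for 3-D) are left unsolved and
reported.

The solver minimizes the sum of squared range-difference residuals
against the earliest-arrival reference receiver by Levenberg-damped
Gauss–Newton: λ starts at 10⁻³, ×10 on a rejected step, ÷10 on an
accepted one; convergence at step < 10⁻⁸ m, stationary gradient, or
exactly zero residual; at most 100 iterations. Starts: the receiver
centroid, then each receiver position pulled 10% toward the centroid
(avoiding the Jacobian singularity at a receiver itself). With the
minimal receiver count the two hyperbola branches can intersect twice,
both with zero residual; among near-ties (cost within 10⁻⁹ m²) the
solution nearest the array centroid is returned — the ghost lies far
outside the array and would in any case be removed by the plausibility
filter. 2-D solves fix depth at a configurable `assumed_depth`.
Residual RMS is reported per fix; with the minimal receiver count the
problem is exactly determined and the residual is ~0 by construction,
so residual diagnostics are informative only for ≥ 4 receivers.

## Filtering and geofencing

A fix is retained iff its horizontal distance to the *nearest* receiver
is ≤ 200 m (boundary retains). The alternative "within radius of every
receiver" reading is available as `scope="all"`. Distances are
horizontal because receiver positions are surface GPS positions; at
200 m range a 15 m depth offset changes the distance by < 1%.
Geofencing tests each track point against a polygon (boundary counts
inside, via `shapely.covers`) and emits one event per consecutive
state change.

## CTCRW model

Each horizontal axis is an independent integrated Ornstein–Uhlenbeck
velocity process. Over a gap Δ, with b = β (s⁻¹) and s = σ (m s^−3/2):

    v' = v e^(−bΔ) + η_v,          Var η_v = s²(1 − e^(−2bΔ))/(2b)
    x' = x + v (1 − e^(−bΔ))/b + η_x,
    Var η_x = s²/b² (Δ − 2(1 − e^(−bΔ))/b + (1 − e^(−2bΔ))/(2b))
    Cov(η_x, η_v) = s²(1 − e^(−bΔ))²/(2b²)

Observations are position + N(0, sd² I) with sd fixed (default 10 m,
the array's measured positioning accuracy) rather than estimated — with
only position data, measurement error and fast process noise are weakly
identified, so pinning sd to an externally measured value is the
honest choice. Initialization: position anchored at the first fix with
a diffuse 10⁶ m² prior variance; velocity zero-mean with 10× the
stationary variance s²/(2b). Filtering/smoothing are the exact
linear-Gaussian recursions (scalar 2×2 inner loop per axis);
predictions at a regular grid insert the grid times as unobserved
states and smooth. Fitting maximizes the filter likelihood over
(log β, log σ) by Nelder–Mead (xatol 10⁻⁶, fatol 10⁻⁸) from a
method-of-moments start (β from the lag-1 autocorrelation of empirical
velocities, σ from their variance corrected for measurement error),
plus optional random restarts. Tests verify the recursions against a
dense joint-Gaussian oracle to 10⁻⁸ and parameter recovery to a median
error well under 20% at n = 2000 fixes.

## Evaluation

* **Matching.** space: minimum spatial distance among reference samples
  within a hard ±30 s window (fixes with no candidate are counted as
  unmatched, never silently dropped); time: minimum |Δt| (ties to the
  earlier sample); space–time: minimum √(Δd² + Δt²) with unit weights
  (1 m ≡ 1 s; both weights configurable). The argmin structure implies
  the per-fix dominance ordering — space ≤ space–time ≤ time on spatial
  error and the reverse on time difference — wherever the compared
  matchers draw from the same candidate set (i.e. the space–time match
  falls inside the space window).
* **Accuracy.** Mean, sample SD (n − 1) and median of spatial error,
  overall and split by membership in the convex hull of the receivers
  (boundary inside), plus mean |Δt|.
* **Reconstruction rate.** The reference path is linearly interpolated
  at 1 s, cut into consecutive 21 s segments (exactly 7 expected
  emissions of a 3 s pinger; segment length must be a multiple of the
  period), and each segment's fix count is divided by 7. The segment's
  distance coordinate is from its midpoint path position to the
  receiver *farthest* from it. The threshold distance solves
  `fitted_rate(d) = 1/3` on an OLS line fit over a configurable
  distance range; a non-negative slope flags "no crossing", and the
  confidence interval comes from the delta method on the OLS
  coefficient covariance.

## Pipeline, formats, determinism

`run_pipeline` executes simulate → group/solve → filter → smooth →
evaluate as one batch (the field system's two-minute server loop is
infrastructure, not math), writing CSV/JSON artifacts stamped with a
SHA-256 config hash and the seed; identical config + seed reproduces
every artifact byte for byte. Timestamps are ISO 8601 UTC at
microsecond precision in files and float epoch seconds in memory
(float64 keeps ~0.1 µs resolution at 2020s epochs, comfortably below
the 0.1 ms clock jitter). Reference tracks load from GPX 1.1 or CSV;
geofences from GeoJSON polygons; configs from YAML.

## Problem sizes in the tests

The default test suite and the acceptance script use a 600 s towed
test (~200 emissions), 50 solver instances against a 0.1 m exhaustive
grid oracle, 10 000-trial detection-rate checks, and 20 × n = 2000
CTCRW recovery fits — sizes chosen so the full suite runs in a few
minutes on one core while leaving every statistical check comfortably
powered.

## Known limitations

* No waveform acoustics: multipath, Doppler, thermocline refraction and
  tag-collision behaviour are outside the simulator, so simulated
  accuracy is an optimistic bound; geometric conclusions transfer, raw
  numbers do not.
* Sound speed is a single constant; no profile or ray bending.
* Clock biases are trusted (no per-receiver bias estimation).
* 2-D solving fixes depth at an assumed value; depth-axis smoothing is
  not implemented.
* The CTCRW has no behavioural switching or drift/advection terms, and
  fitting is frequentist only.
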