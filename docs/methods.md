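# Methods

## Constitutive model and its assumptions

The skin–vessel assembly is a standard linear solid (SLS): a vessel spring
E₁ in series with a Kelvin–Voigt skin element (spring E₂ ∥ dashpot η),
giving

σ + τ_σ σ̇ = E_∞ ε + E₁ τ_σ ε̇,  τ_σ = η/(E₁+E₂),  E_∞ = E₁E₂/(E₁+E₂).

Assumptions inherited from the model class: linear viscoelasticity (small
strains), a single lumped skin layer, and the tonometric sensor reading
taken directly as the surface stress σ after unit conversion.  The vessel
modulus E₁ subsumes the stiffening effect of the 80 mmHg diastolic fill
pressure; it is therefore conditional on that fill pressure.

Solving for strain given stress yields ε̇ + aε = F (a = E₂/η).  Two
boundary conditions close the problem:

* **release** (finite indentation record): ε̂(T) = 0, because the strain
  returns to zero at the end of the unloading phase;
* **periodic** (cam-driven pulse, period T): ε̂(0) = ε̂(T), giving
  C = e^(−aT) ∫₀ᵀ e^(aτ)F dτ / (1 − e^(−aT)).

The pressure map p = K ε̂ + p₀ follows from the collapsible-tube relation
(pressure change proportional to the change of √area, hence to radial
strain).  K lumps 2r₀β√(2π); since all shape comparisons are performed on
min-max normalized waveforms, K is not identifiable from them and defaults
to 1 Pa/strain, with p₀ defaulting to the 80 mmHg diastolic offset.  Both
are configurable for absolute-pressure work.

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| E₁ | vessel modulus | Pa | 39.58 MPa | vessel-only indentation slope at 80 mmHg fill |
| E₂ | skin spring | Pa | 71.32 MPa | grid-search optimum on skin+vessel data |
| η | skin viscosity | Pa·s | 39.94 MPa·s | grid-search optimum on skin+vessel data |
| K | strain→pressure gain | Pa/strain | 1 | unidentifiable under normalization |
| p₀ | pressure offset | Pa | 80 mmHg | diastolic fill pressure |
| tip diameter | flat indenter | m | 4 mm | matches the vessel's outer diameter |
| gauge length | strain normalizer | m | 5 mm | see "open choices" below |
| grid | (0, 80 MPa]×(0, 80 MPa·s], 222 nodes/axis | — | mesh h = 80/221 | reference search protocol |
| sampling | 1000 Hz | — | dt = 1 ms | pulse-sensor rate |
| noise band | 0.1–27 Hz | Hz | — | sensor band-pass |

## Numerics

**Quadrature.** All integrals ∫e^(aτ)F dτ are evaluated with *shifted*
exponentials e^(−a(t−τ)) (non-positive exponents), so no intermediate can
overflow regardless of a·T; the release solution's genuine growth factor
e^(a(T−t)) is clamped at exp(709) so extreme rates degrade to ±inf, never
NaN.  The cumulative integral uses an exponential integrator exact for
piecewise-linear forcing (per-step weights of e^(−a·dt) against a linear
interpolant, run as a linear recurrence through `scipy.signal.lfilter`).
For a·dt ≪ 1 this agrees with the trapezoid rule to O(dt²); unlike the
trapezoid rule it stays exact in the stiff limit a·dt ≫ 1, which the η → 0
elastic limit of the forward model exercises.  Weights switch to a series
expansion below a·dt = 10⁻³ to avoid cancellation.

**Derivatives.** σ̇ and ε̇ use second-order central differences with
periodic wrap for periodic signals, and `np.gradient` with second-order
one-sided end stencils for finite records — matching the O(dt²) accuracy of
the quadrature.

**Forward model boundary condition.** For finite records the forward
(strain→stress) solve uses the causal instantaneous-elastic initial
condition σ(0) = E₁ε(0): the spring chain responds instantly and the
dashpot has no history, so a quiescent experiment starting at zero strain
starts at zero stress, and a step strain relaxes from E₁ε₀ to E_∞ε₀ with
time constant τ_σ (verified against the closed form at machine precision).

**Grid search.** The objective is evaluated at every node; ties break to
the lexicographically smallest (E₂, η).  Nodes sit at k·h, k = 1..222 with
h = 80/221 per axis unit, an open-at-zero reading of the reference
protocol (its stated node count and mesh are not mutually consistent; the
choice only affects the outermost node at 80.36).  Far-from-optimum nodes with
huge a·T can produce +inf objective values (the release solution genuinely
explodes there); they are handled transparently by the argmin.  An optional
Nelder–Mead polish within one cell is off by default so the default
behavior is the bare reference protocol.

**Identifiability under noise.** The objective valley is long and shallow
along correlated (E₂ up, η down) directions — pairs that keep a = E₂/η and
the effective compliance roughly constant fit the data almost equally well.
With 1 % full-scale force noise the grid optimum therefore slides a
seed-dependent handful of cells (each cell is only ~0.5 % of the reference
E₂) along that valley while staying on it; per-axis precision at this noise
level should be read as of order 1–5 % rather than one grid cell.

**Alignment.** Waveform overlays use the L²-optimal integer circular
shift (computed by FFT cross-correlation, ties to the smallest |shift|);
periodic integrals use uniform weights (periodic trapezoid ≡ Riemann sum).

**Augmentation index.** The cycle is anchored at the pulse foot — the
local minimum preceding the steepest upstroke, which is robust against a
dicrotic notch dipping below end-diastole — then peaks with prominence
≥ 2 % of the pulse range are sought in the first 60 % of the period.  AI is
the second peak's height over the first on the foot-anchored normalized
pulse (hence invariant to positive affine rescaling).  Without a distinct
second peak, the late-systolic shoulder (derivative closest to zero after
the first peak) stands in, flagged as a fallback.  Window, prominence and
fallback are configurable; whether AI is taken on normalized or raw
waveforms is a convention — normalized is used throughout.

## Synthetic generator: what it emulates, what it does not

Intravascular pulses are sums of three periodically wrapped Gaussian bumps
(percussion, tidal, dicrotic) scaled exactly to the 80/120 mmHg
diastolic/systolic range, at 650 or 750 ms periods and 1 kHz sampling.
Four age presets (15/35/65/85) move the tidal wave up and toward the
percussion wave with age, so the augmentation index rises monotonically
(0.42 → 0.86) as in vivo morphology trends suggest.  Sensor noise is
additive Gaussian, band-limited to 0.1–27 Hz in the frequency domain and
rescaled to the requested sd (default 0.5 mmHg); every generator is a pure
function of (parameters, seed).

On-skin signals are produced by the *exact* forward counterpart of the
reconstruction (strain→stress of the same SLS), and indentation records by
the same forward model on a triangular 1 mm @ 1 mm/s ramp.  Consequently,
round-trip and parameter-recovery tests validate the *numerics and
identifiability* of the pipeline — solver consistency, boundary conditions,
grid-search correctness — not the physical fidelity of the SLS to real
skin.  Real tissue is nonlinear and multi-layered, real pulses contain
harmonics and beat-to-beat variability the three-bump template lacks, and
real indentation has contact mechanics (the flat-punch constant-area
conversion used here is the simplest defensible choice).  Passing tests
therefore demonstrate that *if* the skin behaves like an SLS, the pipeline
recovers its parameters and inverts its filter; they do not certify the
SLS itself.

The strain gauge length is not physically pinned down; it defaults to 5 mm
and cancels in self-consistent synthetic round trips, so fitted (E₂, η)
from real data are understood as conditional on it (as on the contact-area
model).

## Open design choices made

* The fit objective integrates over the full load–release cycle, matching
  the release boundary condition anchored at "the end of the releasing
  experiment".
* The forward model's finite-record boundary condition is the causal
  initial-value convention (see Numerics), required by the step-relaxation
  closed form and by zero-start indentation records.
* The on-skin signal *leads* the intravascular pulse: the surface stress
  carries a strain-rate term (σ ≈ E_∞ε + c·ε̇), so arg(σ/ε) > 0 at the
  pulse fundamental for the reference constants. The phase lag of strain
  behind a sinusoidal stress grows with η only below the corner
  ω·η = √(E₂(E₁+E₂)) and shrinks beyond it; the monotonicity test pins the
  low-frequency regime.
* Comparisons are on normalized, L²-aligned waveforms; the period is taken
  from metadata (set by the cam speed), never re-estimated.

## Problem sizes

The shipped study uses single periods of 650/750 samples at 1 ms, 2001
sample indentation records, the full 222×222 grid (≈ 49k objective
evaluations, a few seconds), and 40-cycle ensembles — the same sizes the
protocol prescribes, so nothing is scaled down.

## Known limitations

* No wave propagation (the model is zero-dimensional), no radial-to-central
  generalized transfer function, no absolute calibration against cuff
  pressures.
* Absolute reconstructed pressures depend on (K, p₀), which shape data
  cannot identify.
* The AI shoulder fallback on peak-less pulses returns a window-edge point
  for pathological monotone-decay shapes (flagged, not silently wrong).
* Fitting assumes the vessel-only response is linear; strongly nonlinear
  vessels would bias E₁ and, through it, (E₂, η).
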