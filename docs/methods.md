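# Methods

This note records the physical model, the choice of default parameters,
the synthetic-tracking generator and its limitations, the
irreversibility estimator, and the numerical decisions behind
`rotorratchet`. Everything here is implemented in the package; nothing
is fitted after the fact.

## 1. Physical model

A rigid rotor arm of angle ϑ on a fixed pivot moves in an overdamped
bath. The composite energy landscape (in units of kBT) is

```
U(ϑ, t) = A·cos(ϑ − φ_axis)·E(t) − b · Σ_{n=0}^{N−1} exp(−c·d(ϑ, ϑ₀ + n·2π/N)²)
```

* **Obstacle wells.** `N` Gaussian wells of depth `b` (kBT) and inverse
  squared width `c` (rad⁻²), centred at `ϑ₀ + n·2π/N`. The angular
  distance `d(·,·)` is evaluated on the circle; each well is summed over
  ±1 image replicas so the landscape is exactly 2π-periodic (further
  images are below double precision for `c ≥ 1`).
* **Electric drive.** A `cos`-shaped tilt along the field axis `φ_axis`
  with amplitude `A = (4a/π)·V/V_ref`. The factor `4a/π` makes `a` the
  amplitude of the fundamental Fourier component of a square wave of
  peak `4a/π`, so the DC (`waveform="dc"`) and square-wave drives have
  comparable fundamental content. `E(t)` is ±1 square wave with period
  `T`; a Fourier-smoothed family is provided with two dialects:
  `"standard"`, the textbook square-wave partial sum
  `(4/π)Σ_{odd k} sin(2πkt/T)/k`, and `"printed"`, the sawtooth-like
  partial sum `Σ_n sin(2πnt/T)/n` that some lab notes write down as the
  “square wave” — it converges to a sawtooth of amplitude π/2, not a
  square wave, which is why both are kept and tested separately.

Dynamics are overdamped Langevin,

```
dϑ = −(1/λ)·∂U/∂ϑ·dt + sqrt(2·kBT·dt/λ)·ξ,   ξ ~ N(0, 1)
```

integrated with Euler–Maruyama (numba-compiled inner loop). Since U is
expressed in kBT, λ has units kBT·s/rad² and the free diffusion
coefficient is `D = kBT/λ`.

When a torsional spring is engaged (`SpringConfig`), a harmonic term
`½κ(ϑ − ϑ_anchor)²` acting on the *unwrapped* angle is added, modelling
an elastic tether that winds up under driving and unwinds when the
field is removed.

## 2. Default parameters and calibration rationale

The defaults are chosen so the simulated motor lands in the
experimentally relevant operating regime of micrometre-scale rotary
ratchets — hundreds of degrees per second, a fraction of a turn per
field cycle, resolvable by a 250 fps camera:

| parameter | value | rationale |
| --- | --- | --- |
| wells `N` | 2 | minimal broken-symmetry obstacle pattern |
| `a`, `b` | 4 kBT each | drive tilt and well depth both a few kBT: wells trap on the off-phase but are escapable within a half-cycle |
| `c` | 10 rad⁻² | well half-width ≈ 18°, narrow relative to the 180° spacing |
| `ϑ₀` | 45° | maximal symmetry breaking between well pattern and field axis |
| `λ` | 0.1 kBT·s/rad² | sets `D = 10 rad²/s ≈ 3.3×10⁴ deg²/s`; the well relaxation time `λ/U'' ≈ 1–2 ms` is then ≪ the 100 ms half-period, so the rotor equilibrates within each field phase (the ratchet condition), while the drive is still fast enough to beat pure diffusion |
| drive | 5 Hz square, `V = V_ref = 20` | period `T = 0.2 s ≈ 100× the well relaxation time`; the measured speed-vs-frequency curve peaks between 1 and 10 Hz |
| `dt` | 20 µs | ≈ 25× below the stiffest-curvature stability bound (section 6) |
| recording | every 200 steps → 250 fps | matches a fast sCMOS camera and gives ≥ 2 frames per millisecond-scale well event statistic we analyse (we analyse cycle-scale statistics, not intra-well dynamics) |

At these values the motor runs at ≈ 300–450 °/s (0.15–0.25 turns per
field cycle), with effective diffusion `D_eff ≈ 3–4×10⁴ deg²/s` —
far above the bare `D` because each stochastic well hop adds ~180° of
variance per cycle.

These defaults are **frozen study conditions**: all experiments,
property tests and headline numbers are produced at them (or at
explicitly stated variations such as the mirrored motor or the six-well
dwell landscape). They were fixed from the calibration reasoning above
before the quantitative experiments were run, not adjusted afterwards.

## 3. Synthetic tracking generator

`render_tip_positions` converts an angle trajectory into camera-like
tracked tip coordinates:

1. the tip position is `r·(cos ϑ, sin ϑ)` with arm radius `r = 275 nm`;
2. **motion blur**: each camera frame averages all integrator-grid
   samples falling inside its exposure window (full-frame exposure).
   Averaging positions around the circle shrinks the apparent radius by
   the phasor factor `sinc(Δϑ/2)` for a uniform sweep of Δϑ within the
   exposure — a real and tested effect of centroid tracking;
3. **localization noise**: i.i.d. Gaussian noise of σ = 20 nm per
   coordinate (≈ 4° of angle at `r = 275 nm`), seeded explicitly.

Limitations, deliberate and acknowledged: no point-spread-function
rendering or spot-fitting step (noise is injected at the centroid
level, so localization error is exactly Gaussian and angle-independent);
no frame-transfer dead time; no background, bleaching, drift of the
pivot, or tracking outliers; the pivot centre is either known or
estimated as the mean tip position. The generator is therefore a
*best-case* tracking experiment; analysis robustness to outliers is
exercised separately (`robust_slope` uses a Theil–Sen estimator).

`angles_from_positions` + `unwrap` recover ϑ(t); unwrapping chooses the
increment of minimal magnitude per frame, so it is reliable while
`|ω|·Δt_frame + noise < 180°` — at 250 fps and 450 °/s the per-frame
advance is < 2°, far inside the safe region.

## 4. Irreversibility estimator

Entropy production per stroboscopic jump is estimated from the
asymmetry of the transition density, `Δs/kB = ln[p(Δϑ)/p(−Δϑ)]`,
evaluated per lag `τ = ℓT` (default ℓ = 2, 4, 6 field cycles, sampled
stroboscopically at multiples of the drive period so the switching
landscape is at the same phase at both ends of every jump):

* **Jump pairs.** `(ϑ_wrapped at t, Δϑ unwrapped over τ)` pairs from all
  admissible start frames; at least 500 pairs per lag are required.
* **KDE.** A 2-D Gaussian kernel density over (start angle, jump), with
  per-dimension Silverman bandwidths `h = σ·n^(−1/6)` (optionally scaled
  by `bandwidth_scale`); the start-angle dimension is made periodic by
  replicating points at ϑ ± 360°. A floor of `1e-12·max(p)` keeps the
  log-ratio finite in unvisited regions.
* **Antisymmetrization.** The curve is evaluated on a symmetric Δϑ grid
  and antisymmetrized, `s(Δ) ← (s(Δ) − s(−Δ))/2`, removing even-order
  bandwidth artifacts exactly.
* **Grid range.** The Δϑ grid extends to `min over lags of (|mean jump| +
  2·sd)`, i.e. only where every lag has data; this avoids the floor
  region dominating the fit.
* **Slope.** Through-origin least squares of Δs/kB against Δϑ pooled
  over start angles (a 36-point start-angle marginalization grid), one
  slope per lag; the reported slope is the per-motor mean over lags.
  Theory predicts slope = `ω_eff/D_eff` independent of lag, and the
  lag-independence is a tested property.
* **Bias test.** `ω_eff` is the mean per-cycle advance; its 95%
  confidence interval comes from a block bootstrap over blocks of 10
  cycles (100 resamples). A motor is `biased` only if the CI excludes
  zero; unbiased motors are excluded from ensemble collapses because
  the slope normalization (below) is undefined at ω ≈ 0.
* **Collapse.** For an ensemble, each motor's curve is renormalized by
  its own `(ω_eff/D_eff)` prediction; the pooled through-origin slope of
  the renormalized curves is then exactly 1 *if and only if* the
  measured KDE slopes equal the per-motor predictions on average — the
  pooled slope is weighted so the construction does not trivialize the
  per-motor agreement, which is tested separately against the
  closed-form oracle.

**Oracle validation.** The estimator chain is validated on an exact
drift–diffusion process (`drift_diffusion_trajectory`, ω = 2 rad/s,
D = 1 rad²/s, 10⁶ frames) where the answer is known in closed form:
slope ratio 0.978, ω ratio 0.9993, D ratio 0.9997, MSD-crossover ratio
0.996. The ≈ 2% slope bias is the expected KDE smoothing bias at finite
bandwidth; tripling the bandwidth changes the motor slope by less than
a factor 2 (tested), and the acceptance criterion is 5%.

**Finite-bias caveat.** For the strongly biased default motor the
log-ratio slope exceeds the linearized `ω_eff/D_eff` by tens of percent
(e.g. 0.0120 vs 0.0081 kB/deg in the README example). This is not an
estimator failure: `ln[p(Δ)/p(−Δ)] = ωΔ/D` holds exactly only for a
Gaussian propagator, and the stroboscopic propagator of a hopping
ratchet is distinctly non-Gaussian at small lag. The identity is
recovered on the Gaussian oracle and in the weak-bias limit; the
ensemble collapse uses the prediction as a normalization, under which
the pooled slope behaves as theory requires.

## 5. Study-level experiments (`rotorratchet.experiments`)

Reusable, seeded experiment recipes shared by the tests and
`scripts/acceptance.py`. Seeds for independent replicas are derived by
`numpy.random.SeedSequence(entropy=seed, spawn_key=(tag,))` so stages
and experiments never share streams.

* **Boltzmann check** — field off, 60 walkers × 24 s, 8 s burn-in,
  samples every 2 s; χ² of the angle histogram against the
  trapezoid-averaged `exp(−U)` per bin.
* **Free diffusion** — flat landscape, 200 seeds × 2 s; `D` from the
  mean squared frame increment, compared to `kBT/λ` in SE units.
* **Symmetry nulls** — 12 seeds × 24 s each for (i) wells on the field
  axis, (ii) DC field, (iii) 80 kHz drive (period ≲ 1/100 of the well
  relaxation time, too fast to rectify); z-score of the mean drift.
* **Spring reversal** — κ = 0.5 kBT/rad². Because the thermal angle
  spread at stall, `sqrt(kBT/κ) ≈ 81°`, exceeds the deterministic
  wind-up (≈ 60°), a single on/off cycle cannot resolve the sign flip
  per motor; the protocol instead toggles the field through 8 on/off
  phases of 4 s and compares each seed's mean on-phase and off-phase
  velocity, reporting the fraction of seeds with opposite signs
  (0.98 at 50 seeds).
* **Speed vs field axis** — axis stepped 0→180° in 5° increments,
  1.6 s per axis. One 1.6 s endpoint-speed sample has sd ≈
  `sqrt(2·D_eff/1.6) ≈ 210 °/s` against a response amplitude ≈ 400 °/s,
  so a single sweep caps R² near 0.6; `speed_vs_axis_ensemble` averages
  the per-axis speeds across ≥ 6 replicate sweeps before fitting the
  second-harmonic sinusoid, mirroring multi-motor averaging in a real
  experiment. The schedule itself (5°/1.6 s) is never lengthened.
* **Collapse experiment** — 20 motors × 220 cycles; per-motor entropy
  curves, renormalization, pooled slope, bootstrap exclusion counts.

## 6. Numerical choices

* **Stability.** Euler–Maruyama for a stiff well requires
  `dt < λ/max|U''|`; the package computes `max|U''|` on a fine grid of
  the configured landscape (including the spring) and rejects any
  configuration with `dt` above 10% of that bound *before* any
  computation (`check_stability`, also enforced in `validate_config`).
  At the defaults `max|U''| ≈ 80 kBT/rad²`, bound ≈ 1.25 ms, and
  `dt = 20 µs` sits 6× below the 10% margin.
* **Time grid.** `_snap_dt` adjusts `dt` minimally so that the record
  stride and every protocol segment boundary fall exactly on integrator
  steps; segment boundaries in metadata are therefore exact.
* **Determinism.** One `numpy.random.Generator(PCG64)` per simulation,
  constructed from the explicit seed; CSV output via `%.17g` /
  `float_precision="round_trip"` so write→read→write is byte-identical.
* **MSD crossover.** `msd(τ) = 2·D_eff·τ + ω_eff²·τ²` is fitted with
  non-negative least squares on the design `[2τ, τ²]` with weights
  `1/(msd·sqrt(τ))` (equalizing relative error across decades); the
  crossover time is `t_c = 2·D_eff/ω_eff²` and a crossover is reported
  only if the ballistic term contributes > 5% at the longest lag.
* **Efficiency identity.** `efficiency_maximum` locates the maximum of
  `ε(τ) = (ω − τ/ζ_r)·τ/(ζ_eff·ω²)` by dense grid (2×10⁶ points) plus
  bounded scalar minimization, and checks `τ* = ζ_rω/2`,
  `ε_max = ζ_r/(4ζ_eff)` to 1e-9 — a deliberately brute-force check
  that the implemented load line and the closed form agree.
* **Mechanics units.** kBT at 293 K = 4.045 pN·nm; `ζ_r = πηL³` for a
  rod of length L stirring solvent of viscosity η; all converters are
  pure functions with explicit units in their names.
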