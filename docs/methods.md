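# Methods

## Model

The circuit is a non-autonomous additive rate network with four state
variables: the excitatory and inhibitory populations of a brainstem
expiratory-related area (`e_er`, `i_er`) and of the telencephalic nucleus RA
(`e_ra`, `i_ra`).  Each obeys `dx/dt = r(−x + S(arg))` with the logistic
sigmoid `S`; the sigmoid argument is affine in the state and in three
square-pulse drive signals:

* `F` — the initiating-area command, input to `e_er` only;
* `F_delayed` (`Fd`) — the command after relay through thalamus and HVC,
  input to both RA populations;
* `F_delayed2` (`Fd2`) — a second HVC burst used by the pulsatile and P1
  schedules to terminate the self-sustained segment, input to both RA
  populations (in the presets it projects onto the inhibitory one).

Because each variable relaxes toward a sigmoid output, any trajectory
started in the unit box [0, 1]⁴ stays there for all finite parameters and
drives; activities are dimensionless population means, time is in ms.

Modeling assumptions inherited from the circuit design: HVC's internal
dynamics are not modeled (its bursts are idealized square pulses),
transmission delays between directly connected nuclei are lumped into the
drive onsets, and there is no feedback from ER to RA — the network is
feedforward from the drives through RA into ER, with recurrence only inside
each area.

## Rate constants

The two inverse time constants default to `r_er = 0.1495 /ms`
(τ_ER ≈ 6.7 ms, both ER populations) and `r_ra = 0.05 /ms` (τ_RA = 20 ms,
both RA populations).  The numerical prefactors this model is built around
admit more than one reading (printed prefactors of rate equations are
notoriously sensitive to typesetting of fractions and units), so the
package treats the pair of time constants as a calibration and fixes it by
phenomenology.  Candidate parses were simulated exhaustively; only a fast
ER (a few ms) combined with a slower RA (tens of ms) reproduces all of the
following at once:

* the brief leading peak of P0 tracking the 20 ms command pulse,
* a visible interior dip during P2's 22 ms telencephalic delay,
* RA's characteristic sharp rise and tens-of-ms exponential decay after a
  10 ms burst, which carries the long P0 second lobe,
* ER-pair relaxation oscillations with periods of tens of ms (P1 ≈ 75 ms,
  pulsatile ≈ 37 ms) rather than many hundreds,
* the cooling stretch/break dichotomy (below).

A uniformly slow variant (τ_ER = 49.5 ms, τ_RA = 20 ms) is available by
passing `RateConstants(1/49.5, 1/20)`; it leaves all fixed points unchanged
(rates scale the vector field, not its zeros) but merges P0's two lobes into
a single slow hump and slows every oscillation by roughly the ratio of the
ER time constants.

## Drive schedules

All pulses have amplitude 10 (arb. units).  Fixed, published timing:
command widths 20 / 50 / 20 / 40 ms for P0 / pulsatile / P2 / P1; the HVC
burst (`Fd`) is 10 ms wide for P0 and 140 ms for P1, with 100 ms for P1's
`Fd2`; P2's telencephalic input arrives 22 ms after the command.  The
remaining timing is calibration, chosen once and documented here:

* **P0 lumped delay `d_total` = 35 ms.**  Only the HVC→RA leg of the loop
  (10 ms) is pinned; the brainstem→thalamus→HVC leg is free.  35 ms places
  the interior minimum of the resting pattern at ≈ 0.24, i.e. just above
  the default phonation threshold (10 % of the trace maximum) — the regime
  the cooling experiment probes.  The feasible window is narrow (≈ ±1 ms at
  that threshold): the dichotomy is intrinsically a threshold crossing at
  the minimum, and the schedule is calibrated to sit on the correct side of
  it at normal temperature.
* **P2 `Fd` width = 10 ms** (same as P0's HVC burst; unpinned otherwise).
* **Pulsatile `Fd` = `Fd2` = 20 ms.**  The RA subsystem of the
  pulsatile/P1 presets is bistable — an off node, a saddle near
  e_ra ≈ 0.54, and a stable "on" focus near 0.97.  A 20 ms kick lands RA
  just past the saddle, producing the slow on-manifold climb that drives
  the pulsatile segment; shorter kicks fall back to rest.
* **Segment duration (`Fd`→`Fd2` onset interval): 300 ms (pulsatile),
  450 ms (P1)** — several oscillation cycles at the respective periods
  (≈ 37 and ≈ 75 ms).
* **Baseline**: the command starts at t = 50 ms, leaving a resting baseline
  in every trace; horizons are 600 ms (P0, P2) and 800 ms (pulsatile, P1).

Cooling transforms only the HVC-derived signals: every `Fd`/`Fd2` pulse is
widened by the stretch (default 15 ms) and, in mode `both`, delayed by the
extra onset delay (default 5 ms); the command `F` is untouched, and both
runs share parameters and initial condition.

## Pattern mechanisms (as realized by the presets)

* **P0**: the command drives `e_er` directly onto its upper branch (brief
  peak).  When the command ends the ER pair falls toward rest; the RA burst
  response, arriving after the lumped delay, re-excites it onto the "on"
  branch, which then tracks RA's slow decay until the branch folds away —
  the abrupt end of the gesture.  The interior minimum is the hand-off
  between the two inputs.
* **P2**: same ER gains, but a weaker, faster-decaying RA response: the
  second lobe is a shallower modulation (its maximum stays below P0's
  plateau) and the interior dip is shallow.
* **Pulsatile / P1**: the RA pair latches into its self-sustained "on"
  state between `Fd` and `Fd2`; its tonic output places the ER pair inside
  a relaxation-oscillation regime.  The pulsatile preset couples ER more
  strongly (gains 10, 6), giving a shallower ripple on a high plateau; the
  P1 preset (gains 4.65, 4.5) yields near-full-depth harmonic-like cycles.
  `Fd2`, projecting onto RA's inhibitory population, shuts the segment
  down.

## Feature extraction

All operators act on uniformly sampled traces.  Defaults: extremum
prominence 0.02 activity units (suppresses integration ripple), phonation
threshold 10 % of the trace's global maximum (the threshold concept is
physiological but its value is a convention; a relative threshold keeps
pulse segmentation meaningful across amplitude conventions), minimum pulse
duration 2 ms.

* Extrema: prominence-filtered maxima/minima (scipy `find_peaks` on the
  trace and its negation), merged and de-duplicated so kinds alternate.
* Pulse segmentation: maximal supra-threshold runs as half-open intervals.
* Dominant period: median interval between successive maxima.
* RA amplitude trend: with ≥ 3 prominent `e_ra` peaks, the least-squares
  slope of peak heights vs. time; otherwise the slope of the `e_ra` level
  itself over the window (the RA subsystem here typically climbs
  monotonically rather than oscillating, and the level slope is what
  separates the pulsatile climb, ≈ +6·10⁻⁴/ms, from P1's saturated
  ≈ −2·10⁻⁵/ms).  |slope| < 2·10⁻⁴/ms counts as constant.  The default
  window is the self-sustained segment (end of the last `Fd` pulse to the
  first `Fd2` onset), derived from the drive metadata stored on each
  trajectory.
* Classifier (fixed constants, chosen from the preset runs before the test
  suite was frozen, not fitted): ≥ 3 maxima whose interval coefficient of
  variation is < 0.35 → oscillatory, split pulsatile/P1 at relative
  peak-to-trough ripple 0.75 (measured 0.65 vs 0.84); a single
  supra-threshold pulse with two lobe maxima and one interior minimum →
  split P0/P2 at relative minimum depth 0.5 (measured 0.25 vs 0.88);
  anything else, including traces whose maximum stays below 0.05, is
  `unknown`.

## Numerics

* **Integrator**: classical fixed-step RK4, default dt = 0.05 ms.  The
  drives are discontinuous, so an adaptive stepper buys little; a fixed
  grid makes runs bit-reproducible.  Drive values are sampled at stage
  times; the final stage of each step uses the drive's left-sided limit so
  that a pulse edge landing on a step boundary never leaks into the
  preceding step — on edge-aligned grids the scheme keeps clean 4th-order
  convergence (observed order ≈ 4.0 on the P0 preset), and unaligned edges
  cost a localized error far below dt = 0.05 ripple.  Edge comparisons
  carry a 1 ns tolerance to absorb floating-point jitter in stage times.
* **Equilibria**: roots of the rate-free residual `−x + S(args)` refined by
  scipy's damped hybrid Powell method from a regular grid of starts in the
  unit box; accepted below residual norm 1e−10, merged within 1e−6, sorted
  by `e_er`.  These tolerances are conventional.
* **Initial condition**: by default the resting state, obtained by relaxing
  the undriven circuit for 500 ms from the origin (an order of magnitude
  longer than the slowest time constant; the residual drift is ≈ 1e−8).
* **Sigmoid guard**: arguments clamped to ±700 before exponentiation; the
  model never exceeds a few hundred, so this has no effect at model scales.

## Synthetic test fixtures

`generate_fixture` produces analytic traces — a sine (known period and
extrema), a two-Gaussian bump pair (valley depth set in closed form) and a
geometrically decaying pulse train — used to test the feature operators
against exactly known answers.  They emulate trace *shapes* only: they
contain no noise, no baseline drift and none of the circuit's dynamics, so
tests passing on them validate the operators' bookkeeping (prominence,
thresholds, periods), not robustness to recorded-data artifacts.
Recorded pressure series can be loaded with `read_pressure_series`
(resampling to a uniform grid, optional min–max normalization), but no
recorded data ships with the package.

## Known limitations

* The two time constants are a phenomenological calibration (see above),
  not independently measured quantities; absolute time scales of the
  simulated patterns inherit that uncertainty.
* The cooling dichotomy at the default threshold is a genuine knife edge
  (≈ ±1 ms in the P0 delay): small changes to the threshold convention or
  schedule move the breaking point.  This sharpness is a property of the
  mechanism (a fold crossing), not of the implementation.
* The pulsatile/P1 oscillating segments depend on unpinned schedule
  parameters (kick width, segment length); other choices within the
  latching regime rescale the segment without changing the mechanism.
* No periodic HVC drive trains, no bilateral syrinx or sound synthesis, no
  spiking or conductance-based dynamics, and no noise-driven variants.
* The classifier is a rule set tuned to the four preset morphologies; it is
  not a general-purpose classifier for recorded pressure patterns.
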