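# Methods

## Model

Channel gating is a continuous-time Markov chain. The wild-type topology is

```
C0 = C1 = C2 = C3 = O = P = N = NC
                    \
                     Cf            (enabled for ΔN-style schemes)
```

* `C0..C3 = O` — the activation path: three identical voltage-sensor steps
  carrying 3.0 e₀ each, with rates `a(V) = a0·exp(V/Va)` and
  `b(V) = b0·exp(−V/Vb)`, followed by a concerted opening `ko/kc`
  (voltage-independent) carrying 1.0 e₀. The scheme's total gating charge is
  therefore 10 e₀ per channel.
* `O = P` — docking of the amino terminus near the T1 window (`kd/ku`,
  voltage-independent). **P conducts**: the pre-block state precedes pore
  occlusion.
* `P = N` — pore occlusion (`kb/kub`); `N = NC` — C-type inactivation of the
  blocked channel (`kci/kcr`). All voltage-independent; the flat voltage
  dependence of the fast decay above +20 mV motivates this.
* `O = Cf` — direct C-type entry from the open state (`kci0/kcr0`); the only
  inactivation path in ΔN-style schemes (which omit P/N/NC entirely).

Bath modulators (multiplicative on evaluated rates):

| factor | applied to | form | default |
|---|---|---|---|
| K⁺ protection of C entry | `kci`, `kci0` | `1/(1 + K/K_K)` | `K_K = 1 mM` |
| K⁺ destabilization of the C state | `kcr`, `kcr0` | `1 + g_K·K/(K + K_Kr)` | `g_K = 2.45`, `K_Kr = 5 mM` |
| K⁺ push-off of the N-terminal blocker | `kub` | `1 + θ·K/(K + K_K)` | `θ = 0.5` |
| Zn²⁺ acceleration of C entry | `kci`, `kci0` | `1 + η·Zn/(K_Zn + Zn)` | `η = 3.3`, `K_Zn = 100 µM` |
| U-type flag | `kci`, `kci0` | replaces protection by `1 + K/K_K` | off |

`K_K = 1 mM` reflects the millimolar-range protection of C-type inactivation
by external K⁺; `g_K` is solved from the published ~2× faster ΔN recovery in
isotonic K⁺; `η` and `K_Zn` from the ~3× acceleration of the I8Q slow decay
at 300 µM Zn²⁺. TEA is accepted in a `Condition` but has no effect (AKv1 is
TEA-insensitive). The reversal potential is Nernstian with `K_in = 100 mM`
(K-methanesulfonate-like internal); driving force is ohmic, no rectification.

C-type *recovery* may carry a weak hyperpolarization-favored voltage
dependence, `kcr(V) = kcr·exp(−(V+80)/Vcr)` anchored at the −80 mV holding
potential (`Vcr = None` disables it). This deviates from a strictly
voltage-independent C-path by design: for ΔN the published pair
{steady/peak 0.245 after 10 s at +40 mV with τ ≈ 3.5 s} and
{recovery τ ≈ 3.5 s at −80 mV} is algebraically incompatible with a single
voltage-independent `O = Cf` pair — the first pins `kcr(+40)` to
~5.6·10⁻⁵ ms⁻¹ while the second requires ~2.9·10⁻⁴ ms⁻¹ at −80 mV. The
calibrated `Vcr ≈ 74 mV` corresponds to ~0.35 e₀, a plausibly weak
conformational charge. Only the ΔN preset uses it.

Units throughout: ms, mV, ms⁻¹, mM (K⁺), µM (Zn²⁺), e₀ per channel; ionic
current is normalized per channel × unit conductance.

## Calibration

No rate constants are published, only fitted observables. Each preset is
produced by `calibrate_preset`:

1. **Algebraic seed.** `two_state_block` inverts a fast decay τ and a
   stationary fraction into pool-level block rates
   (α = (1−f)/τ, β = f/τ), mapped onto `kb/kub` through the pre-block
   occupancy; slow recovery τ seeds `kcr` (or `kcr0`); the activation
   midpoint is solved exactly on the equilibrium activation chain
   (`shift_activation_midpoint`, Brent root-finding on the fitted V½ of the
   analytic Q-V/G-V).
2. **Refinement.** Remaining free rates are refined by `scipy`
   `least_squares` in log-parameter space. Each residual is the *relative
   error of a simulated-and-refitted observable*: the target protocol is
   simulated (slightly coarser grid; the fits are grid-insensitive on
   noiseless data) and the same exponential-fitting pipeline extracts
   τ's, amplitude fractions, st/peak or init. Component counts are fixed
   per target during refinement so the objective stays smooth. Tolerance is
   5% per observable; an infeasible set raises `CalibrationError` naming
   the offending observables.

Calibration recipes: AKv1 frees `kb, kub, kci, kcr, θ` against the ND96
decay (τ₁, st/peak), the isotonic-K decay τ, and the ND96/isotonic-K
recovery τ's; I8Q frees `kb, kub, kci, kcr` against the ND96 slow component
(τ₂, A₂/(A₁+A₂)) and the isotonic-K row (τ, st/peak) whose two_state_block
inversion also provides the seed; ΔN frees `kci0, kcr0, Vcr` against the
10-s decay and the post-10-s-prepulse recovery. Pre-block stability is a
fixed design constant: `kd/(kd+ku) = 0.83` for AKv1 (stable pre-block),
`0.09` for I8Q (unstable). Notably, the refined AKv1 solution realizes the
~16× faster isotonic-K recovery almost entirely through the suppression of
C-type re-entry (blocked channels escape instead of cycling into NC) and
drives the push-off gain toward zero; the push-off remains available as a
parameter but is not required by the calibrated wild type.

Gating presets (`*-W391F`) reuse the parent kinetics with conductance zero,
a 10× faster midpoint-preserving activation clock — the published 10-ms
gating pulses presuppose that ON charge saturates within the pulse, which
requires the slowest sensor mode well below 10 ms even at the Q-V midpoint —
and the midpoint shift re-anchored to the published Q-V V½.

## Numerics

* **Propagation** uses the spectral decomposition of the generator (the
  schemes are trees, hence real spectra); it equals the matrix exponential
  to rounding error (contract: 1e−8; verified against `scipy.linalg.expm`
  and against a 10⁵-trajectory Gillespie ensemble within 3 SE).
  Decompositions are cached by matrix bytes. Occupancies are clipped and
  renormalized to the simplex (drift < 1e−12).
* **Sweep initialization**: each sweep starts from the holding-potential
  limit of a channel resting in C0 (equals the stationary law for
  irreducible schemes and stays physical for degenerate ones), emulating
  long inter-sweep rest intervals; sweeps are independent.
* **Sampling**: segments are sampled at the protocol interval (default
  0.1 ms for ≤2-s sweeps, coarser for multi-second segments, capped at
  12 000 samples/segment — exact propagation makes the grid a measurement
  choice, not an accuracy choice). The first sample of every segment sits
  just inside the step edge so fast gating transients and instantaneous
  ohmic jumps are resolved; gating Q-V protocols use 5-µs sampling because
  the ON transient at strong depolarizations relaxes in tens of µs.
* **Exponential fits**: multi-start τ ladder (seeds at τ_crude/3 and
  3·τ_crude from the 1/e crossing, 5 starts for double fits, amplitudes
  seeded by linear solve), bounded `least_squares`, best SSE wins, ties
  toward smaller τ₂/τ₁; τ₂/τ₁ ≤ 3 is flagged near-degenerate. Decay fits
  start at the sample of peak current; recovery fits reference t = 0 so
  amplitudes extrapolate to zero interval (the published `init`
  convention). Component selection: a second exponential is kept only if it
  improves the SSE by >10% and both amplitudes exceed 2% of the peak —
  deterministic given a trace. Fits are unweighted and unconstrained
  (Y0 free).
* **Peak location**: global maximum within the pulse; a 0.5-ms median
  filter is applied first when the trace is flagged noisy.
* **P/n subtraction** scales the command excursion by 1/n from a −140 mV
  subtraction holding, removes per-trace baselines, and subtracts the
  summed subtraction currents; linear leak and capacitive components cancel
  exactly, and the residual equals the (computed, small) nonlinear charge
  moved within the subtraction voltage range.

## What the synthetic data emulate — and what they do not

`kvclamp.synth` generates what the analysis pipeline sees in real
two-electrode voltage-clamp and cut-open-oocyte recordings:
piecewise-constant commands, exponential decays riding on a fast
activation, multi-second recovery, additive Gaussian noise (default σ = 1%
of peak), optional linear leak and a bi-exponential ~1-ms capacitive
transient (included solely to exercise P/n subtraction), and per-oocyte
spread as log-normal rate multipliers (default CV 10%, matching the
mean±SD character of published ensembles). Not emulated: series-resistance
and clamp-speed artifacts, endogenous oocyte currents, expression-level
drift, correlated (1/f) noise, and digitization effects. Passing tests
therefore demonstrate correctness of the measurement chain on model-faithful
data, not robustness to every artifact of real recordings.

## Known limitations

* With voltage-independent C-type rates, the wild-type ND96 decay carries a
  visible slow component (the published fit was a single exponential); its
  fitted fast τ, st/peak and recovery τ's are the calibrated quantities.
* The I8Q preset is calibrated to the ND96 *decay* row; its simulated ND96
  slow recovery τ comes out ~2× slower than the published recovery-table
  value — the two are not simultaneously satisfiable with voltage-
  independent `kci/kcr` (the same tension resolved for ΔN by `Vcr`, left
  unresolved here because the decay row is the binding constraint).
* The cumulative-inactivation dip at depolarized inter-pulse potentials is
  reproduced; at strongly hyperpolarized inter-pulse potentials it is
  attenuated only through faster deactivation (the docking rates carry no
  voltage dependence of their own).
* Single-channel dwell times, GHK permeation, temperature dependence and
  structural interpretation of the turret mutants are out of scope; the
  U-type-like preset (`dN-A378E`) is qualitative only (inverted K⁺
  dependence, uncalibrated magnitude).
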