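# kvclamp

Voltage-clamp simulation and analysis of coupled N-type/C-type inactivation
in Kv1 potassium channels, built around the *Aplysia* Kv1 channel (AKv1),
its amino-terminal point mutant I8Q, and the amino-terminal deletion ΔN.

## The scientific problem

Kv1 channels inactivate by two distinct mechanisms. **N-type** inactivation
is an open-channel block by the channel's own amino terminus: the terminus
first docks near the T1 domain (the *pre-block* state, still conducting),
then occludes the pore. **C-type** inactivation is a slow rearrangement of
the outer pore, suppressed by external K⁺ and accelerated by external Zn²⁺
(via a turret histidine). In wild-type AKv1 the two are tightly coupled: a
blocked channel enters the C-type state quickly, so recovery from a brief
depolarization is rate-limited by the slow C-type exit (seconds), and
repetitive short pulses cause cumulative inactivation and gating-charge
immobilization. In I8Q the pre-block state is unstable, the coupling is
inefficient, and the channel recovers mostly through fast unblocking.

`kvclamp` implements this picture as a Markov state model

```
C0 = C1 = C2 = C3 = O = P = N = NC        (+ O = Cf for ΔN-style schemes)
```

with three voltage-sensor steps (3 e₀ each), a concerted opening (1 e₀),
voltage-independent docking (kd/ku), block (kb/kub) and C-type
entry/exit (kci/kcr), and bath modulators: K⁺ protection of C-type entry,
K⁺ destabilization of the C-type state, a K⁺ "push-off" on unblocking, and
Zn²⁺ acceleration of C-type entry. Both O and P conduct. Occupancies evolve
as dp/dt = pQ(V) under piecewise-constant commands; ionic current is
`g·(p_O+p_P)·(V−E_K)` and gating current is the net charge flux of the
sensor transitions.

Because no rate constants are published — only fitted observables (decay and
recovery time constants, component fractions, steady/peak ratios, Boltzmann
midpoints) — every preset is **calibrated at run time**: the two-state
pore-block algebra (τ = 1/(α+β), stationary fraction β/(α+β)) seeds the
rates, and bounded least squares refines them until the *simulated and
re-fitted* observables match the published numbers.

The analysis pipeline mirrors standard electrophysiology practice: Boltzmann
fits `Y = Ymax/(1+exp((V−V½)/k))`, single/double exponential decomposition
`Y = Y0 + ΣAᵢ·exp(−t/τᵢ)` with a deterministic component-selection rule,
two-pulse recovery normalization with `init = 1 − Σ|Aᵢ|`, steady/peak
ratios, tandem-pulse cumulative-inactivation curves, ON gating-charge
integration, Q-V fits, charge-recovery (immobilization) analysis, and P/n
leak-subtraction emulation.

## Worked example

```sh
kvclamp demo
```

prints (each line is a calibrated preset simulated through a 1-s +40 mV step
and decomposed by the automatic decay analysis):

```
AKv1 in ND96: 2 exponential component(s) [22.0 ms, 429.8 ms], st/peak = 0.078
I8Q in ND96: 2 exponential component(s) [27.9 ms, 960.6 ms], st/peak = 0.288
I8Q in highK: 1 exponential component(s) [27.7 ms], st/peak = 0.512
```

Reading these numbers: AKv1 in the standard 2 mM K⁺ bath (ND96) inactivates
with a fast ~22-ms pore block and retains only 7.8% of its peak current
after 1 s. I8Q shows the same fast block plus a distinct slow (~1 s)
component — the signature of weak N-C coupling. In isotonic K⁺ (98 mM),
which suppresses C-type inactivation, the I8Q slow component disappears and
half the current persists (st/peak ≈ 0.51): pure, reversible N-type block.

The same machinery is available programmatically:

```python
from kvclamp import get_preset, make_step_family, simulate_ionic, analyze_decay
from kvclamp.scheme import CONDITIONS

trace = simulate_ionic(get_preset("I8Q"), CONDITIONS["ND96"],
                       make_step_family(40, 40, 10, 1000))[0]
fit = analyze_decay(trace)
fit.taus, fit.a2_frac, fit.st_peak
```

Other entry points: `kvclamp simulate` writes CSV/ATF trace families (with
optional Gaussian noise, linear leak, capacitive transients and per-oocyte
rate jitter, plus a JSON truth manifest); `kvclamp fit` / `kvclamp recover`
analyze trace directories; `kvclamp calibrate` emits a calibrated preset as
JSON; `kvclamp reproduce <id>|all` recomputes the benchmark observables and
reports recovered vs published values with relative errors.

Synthetic datasets are laid out as one directory per scenario containing
`repNN_sweepMM.csv` traces (columns `time_ms, current, voltage_mV,
sweep_id`, segment markers in a `#` header line) and a `manifest.json`
recording the seed and ground-truth rate multipliers.

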