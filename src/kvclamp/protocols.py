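"""Declarative voltage-clamp protocols and the simulation driver.

A :class:`VoltageProtocol` is a family of sweeps, each a list of
piecewise-constant command segments.  Sweeps are simulated independently from
full equilibrium at the holding potential, emulating long inter-sweep rest
intervals that allow complete recovery from slow inactivation.

Ionic current is ohmic, ``I = g * (p_O + p_P) * (V - E_K)`` per channel with
unit conductance; gating current is the net charge flux of the charged
transitions (e0/ms per channel).  Linear leak and capacitive artifacts are
not part of the forward model here -- they are injected by
:mod:`kvclamp.synth` so that P/n subtraction can be exercised against a
known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .scheme import (
    Condition,
    build_generator,
    gating_flux,
    propagate,
    steady_state,
)

__all__ = [
    "Segment",
    "SegSpan",
    "VoltageProtocol",
    "SimTrace",
    "make_step_family",
    "make_two_pulse",
    "simulate_ionic",
    "simulate_gating",
    "p_over_n_subtract",
]

#: samples per segment are capped so multi-second rest intervals do not
#: dominate the grid (occupancy propagation is exact at any step size)
MAX_SEGMENT_SAMPLES = 12_000


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant command step: voltage (mV), duration (ms), label."""

    V: float
    dur: float
    label: str = ""


@dataclass(frozen=True)
class SegSpan:
    """Location of a segment inside a sampled trace (first/last sample time)."""

    label: str
    t0: float
    t1: float
    V: float


@dataclass(frozen=True)
class VoltageProtocol:
    """Holding potential plus an ordered segment list per sweep."""

    name: str
    holding: float
    dt: float  # sampling interval, ms
    sweeps: tuple[tuple[Segment, ...], ...]
    sweep_meta: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("protocol has no sweeps")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")
        shortest = min(s.dur for sw in self.sweeps for s in sw)
        if shortest <= 0:
            raise ValueError("segment durations must be positive")
        if self.dt > shortest / 10.0:
            raise ValueError(
                f"sampling interval {self.dt} ms too coarse for the shortest "
                f"segment ({shortest} ms); need <= shortest/10"
            )
        if self.sweep_meta and len(self.sweep_meta) != len(self.sweeps):
            raise ValueError("sweep_meta length must match sweeps")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


@dataclass
class SimTrace:
    """A sampled current trace with segment boundary markers."""

    t: np.ndarray  # ms, strictly increasing
    i: np.ndarray  # current (normalized per channel) or gating current (e0/ms)
    v: np.ndarray  # command voltage at each sample
    segments: tuple[SegSpan, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time must be strictly increasing")
        for seg in self.segments:
            if not (self.t[0] <= seg.t0 <= seg.t1 <= self.t[-1]):
                raise ValueError("segment markers outside trace time range")

    def segment(self, which: str | int) -> SegSpan:
        if isinstance(which, int):
            return self.segments[which]
        for seg in self.segments:
            if seg.label == which:
                return seg
        raise KeyError(f"no segment labelled {which!r}")

    def copy_with(self, i: np.ndarray, **meta) -> "SimTrace":
        return SimTrace(
            t=self.t.copy(),
            i=np.asarray(i, dtype=float),
            v=self.v.copy(),
            segments=self.segments,
            meta={**self.meta, **meta},
        )


# ---------------------------------------------------------------------------
# protocol constructors
# ---------------------------------------------------------------------------


def _default_dt(longest_ms: float) -> float:
    return 0.1 if longest_ms <= 2000.0 else 1.0


def make_step_family(
    V_from: float,
    V_to: float,
    dV: float,
    duration: float,
    holding: float = -80.0,
    dt: float | None = None,
    pre_ms: float = 5.0,
    post_ms: float = 30.0,
    name: str = "step_family",
) -> VoltageProtocol:
    """Family of step depolarizations, one sweep per step voltage."""
    if dV <= 0:
        raise ValueError("dV must be positive")
    steps = np.arange(V_from, V_to + dV / 2.0, dV)
    if steps.size == 0:
        raise ValueError("empty voltage range")
    sweeps = []
    meta = []
    for v in steps:
        sweeps.append(
            (
                Segment(holding, pre_ms, "pre"),
                Segment(float(v), duration, "step"),
                Segment(holding, post_ms, "post"),
            )
        )
        meta.append({"step_V": float(v)})
    if dt is None:
        dt = min(_default_dt(duration), pre_ms / 10.0, post_ms / 10.0)
    return VoltageProtocol(
        name=name,
        holding=holding,
        dt=dt,
        sweeps=tuple(sweeps),
        sweep_meta=tuple(meta),
    )


def make_two_pulse(
    prepulse_ms: float,
    intervals: list[float],
    inter_V: float,
    test_ms: float,
    pulse_V: float = 40.0,
    holding: float = -80.0,
    dt: float | None = None,
    pre_ms: float = 5.0,
    post_ms: float = 10.0,
    name: str = "two_pulse",
) -> VoltageProtocol:
    """Prepulse / variable-interval / test-pulse family (recovery, tandem, gating)."""
    if not intervals or any(iv <= 0 for iv in intervals):
        raise ValueError("intervals must be nonempty and positive")
    if dt is None:
        dt = min(
            _default_dt(prepulse_ms),
            min(intervals) / 10.0,
            test_ms / 10.0,
            pre_ms / 10.0,
            post_ms / 10.0,
        )
    sweeps = []
    meta = []
    for iv in intervals:
        sweeps.append(
            (
                Segment(holding, pre_ms, "pre"),
                Segment(pulse_V, prepulse_ms, "1P"),
                Segment(inter_V, float(iv), "gap"),
                Segment(pulse_V, test_ms, "2P"),
                Segment(holding, post_ms, "post"),
            )
        )
        meta.append({"interval_ms": float(iv)})
    return VoltageProtocol(
        name=name,
        holding=holding,
        dt=dt,
        sweeps=tuple(sweeps),
        sweep_meta=tuple(meta),
    )


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def _segment_grid(dur: float, dt: float) -> np.ndarray:
    n = int(np.ceil(dur / dt - 1e-9))
    if n > MAX_SEGMENT_SAMPLES:
        n = MAX_SEGMENT_SAMPLES
    n = max(n, 10)
    step = dur / n
    # first sample sits just inside the step edge so fast relaxation spikes
    # (gating ON/OFF transients, instantaneous ohmic jumps) are resolved
    return np.concatenate([[step * 1e-4], np.linspace(step, dur, n)])


def _simulate_sweep(preset, cond: Condition, segments, dt: float, kind: str):
    """Propagate one sweep; returns (t, i, v, spans, p_end)."""
    scheme = preset.scheme
    cidx = scheme.conducting_indices()
    Q_hold = build_generator(scheme, preset.params, cond.at(segments[0].V))
    # sweeps start from the holding-potential limit of a channel resting in
    # the deepest closed state (equals the stationary law when the scheme is
    # irreducible, and stays physical when branches are disconnected)
    p0 = np.zeros(scheme.n_states)
    p0[0] = 1.0
    p = propagate(Q_hold, p0, np.array([1e8]))[0]
    t_parts, i_parts, v_parts, spans = [], [], [], []
    t_now = 0.0
    for seg in segments:
        cv = cond.at(seg.V)
        Q = build_generator(scheme, preset.params, cv)
        local = _segment_grid(seg.dur, dt)
        grid = np.concatenate([[0.0], local])
        traj = propagate(Q, p, grid)
        p = traj[-1]
        if kind == "ionic":
            cur = preset.g * traj[1:, cidx].sum(axis=1) * (seg.V - cv.E_K)
        else:
            cur = gating_flux(Q, traj[1:], scheme)
        tt = t_now + local
        t_parts.append(tt)
        i_parts.append(cur)
        v_parts.append(np.full(local.size, seg.V))
        spans.append(SegSpan(seg.label, float(tt[0]), float(tt[-1]), seg.V))
        t_now = float(tt[-1])
    return (
        np.concatenate(t_parts),
        np.concatenate(i_parts),
        np.concatenate(v_parts),
        tuple(spans),
    )


def simulate_ionic(
    preset, cond: Condition, protocol: VoltageProtocol
) -> list[SimTrace]:
    """Ionic current traces, one per sweep, noiseless."""
    out = []
    for k, segments in enumerate(protocol.sweeps):
        t, i, v, spans = _simulate_sweep(preset, cond, segments, protocol.dt, "ionic")
        meta = dict(protocol.sweep_meta[k]) if protocol.sweep_meta else {}
        meta.update(protocol=protocol.name, preset=preset.name, sweep=k)
        out.append(SimTrace(t=t, i=i, v=v, segments=spans, meta=meta))
    return out


def simulate_gating(
    preset, cond: Condition, protocol: VoltageProtocol
) -> list[SimTrace]:
    """Gating-current traces (e0/ms per channel), one per sweep.

    Intended for non-conducting (W391F-analogue) presets; a conducting preset
    is accepted with a warning and treated as if its conductance were zero.
    """
    if preset.g != 0.0:
        warnings.warn(
            f"preset {preset.name!r} conducts; simulating gating current with g=0",
            stacklevel=2,
        )
    out = []
    for k, segments in enumerate(protocol.sweeps):
        t, i, v, spans = _simulate_sweep(preset, cond, segments, protocol.dt, "gating")
        meta = dict(protocol.sweep_meta[k]) if protocol.sweep_meta else {}
        meta.update(protocol=protocol.name, preset=preset.name, sweep=k, gating=True)
        out.append(SimTrace(t=t, i=i, v=v, segments=spans, meta=meta))
    return out


# ---------------------------------------------------------------------------
# P/n leak subtraction
# ---------------------------------------------------------------------------


def _baseline(trace: SimTrace) -> float:
    sl = trace.segments[0]
    m = (trace.t >= sl.t0) & (trace.t <= sl.t1)
    return float(trace.i[m].mean())


def make_subtraction_sweep(
    segments: tuple[Segment, ...], holding: float, n: int, sub_holding: float
) -> tuple[Segment, ...]:
    """Command for one P/n subtraction sweep: 1/n-scaled steps from sub_holding."""
    return tuple(
        Segment(sub_holding + (s.V - holding) / n, s.dur, s.label) for s in segments
    )


def p_over_n_subtract(
    raw: SimTrace, sub_sweeps: list[SimTrace], n: int
) -> SimTrace:
    """Remove linear components from ``raw`` using n scaled subtraction sweeps.

    Each subtraction sweep carries 1/n of the main command excursion from a
    hyperpolarized subtraction holding; baselines (first-segment means) are
    removed from every trace, the baseline-corrected subtraction currents are
    summed and subtracted.  Linear leak and capacitive currents cancel
    exactly; nonlinear gating charge moved within the subtraction voltage
    range remains as the method's (measurable) error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(sub_sweeps) != n:
        raise ValueError(f"expected {n} subtraction sweeps, got {len(sub_sweeps)}")
    corrected = raw.i - _baseline(raw)
    for sub in sub_sweeps:
        if sub.t.shape != raw.t.shape:
            raise ValueError("subtraction sweep grid does not match raw sweep")
        corrected = corrected - (sub.i - _baseline(sub))
    return raw.copy_with(corrected, leak_subtracted=True, p_over_n=n)
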