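"""Quantitative trace analysis: Boltzmann fits, exponential decomposition,
recovery normalization, steady/peak ratios, and gating-charge analysis.

Conventions follow standard two-electrode voltage-clamp practice:

* activation / Q-V curves are fit with ``Y = Ymax / (1 + exp((V - Vhalf)/k))``
  (``k`` negative for curves rising with depolarization);
* current decays and recovery time courses are fit with
  ``Y = Y0 + sum_i A_i * exp(-t/tau_i)`` (one or two components, ``tau``
  sorted ascending, recovery amplitudes negative);
* the initial level of a normalized recovery curve, ``init``
  (the proportion of channels still activatable right after the prepulse),
  is ``1 - sum_i |A_i|`` after normalization by the fitted plateau ``Y0``;
* ``st/peak`` is the current at the end of a pulse divided by the peak
  current during it;
* ON gating charge ``Q_on`` is the time integral of the gating current over
  the depolarizing pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import medfilt

from .protocols import SimTrace

__all__ = [
    "BoltzmannFit",
    "ExpFit",
    "RecoveryResult",
    "CumulativeResult",
    "ChargeResult",
    "fit_boltzmann",
    "fit_exponential",
    "analyze_decay",
    "analyze_recovery",
    "analyze_cumulative",
    "integrate_qon",
    "analyze_qv",
    "analyze_charge_recovery",
]

# model selection: a second exponential is accepted only if it improves the
# SSE by >10% and both amplitudes exceed 2% of the peak (or plateau) scale
SSE_IMPROVEMENT = 0.10
MIN_AMP_FRAC = 0.02
#: below this tau2/tau1 ratio a two-component fit is flagged near-degenerate
MIN_TAU_RATIO = 3.0


@dataclass
class BoltzmannFit:
    """Result of a Boltzmann fit; satisfies Y(V_half) = Ymax/2 by construction."""

    Ymax: float
    V_half: float  # mV
    k: float  # mV, negative for activation-type curves
    residual_norm: float
    n_points: int

    def __call__(self, V: np.ndarray) -> np.ndarray:
        return self.Ymax / (1.0 + np.exp((np.asarray(V) - self.V_half) / self.k))


@dataclass
class ExpFit:
    """Single/double exponential fit record.

    ``components`` is ``[(A1, tau1), (A2, tau2)]`` sorted by ascending tau;
    ``n_comp`` may be 0 for a non-decaying trace (st/peak only).
    """

    y0: float
    components: list[tuple[float, float]]
    residual_norm: float
    n_points: int
    near_degenerate: bool = False
    st_peak: float | None = None
    t0: float = 0.0

    @property
    def n_comp(self) -> int:
        return len(self.components)

    @property
    def taus(self) -> list[float]:
        return [tau for _a, tau in self.components]

    @property
    def amplitudes(self) -> list[float]:
        return [a for a, _tau in self.components]

    @property
    def a2_frac(self) -> float | None:
        """Relative amplitude of the slow component, A2/(A1+A2)."""
        if self.n_comp != 2:
            return None
        a1, a2 = self.components[0][0], self.components[1][0]
        return a2 / (a1 + a2)

    @property
    def tau_dominant(self) -> float | None:
        """Time constant of the largest-|A| component."""
        if not self.components:
            return None
        return max(self.components, key=lambda c: abs(c[0]))[1]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full(t.shape, self.y0)
        for a, tau in self.components:
            y = y + a * np.exp(-(t - self.t0) / tau)
        return y


@dataclass
class RecoveryResult:
    """Two-pulse recovery analysis: peak-current ratios vs inter-pulse interval."""

    intervals: np.ndarray  # ms
    ratio: np.ndarray  # I_peak(2P)/I_peak(1P)
    norm_ratio: np.ndarray  # ratio / fitted Y0
    fit: ExpFit  # fit of the raw ratio time course
    init: float  # 1 - sum|A_i| after Y0 normalization


@dataclass
class CumulativeResult:
    """Tandem-pulse cumulative-inactivation analysis."""

    intervals: np.ndarray
    ratio: np.ndarray  # I_2nd/I_1st
    fit: ExpFit
    ratio_at_1ms_fit: float
    ratio_at_1ms_raw: float  # value at the shortest measured interval


@dataclass
class ChargeResult:
    """Gating-charge analysis over a sweep family."""

    q_on: np.ndarray  # e0 per channel per sweep
    intervals: np.ndarray | None = None
    q2_over_q1: np.ndarray | None = None
    fit: ExpFit | None = None  # single-exp fit, Y0/A1 normalized by Q1
    plateau: float | None = None
    immobilized_frac: float | None = None
    qv_table: np.ndarray | None = None  # (V, Q_norm) rows
    qv_fit: BoltzmannFit | None = None


# ---------------------------------------------------------------------------
# basic fitting primitives
# ---------------------------------------------------------------------------


def fit_boltzmann(V: np.ndarray, Y: np.ndarray, n_restarts: int = 3) -> BoltzmannFit:
    """Least-squares Boltzmann fit of Y(V).

    The slope factor keeps the field's sign convention: negative ``k`` for
    curves that rise with depolarization.  On non-convergence after the
    restart ladder the best parameter set found is returned.
    """
    V = np.asarray(V, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if V.size < 4:
        raise ValueError("need at least 4 points spanning the transition")

    ymax0 = float(Y.max())
    half = ymax0 / 2.0
    i = int(np.argmin(np.abs(Y - half)))
    vh0 = float(V[i])
    rising = Y[np.argmax(V)] > Y[np.argmin(V)]
    dv = float(np.ptp(V)) / 4.0 or 1.0

    def resid(x: np.ndarray) -> np.ndarray:
        ymax, vh, k = x
        z = np.clip((V - vh) / k, -500.0, 500.0)
        return ymax / (1.0 + np.exp(z)) - Y

    best = None
    for scale in [1.0, 0.3, 3.0][:n_restarts]:
        k0 = (-dv if rising else dv) * scale
        sol = least_squares(resid, x0=[ymax0, vh0, k0], method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    ymax, vh, k = best.x
    return BoltzmannFit(
        Ymax=float(ymax),
        V_half=float(vh),
        k=float(k),
        residual_norm=float(np.linalg.norm(best.fun)),
        n_points=V.size,
    )


def _crude_tau(t: np.ndarray, y: np.ndarray) -> float:
    """1/e crossing of the normalized decay amplitude (seed for tau)."""
    span = y[0] - y[-1]
    if abs(span) < 1e-300:
        return max((t[-1] - t[0]) / 3.0, 1e-6)
    z = (y - y[-1]) / span
    below = np.where(z <= np.exp(-1.0))[0]
    if below.size:
        return max(float(t[below[0]] - t[0]), (t[1] - t[0]) if t.size > 1 else 1e-3)
    return float(t[-1] - t[0])


def _exp_resid(x: np.ndarray, t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    y0 = x[0]
    model = np.full(t.shape, y0)
    for i in range(n):
        model = model + x[1 + 2 * i] * np.exp(-t / x[2 + 2 * i])
    return model - y


def fit_exponential(
    t: np.ndarray,
    y: np.ndarray,
    n_comp: int = 1,
    window: tuple[float, float] | None = None,
    t_ref: float | None = None,
) -> ExpFit:
    """Fit ``Y0 + sum A_i exp(-t/tau_i)`` with a multi-start tau ladder.

    ``window`` restricts the fit to ``window[0] <= t <= window[1]``.  Time is
    referenced to ``t_ref`` (default: the first fitted sample; recovery fits
    pass 0 so amplitudes extrapolate to zero interval).  Double fits seed tau
    at (tau_crude/3, 3*tau_crude) plus perturbations (5 starts); the best SSE
    wins, ties broken toward the smaller tau2/tau1.  A double fit with
    tau2/tau1 <= 3 is flagged ``near_degenerate``.
    """
    if n_comp not in (1, 2):
        raise ValueError("n_comp must be 1 or 2")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    if t.size < 2 * n_comp + 1:
        raise ValueError("fewer points than parameters")
    t0 = float(t[0]) if t_ref is None else float(t_ref)
    ts = t - t0
    tau_c = _crude_tau(ts, y)
    span = float(y[0] - y[-1])
    scale = max(abs(span), abs(y).max(), 1e-12)

    if n_comp == 1:
        seeds = [(tau_c,), (tau_c / 3.0,), (3.0 * tau_c,)]
    else:
        seeds = [
            (tau_c / 3.0, 3.0 * tau_c),
            (tau_c / 10.0, 10.0 * tau_c),
            (tau_c, 10.0 * tau_c),
            (tau_c / 3.0, 30.0 * tau_c),
            (tau_c, 3.0 * tau_c),
        ]

    tmax = max(float(ts[-1]), 1e-6)
    results = []
    for taus in seeds:
        # linear solve for Y0 and amplitudes at the seeded taus
        basis = np.column_stack(
            [np.ones_like(ts)] + [np.exp(-ts / tau) for tau in taus]
        )
        lin, *_ = np.linalg.lstsq(basis, y, rcond=None)
        x0 = [lin[0]]
        for i, tau in enumerate(taus):
            x0 += [lin[1 + i], tau]
        lo = [-np.inf] + [-np.inf, 1e-9] * n_comp
        hi = [np.inf] + [np.inf, 100.0 * tmax] * n_comp
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            _exp_resid, x0=x0, bounds=(lo, hi), args=(ts, y, n_comp), max_nfev=4000
        )
        results.append(sol)

    def sse(sol):
        return float(sol.cost)

    def ratio(sol):
        if n_comp == 1:
            return 1.0
        taus = sorted([sol.x[2], sol.x[4]])
        return taus[1] / max(taus[0], 1e-300)

    best_sse = min(sse(s) for s in results)
    tol = max(1e-12 * scale**2, 1e-6 * best_sse)
    best = min(results, key=lambda s: (sse(s) > best_sse + tol, ratio(s)))

    comps = sorted(
        [(float(best.x[1 + 2 * i]), float(best.x[2 + 2 * i])) for i in range(n_comp)],
        key=lambda c: c[1],
    )
    degenerate = n_comp == 2 and comps[1][1] / comps[0][1] <= MIN_TAU_RATIO
    return ExpFit(
        y0=float(best.x[0]),
        components=comps,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_points=t.size,
        near_degenerate=degenerate,
        t0=t0,
    )


# ---------------------------------------------------------------------------
# trace-level analyses
# ---------------------------------------------------------------------------


def _pulse_slice(trace: SimTrace, segment: str | int) -> tuple[slice, float]:
    seg = trace.segment(segment)
    m = (trace.t >= seg.t0) & (trace.t <= seg.t1)
    idx = np.where(m)[0]
    if idx.size == 0:
        raise ValueError(f"segment {segment!r} contains no samples")
    return slice(idx[0], idx[-1] + 1), seg.V


def _locate_peak(t: np.ndarray, i: np.ndarray, noisy: bool) -> int:
    if noisy and t.size > 8:
        dt = float(np.median(np.diff(t))) or 1.0
        k = max(3, int(round(0.5 / dt)) | 1)  # 0.5-ms median filter, odd width
        i = medfilt(i, min(k, (t.size - 1) | 1))
    return int(np.argmax(i))


def _select_n_comp(
    fit1: ExpFit, fit2: ExpFit, amp_scale: float
) -> ExpFit:
    sse1 = fit1.residual_norm**2
    sse2 = fit2.residual_norm**2
    improved = sse2 < (1.0 - SSE_IMPROVEMENT) * sse1
    big_enough = all(abs(a) >= MIN_AMP_FRAC * amp_scale for a in fit2.amplitudes)
    if improved and big_enough and not fit2.near_degenerate:
        return fit2
    return fit1


def analyze_decay(trace: SimTrace, pulse_segment: str | int = "step") -> ExpFit:
    """Decompose the current decay during a depolarizing pulse.

    The fit window starts at the sample of peak current and runs to the end
    of the pulse.  The number of components (1 or 2) is chosen by a
    deterministic rule: two components are kept only when they improve the
    SSE by more than 10% and both amplitudes exceed 2% of the peak.  A trace
    whose decay amplitude is below 2% of peak is returned as ``n_comp = 0``
    with the steady/peak ratio only.
    """
    sl, _v = _pulse_slice(trace, pulse_segment)
    t = trace.t[sl]
    i = trace.i[sl]
    noisy = bool(trace.meta.get("noisy", False))
    pk = _locate_peak(t, i, noisy)
    peak = float(i[pk])
    if peak <= 0:
        raise ValueError("pulse contains no detectable peak")
    st_peak = float(i[-1] / peak)

    if peak - i[-1] < MIN_AMP_FRAC * abs(peak):
        return ExpFit(
            y0=float(i[-1]),
            components=[],
            residual_norm=0.0,
            n_points=int(t.size - pk),
            st_peak=st_peak,
            t0=float(t[pk]),
        )

    td, yd = t[pk:], i[pk:]
    fit1 = fit_exponential(td, yd, n_comp=1)
    fit2 = fit_exponential(td, yd, n_comp=2)
    fit = _select_n_comp(fit1, fit2, abs(peak))
    fit.st_peak = st_peak
    return fit


def _peak_in(trace: SimTrace, label: str) -> float:
    sl, _v = _pulse_slice(trace, label)
    noisy = bool(trace.meta.get("noisy", False))
    seg = trace.i[sl]
    pk = _locate_peak(trace.t[sl], seg, noisy)
    return float(seg[pk])


def analyze_recovery(
    sweeps: list[SimTrace],
    pre_label: str = "1P",
    test_label: str = "2P",
    n_comp: int | None = None,
) -> RecoveryResult:
    """Recovery from inactivation out of a two-pulse sweep family.

    The test/prepulse peak ratio is plotted against the inter-pulse interval
    and fitted with one or two exponentials (decay-style selection rule
    unless ``n_comp`` forces it); the curve is then normalized by the fitted
    plateau Y0, and ``init`` is ``1 - sum|A_i|`` of the normalized fit.
    """
    intervals = np.array([sw.meta["interval_ms"] for sw in sweeps], dtype=float)
    order = np.argsort(intervals)
    intervals = intervals[order]
    sweeps = [sweeps[k] for k in order]
    p1 = np.array([_peak_in(sw, pre_label) for sw in sweeps])
    p2 = np.array([_peak_in(sw, test_label) for sw in sweeps])
    if np.any(np.abs(p1) < 1e-12):
        raise ValueError("prepulse peak is ~0; cannot form recovery ratio")
    ratio = p2 / p1

    if n_comp is not None:
        fit = fit_exponential(intervals, ratio, n_comp=n_comp, t_ref=0.0)
    else:
        fit1 = fit_exponential(intervals, ratio, n_comp=1, t_ref=0.0)
        if intervals.size >= 6:
            fit2 = fit_exponential(intervals, ratio, n_comp=2, t_ref=0.0)
            fit = _select_n_comp(fit1, fit2, max(abs(fit1.y0), 1e-12))
        else:
            fit = fit1
    y0 = fit.y0
    if abs(y0) < 1e-12:
        raise ValueError("fitted plateau Y0 ~ 0; cannot normalize recovery")
    norm = ratio / y0
    init = 1.0 - sum(abs(a) / abs(y0) for a in fit.amplitudes)
    return RecoveryResult(
        intervals=intervals, ratio=ratio, norm_ratio=norm, fit=fit, init=float(init)
    )


def analyze_cumulative(
    sweeps: list[SimTrace],
    first_label: str = "1P",
    second_label: str = "2P",
) -> CumulativeResult:
    """Tandem-pulse ratio I_2nd/I_1st vs interval, with the 1-ms estimate.

    Reports the ratio extrapolated to 1 ms after the first pulse both from
    the exponential fit and from the shortest measured interval (the two
    conventions used for quantifying cumulative inactivation onset).
    """
    rec = analyze_recovery(sweeps, pre_label=first_label, test_label=second_label)
    at1_fit = float(rec.fit(np.array([1.0]))[0])
    at1_raw = float(rec.ratio[0])
    return CumulativeResult(
        intervals=rec.intervals,
        ratio=rec.ratio,
        fit=rec.fit,
        ratio_at_1ms_fit=at1_fit,
        ratio_at_1ms_raw=at1_raw,
    )


# ---------------------------------------------------------------------------
# gating-charge analyses
# ---------------------------------------------------------------------------


def integrate_qon(trace: SimTrace, pulse_segment: str | int = "step") -> float:
    """ON gating charge: trapezoidal integral of I_g over the pulse (e0)."""
    sl, _v = _pulse_slice(trace, pulse_segment)
    return float(np.trapezoid(trace.i[sl], trace.t[sl]))


def analyze_qv(
    sweeps: list[SimTrace], pulse_segment: str | int = "step"
) -> ChargeResult:
    """Q-V relationship: per-step Q_on, normalized to its maximum, Boltzmann fit."""
    if len(sweeps) < 5:
        raise ValueError("need at least 5 step voltages for a Q-V fit")
    V = np.empty(len(sweeps))
    q = np.empty(len(sweeps))
    for k, sw in enumerate(sweeps):
        sl, v = _pulse_slice(sw, pulse_segment)
        V[k] = v
        q[k] = np.trapezoid(sw.i[sl], sw.t[sl])
    qn = q / q.max()
    fit = fit_boltzmann(V, qn)
    return ChargeResult(
        q_on=q, qv_table=np.column_stack([V, qn]), qv_fit=fit
    )


def analyze_charge_recovery(
    sweeps: list[SimTrace],
    pre_label: str = "1P",
    test_label: str = "2P",
) -> ChargeResult:
    """Gating-charge recovery: Q2/Q1 vs interval, single-exponential fit.

    The fitted Y0 and A1 are already in Q1-normalized units because the
    per-sweep ratio divides by the first-pulse Q_on; the immobilized fraction
    is ``1 - plateau``.
    """
    intervals = np.array([sw.meta["interval_ms"] for sw in sweeps], dtype=float)
    order = np.argsort(intervals)
    intervals = intervals[order]
    sweeps = [sweeps[k] for k in order]
    q1 = np.empty(len(sweeps))
    q2 = np.empty(len(sweeps))
    for k, sw in enumerate(sweeps):
        sl1, _ = _pulse_slice(sw, pre_label)
        sl2, _ = _pulse_slice(sw, test_label)
        q1[k] = np.trapezoid(sw.i[sl1], sw.t[sl1])
        q2[k] = np.trapezoid(sw.i[sl2], sw.t[sl2])
    if np.any(q1 <= 0):
        raise ValueError("first-pulse Q_on must be positive")
    ratio = q2 / q1
    fit = fit_exponential(intervals, ratio, n_comp=1, t_ref=0.0)
    plateau = float(fit.y0)
    return ChargeResult(
        q_on=q1,
        intervals=intervals,
        q2_over_q1=ratio,
        fit=fit,
        plateau=plateau,
        immobilized_frac=1.0 - plateau,
    )
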