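"""Benchmark round-trips: recompute each published observable through the
full calibrate -> simulate -> fit chain and compare with its reference value.

Each benchmark runs the complete measurement path on noiseless simulated
data: the preset is calibrated from the published tables, the published
protocol is simulated, and the analysis pipeline (automatic component
selection included) produces the number that is compared.
"""

from __future__ import annotations

import numpy as np

from . import reference as ref
from .fits import analyze_decay, analyze_qv, analyze_recovery, fit_boltzmann
from .presets import get_preset
from .protocols import make_step_family, make_two_pulse
from .scheme import CONDITIONS
from .protocols import simulate_gating, simulate_ionic

__all__ = ["BENCHMARKS", "run_benchmark", "run_all"]


def _decay_fit(preset_name: str, cond: str, pulse_ms: float = 1000.0):
    proto = make_step_family(40.0, 40.0, 10.0, pulse_ms, name="bench_step")
    trace = simulate_ionic(get_preset(preset_name), CONDITIONS[cond], proto)[0]
    return analyze_decay(trace), trace


def _recovery_fit(preset_name: str, cond: str, intervals, prepulse_ms: float = 1000.0):
    proto = make_two_pulse(
        prepulse_ms,
        list(intervals),
        -80.0,
        20.0,
        dt=min(0.5, min(intervals) / 10.0),
        name="bench_rec",
    )
    sweeps = simulate_ionic(get_preset(preset_name), CONDITIONS[cond], proto)
    return analyze_recovery(sweeps)


def akv1_nd96_decay_tau() -> tuple[float, int]:
    fit, trace = _decay_fit("AKv1", "ND96")
    return fit.components[0][1], trace.t.size


def i8q_nd96_slow_tau() -> tuple[float, int]:
    fit, trace = _decay_fit("I8Q", "ND96")
    if fit.n_comp != 2:
        raise RuntimeError("expected a two-component decay for I8Q in ND96")
    return fit.components[1][1], trace.t.size


def i8q_nd96_slow_frac() -> tuple[float, int]:
    fit, trace = _decay_fit("I8Q", "ND96")
    return fit.a2_frac, trace.t.size


def i8q_highk_st_peak() -> tuple[float, int]:
    fit, trace = _decay_fit("I8Q", "highK")
    return fit.st_peak, trace.t.size


def akv1_nd96_recovery_tau() -> tuple[float, int]:
    rec = _recovery_fit("AKv1", "ND96", ref.INTERVALS_WT)
    return rec.fit.components[-1][1], rec.intervals.size


def akv1_highk_recovery_tau() -> tuple[float, int]:
    rec = _recovery_fit("AKv1", "highK", ref.INTERVALS_I8Q)
    return rec.fit.components[0][1], rec.intervals.size


def dn_inactivation_tau_s() -> tuple[float, int]:
    fit, trace = _decay_fit("dN", "ND96", pulse_ms=10_000.0)
    return fit.tau_dominant / 1000.0, trace.t.size


def dn_recovery_tau_s() -> tuple[float, int]:
    rec = _recovery_fit("dN", "ND96", ref.INTERVALS_DN, prepulse_ms=10_000.0)
    return rec.fit.components[-1][1] / 1000.0, rec.intervals.size


def akv1_activation_vhalf() -> tuple[float, int]:
    # noiseless conductance points generated from the published activation
    # parameters, recovered by the Boltzmann fitting operation
    pars = ref.ACTIVATION["AKv1"]
    V = np.arange(-20.0, 60.1, 10.0)
    Y = 1.0 / (1.0 + np.exp((V - pars["V_half"]) / pars["k"]))
    return fit_boltzmann(V, Y).V_half, V.size


def i8q_qv_vhalf() -> tuple[float, int]:
    # gating transients are fast; sample at 5 us so the ON charge integral
    # resolves the edge spike
    proto = make_step_family(
        -40.0, 60.0, 10.0, 10.0, post_ms=30.0, dt=0.005, name="bench_qv"
    )
    sweeps = simulate_gating(get_preset("I8Q-W391F"), CONDITIONS["ND96"], proto)
    return analyze_qv(sweeps).qv_fit.V_half, len(sweeps)


#: id -> (callable, reference value, units)
BENCHMARKS = {
    "akv1-nd96-decay-tau": (akv1_nd96_decay_tau, ref.DECAY[("AKv1", "ND96")]["tau1"], "ms"),
    "i8q-nd96-slow-tau": (i8q_nd96_slow_tau, ref.DECAY[("I8Q", "ND96")]["tau2"], "ms"),
    "i8q-nd96-slow-frac": (i8q_nd96_slow_frac, ref.DECAY[("I8Q", "ND96")]["a2_frac"], ""),
    "i8q-highk-st-peak": (i8q_highk_st_peak, ref.DECAY[("I8Q", "highK")]["st_peak"], ""),
    "akv1-nd96-recovery-tau": (
        akv1_nd96_recovery_tau,
        ref.RECOVERY[("AKv1", "ND96")]["tau2"],
        "ms",
    ),
    "akv1-highk-recovery-tau": (
        akv1_highk_recovery_tau,
        ref.RECOVERY[("AKv1", "highK")]["tau1"],
        "ms",
    ),
    "dn-inactivation-tau": (
        dn_inactivation_tau_s,
        ref.DECAY_10S[("dN", "ND96")]["tau2"] / 1000.0,
        "s",
    ),
    "dn-recovery-tau": (
        dn_recovery_tau_s,
        ref.RECOVERY_10S[("dN", "ND96")]["tau1"] / 1000.0,
        "s",
    ),
    "akv1-activation-vhalf": (
        akv1_activation_vhalf,
        ref.ACTIVATION["AKv1"]["V_half"],
        "mV",
    ),
    "i8q-qv-vhalf": (i8q_qv_vhalf, ref.QV["I8Q"]["V_half"], "mV"),
}


def run_benchmark(bench_id: str) -> dict:
    fn, reference, units = BENCHMARKS[bench_id]
    value, n = fn()
    return {
        "id": bench_id,
        "value": float(value),
        "reference": float(reference),
        "units": units,
        "rel_error": float(abs(value - reference) / abs(reference)) if reference else None,
        "n": int(n),
    }


def run_all() -> dict[str, dict]:
    return {bid: run_benchmark(bid) for bid in BENCHMARKS}
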