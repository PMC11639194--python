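"""Shared fixtures: calibrated presets (cached per session) and synthetic
trace fabrication helpers used by the fit-pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest

from kvclamp.presets import get_preset
from kvclamp.protocols import SegSpan, SimTrace
from kvclamp.scheme import RateParams, StateScheme


@pytest.fixture(scope="session")
def akv1():
    return get_preset("AKv1")


@pytest.fixture(scope="session")
def i8q():
    return get_preset("I8Q")


@pytest.fixture(scope="session")
def dn():
    return get_preset("dN")


@pytest.fixture(scope="session")
def two_state():
    """Minimal open <-> blocked scheme with pure kb/kub kinetics."""
    scheme = StateScheme(
        name="two",
        states=("O", "N"),
        conducting=frozenset({"O"}),
        transitions=(("O", "N", "kb", 1.0), ("N", "O", "kub", -1.0)),
    )

    def make(alpha: float, beta: float):
        return scheme, RateParams(kb=alpha, kub=beta, theta_push=0.0)

    return make


def fabricate_two_pulse(intervals, ratios, peak1: float = 1.0) -> list[SimTrace]:
    """Build minimal two-pulse sweeps whose 1P/2P peak ratio is prescribed."""
    sweeps = []
    for iv, r in zip(intervals, ratios):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        i = np.array([peak1, peak1 * 0.5, 0.0, 0.0, r * peak1, r * peak1 * 0.5])
        v = np.array([40.0, 40.0, -80.0, -80.0, 40.0, 40.0])
        segs = (
            SegSpan("1P", 0.0, 1.0, 40.0),
            SegSpan("gap", 2.0, 3.0, -80.0),
            SegSpan("2P", 4.0, 5.0, 40.0),
        )
        sweeps.append(
            SimTrace(t=t, i=i, v=v, segments=segs, meta={"interval_ms": float(iv)})
        )
    return sweeps


def fabricate_gating_two_pulse(intervals, q1: float, q2s) -> list[SimTrace]:
    """Rectangular gating pulses with prescribed ON charges Q1 and Q2."""
    sweeps = []
    for iv, q2 in zip(intervals, q2s):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        i = np.array([q1, q1, 0.0, 0.0, q2, q2])
        v = np.array([40.0, 40.0, -80.0, -80.0, 40.0, 40.0])
        segs = (
            SegSpan("1P", 0.0, 1.0, 40.0),
            SegSpan("gap", 2.0, 3.0, -80.0),
            SegSpan("2P", 4.0, 5.0, 40.0),
        )
        sweeps.append(
            SimTrace(t=t, i=i, v=v, segments=segs, meta={"interval_ms": float(iv)})
        )
    return sweeps
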