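"""Synthetic study-emulating datasets: noisy trace ensembles with truth manifests.

The generator reproduces what two-electrode voltage-clamp (ionic) and
cut-open-oocyte (gating) recordings of this channel family look like to the
analysis pipeline: piecewise-constant commands, single/double-exponential
decays riding on a fast activation, multi-second recovery, additive Gaussian
noise, and -- optionally -- a linear leak plus capacitive transients for
exercising P/n subtraction.  Oocyte-to-oocyte spread is emulated by
log-normal multipliers on the kinetic rates (the published tables report
mean +/- SD over oocytes).

Truth manifests are JSON sidecars next to the CSV traces; analyses must
never read truth from the trace files themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .channel import ChannelPreset
from .protocols import SimTrace, VoltageProtocol, simulate_gating, simulate_ionic
from .scheme import Condition
from . import traceio

__all__ = ["NoiseSpec", "ReplicateSpec", "apply_artifacts", "generate_dataset", "make_fixture_suite"]

#: kinetic rates subject to per-oocyte jitter
_JITTERED = ("a0", "b0", "ko", "kc", "kd", "ku", "kb", "kub", "kci", "kcr", "kci0", "kcr0")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement artifacts: additive Gaussian noise (fraction of peak),
    linear leak conductance, and a bi-exponential capacitive transient."""

    sigma: float = 0.01
    leak_g: float = 0.0  # leak current = leak_g * V (E_leak = 0)
    cap_amp: float = 0.0  # transient amplitude per 100 mV step
    cap_tau: float = 1.0  # ms; fast sub-component has tau/5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for nonzero noise")


@dataclass(frozen=True)
class ReplicateSpec:
    """Per-oocyte variability: n replicates with log-normal rate multipliers."""

    n_oocytes: int = 1
    cv: float = 0.1

    def __post_init__(self) -> None:
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def apply_artifacts(
    trace: SimTrace, spec: NoiseSpec, rng: np.random.Generator | None = None
) -> SimTrace:
    """Add leak, capacitive transients and Gaussian noise to a clean trace."""
    i = trace.i.astype(float).copy()
    if spec.leak_g != 0.0:
        i += spec.leak_g * trace.v
    if spec.cap_amp != 0.0:
        prev_v = trace.segments[0].V
        for seg in trace.segments:
            dv = seg.V - prev_v
            prev_v = seg.V
            if dv == 0.0:
                continue
            tail = trace.t >= seg.t0
            dt = trace.t[tail] - seg.t0
            amp = spec.cap_amp * dv / 100.0
            i[tail] += amp * (
                0.7 * np.exp(-dt / (spec.cap_tau / 5.0)) + 0.3 * np.exp(-dt / spec.cap_tau)
            )
    if spec.sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        i += spec.sigma * np.abs(trace.i).max() * rng.standard_normal(i.shape)
    return trace.copy_with(i, noisy=spec.sigma > 0, noise_sigma=spec.sigma)


def _jitter_params(preset: ChannelPreset, cv: float, rng: np.random.Generator):
    if cv == 0:
        return preset, {}
    s = float(np.sqrt(np.log1p(cv**2)))
    mult = {}
    kw = {}
    for name in _JITTERED:
        v = getattr(preset.params, name)
        if v > 0:
            m = float(rng.lognormal(mean=-0.5 * s**2, sigma=s))
            mult[name] = m
            kw[name] = v * m
    return preset.with_params(**kw), mult


def generate_dataset(
    preset: ChannelPreset,
    cond: Condition,
    protocol: VoltageProtocol,
    noise: NoiseSpec,
    reps: ReplicateSpec,
    out_dir: str | Path,
    kind: str = "ionic",
    fmt: str = "csv",
) -> Path:
    """Simulate and write a replicate ensemble plus its truth manifest.

    One subdirectory-flat CSV (or ATF) per replicate and sweep; a
    ``manifest.json`` records the ground-truth rate multipliers and the seed.
    Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(noise.seed if noise.seed is not None else 0)
    rep_seeds = master.spawn(reps.n_oocytes)
    simulate = simulate_ionic if kind == "ionic" else simulate_gating
    manifest = {
        "preset": preset.name,
        "kind": kind,
        "protocol": protocol.name,
        "condition": {"K_out": cond.K_out, "Zn": cond.Zn, "TEA": cond.TEA},
        "seed": noise.seed,
        "noise": {"sigma": noise.sigma, "leak_g": noise.leak_g, "cap_amp": noise.cap_amp},
        "cv": reps.cv,
        "replicates": [],
    }
    for r, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        rp, mult = _jitter_params(preset, reps.cv, rng)
        files = []
        for k, sweep in enumerate(simulate(rp, cond, protocol)):
            noisy = apply_artifacts(sweep, noise, rng)
            noisy.meta["replicate"] = r
            ext = "atf" if fmt == "atf" else "csv"
            path = out / f"rep{r:02d}_sweep{k:02d}.{ext}"
            if fmt == "atf":
                traceio.write_atf(noisy, path)
            else:
                traceio.write_csv(noisy, path)
            files.append(path.name)
        manifest["replicates"].append(
            {"replicate": r, "rate_multipliers": mult, "files": files}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def make_fixture_suite(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Emit the curated fixture set: one small noiseless trace family per
    benchmark scenario plus one noisy ensemble per conducting preset.

    Regeneration with the same seed is idempotent.
    """
    from . import reference as ref
    from .presets import get_preset
    from .protocols import make_step_family, make_two_pulse
    from .scheme import CONDITIONS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    quiet = NoiseSpec(sigma=0.0)
    one = ReplicateSpec(n_oocytes=1, cv=0.0)
    made: dict[str, Path] = {}

    step1s = make_step_family(
        40.0, 40.0, 10.0, 1000.0, dt=1.0, pre_ms=10.0, post_ms=20.0, name="step1s_40"
    )
    step10s = make_step_family(
        40.0, 40.0, 10.0, 10_000.0, dt=5.0, pre_ms=50.0, post_ms=50.0, name="step10s_40"
    )
    rec_i8q = make_two_pulse(
        1000.0, list(ref.INTERVALS_I8Q), -80.0, 20.0, dt=0.2, name="rec2p_fine"
    )
    scenarios = {
        "akv1_nd96_step1s": ("AKv1", "ND96", step1s),
        "i8q_nd96_step1s": ("I8Q", "ND96", step1s),
        "i8q_highk_step1s": ("I8Q", "highK", step1s),
        "dn_nd96_step10s": ("dN", "ND96", step10s),
        "i8q_nd96_rec2p": ("I8Q", "ND96", rec_i8q),
    }
    for key, (preset, cond, proto) in scenarios.items():
        made[key] = generate_dataset(
            get_preset(preset), CONDITIONS[cond], proto, quiet, one, out / key
        )
    for preset in ("AKv1", "I8Q", "dN"):
        made[f"{preset.lower()}_noisy"] = generate_dataset(
            get_preset(preset),
            CONDITIONS["ND96"],
            step1s,
            NoiseSpec(sigma=0.01, seed=seed),
            ReplicateSpec(n_oocytes=3, cv=0.1),
            out / f"{preset.lower()}_noisy",
        )
    return made
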