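"""Markov state schemes and rate matrices for Kv1 gating with coupled inactivation.

The channel is modelled as a continuous-time Markov chain.  The wild-type
topology is a linear activation path of four identical voltage-sensor steps
followed by a concerted opening, an N-type inactivation branch (docking of the
amino terminus near the T1 window, then pore occlusion, then entry into the
C-type inactivated state), and -- for amino-terminal deletion constructs -- a
direct C-type path from the open state::

    C0 = C1 = C2 = C3 = O = P = N = NC
                        \\
                         Cf          (dN-style schemes only)

``O`` and ``P`` conduct: the pre-block state still carries current, the block
occurs only on pore occlusion.  Each voltage-sensor step (C0-C1, C1-C2,
C2-C3) carries 3.0 e0 and the concerted opening (C3-O) carries 1.0 e0,
10 e0 per channel in total.

External modulators act multiplicatively on the evaluated rates:

* K+ suppresses C-type entry, ``kci * 1/(1 + K/K_K)`` (inverted to
  ``(1 + K/K_K)`` for U-type-like mutants, ``u_type=True``),
* K+ destabilizes the C-type state, ``kcr * (1 + g_K * K/(K + K_Kr))``,
* K+ pushes the N-terminal blocker off the pore,
  ``kub * (1 + theta_push * K/(K + K_K))``,
* Zn2+ accelerates C-type entry, ``kci * (1 + eta_Zn * Zn/(K_Zn + Zn))``.

Units: time ms, voltage mV, rates 1/ms, concentrations mM (K+) and uM (Zn2+),
charge e0 per channel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

__all__ = [
    "THERMAL_VOLTAGE_MV",
    "Condition",
    "RateParams",
    "StateScheme",
    "ND96",
    "HIGH_K",
    "CONDITIONS",
    "akv1_scheme",
    "dn_scheme",
    "build_generator",
    "propagate",
    "steady_state",
    "two_state_block",
    "gating_flux",
    "gillespie_sample",
]

#: Room-temperature thermal voltage kT/e0 (mV); a two-state sensor of valence
#: z has a Boltzmann slope of -THERMAL_VOLTAGE_MV/z.
THERMAL_VOLTAGE_MV = 25.7

#: Gating valences of the activation path (per-step and opening, e0).
Z_STEP = 3.0
Z_OPEN = 1.0


@dataclass(frozen=True)
class Condition:
    """Recording condition: membrane potential and bath composition.

    ``V`` is transient (protocols override it per segment); the ionic
    composition is fixed for a sweep.  ``TEA`` is accepted but has no effect
    on AKv1-family kinetics.  ``K_in`` sets the Nernst reversal potential.
    """

    V: float = -80.0  # mV
    K_out: float = 2.0  # mM
    Zn: float = 0.0  # uM
    TEA: float = 0.0  # mM
    K_in: float = 100.0  # mM

    def __post_init__(self) -> None:
        for name in ("K_out", "Zn", "TEA", "K_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def at(self, V: float) -> "Condition":
        return replace(self, V=V)

    @property
    def E_K(self) -> float:
        """Nernst K+ reversal potential (mV); K_out floored at 50 uM."""
        return THERMAL_VOLTAGE_MV * math.log(max(self.K_out, 0.05) / self.K_in)


#: Standard external solution (2 mM K+).
ND96 = Condition(K_out=2.0)
#: Isotonic-K+ external solution (98 mM KCl).
HIGH_K = Condition(K_out=98.0)

CONDITIONS: dict[str, Condition] = {
    "ND96": ND96,
    "highK": HIGH_K,
    "TEA77": Condition(K_out=2.0, TEA=77.0),
    "Zn100": Condition(K_out=2.0, Zn=100.0),
    "Zn300": Condition(K_out=2.0, Zn=300.0),
    "highK_Zn300": Condition(K_out=98.0, Zn=300.0),
}


@dataclass(frozen=True)
class RateParams:
    """Rate constants, voltage dependences and bath modulators of a preset.

    Voltage-dependent activation: forward ``a0*exp(V/Va)``, backward
    ``b0*exp(-V/Vb)`` per step.  Docking (``kd``/``ku``), block
    (``kb``/``kub``) and C-type entry (``kci``, ``kci0``) are
    voltage-independent.  C-type recovery (``kcr``, ``kcr0``) may carry a weak
    hyperpolarization-favored e-fold voltage ``Vcr`` (anchored at -80 mV so the
    stored value is the resting-rate; ``Vcr=None`` means voltage-independent).
    """

    a0: float = 0.2  # 1/ms
    Va: float = 2.0 * THERMAL_VOLTAGE_MV / Z_STEP  # mV per e-fold
    b0: float = 0.2
    Vb: float = 2.0 * THERMAL_VOLTAGE_MV / Z_STEP
    ko: float = 1.5
    kc: float = 0.3
    kd: float = 0.0  # docking O->P
    ku: float = 0.0
    kb: float = 0.0  # pore block P->N
    kub: float = 0.0
    kci: float = 0.0  # C-type entry from N
    kcr: float = 0.0
    kci0: float = 0.0  # direct C-type entry from O (dN-style)
    kcr0: float = 0.0
    # bath modulators
    K_K: float = 1.0  # mM, half-suppression of C-type entry by K+ (also push-off)
    K_Kr: float = 5.0  # mM, half-constant of K+ destabilization of the C state
    theta_push: float = 0.5  # K+ push-off gain on kub
    g_K: float = 2.45  # K+ destabilization gain on kcr/kcr0
    K_Zn: float = 100.0  # uM
    eta_Zn: float = 3.3  # max fold-acceleration of C entry by Zn2+
    u_type: bool = False  # inverted K+ dependence of C entry
    Vcr: float | None = None  # mV per e-fold on kcr/kcr0 (hyperpol-favored)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("u_type", "Vcr") or v is None:
                continue
            if v < 0:
                raise ValueError(f"rate/modulator {f.name} must be >= 0")
        if self.Va <= 0 or self.Vb <= 0:
            raise ValueError("Va and Vb must be positive")
        for name in ("K_K", "K_Kr", "K_Zn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- modulator factors -------------------------------------------------
    def _m_K(self, cond: Condition) -> float:
        x = cond.K_out / self.K_K
        return (1.0 + x) if self.u_type else 1.0 / (1.0 + x)

    def _m_Zn(self, cond: Condition) -> float:
        return 1.0 + self.eta_Zn * cond.Zn / (self.K_Zn + cond.Zn)

    def _push(self, cond: Condition) -> float:
        return 1.0 + self.theta_push * cond.K_out / (cond.K_out + self.K_K)

    def _destab(self, cond: Condition) -> float:
        return 1.0 + self.g_K * cond.K_out / (cond.K_out + self.K_Kr)

    def _vcr(self, V: float) -> float:
        if self.Vcr is None:
            return 1.0
        return math.exp(-(V + 80.0) / self.Vcr)

    def rate(self, name: str, cond: Condition) -> float:
        """Evaluate a named transition rate (1/ms) at ``cond``."""
        V = cond.V
        if name == "a":
            r = self.a0 * math.exp(V / self.Va)
        elif name == "b":
            r = self.b0 * math.exp(-V / self.Vb)
        elif name == "ko":
            r = self.ko
        elif name == "kc":
            r = self.kc
        elif name == "kd":
            r = self.kd
        elif name == "ku":
            r = self.ku
        elif name == "kb":
            r = self.kb
        elif name == "kub":
            r = self.kub * self._push(cond)
        elif name in ("kci", "kci0"):
            r = getattr(self, name) * self._m_K(cond) * self._m_Zn(cond)
        elif name in ("kcr", "kcr0"):
            r = getattr(self, name) * self._destab(cond) * self._vcr(V)
        else:
            raise KeyError(f"unknown transition rate name: {name!r}")
        if r < 0 or not math.isfinite(r):
            raise ValueError(f"rate {name} evaluated to {r}")
        return r


@dataclass(frozen=True)
class StateScheme:
    """Named channel states and the (symmetric) list of charged transitions.

    ``transitions`` holds directed entries ``(frm, to, rate_name, z)`` with
    ``z`` the elementary charge moved, signed along the depolarizing
    direction; every forward edge has a matching backward edge.
    """

    name: str
    states: tuple[str, ...]
    conducting: frozenset[str]
    transitions: tuple[tuple[str, str, str, float], ...]

    def __post_init__(self) -> None:
        if not self.conducting <= set(self.states):
            raise ValueError("conducting states must be a subset of states")
        pairs = {(t[0], t[1]) for t in self.transitions}
        for frm, to in pairs:
            if (to, frm) not in pairs:
                raise ValueError(f"transition {frm}->{to} lacks a backward entry")
        if any(t[3] != 0 for t in self.transitions):
            fwd = sum(t[3] for t in self.transitions if t[3] > 0)
            if fwd <= 0:
                raise ValueError("total forward activation charge must be positive")

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def conducting_indices(self) -> np.ndarray:
        idx = self.index
        return np.array(sorted(idx[s] for s in self.conducting), dtype=int)


def _chain_edges() -> list[tuple[str, str, str, float]]:
    edges: list[tuple[str, str, str, float]] = []
    closed = ["C0", "C1", "C2", "C3"]
    for i in range(3):
        edges.append((closed[i], closed[i + 1], "a", Z_STEP))
        edges.append((closed[i + 1], closed[i], "b", -Z_STEP))
    edges.append(("C3", "O", "ko", Z_OPEN))
    edges.append(("O", "C3", "kc", -Z_OPEN))
    return edges


def total_forward_charge(scheme: StateScheme) -> float:
    """Total gating charge per channel (e0): sum of positive z over transitions."""
    return sum(t[3] for t in scheme.transitions if t[3] > 0)


def akv1_scheme(direct_c: bool = False) -> StateScheme:
    """Full wild-type topology: activation chain, pre-block, N-block, N-C path.

    ``direct_c=True`` additionally enables the O<->Cf path (kci0/kcr0).
    """
    edges = _chain_edges()
    edges += [
        ("O", "P", "kd", 0.0),
        ("P", "O", "ku", 0.0),
        ("P", "N", "kb", 0.0),
        ("N", "P", "kub", 0.0),
        ("N", "NC", "kci", 0.0),
        ("NC", "N", "kcr", 0.0),
    ]
    states = ["C0", "C1", "C2", "C3", "O", "P", "N", "NC"]
    if direct_c:
        edges += [("O", "Cf", "kci0", 0.0), ("Cf", "O", "kcr0", 0.0)]
        states.append("Cf")
    return StateScheme(
        name="akv1" + ("+Cf" if direct_c else ""),
        states=tuple(states),
        conducting=frozenset({"O", "P"}),
        transitions=tuple(edges),
    )


def dn_scheme() -> StateScheme:
    """Amino-terminal deletion topology: no P/N/NC, direct O<->Cf C-type path."""
    edges = _chain_edges()
    edges += [("O", "Cf", "kci0", 0.0), ("Cf", "O", "kcr0", 0.0)]
    return StateScheme(
        name="dn",
        states=("C0", "C1", "C2", "C3", "O", "Cf"),
        conducting=frozenset({"O"}),
        transitions=tuple(edges),
    )


def build_generator(
    scheme: StateScheme, params: RateParams, cond: Condition
) -> np.ndarray:
    """Evaluate the infinitesimal generator Q (1/ms) of ``scheme`` at ``cond``.

    Off-diagonal ``Q[i, j]`` is the i->j rate; each diagonal entry is minus
    its row's off-diagonal sum, so rows sum to zero exactly.
    """
    idx = scheme.index
    n = scheme.n_states
    Q = np.zeros((n, n))
    for frm, to, name, _z in scheme.transitions:
        Q[idx[frm], idx[to]] += params.rate(name, cond)
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return Q


def _check_generator(Q: np.ndarray, tol: float = 1e-9) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    scale = max(1.0, float(np.abs(Q).max()))
    if np.abs(Q.sum(axis=1)).max() > tol * scale:
        raise ValueError("non-conservative generator: row sums differ from 0")
    off = Q - np.diag(np.diag(Q))
    if off.min() < -tol * scale:
        raise ValueError("generator has negative off-diagonal rates")


_EIG_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray, np.ndarray] | None] = {}


def _eig_of(Q: np.ndarray):
    """Cached spectral decomposition of Q^T; None when unusable (complex or
    ill-conditioned eigenbasis)."""
    key = Q.tobytes()
    if key in _EIG_CACHE:
        return _EIG_CACHE[key]
    lam, V = np.linalg.eig(Q.T)
    out = None
    if (
        np.abs(lam.imag).max() <= 1e-9 * max(1.0, np.abs(lam.real).max())
        and np.linalg.cond(V) < 1e8
    ):
        # lam <= 0 for a conservative generator; clip spurious positives
        out = (np.minimum(lam.real, 0.0), V, np.linalg.inv(V))
    if len(_EIG_CACHE) > 256:
        _EIG_CACHE.clear()
    _EIG_CACHE[key] = out
    return out


def propagate(Q: np.ndarray, p0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Solve dp/dt = p Q from ``p0`` on ``t_grid`` (ms), exactly.

    Uses the spectral decomposition of Q (the schemes here are trees, so Q is
    similar to a symmetric matrix and has a real spectrum); falls back to
    stepwise ``expm`` if the eigenbasis is ill-conditioned.  Occupancies are
    renormalized to the simplex; the result matches the matrix exponential to
    better than 1e-8 relative.
    """
    Q = np.asarray(Q, dtype=float)
    _check_generator(Q)
    p0 = np.asarray(p0, dtype=float)
    if p0.min() < -1e-12 or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability vector")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be one-dimensional and nondecreasing")

    traj = None
    decomp = _eig_of(Q)
    if decomp is not None:
        lam, V, Vinv = decomp
        c = Vinv @ p0  # coordinates in eigenbasis of Q^T
        traj = np.real(np.exp(np.outer(t, lam)) * c) @ V.T
    if traj is None:  # pragma: no cover - degenerate spectra
        traj = np.empty((t.size, p0.size))
        p = p0.copy()
        prev = 0.0
        for k, tk in enumerate(t):
            if tk > prev:
                p = p @ expm(Q * (tk - prev))
                prev = tk
            traj[k] = p
    traj = np.clip(traj, 0.0, None)
    traj /= traj.sum(axis=1, keepdims=True)
    return traj


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary occupancy: the null vector of Q^T normalized to sum 1.

    For a reducible generator the stationary law is not unique; a warning is
    issued and closed communicating classes are weighted equally.
    """
    Q = np.asarray(Q, dtype=float)
    _check_generator(Q)
    n = Q.shape[0]
    adj = (Q > 0).astype(int)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        outside = np.setdiff1d(np.arange(n), members)
        if outside.size == 0 or np.all(Q[np.ix_(members, outside)] <= 0):
            closed.append(members)
    if len(closed) > 1:
        warnings.warn(
            "reducible generator: returning equal-weight mixture over "
            f"{len(closed)} closed classes",
            stacklevel=2,
        )
    pi = np.zeros(n)
    for members in closed:
        sub = Q[np.ix_(members, members)]
        sub = sub - np.diag(np.diag(sub))
        sub[np.diag_indices(len(members))] = -sub.sum(axis=1)
        A = np.vstack([sub.T, np.ones(len(members))])
        b = np.zeros(len(members) + 1)
        b[-1] = 1.0
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi[members] += np.clip(sol, 0.0, None) / len(closed)
    return pi / pi.sum()


def two_state_block(tau_inacti: float, steady_frac: float) -> tuple[float, float]:
    """Invert the single-step pore-block relations.

    For open <-> blocked with association rate alpha and dissociation rate
    beta, the decay time constant is 1/(alpha+beta) and the stationary
    conducting fraction is beta/(alpha+beta); this returns
    ``(alpha, beta) = ((1-f)/tau, f/tau)``.
    """
    if tau_inacti <= 0:
        raise ValueError("tau_inacti must be positive")
    if not 0.0 <= steady_frac < 1.0:
        raise ValueError("steady_frac must lie in [0, 1)")
    beta = steady_frac / tau_inacti
    alpha = (1.0 - steady_frac) / tau_inacti
    return alpha, beta


def gating_flux(Q: np.ndarray, p_traj: np.ndarray, scheme: StateScheme) -> np.ndarray:
    """Gating current I_g(t) = sum over transitions of z * p_from * rate (e0/ms).

    ``Q`` must be the generator the trajectory was propagated under; backward
    transitions carry negative z, so the sum is the net charge flux and its
    time integral over a pulse equals the net charge moved.
    """
    idx = scheme.index
    p_traj = np.atleast_2d(np.asarray(p_traj, dtype=float))
    ig = np.zeros(p_traj.shape[0])
    for frm, to, _name, z in scheme.transitions:
        if z != 0.0:
            ig += z * p_traj[:, idx[frm]] * Q[idx[frm], idx[to]]
    return ig


def gillespie_sample(
    scheme: StateScheme,
    params: RateParams,
    cond: Condition,
    n_traj: int,
    seed: int,
    t_grid: np.ndarray,
    p0: np.ndarray | None = None,
) -> np.ndarray:
    """Exact stochastic simulation of the jump process (the oracle for propagate).

    Returns an ``(n_traj, len(t_grid))`` integer array of state indices
    sampled at ``t_grid``.  Trajectories start from ``p0`` (default: the
    first state) and are vectorized over the ensemble; the same seed yields
    identical output.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    Q = build_generator(scheme, params, cond)
    n = scheme.n_states
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be nondecreasing")

    exit_rate = -np.diag(Q)
    off = Q - np.diag(np.diag(Q))
    denom = np.where(exit_rate > 0, exit_rate, 1.0)[:, None]
    jump_cum = np.cumsum(off / denom, axis=1)

    if p0 is None:
        state = np.zeros(n_traj, dtype=int)
    else:
        p0 = np.asarray(p0, dtype=float)
        state = rng.choice(n, size=n_traj, p=p0 / p0.sum())

    def _hold(states: np.ndarray) -> np.ndarray:
        r = exit_rate[states]
        out = np.full(states.shape, np.inf)
        live = r > 0
        out[live] = rng.exponential(1.0 / r[live])
        return out

    t_now = np.zeros(n_traj)
    t_next = _hold(state)
    out = np.empty((n_traj, t.size), dtype=int)
    for k, tk in enumerate(t):
        while True:
            due = t_next <= tk
            if not np.any(due):
                break
            s = state[due]
            u = rng.random(s.size)
            state[due] = (u[:, None] > jump_cum[s]).sum(axis=1)
            t_now = np.where(due, t_next, t_now)
            t_next = np.where(due, t_now + _hold(state), t_next)
        out[:, k] = state
    return out


def occupancy_from_samples(samples: np.ndarray, n_states: int) -> np.ndarray:
    """Ensemble occupancy estimates (n_times, n_states) from gillespie_sample output."""
    n_traj, n_t = samples.shape
    occ = np.zeros((n_t, n_states))
    for s in range(n_states):
        occ[:, s] = (samples == s).mean(axis=0)
    return occ
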