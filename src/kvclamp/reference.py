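"""Published benchmark observables for AKv1 and its mutants.

These are the mean values of the standard two-electrode voltage-clamp
observables reported for the *Aplysia* Kv1 channel (AKv1), its
amino-terminal point mutant I8Q, and the amino-terminal deletion dN, under
the standard low-K+ bath (ND96, 2 mM K+) and the isotonic-K+ bath (98 mM).
They are the *inputs* to preset calibration (the model's rate constants are
not published; only these observables are) and the reference values the
``reproduce`` command compares against.

Keys follow the analysis pipeline's vocabulary:

* ``tau1`` / ``tau2`` -- fast/slow decay or recovery time constants (ms),
* ``a2_frac`` -- relative amplitude of the slow component, A2/(A1+A2),
* ``st_peak`` -- current at the end of the pulse over peak current,
* ``init`` -- activatable proportion right after the prepulse,
* ``V_half`` / ``k`` -- Boltzmann parameters (mV).
"""

from __future__ import annotations

# -- 1-s step to +40 mV, current decay --------------------------------------
DECAY = {
    ("AKv1", "ND96"): {"tau1": 21.9, "st_peak": 0.078},
    ("AKv1", "highK"): {"tau1": 23.2, "st_peak": 0.135},
    ("I8Q", "ND96"): {"tau1": 24.2, "tau2": 964.2, "a2_frac": 0.398, "st_peak": 0.232},
    ("I8Q", "highK"): {"tau1": 27.8, "st_peak": 0.512},
    ("I8Q", "Zn300"): {"tau1": 28.6, "tau2": 315.8, "a2_frac": 0.512},
}

# -- 10-s step to +40 mV (slow-inactivation constructs), seconds ------------
DECAY_10S = {
    ("dN", "ND96"): {"tau1": 0.531e3, "tau2": 3.522e3, "a2_frac": 0.943, "st_peak": 0.245},
    ("dN", "highK"): {"tau2": 7.513e3, "st_peak": 0.448},
}

# -- two-pulse recovery from inactivation (1-s prepulse), ms ----------------
RECOVERY = {
    ("AKv1", "ND96"): {"tau2": 3454.2, "init": 0.043},
    ("AKv1", "highK"): {"tau1": 216.0, "init": 0.132},
    ("I8Q", "ND96"): {"tau1": 48.1, "tau2": 2038.4, "a2_frac": 0.735, "init": 0.219},
    ("I8Q", "highK"): {"tau1": 22.6, "a2_frac": 0.13, "init": 0.517},
}

# -- two-pulse recovery after a 10-s prepulse (dN), ms ----------------------
RECOVERY_10S = {
    ("dN", "ND96"): {"tau1": 3491.0, "init": 0.325},
    ("dN", "highK"): {"tau1": 1781.0, "init": 0.61},
}

# -- steady-state activation (conductance-voltage Boltzmann), mV ------------
ACTIVATION = {
    "AKv1": {"V_half": 0.9, "k": -6.3},
    "I8Q": {"V_half": 4.6, "k": -5.4},
    "dN": {"V_half": 6.7, "k": -6.0},
}

# -- ON gating charge Q-V Boltzmann (non-conducting W391F analogues), mV ----
QV = {
    "AKv1": {"V_half": -0.5, "k": -9.4},
    "I8Q": {"V_half": 8.1, "k": -8.3},
}

# -- recovery-interval ladders used in the published two-pulse families (ms)
INTERVALS_WT = [10, 100, 500, 1000, 2000, 5000, 10_000, 20_000, 30_000]
INTERVALS_I8Q = [2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10_000, 20_000]
#: tandem-pulse interval ladder (cumulative inactivation)
INTERVALS_TANDEM = [5, 10, 25, 50, 100, 200, 500]
#: dN families use a log ladder (the published interval list is not printed)
INTERVALS_DN = [200, 500, 1000, 2000, 5000, 10_000, 20_000]
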