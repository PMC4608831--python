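"""Stochastic Hodgkin-Huxley model of a midbrain (TS) electrosensory neuron.

Single-compartment conductance-based model with spiking sodium (instantaneous
``m_inf**3`` activation coupled to the potassium gate through a ``0.85 - n``
inactivation term), delayed-rectifier potassium, leak, and two subthreshold
currents: a hyperpolarization-activated inward current (h, HCN) and a
low-threshold T-type calcium current (instantaneous ``s_inf**3`` activation
with a slow inactivation gate ``eta``).  Synaptic input enters as a
time-varying excitatory conductance (see :mod:`chirpinv.afferent`) and
intrinsic variability as additive Gaussian current noise integrated with the
Euler-Maruyama scheme at a 0.025 ms step.

Units are the model's phenomenological mix (uF, uS, nA, mV with C = 1), so
``dV/dt`` is numerically the summed current; they are not SI-consistent and
are kept exactly as conventionally written for this cell type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "TsModelParams",
    "GateState",
    "VoltageTrace",
    "steady_state_gates",
    "ionic_currents",
    "integrate",
    "detect_spikes",
    "resting_state",
    "IntegrationDiverged",
]

_ETA_PARSES = ("literal", "product")


class IntegrationDiverged(RuntimeError):
    """Raised when the state leaves the finite range during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration diverged at step {step}")


@dataclass
class TsModelParams:
    """All biophysical parameters of the TS model.

    Conductances in uS, reversal potentials in mV, currents in nA,
    capacitance in uF, times in ms.  ``eta_parse`` selects between the two
    admissible readings of the T-current inactivation steady state
    ("literal": 1/(0.5 + 0.25 + exp((V+82)/6.3)); "product":
    1/(0.5 + 0.25*exp((V+82)/6.3))); both are monotone in voltage.

    ``tau_n_scale`` multiplies the delayed-rectifier relaxation time
    ``tau_n = tau_n_scale / (alpha_n + beta_n)``.  The default 1.0 is the
    standard Hodgkin-Huxley relaxation time (~5 ms near rest), which is
    required for the cell to fire at all when driven through the 20 ms
    alpha-kernel synapse; a scale of 0.05 makes n essentially
    instantaneous, quenching every regenerative upswing before it starts,
    and is kept selectable only for sensitivity analyses.
    """

    C: float = 1.0
    g_Na: float = 30.0
    g_K: float = 10.0
    g_leak: float = 0.18
    g_h: float = 7.0
    g_T: float = 0.32
    E_Na: float = 60.0
    E_K: float = -85.0
    E_leak: float = -65.0
    E_h: float = -30.0
    E_Ca: float = 120.0
    I_bias: float = 0.0
    sigma_noise: float = 1.0
    noise_sd: float = 0.8
    Phi: float = 2.0
    tau_eta: float = 30.0
    dt: float = 0.025
    seed: int | None = None
    eta_parse: str = "literal"
    tau_n_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("C", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_Na", "g_K", "g_leak", "g_h", "g_T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eta_parse not in _ETA_PARSES:
            raise ValueError(f"eta_parse must be one of {_ETA_PARSES}")

    def with_(self, **kw) -> "TsModelParams":
        return replace(self, **kw)


@dataclass
class GateState:
    V: float
    eta: float
    h: float
    n: float


@dataclass
class VoltageTrace:
    V: np.ndarray
    dt: float
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))
    h_range: tuple[float, float] = (0.0, 0.0)   # (min, max) over the run
    n_range: tuple[float, float] = (0.0, 0.0)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.V.size) * self.dt


# ---------------------------------------------------------------------------
# gating kinetics (scalar, numba-compiled; shared by API and integrator)

_SINGULARITY_EPS = 1e-7  # window around V = -40.7 where the x/(1-e^-x) limit is used


@njit(cache=True)
def _gates(V: float, eta_alt: int, tau_n_scale: float):
    x = V + 40.7
    if abs(x) < _SINGULARITY_EPS:
        alpha_m = 1.0     # lim 0.1 x / (1 - exp(-0.1 x))
        alpha_n = 0.1     # lim 0.01 x / (0.1 x) * ... = 0.01/0.1
    else:
        e = math.exp(-0.1 * x)
        alpha_m = 0.1 * x / (1.0 - e)
        alpha_n = 0.01 * x / (1.0 - e)
    beta_m = 4.0 * math.exp(-0.05 * (V + 49.7))
    beta_n = 0.125 * math.exp(-0.0125 * (V + 50.7))
    m_inf = alpha_m / (alpha_m + beta_m)
    n_inf = alpha_n / (alpha_n + beta_n)
    tau_n = tau_n_scale / (alpha_n + beta_n)
    if eta_alt:
        eta_inf = 1.0 / (0.5 + 0.25 * math.exp((V + 82.0) / 6.3))
    else:
        eta_inf = 1.0 / (0.5 + 0.25 + math.exp((V + 82.0) / 6.3))
    s_inf = 1.0 / (1.0 + math.exp(-(V + 63.0) / 7.8))
    h_inf = 1.0 / (1.0 + math.exp(0.151 * (V + 73.0)))
    tau_h = math.exp(0.033 * (V + 75.0)) / (
        0.011 * (1.0 + math.exp(0.083 * (V + 75.0)))
    )
    return m_inf, eta_inf, s_inf, n_inf, h_inf, tau_n, tau_h


def steady_state_gates(V, eta_parse: str = "literal", tau_n_scale: float = 1.0) -> dict:
    """Steady-state gate values and time constants at voltage ``V`` (mV).

    Returns a dict of arrays (or scalars) with keys ``m_inf``, ``eta_inf``,
    ``s_inf``, ``n_inf``, ``h_inf``, ``tau_n``, ``tau_h``.  The removable
    singularities of alpha_m and alpha_n at V = -40.7 mV are replaced by
    their analytic limits.
    """
    if eta_parse not in _ETA_PARSES:
        raise ValueError(f"eta_parse must be one of {_ETA_PARSES}")
    alt = 1 if eta_parse == "product" else 0
    Varr = np.atleast_1d(np.asarray(V, dtype=float))
    out = np.empty((7, Varr.size))
    for i, v in enumerate(Varr):
        out[:, i] = _gates(v, alt, tau_n_scale)
    keys = ("m_inf", "eta_inf", "s_inf", "n_inf", "h_inf", "tau_n", "tau_h")
    if np.isscalar(V) or np.asarray(V).ndim == 0:
        return {k: float(out[j, 0]) for j, k in enumerate(keys)}
    return {k: out[j] for j, k in enumerate(keys)}


def ionic_currents(
    state: GateState,
    g_on: float,
    g_off: float,
    params: TsModelParams,
    syn_cfg=None,
) -> dict:
    """All membrane currents at the given state (model current units).

    Sodium uses instantaneous ``m_inf**3`` with the ``0.85 - n`` inactivation
    coupling; the T current uses instantaneous ``s_inf**3`` with the dynamic
    ``eta`` gate.  The sign convention makes each current the contribution
    to ``C dV/dt`` (positive = depolarizing).
    """
    g = steady_state_gates(state.V, params.eta_parse, params.tau_n_scale)
    V = state.V
    I_Na = -params.g_Na * g["m_inf"] ** 3 * (0.85 - state.n) * (V - params.E_Na)
    I_KDR = -params.g_K * state.n ** 4 * (V - params.E_K)
    I_h = -params.g_h * state.h * (V - params.E_h)
    I_T = -params.g_T * g["s_inf"] ** 3 * state.eta * (V - params.E_Ca)
    I_leak = -params.g_leak * (V - params.E_leak)
    if syn_cfg is not None:
        from .afferent import synaptic_current

        I_syn = float(synaptic_current(V, g_on, g_off, syn_cfg))
    else:
        I_syn = 0.0
    return {
        "I_Na": I_Na,
        "I_KDR": I_KDR,
        "I_h": I_h,
        "I_T": I_T,
        "I_leak": I_leak,
        "I_syn": I_syn,
    }


def resting_state(params: TsModelParams, V0: float | None = None) -> GateState:
    """Initial state: V at E_leak (or ``V0``) with gates at steady state."""
    V = params.E_leak if V0 is None else V0
    g = steady_state_gates(V, params.eta_parse, params.tau_n_scale)
    return GateState(V=V, eta=g["eta_inf"], h=g["h_inf"], n=g["n_inf"])


# ---------------------------------------------------------------------------
# Euler-Maruyama integration


@njit(cache=True)
def _integrate_core(
    V0, eta0, h0, n0,
    drive, noise,
    dt, C,
    g_Na, g_K, g_leak, g_h, g_T,
    E_Na, E_K, E_leak, E_h, E_Ca, E_syn,
    I_bias, Phi, tau_eta, eta_alt, tau_n_scale,
):
    n_steps = drive.size
    V_out = np.empty(n_steps + 1)
    V = V0
    eta = eta0
    h = h0
    n = n0
    h_lo = h_hi = h
    n_lo = n_hi = n
    V_out[0] = V
    for i in range(n_steps):
        m_inf, eta_inf, s_inf, n_inf, h_inf, tau_n, tau_h = _gates(V, eta_alt, tau_n_scale)
        I = (
            -g_Na * m_inf ** 3 * (0.85 - n) * (V - E_Na)
            - g_K * n ** 4 * (V - E_K)
            - g_h * h * (V - E_h)
            - g_T * s_inf ** 3 * eta * (V - E_Ca)
            - g_leak * (V - E_leak)
            - drive[i] * (V - E_syn)
            + I_bias
        )
        V = V + dt * I / C + noise[i]
        eta = eta + dt * Phi * (eta_inf - eta) / tau_eta
        h = h + dt * (h_inf - h) / tau_h
        n = n + dt * (n_inf - n) / tau_n
        if h < h_lo:
            h_lo = h
        elif h > h_hi:
            h_hi = h
        if n < n_lo:
            n_lo = n
        elif n > n_hi:
            n_hi = n
        if not (-1e4 < V < 1e4):
            V_out[i + 1] = V
            return V_out, i + 1, h_lo, h_hi, n_lo, n_hi
        V_out[i + 1] = V
    return V_out, -1, h_lo, h_hi, n_lo, n_hi


def integrate(
    params: TsModelParams,
    g_on: np.ndarray,
    g_off: np.ndarray,
    syn_cfg=None,
    t_end: float | None = None,
    cond_bin_ms: float | None = None,
    rng: np.random.Generator | None = None,
    threshold: float = 0.0,
) -> VoltageTrace:
    """Euler-Maruyama integration of the TS model driven by ON/OFF input.

    ``g_on``/``g_off`` are conductance series (uS); when ``cond_bin_ms``
    differs from ``params.dt`` they are linearly resampled onto the
    integration grid.  The membrane receives the mixed synaptic drive of
    :func:`chirpinv.afferent.mixed_drive` plus ``I_bias`` and the additive
    noise increment ``sigma_noise * noise_sd * sqrt(dt) * N(0,1) / C`` per
    step.  A fixed ``params.seed`` (or explicit ``rng``) makes the trace
    bit-reproducible.

    Raises :class:`IntegrationDiverged` (naming the step) if the voltage
    leaves +/- 1e4 mV.
    """
    from .afferent import SynapticConfig, mixed_drive

    cfg = syn_cfg or SynapticConfig()
    g_on = np.asarray(g_on, dtype=float)
    g_off = np.asarray(g_off, dtype=float)
    bin_ms = params.dt if cond_bin_ms is None else cond_bin_ms
    support = g_on.size * bin_ms
    if t_end is None:
        t_end = support
    if t_end > support + 1e-9:
        raise ValueError("t_end exceeds the conductance support")
    n_steps = int(round(t_end / params.dt))
    t_grid = np.arange(n_steps) * params.dt
    if abs(bin_ms - params.dt) > 1e-12:
        t_cond = np.arange(g_on.size) * bin_ms
        g_on = np.interp(t_grid, t_cond, g_on)
        g_off = np.interp(t_grid, t_cond, g_off)
    else:
        g_on = g_on[:n_steps]
        g_off = g_off[:n_steps]
    drive = mixed_drive(g_on, g_off, cfg)

    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.sigma_noise == 0.0:
        noise = np.zeros(n_steps)
    else:
        noise = (
            params.sigma_noise
            * params.noise_sd
            * math.sqrt(params.dt)
            / params.C
            * rng.standard_normal(n_steps)
        )

    s0 = resting_state(params)
    eta_alt = 1 if params.eta_parse == "product" else 0
    V, bad, h_lo, h_hi, n_lo, n_hi = _integrate_core(
        s0.V, s0.eta, s0.h, s0.n,
        drive, noise,
        params.dt, params.C,
        params.g_Na, params.g_K, params.g_leak, params.g_h, params.g_T,
        params.E_Na, params.E_K, params.E_leak, params.E_h, params.E_Ca,
        cfg.E_syn, params.I_bias, params.Phi, params.tau_eta, eta_alt,
        params.tau_n_scale,
    )
    if bad >= 0:
        raise IntegrationDiverged(bad)
    spikes = detect_spikes(V, params.dt, threshold)
    return VoltageTrace(
        V=V, dt=params.dt, spike_times=spikes,
        h_range=(h_lo, h_hi), n_range=(n_lo, n_hi),
    )


def detect_spikes(
    V: np.ndarray, dt: float, threshold: float = 0.0, lockout_ms: float = 1.0
) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a lockout.

    One spike per crossing; crossings within ``lockout_ms`` of the previous
    accepted spike are discarded so noise-jittered re-crossings of the same
    action potential are not double counted.
    """
    V = np.asarray(V, dtype=float)
    above = V >= threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if crossings.size == 0:
        return np.array([])
    times = crossings * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= lockout_ms:
            kept.append(t)
    return np.asarray(kept)
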