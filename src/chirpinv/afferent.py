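"""Conversion of hindbrain population rates into synaptic drive.

The ON and OFF population PSTHs are each convolved with a causal alpha
kernel ``alpha(t) = (t/tau_syn) exp(1 - t/tau_syn)`` (unit peak at
``t = tau_syn``) and scaled by ``zeta * g_max`` to give time-varying
excitatory conductances.  The synaptic current mixes the two with weight
``sigma_B`` (fraction of ON input):

    I_syn = -2 g_syn (sigma_B g_ON/g_max + (1 - sigma_B) g_OFF/g_max) (V - E_syn)

with ``g_syn = W_s * g_max`` the reported maximal synaptic conductance.
Rates enter in spikes/s with time in ms, so a constant rate r yields the
steady conductance ``zeta * g_max * r * e * tau_syn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SynapticConfig", "psth_to_conductance", "synaptic_current", "mixed_drive"]


@dataclass
class SynapticConfig:
    """Synaptic conversion constants.

    zeta : rate-to-conductance scale (dimensionless, 0.0005)
    g_max : maximal unitary conductance, uS (0.13)
    tau_syn : alpha-kernel time constant, ms (20)
    sigma_B : fraction of ON-type input, in [0, 1]
    W_s : dimensionless synaptic weight; g_syn = W_s * g_max
    E_syn : excitatory reversal potential, mV (0)
    """

    zeta: float = 0.0005
    g_max: float = 0.13
    tau_syn: float = 20.0
    sigma_B: float = 0.5
    W_s: float = 1.0
    E_syn: float = 0.0

    def __post_init__(self) -> None:
        if self.zeta <= 0 or self.g_max <= 0 or self.tau_syn <= 0:
            raise ValueError("zeta, g_max and tau_syn must be positive")
        if not 0.0 <= self.sigma_B <= 1.0:
            raise ValueError("sigma_B must lie in [0, 1]")

    @property
    def g_syn(self) -> float:
        """Reported maximal synaptic conductance W_s * g_max, uS."""
        return self.W_s * self.g_max


def alpha_kernel(bin_ms: float, tau_syn: float, support_tau: float = 10.0) -> np.ndarray:
    """Causal alpha kernel sampled at ``bin_ms`` with unit peak value."""
    t = np.arange(0.0, support_tau * tau_syn, bin_ms)
    return (t / tau_syn) * np.exp(1.0 - t / tau_syn)


def psth_to_conductance(
    psth: np.ndarray, cfg: SynapticConfig, bin_ms: float
) -> np.ndarray:
    """g(t) = zeta * g_max * (PSTH * alpha)(t), causal, non-negative (uS).

    Zero-padded causal convolution (the stimuli begin from silence); the
    output has the same length and sampling as the input rate series.
    """
    rate = np.asarray(psth, dtype=float)
    if (rate < 0).any():
        raise ValueError("rates must be non-negative")
    kern = alpha_kernel(bin_ms, cfg.tau_syn)
    g = np.convolve(rate, kern)[: rate.size] * bin_ms  # rate in sp/s, t in ms
    return cfg.zeta * cfg.g_max * g


def synaptic_current(
    V: float | np.ndarray,
    g_on: float | np.ndarray,
    g_off: float | np.ndarray,
    cfg: SynapticConfig,
):
    """Instantaneous mixed ON/OFF synaptic current (model current units).

    Linear in each conductance, zero at V = E_syn, and depolarizing
    (positive) whenever V < E_syn and any conductance is positive.
    """
    if not 0.0 <= cfg.sigma_B <= 1.0:
        raise ValueError("sigma_B must lie in [0, 1]")
    if np.any(np.asarray(g_on) < 0) or np.any(np.asarray(g_off) < 0):
        raise ValueError("conductances must be non-negative")
    mix = cfg.sigma_B * np.asarray(g_on) / cfg.g_max + (
        1.0 - cfg.sigma_B
    ) * np.asarray(g_off) / cfg.g_max
    return -2.0 * cfg.g_syn * mix * (np.asarray(V) - cfg.E_syn)


def mixed_drive(g_on: np.ndarray, g_off: np.ndarray, cfg: SynapticConfig) -> np.ndarray:
    """Voltage-independent drive a(t) with I_syn = -a(t) (V - E_syn).

    Precomputing a(t) = 2 g_syn (sigma_B g_ON + (1-sigma_B) g_OFF)/g_max
    lets the integrator treat the synapse as a time-varying conductance.
    """
    mix = cfg.sigma_B * np.asarray(g_on, float) + (1.0 - cfg.sigma_B) * np.asarray(
        g_off, float
    )
    return 2.0 * cfg.g_syn * mix / cfg.g_max


def steady_state_conductance(rate: float, cfg: SynapticConfig) -> float:
    """Closed form for a constant rate: zeta * g_max * r * e * tau_syn."""
    return cfg.zeta * cfg.g_max * rate * math.e * cfg.tau_syn
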