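"""End-to-end model evaluation: stimuli + ELL input + TS model -> FI.

Shared by the differential-evolution search and the parameter sweeps.  The
synaptic conductances are precomputed once per stimulus (they do not depend
on the searched parameters), so each candidate evaluation only re-runs the
stochastic integration and the metric suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .afferent import SynapticConfig, psth_to_conductance
from .invariance_metrics import (
    CHIRP_WINDOW_MS,
    SMOOTH_BIG_MS,
    SMOOTH_SMALL_MS,
    InvarianceResult,
    compute_psth,
    csi,
    fi,
    vpd_avg,
)
from .stimgen import StimulusTrace
from .synthetic_ell import PopulationPsthPair, SpikeTrainSet
from .ts_model import IntegrationDiverged, TsModelParams, integrate

__all__ = ["ModelEvaluator", "BURN_IN_MS"]

log = logging.getLogger(__name__)

#: Discarded settling time before any metric window (ms).
BURN_IN_MS = 150.0

#: Tunable parameter names an evaluation may override.
TUNABLE = ("sigma_B", "g_syn", "I_bias", "g_h", "g_T", "sigma_noise")


@dataclass
class ModelEvaluator:
    """Evaluates TS-model parameter sets on a battery of chirp stimuli.

    Parameters
    ----------
    stimuli, psth_pairs : matched lists (one ELL ON/OFF PSTH pair per
        stimulus).
    base_params : TsModelParams defaults for everything not overridden.
    syn_template : SynapticConfig carrying zeta, g_max, tau_syn, E_syn.
    n_trials : stochastic repeats per stimulus entering the metrics.
    burn_in_ms : settling time discarded before the analysis window.
    """

    stimuli: list[StimulusTrace]
    psth_pairs: list[PopulationPsthPair]
    base_params: TsModelParams = field(default_factory=TsModelParams)
    syn_template: SynapticConfig = field(default_factory=SynapticConfig)
    n_trials: int = 5
    burn_in_ms: float = BURN_IN_MS

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.psth_pairs):
            raise ValueError("stimuli and PSTH pairs must match one-to-one")
        dt = self.base_params.dt
        self._g_on = []
        self._g_off = []
        for stim, pair in zip(self.stimuli, self.psth_pairs):
            g_on = psth_to_conductance(pair.on_rate, self.syn_template, pair.bin_ms)
            g_off = psth_to_conductance(pair.off_rate, self.syn_template, pair.bin_ms)
            t_cond = np.arange(g_on.size) * pair.bin_ms
            t_grid = np.arange(0.0, stim.duration, dt)
            self._g_on.append(np.interp(t_grid, t_cond, g_on))
            self._g_off.append(np.interp(t_grid, t_cond, g_off))

    # -- helpers ----------------------------------------------------------

    def _chirp_onset_rel(self, stim: StimulusTrace) -> float:
        if not stim.chirp_onsets:
            raise ValueError(f"stimulus {stim.stimulus_id!r} has no chirp")
        return stim.chirp_onsets[0] - self.burn_in_ms

    def _smooth_for(self, stim: StimulusTrace) -> float:
        kinds = {c.kind for c in stim.chirps}
        return SMOOTH_BIG_MS if kinds == {"big"} else SMOOTH_SMALL_MS

    # -- evaluation -------------------------------------------------------

    def simulate_trains(
        self, overrides: dict, seed: int, tag: int = 0
    ) -> SpikeTrainSet:
        """Spike trains for all stimuli and trials at one parameter set.

        Per-trial seeds derive deterministically from ``(seed, tag,
        stimulus index, trial)`` so results do not depend on evaluation
        order.
        """
        bad = set(overrides) - set(TUNABLE)
        if bad:
            raise ValueError(f"unknown tunable parameter(s): {sorted(bad)}")
        params = self.base_params.with_(
            **{
                k: overrides[k]
                for k in ("I_bias", "g_h", "g_T", "sigma_noise")
                if k in overrides
            }
        )
        syn = SynapticConfig(
            zeta=self.syn_template.zeta,
            g_max=self.syn_template.g_max,
            tau_syn=self.syn_template.tau_syn,
            sigma_B=overrides.get("sigma_B", self.syn_template.sigma_B),
            W_s=overrides.get("g_syn", self.syn_template.g_syn)
            / self.syn_template.g_max,
            E_syn=self.syn_template.E_syn,
        )
        trains = {}
        duration = self.stimuli[0].duration - self.burn_in_ms
        for i, stim in enumerate(self.stimuli):
            for trial in range(self.n_trials):
                rng = np.random.default_rng([seed, tag, i, trial])
                trace = integrate(
                    params, self._g_on[i], self._g_off[i], syn, rng=rng
                )
                st = trace.spike_times
                st = st[st >= self.burn_in_ms] - self.burn_in_ms
                trains[(stim.stimulus_id, trial)] = st
        return SpikeTrainSet(
            trains=trains, n_trials=self.n_trials, duration=duration
        )

    def evaluate(
        self, overrides: dict, seed: int, tag: int = 0
    ) -> InvarianceResult:
        """CSI_avg, VPD_avg and FI for one parameter set.

        Raises :class:`chirpinv.ts_model.IntegrationDiverged` if any trial
        blows up (callers decide whether that is fatal).
        """
        trains = self.simulate_trains(overrides, seed, tag)
        duration = self.stimuli[0].duration - self.burn_in_ms
        csis = {}
        for stim in self.stimuli:
            p = compute_psth(
                trains,
                stimulus_id=stim.stimulus_id,
                smooth_ms=self._smooth_for(stim),
                duration=duration,
            )
            csis[stim.stimulus_id] = csi(
                p, self._chirp_onset_rel(stim), CHIRP_WINDOW_MS
            )
        csi_avg = float(np.mean(list(csis.values())))
        v = vpd_avg(trains)
        return InvarianceResult(
            csi_avg=csi_avg,
            vpd_avg=v,
            fi=fi(csi_avg, v),
            csi_per_stimulus=csis,
        )

    def evaluate_fi(self, overrides: dict, seed: int, tag: int = 0) -> float:
        """FI only; diverged integrations score 0 (logged)."""
        try:
            return self.evaluate(overrides, seed, tag).fi
        except IntegrationDiverged as exc:
            log.warning("diverged at %s: %s", overrides, exc)
            return 0.0
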