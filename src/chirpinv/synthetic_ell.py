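"""Surrogate hindbrain (ELL) population input.

No recorded ELL pyramidal-cell dataset accompanies this pipeline, so this
module generates population-averaged ON/OFF peri-stimulus time histograms
(PSTHs), trial-resolved spike trains, and cycle-averaged membrane traces
with the statistical structure the downstream analysis assumes:

* ON cells phase-lock to the rising phase of the beat AM, OFF cells to the
  falling phase (antiphase to ON);
* during a chirp each population is transiently excited or suppressed
  toward zero, with the sign set deterministically by the beat phase at
  which the chirp falls (excitation when the chirp lands on the cell's
  preferred phase, suppression otherwise) — so the same chirp drives some
  waveform variants with excitation and others with inhibition;
* smooth, seeded rate noise on top, rates clipped at zero.

This parametric stand-in reproduces the qualitative features the midbrain
model integrates (phase locking, ON/OFF antiphase, signed heterogeneous
chirp transients, non-invariance of the hindbrain input itself); it is not
a biophysical ELL model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .stimgen import StimulusTrace, beat_phase_at

__all__ = [
    "EllGainConfig",
    "PopulationPsthPair",
    "SpikeTrainSet",
    "generate_population_psths",
    "generate_spike_trains",
    "generate_cycle_vm",
]


@dataclass
class EllGainConfig:
    """Gains of the surrogate ELL rate model (all spikes/s unless noted).

    Defaults are physiologically motivated for ELL pyramidal cells:
    a ~40 sp/s baseline, strong but unclipped beat phase locking, chirp
    transients reaching ~160 sp/s, and weak smooth rate noise.
    """

    baseline: float = 40.0          # mean rate
    beat_depth: float = 35.0        # phase-locking modulation depth
    chirp_gain: float = 120.0       # added rate at an excitatory transient
    suppression: float = 0.9        # fractional rate removal at a suppressive transient
    chirp_sigma_ms: float = 7.0     # width of the chirp transient
    noise_gain: float = 5.0         # SD of smooth rate noise
    noise_smooth_ms: float = 5.0    # Gaussian kernel of the rate noise
    rate_max: float = 400.0         # hard ceiling

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.beat_depth < 0:
            raise ValueError("baseline and beat_depth must be non-negative")


@dataclass
class PopulationPsthPair:
    """Time-binned ON and OFF population firing-rate profiles."""

    on_rate: np.ndarray      # spikes/s
    off_rate: np.ndarray     # spikes/s
    bin_ms: float
    stimulus_id: str = ""
    chirp_onset: float | None = None

    def __post_init__(self) -> None:
        self.on_rate = np.asarray(self.on_rate, dtype=float)
        self.off_rate = np.asarray(self.off_rate, dtype=float)
        if self.on_rate.shape != self.off_rate.shape:
            raise ValueError("ON and OFF rate profiles must have equal length")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if (self.on_rate < 0).any() or (self.off_rate < 0).any():
            raise ValueError("rates must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.on_rate.size) * self.bin_ms


@dataclass
class SpikeTrainSet:
    """Spike-time lists indexed by (stimulus_id, trial)."""

    trains: dict = field(default_factory=dict)   # (stimulus_id, trial) -> ndarray ms
    n_trials: int = 0
    duration: float = 0.0

    def __post_init__(self) -> None:
        for key, st in self.trains.items():
            st = np.asarray(st, dtype=float)
            if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0 or st[-1] > self.duration):
                raise ValueError(f"invalid spike train for {key}")
            self.trains[key] = st

    def all_trains(self) -> list[np.ndarray]:
        return [self.trains[k] for k in sorted(self.trains)]


def _chirp_sign_on(phase_deg: float) -> int:
    """+1 (excitation) when the chirp lands on the ON cell's preferred
    (rising) beat phase, -1 (suppression) otherwise.

    Phase 0 is the beat maximum; the AM rises over (180, 360) degrees.
    """
    return 1 if 180.0 <= phase_deg % 360.0 < 360.0 else -1


def generate_population_psths(
    stimuli: list[StimulusTrace],
    gain_cfg: EllGainConfig | None = None,
    seed: int | None = None,
    bin_ms: float = 0.5,
) -> list[PopulationPsthPair]:
    """Surrogate ON/OFF population PSTHs for each stimulus.

    The beat response is the smoothed, normalised time derivative of the AM:
    ON = baseline + depth * dA/dt, OFF = baseline - depth * dA/dt (antiphase
    by construction).  Chirp transients are Gaussian bumps whose sign per
    population follows :func:`_chirp_sign_on`; suppression multiplies the
    rate toward zero instead of adding.
    """
    cfg = gain_cfg or EllGainConfig()
    rng = np.random.default_rng(seed)
    out: list[PopulationPsthPair] = []
    for stim in stimuli:
        step = max(int(round(bin_ms / stim.dt)), 1)
        am = stim.samples
        t = stim.times
        deriv = np.gradient(am, stim.dt)
        deriv = gaussian_filter1d(deriv, max(1.0 / stim.dt, 1.0))
        # normalise by the beat-segment derivative amplitude
        mask = np.ones(t.size, dtype=bool)
        for onset in stim.chirp_onsets:
            mask &= np.abs(t - onset) > 30.0
        scale = np.max(np.abs(deriv[mask])) if mask.any() else np.max(np.abs(deriv))
        d = deriv / scale if scale > 0 else deriv
        d = np.clip(d, -3.0, 3.0)

        on = cfg.baseline + cfg.beat_depth * d
        off = cfg.baseline - cfg.beat_depth * d
        for onset in stim.chirp_onsets:
            phase = beat_phase_at(stim, onset, before=onset - 25.0)
            bump = np.exp(-0.5 * ((t - onset) / cfg.chirp_sigma_ms) ** 2)
            if _chirp_sign_on(phase) > 0:
                on = on + cfg.chirp_gain * bump
                off = off * (1.0 - cfg.suppression * bump)
            else:
                off = off + cfg.chirp_gain * bump
                on = on * (1.0 - cfg.suppression * bump)

        if cfg.noise_gain > 0:
            k = cfg.noise_smooth_ms / stim.dt
            non = gaussian_filter1d(rng.normal(0.0, 1.0, t.size), k)
            noff = gaussian_filter1d(rng.normal(0.0, 1.0, t.size), k)
            # renormalise so the smoothed noise keeps the configured SD
            for nz in (non, noff):
                s = nz.std()
                if s > 0:
                    nz *= cfg.noise_gain / s
            on = on + non
            off = off + noff

        on = np.clip(on, 0.0, cfg.rate_max)[::step]
        off = np.clip(off, 0.0, cfg.rate_max)[::step]
        out.append(
            PopulationPsthPair(
                on_rate=on,
                off_rate=off,
                bin_ms=stim.dt * step,
                stimulus_id=stim.stimulus_id,
                chirp_onset=stim.chirp_onsets[0] if stim.chirp_onsets else None,
            )
        )
    return out


def generate_spike_trains(
    rate_profile: np.ndarray,
    bin_ms: float,
    n_trials: int,
    seed: int | None = None,
    stimulus_id: str = "",
) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spike trains sampled by thinning.

    Homogeneous candidates at the profile's maximum rate are thinned with
    acceptance probability rate(t)/rate_max; seeded and reproducible.
    """
    rate = np.asarray(rate_profile, dtype=float)
    if (rate < 0).any():
        raise ValueError("rates must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    duration = rate.size * bin_ms
    rmax = float(rate.max()) if rate.size else 0.0
    rng = np.random.default_rng(seed)
    trains = {}
    for trial in range(n_trials):
        if rmax == 0.0:
            trains[(stimulus_id, trial)] = np.array([])
            continue
        n_cand = rng.poisson(rmax * 1e-3 * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        idx = np.minimum((cand / bin_ms).astype(int), rate.size - 1)
        keep = rng.uniform(0.0, 1.0, size=n_cand) < rate[idx] / rmax
        st = cand[keep]
        st = st[np.concatenate(([True], np.diff(st) > 0))] if st.size else st
        trains[(stimulus_id, trial)] = st
    return SpikeTrainSet(trains=trains, n_trials=n_trials, duration=duration)


def generate_cycle_vm(
    peak_ratio: float,
    cycle_ms: float = 100.0,
    dt: float = 0.1,
    bump_sigma_frac: float = 1.0 / 14.0,
    floor: float = 0.0,
) -> np.ndarray:
    """Cycle-averaged membrane-potential fixture for the bimodality index.

    One Gaussian bump of unit height at phase 0 and a second of height
    ``peak_ratio`` half a cycle later, above a flat floor; bumps wrap
    circularly.  ``peak_ratio`` = 1 gives two equal bumps, 0 a unimodal
    trace.
    """
    if not 0.0 <= peak_ratio <= 1.0:
        raise ValueError("peak_ratio must lie in [0, 1]")
    t = np.arange(0.0, cycle_ms, dt)
    sigma = bump_sigma_frac * cycle_ms

    def bump(center: float) -> np.ndarray:
        out = np.zeros_like(t)
        for shift in (-cycle_ms, 0.0, cycle_ms):
            out += np.exp(-0.5 * ((t - center - shift) / sigma) ** 2)
        return out

    return floor + bump(0.0) + peak_ratio * bump(cycle_ms / 2.0)


def write_psth_csv(pair: PopulationPsthPair, path) -> None:
    """Delimited text, one bin per row: time_ms, on_rate, off_rate."""
    import pandas as pd

    pd.DataFrame(
        {"time_ms": pair.times, "on_rate": pair.on_rate, "off_rate": pair.off_rate}
    ).to_csv(path, index=False)


def write_spikes_csv(spikes: SpikeTrainSet, path) -> None:
    """Delimited text, one spike per row: stimulus_id, trial, spike_ms."""
    import pandas as pd

    rows = [
        (sid, trial, t)
        for (sid, trial), st in sorted(spikes.trains.items())
        for t in st
    ]
    pd.DataFrame(rows, columns=["stimulus_id", "trial", "spike_ms"]).to_csv(
        path, index=False
    )


def read_spikes_csv(path, duration: float) -> SpikeTrainSet:
    import pandas as pd

    df = pd.read_csv(path)
    trains = {}
    for (sid, trial), grp in df.groupby(["stimulus_id", "trial"]):
        trains[(str(sid), int(trial))] = np.sort(grp["spike_ms"].to_numpy(float))
    n_trials = max((k[1] for k in trains), default=-1) + 1
    return SpikeTrainSet(trains=trains, n_trials=n_trials, duration=duration)
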