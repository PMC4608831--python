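"""Response quantification: PSTHs, selectivity, spike-train distances, and
the feature-invariance score.

A neuron is *feature invariant* when it responds selectively to the chirp
(rather than the beat) and does so similarly across heterogeneous chirp
waveforms.  Selectivity is captured by the chirp selectivity index

    CSI = (R_C - R_B) / (R_C + R_B)

contrasting the maximum PSTH rate in a 100 ms window from chirp onset (R_C)
against the maximum elsewhere (R_B), and response similarity by the mean
Victor-Purpura spike-train distance (VPD, cost parameter q = 100 /s) over
all pairs of trials pooled across stimuli.  The two combine into

    FI = [CSI_avg - alpha * VPD_avg]_+        (alpha = 0.01)

rectified at zero.  A PSTH-based variant substitutes the circularly aligned
RMSE between PSTH pairs (FI_RMSE, gamma = 0.0041).  The bimodality index
quantifies mixed ON+OFF subthreshold input from a cycle-averaged membrane
trace, and robustness summarises an FI parameter map as the percentage of
grid cells at or above threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .synthetic_ell import SpikeTrainSet

__all__ = [
    "Psth",
    "InvarianceResult",
    "compute_psth",
    "csi",
    "vpd",
    "vpd_avg",
    "rmse_avg",
    "fi",
    "fi_rmse",
    "bimodality_index",
    "robustness",
    "DEFAULT_ALPHA",
    "DEFAULT_GAMMA",
    "DEFAULT_Q",
]

DEFAULT_ALPHA = 0.01       # CSI-vs-VPD trade-off in FI
DEFAULT_GAMMA = 0.0041     # CSI-vs-RMSE trade-off in FI_RMSE
DEFAULT_Q = 100.0          # VPD shift cost, 1/s
DEFAULT_BIN_MS = 0.1
SMOOTH_SMALL_MS = 10.8     # boxcar for small-chirp PSTHs
SMOOTH_BIG_MS = 5.0        # boxcar for the big-chirp PSTH
CHIRP_WINDOW_MS = 100.0    # response window from chirp onset
FI_ELIGIBLE = 0.2          # below this a cell is labelled non-invariant


@dataclass
class Psth:
    rate: np.ndarray      # spikes/s per bin
    bin_ms: float = DEFAULT_BIN_MS
    smooth_ms: float = SMOOTH_SMALL_MS
    t0_ms: float = 0.0    # time of the first bin edge

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        if (self.rate < 0).any():
            raise ValueError("PSTH rates must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0_ms + (np.arange(self.rate.size) + 0.5) * self.bin_ms


@dataclass
class InvarianceResult:
    csi_avg: float
    vpd_avg: float
    fi: float
    rmse_avg: float | None = None
    fi_rmse: float | None = None
    csi_per_stimulus: dict | None = None
    alpha: float = DEFAULT_ALPHA
    gamma: float = DEFAULT_GAMMA
    q: float = DEFAULT_Q

    @property
    def invariant(self) -> bool:
        return self.fi > FI_ELIGIBLE


# ---------------------------------------------------------------------------
# PSTH


def compute_psth(
    trains: SpikeTrainSet,
    stimulus_id: str | None = None,
    bin_ms: float = DEFAULT_BIN_MS,
    smooth_ms: float = SMOOTH_SMALL_MS,
    t0_ms: float = 0.0,
    duration: float | None = None,
) -> Psth:
    """Trial-averaged, boxcar-smoothed firing rate (spikes/s).

    Bins spikes at ``bin_ms`` from ``t0_ms`` to ``duration``, averages over
    trials, converts to a rate and smooths with a ``smooth_ms`` boxcar.
    Smoothing conserves spike mass up to edge effects, so the integral of
    the rate equals the mean spike count per trial.
    """
    keys = [
        k for k in trains.trains
        if stimulus_id is None or k[0] == stimulus_id
    ]
    if not keys:
        raise ValueError("no trials for the requested stimulus")
    dur = trains.duration if duration is None else duration
    edges = np.arange(t0_ms, dur + bin_ms * 0.5, bin_ms)
    counts = np.zeros(edges.size - 1)
    for k in keys:
        c, _ = np.histogram(trains.trains[k], bins=edges)
        counts += c
    rate = counts / len(keys) / (bin_ms * 1e-3)
    width = max(int(round(smooth_ms / bin_ms)), 1)
    if width > 1:
        rate = np.convolve(rate, np.ones(width) / width, mode="same")
    return Psth(rate=rate, bin_ms=bin_ms, smooth_ms=smooth_ms, t0_ms=t0_ms)


def csi(
    psth: Psth,
    chirp_onset: float,
    window_ms: float = CHIRP_WINDOW_MS,
    guard_ms: float | None = None,
) -> float:
    """Chirp selectivity index (R_C - R_B) / (R_C + R_B) in [-1, 1].

    R_C is the maximum rate within ``[chirp_onset, chirp_onset+window_ms]``
    and R_B the maximum elsewhere.  A guard band of half the smoothing width
    (default) is excluded at the window edges so boxcar leakage of the chirp
    response does not inflate R_B.  Returns 0 when both maxima are 0.
    """
    t = psth.times
    if guard_ms is None:
        guard_ms = psth.smooth_ms / 2.0
    in_chirp = (t >= chirp_onset) & (t <= chirp_onset + window_ms)
    in_beat = (t < chirp_onset - guard_ms) | (t > chirp_onset + window_ms + guard_ms)
    if not in_chirp.any() or not in_beat.any():
        raise ValueError("chirp window must lie inside the PSTH support")
    r_c = float(psth.rate[in_chirp].max())
    r_b = float(psth.rate[in_beat].max())
    if r_c == 0.0 and r_b == 0.0:
        return 0.0
    return (r_c - r_b) / (r_c + r_b)


# ---------------------------------------------------------------------------
# Victor-Purpura distance


@njit(cache=True)
def _vpd_dp(a: np.ndarray, b: np.ndarray, q_per_ms: float) -> float:
    na, nb = a.size, b.size
    prev = np.empty(nb + 1)
    cur = np.empty(nb + 1)
    for j in range(nb + 1):
        prev[j] = j
    for i in range(1, na + 1):
        cur[0] = i
        for j in range(1, nb + 1):
            shift = prev[j - 1] + q_per_ms * abs(a[i - 1] - b[j - 1])
            ins = cur[j - 1] + 1.0
            dele = prev[j] + 1.0
            m = shift
            if ins < m:
                m = ins
            if dele < m:
                m = dele
            cur[j] = m
        prev, cur = cur, prev
    return prev[nb]


def vpd(a: np.ndarray, b: np.ndarray, q: float = DEFAULT_Q) -> float:
    """Exact Victor-Purpura distance between two spike-time lists (ms).

    Dynamic program with unit insert/delete cost and shift cost
    ``q * |dt|`` (q in 1/s, spike times in ms); symmetric and a true metric
    on spike trains.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for x in (a, b):
        if x.size > 1 and np.any(np.diff(x) < 0):
            raise ValueError("spike times must be sorted")
    return float(_vpd_dp(a, b, q * 1e-3))


def vpd_avg(trains: SpikeTrainSet, q: float = DEFAULT_Q) -> float:
    """Mean VPD over all unordered pairs of (stimulus, trial) spike trains.

    Pairs are pooled across stimuli — both within- and between-stimulus
    pairs count, self-pairs do not — giving M = C(N*N_T, 2) comparisons.
    """
    all_tr = trains.all_trains()
    if len(all_tr) < 2:
        raise ValueError("need at least two spike trains")
    q_ms = q * 1e-3
    total = 0.0
    m = 0
    for i in range(len(all_tr)):
        for j in range(i + 1, len(all_tr)):
            total += _vpd_dp(all_tr[i], all_tr[j], q_ms)
            m += 1
    return total / m


def vpd_avg_between(trains: SpikeTrainSet, q: float = DEFAULT_Q) -> float:
    """Between-stimulus-only variant of :func:`vpd_avg` (sensitivity check)."""
    keys = sorted(trains.trains)
    pairs = [
        (i, j)
        for i in range(len(keys))
        for j in range(i + 1, len(keys))
        if keys[i][0] != keys[j][0]
    ]
    if not pairs:
        raise ValueError("no between-stimulus pairs")
    q_ms = q * 1e-3
    return sum(
        _vpd_dp(trains.trains[keys[i]], trains.trains[keys[j]], q_ms)
        for i, j in pairs
    ) / len(pairs)


# ---------------------------------------------------------------------------
# PSTH-based invariance


def _circular_align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circularly shift ``b`` to the lag maximising its cross-correlation
    with ``a`` (FFT circular correlation)."""
    fa = np.fft.rfft(a)
    fb = np.fft.rfft(b)
    xc = np.fft.irfft(fa * np.conj(fb), n=a.size)
    lag = int(np.argmax(xc))
    return np.roll(b, lag)


def rmse_avg(psths: list[Psth]) -> float:
    """Mean RMSE over all unordered PSTH pairs after circular alignment.

    For each pair the second PSTH is circularly shifted to the maximum of
    the cross-correlogram before the RMSE is taken, so pure timing offsets
    do not register as dissimilarity.
    """
    if len(psths) < 2:
        raise ValueError("need at least two PSTHs")
    n = psths[0].rate.size
    for p in psths:
        if p.rate.size != n:
            raise ValueError("PSTHs must have equal length")
    total = 0.0
    m = 0
    for i in range(len(psths)):
        for j in range(i + 1, len(psths)):
            b = _circular_align(psths[i].rate, psths[j].rate)
            total += math.sqrt(float(np.mean((psths[i].rate - b) ** 2)))
            m += 1
    return total / m


# ---------------------------------------------------------------------------
# feature invariance


def fi(csi_avg: float, vpd_avg: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Feature-invariance score [CSI_avg - alpha * VPD_avg]_+.

    The rectification (x * H0(x)) keeps the score at zero whenever the
    penalised selectivity is negative and leaves the graded value otherwise;
    FI is non-decreasing in CSI_avg and non-increasing in VPD_avg.
    """
    x = csi_avg - alpha * vpd_avg
    return x if x > 0.0 else 0.0


def fi_rmse(csi_avg: float, rmse_avg: float, gamma: float = DEFAULT_GAMMA) -> float:
    """PSTH-based feature invariance [CSI_avg - gamma * RMSE_avg]_+."""
    x = csi_avg - gamma * rmse_avg
    return x if x > 0.0 else 0.0


def bimodality_index(mean_vm_cycle: np.ndarray) -> float:
    """Ratio of the cycle-averaged response half a period after its peak.

    The baseline (minimum) is subtracted, the trace circularly rotated so
    its maximum sits at index 0, and the value at half the period divided by
    the value at 0.  Equals 1 for two equal response phases pi apart and 0
    for a single response phase.
    """
    v = np.asarray(mean_vm_cycle, dtype=float)
    v = v - v.min()
    if v.max() == 0.0:
        raise ValueError("bimodality undefined for a flat signal")
    v = np.roll(v, -int(np.argmax(v)))
    return float(v[v.size // 2] / v[0])


def robustness(fi_grid: np.ndarray, threshold: float = 0.7) -> float:
    """Percentage of grid cells with FI >= threshold (NaN cells excluded)."""
    g = np.asarray(fi_grid, dtype=float)
    valid = np.isfinite(g)
    if not valid.any():
        raise ValueError("empty FI grid")
    return 100.0 * float(np.count_nonzero(g[valid] >= threshold)) / int(valid.sum())


def write_metrics_csv(results: dict[str, InvarianceResult], path) -> None:
    """One row per configuration: csi_avg, vpd_avg, rmse_avg, fi, fi_rmse."""
    import pandas as pd

    rows = []
    for name, r in results.items():
        rows.append(
            {
                "config": name,
                "csi_avg": r.csi_avg,
                "vpd_avg": r.vpd_avg,
                "rmse_avg": r.rmse_avg if r.rmse_avg is not None else np.nan,
                "fi": r.fi,
                "fi_rmse": r.fi_rmse if r.fi_rmse is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
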