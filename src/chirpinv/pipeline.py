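"""Configuration-driven end-to-end pipeline.

Reads a YAML configuration, runs stimulus synthesis -> surrogate ELL input
-> synaptic conversion -> TS-model simulation -> invariance metrics
(optionally followed by a differential-evolution search and/or parameter
sweeps), and writes delimited-text tables, an HDF5 trace bundle, and a JSON
manifest recording the configuration hash, seeds, package version and the
eta-parse flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .afferent import SynapticConfig
from .de_search import DeConfig, fit_ts_model
from .evaluate import ModelEvaluator
from .invariance_metrics import InvarianceResult, write_metrics_csv
from .stimgen import standard_chirp_stimuli, write_trace_csv
from .synthetic_ell import (
    EllGainConfig,
    generate_population_psths,
    write_psth_csv,
    write_spikes_csv,
)
from .sweep import SweepSpec, compare_robustness, pairwise_sweep
from .ts_model import TsModelParams

__all__ = ["load_config", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stimulus": {
        "receiver_freq_hz": 750.0,
        "duration_ms": 600.0,
        "dt_ms": 0.025,
        "chirp_onset_ms": 350.0,
        "contrast": 0.2,
    },
    "synthetic_ell": {},       # EllGainConfig overrides
    "synapse": {},             # SynapticConfig overrides (sigma_B, W_s, ...)
    "ts_model": {},            # TsModelParams overrides
    "analysis": {"n_trials": 10},
    "de_search": {"enabled": False},
    "sweep": {"enabled": False},
}


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    """Load and validate a YAML config, merged over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    cfg = _merge(DEFAULT_CONFIG, user)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    """Schema checks with key paths, before any computation."""
    errs = []
    stim = cfg["stimulus"]
    for key in ("receiver_freq_hz", "duration_ms", "dt_ms"):
        if not isinstance(stim.get(key), (int, float)) or stim[key] <= 0:
            errs.append(f"stimulus.{key}: must be a positive number")
    if stim.get("chirp_onset_ms", 0) >= stim.get("duration_ms", 1):
        errs.append("stimulus.chirp_onset_ms: must precede duration_ms")
    for block, cls in (
        ("synthetic_ell", EllGainConfig),
        ("synapse", SynapticConfig),
        ("ts_model", TsModelParams),
    ):
        allowed = set(cls.__dataclass_fields__)
        unknown = set(cfg.get(block, {})) - allowed
        if unknown:
            errs.append(f"{block}: unknown key(s) {sorted(unknown)}")
    if errs:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errs))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_inputs(cfg: dict, seed: int):
    """Stimuli and surrogate ELL PSTH pairs for a config."""
    stim_cfg = cfg["stimulus"]
    stimuli = standard_chirp_stimuli(
        f_receiver=stim_cfg["receiver_freq_hz"],
        duration=stim_cfg["duration_ms"],
        dt=stim_cfg["dt_ms"],
        chirp_onset=stim_cfg["chirp_onset_ms"],
        contrast=stim_cfg["contrast"],
    )
    gain = EllGainConfig(**cfg.get("synthetic_ell", {}))
    pairs = generate_population_psths(stimuli, gain, seed=seed)
    return stimuli, pairs


def run_pipeline(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute the configured pipeline and write the artifact bundle.

    Returns a manifest dict (also written to ``manifest.json``) with the
    config hash, seeds, versions, eta-parse flag and the output file list.
    """
    cfg = load_config(config_path) if not isinstance(config_path, dict) else _merge(
        DEFAULT_CONFIG, config_path
    )
    if isinstance(config_path, dict):
        _validate(cfg)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stimuli, pairs = build_inputs(cfg, seed)
    params = TsModelParams(**cfg.get("ts_model", {}))
    syn = SynapticConfig(**cfg.get("synapse", {}))
    n_trials = int(cfg["analysis"].get("n_trials", 10))

    written = []
    for stim, pair in zip(stimuli, pairs):
        p = out / f"stimulus_{stim.stimulus_id}.csv"
        write_trace_csv(stim, p)
        written.append(p.name)
        p = out / f"psth_{stim.stimulus_id}.csv"
        write_psth_csv(pair, p)
        written.append(p.name)

    evaluator = ModelEvaluator(
        stimuli=stimuli, psth_pairs=pairs, base_params=params,
        syn_template=syn, n_trials=n_trials,
    )
    trains = evaluator.simulate_trains({}, seed=seed)
    write_spikes_csv(trains, out / "ts_spikes.csv")
    written.append("ts_spikes.csv")
    result = evaluator.evaluate({}, seed=seed)
    write_metrics_csv({"default": result}, out / "metrics.csv")
    written.append("metrics.csv")

    manifest = {
        "package": "chirpinv",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "eta_parse": params.eta_parse,
        "outputs": written,
        "metrics": {
            "csi_avg": result.csi_avg,
            "vpd_avg": result.vpd_avg,
            "fi": result.fi,
        },
    }

    de_cfg = cfg.get("de_search", {})
    if de_cfg.get("enabled"):
        cfg_de = DeConfig(
            K=int(de_cfg.get("K", 20)),
            generations=int(de_cfg.get("generations", 30)),
            seed=seed,
            target_fi=de_cfg.get("target_fi"),
        )
        fit = fit_ts_model(
            stimuli, pairs, base_params=params, cfg=cfg_de,
            syn_template=syn, n_trials=int(de_cfg.get("n_trials", 5)),
        )
        res = {
            "genes": fit["best_genes"],
            "fi": fit["best"].fi,
            "history": fit["history"],
            "seed": seed,
            "eta_parse": params.eta_parse,
        }
        (out / "de_result.json").write_text(json.dumps(res, indent=2))
        written.append("de_result.json")
        manifest["de_search"] = {"fi": fit["best"].fi, "genes": fit["best_genes"]}

    sw_cfg = cfg.get("sweep", {})
    if sw_cfg.get("enabled"):
        spec = SweepSpec(
            param_x=sw_cfg["param_x"],
            x_values=np.asarray(sw_cfg["x_values"], dtype=float),
            param_y=sw_cfg["param_y"],
            y_values=np.asarray(sw_cfg["y_values"], dtype=float),
            base=sw_cfg.get("base", {}),
            model_params=params,
            syn_template=syn,
            n_trials=int(sw_cfg.get("n_trials", 10)),
            seed=seed,
        )
        if sw_cfg.get("compare_subthreshold"):
            comp = compare_robustness(spec, stimuli=stimuli, psth_pairs=pairs)
            grid = comp["grid_with"]
            manifest["sweep"] = {
                "robust_with": comp["robust_with"],
                "robust_without": comp["robust_without"],
            }
        else:
            grid = pairwise_sweep(spec, stimuli, pairs)
            manifest["sweep"] = {"robustness": grid.robustness}
        np.savetxt(out / "fi_grid.csv", grid.fi, delimiter=",")
        written.append("fi_grid.csv")

    save_hdf5_bundle(out / "traces.h5", stimuli, pairs, trains)
    written.append("traces.h5")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def save_hdf5_bundle(path, stimuli, pairs, trains) -> None:
    """Stimuli, PSTH pairs and spike trains in one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        for stim, pair in zip(stimuli, pairs):
            g = f.create_group(f"stimuli/{stim.stimulus_id}")
            g.create_dataset("am", data=stim.samples)
            g.attrs["dt_ms"] = stim.dt
            g.attrs["beat_freq_hz"] = stim.beat_freq
            g.attrs["chirp_onsets_ms"] = stim.chirp_onsets
            g.create_dataset("on_rate", data=pair.on_rate)
            g.create_dataset("off_rate", data=pair.off_rate)
            g.attrs["psth_bin_ms"] = pair.bin_ms
        for (sid, trial), st in sorted(trains.trains.items()):
            f.create_dataset(f"spikes/{sid}/trial_{trial:03d}", data=st)
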