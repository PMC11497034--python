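"""Run configuration: one schema across all pipeline stages.

Defaults mirror the acquisition and analysis settings of the assay
(200 kHz sampling, 20 kHz order-1 Butterworth, order-1 Savitzky-Golay
baseline, 4-sigma thresholds, 10 ms photon bins).  Field names embed units
(_nm, _min, _pA, _Hz, _s) to keep unit bugs out of config files.  A config
is a plain nested mapping, loadable from YAML/JSON, validated against this
schema (unknown keys are rejected), and every run writes its resolved config
next to its outputs so any run is reproducible from that file alone.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "resolve_config", "apply_overrides", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration (unknown key or malformed file)."""


_DEFAULTS: dict = {
    "geometry": {
        "tip_radius_nm": 15.0,
        "half_cone_angle_rad": 0.1,
        "conductivity_S_per_m": 8.6,
        "open_conductance_nS": None,  # derived from geometry when omitted
    },
    "filter": {"cutoff_Hz": 20_000.0, "order": 1},
    "baseline": {"window": 50_001},
    "detect": {
        "k": 4.0,
        "merge_gap": 5,
        "min_duration": 2,
        "polarity": "auto",
        "boundary_sigma": 1.0,
    },
    "burst": {"k": 4.0, "blink_gap": 1, "min_duration_bins": 1},
    "dwell_histogram": {"t_min_s": 0.01, "t_max_s": 100.0, "bins_per_decade": 20},
    "kinetics_fit": {"pooled": False},
    "simulate_trace": {
        "duration_s": 10.0,
        "sampling_rate_Hz": 200_000.0,
        "applied_voltage_mV": -500.0,
        "noise_sigma_pA": 20.0,
        "drift_pA_per_s": 2.0,
        "drift_sine_amp_pA": 10.0,
        "drift_sine_freq_Hz": 0.1,
        "bessel_cutoff_Hz": 10_000.0,
        "incubation_time_min": 0.0,
        "components": [
            {
                "volume_median_nm3": 1000.0,
                "volume_log_sd": 0.5,
                "rate_per_s": 5.0,
                "dwell_median_s": 1e-3,
                "dwell_log_sd": 0.3,
            }
        ],
    },
    "simulate_photons": {
        "duration_s": 60.0,
        "bin_width_s": 0.010,
        "diameters_nm": [200.0, 200.0],
        "waist_xy_nm": 2000.0,
        "waist_z_nm": 6000.0,
        "peak_rate_per_s": 1.0e6,
        "background_rate_per_s": 1.0e3,
        "temperature_K": 298.15,
        "viscosity_Pa_s": 8.9e-4,
        "box_nm": 20_000.0,
        "incubation_time_min": 0.0,
    },
    "simulate_kinetics": {
        "I_i": 0.0,
        "I_f": 100.0,
        "T50_min": 630.0,
        "tau_min": 40.0,
        "noise_sigma": 3.0,
        "t_max_min": 1200.0,
        "interval_min": 10.0,
        "n_replicates": 3,
        "condition": "control",
    },
    "seed": 0,
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON config file and merge it over the defaults."""
    if path is None:
        return default_config()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return default_config()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return _merge(_DEFAULTS, raw)


def apply_overrides(config: dict, overrides: list[str]) -> dict:
    """Apply ``--set section.key=value`` overrides (values parsed as YAML)."""
    out = copy.deepcopy(config)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override must look like key=value, got {item!r}")
        dotted, raw_value = item.split("=", 1)
        value = yaml.safe_load(raw_value)
        node = out
        keys = dotted.split(".")
        for key in keys[:-1]:
            if key not in node or not isinstance(node[key], dict):
                raise ConfigError(f"unknown config section: {dotted}")
            node = node[key]
        if keys[-1] not in node:
            raise ConfigError(f"unknown config key: {dotted}")
        node[keys[-1]] = value
    return out


def resolve_config(config: dict, out_dir: str | Path) -> Path:
    """Write the fully resolved config next to the run outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    return path
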