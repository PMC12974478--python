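"""Versioned YAML serialization of every tunable constant.

The dump captures the channel definitions (baseline half-voltages, slopes,
exponents), integrator and calcium constants, sensor time constants,
regulation time constants / weight profiles / soft penalty, the reference
conductance densities, and the detection thresholds — enough to audit or
re-pin a run's configuration.  Loading returns the nested dict and verifies
the schema version.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from . import burst
from .channels import CHANNELS
from .ensemble import (REFERENCE_GMAX, REFERENCE_LEAK_G, SETTLE_DURATION_S,
                       CALIBRATION_WINDOW_S)
from .model import DEFAULT_CONSTANTS
from .regulation import (G_WEIGHT_PROFILE, H_WEIGHT_PROFILE, MAX_G_LOG_RATE,
                         SOFT_PENALTY_DEFAULT, TAU_G_DEFAULT,
                         TAU_HALF_DEFAULT)
from .sensing import SensorConfig

CONFIG_VERSION = 1

__all__ = ["CONFIG_VERSION", "current_config", "dump_config", "load_config"]


def current_config() -> dict:
    return {
        "version": CONFIG_VERSION,
        "channels": [
            {k: v for k, v in asdict(c).items() if v is not None}
            for c in CHANNELS
        ],
        "model_constants": asdict(DEFAULT_CONSTANTS),
        "sensor": asdict(SensorConfig()),
        "regulation": {
            "tau_g_s": TAU_G_DEFAULT,
            "tau_half_s": TAU_HALF_DEFAULT,
            "soft_penalty_per_s": SOFT_PENALTY_DEFAULT,
            "max_g_log_rate_per_s": MAX_G_LOG_RATE,
            "conductance_weight_profile": G_WEIGHT_PROFILE.tolist(),
            "halfshift_weight_profile": H_WEIGHT_PROFILE.tolist(),
        },
        "reference_model": {
            "gmax_uS": REFERENCE_GMAX.tolist(),
            "leak_g_uS": REFERENCE_LEAK_G,
            "settle_duration_s": SETTLE_DURATION_S,
            "calibration_window_s": CALIBRATION_WINDOW_S,
        },
        "detection": {
            "spike_threshold_mV": burst.SPIKE_THRESHOLD_MV,
            "min_peak_separation_s": burst.MIN_PEAK_SEPARATION_S,
            "min_spike_prominence_mV": burst.MIN_SPIKE_PROMINENCE_MV,
            "quiescent_isi_s": burst.QUIESCENT_ISI_S,
            "intra_burst_isi_s": burst.INTRA_BURST_ISI_S,
        },
    }


def dump_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(current_config(), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg.get("version") != CONFIG_VERSION:
        raise ValueError(
            f"unsupported config version {cfg.get('version')!r}")
    return cfg
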