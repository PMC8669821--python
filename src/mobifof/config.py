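"""Run configuration: defaults encode the protocol thresholds exactly.

All analysis thresholds (0.2 m/s speed gate, 15 s minimum bout, 6 h
valid-day rule, FES-I > 19 grouping, 45 deg / 0.5-10 s turn rule, |r| >
0.2 screen, 0.1/0.3/0.5 effect-size bands, 0.5/0.7 correlation bands) are
defaulted here and flagged when a config deviates from them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "mobifof_run"
    # cohort
    n_fof_pos: int = 9
    n_fof_neg: int = 17
    n_days: int = 14
    wear_hours: float | None = None   # None -> phenotype default (12 h)
    synthesize_signals: bool = False  # timeline fast path by default
    # group effects (None entries fall back to GroupEffectConfig defaults)
    group_effects: dict = field(default_factory=dict)
    # detection / retention thresholds (protocol defaults)
    speed_gate_ms: float = 0.2
    min_bout_s: float = 15.0
    valid_day_hours: float = 6.0
    fes_i_threshold: int = 19
    turn_min_angle_deg: float = 45.0
    turn_duration_range_s: tuple = (0.5, 10.0)
    effect_screen_r: float = 0.2
    effect_bands: tuple = (0.1, 0.3, 0.5)
    rho_bands: tuple = (0.5, 0.7)
    # classification
    tree_max_depth: int = 3
    tree_min_samples_leaf: int = 2
    selection_in_folds: bool = False  # honest variant of feature selection

    def tree_params(self) -> dict:
        return dict(criterion="gini", max_depth=self.tree_max_depth,
                    min_samples_leaf=self.tree_min_samples_leaf)


PROTOCOL_DEFAULTS = {
    "speed_gate_ms": 0.2, "min_bout_s": 15.0, "valid_day_hours": 6.0,
    "fes_i_threshold": 19, "turn_min_angle_deg": 45.0,
    "turn_duration_range_s": (0.5, 10.0), "effect_screen_r": 0.2,
    "effect_bands": (0.1, 0.3, 0.5), "rho_bands": (0.5, 0.7),
}

_RANGES = {
    "seed": (0, 2**31 - 1), "n_fof_pos": (1, None), "n_fof_neg": (1, None),
    "n_days": (1, None), "speed_gate_ms": (0.0, None), "min_bout_s": (0.0, None),
    "valid_day_hours": (0.0, None), "fes_i_threshold": (0, None),
    "turn_min_angle_deg": (0.0, None), "effect_screen_r": (0.0, 1.0),
    "tree_max_depth": (1, None), "tree_min_samples_leaf": (1, None),
}


class ConfigError(ValueError):
    pass


def validate_config(raw: dict | None) -> tuple:
    """Type/range-check a raw config mapping and inject defaults.

    Returns ``(RunConfig, warnings)`` where warnings list any field that
    deviates from the protocol default.  Unknown keys and out-of-range
    values are named individually.
    """
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("turn_duration_range_s", "effect_bands", "rho_bands"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    errors = []
    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key)
        if lo is not None and v < lo:
            errors.append(f"{key}={v} below minimum {lo}")
        if hi is not None and v > hi:
            errors.append(f"{key}={v} above maximum {hi}")
    if cfg.turn_duration_range_s[0] >= cfg.turn_duration_range_s[1]:
        errors.append("turn_duration_range_s must be increasing")
    if errors:
        raise ConfigError("; ".join(errors))
    notes = []
    for key, default in PROTOCOL_DEFAULTS.items():
        if getattr(cfg, key) != default:
            notes.append(f"{key}={getattr(cfg, key)} deviates from protocol default {default}")
    return cfg, notes


def load_config(path) -> tuple:
    raw = yaml.safe_load(Path(path).read_text()) if path else {}
    return validate_config(raw)


def dump_config(cfg: RunConfig) -> str:
    d = asdict(cfg)
    for key in ("turn_duration_range_s", "effect_bands", "rho_bands"):
        d[key] = list(d[key])
    return yaml.safe_dump(d, sort_keys=True)
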