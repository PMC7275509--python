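"""Pipeline configuration: one YAML file drives every command.

The schema is deliberately flat; unknown keys raise a schema error that
lists the offending keys, so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "paths", "preprocessing", "covariates", "model", "simulation",
         "inference", "summaries"},
    "paths": {"tracks", "out_dir", "fit", "decoded", "bursts"},
    "preprocessing": {"max_gap_hours", "min_weeks", "snow_threshold",
                      "speed_screen_v_max", "season"},
    "model": {"n_states", "n_starts", "selection_n_starts", "final_n_starts",
              "max_iter"},
    "simulation": {"season", "n_animals", "n_hours", "start_time", "seed",
                   "gap_start_prob", "gap_mean_length"},
    "inference": {"n_draws", "curve_grid_points"},
    "summaries": {"proximity_threshold_m", "latitude", "longitude"},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    paths: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    digest: str = ""
    source: str = ""

    def out_dir(self) -> Path:
        d = Path(self.paths.get("out_dir", "out"))
        d.mkdir(parents=True, exist_ok=True)
        return d

    def header_lines(self) -> list[str]:
        return [f"config_digest: {self.digest}", f"seed: {self.seed}"]


def _validate(raw: dict):
    bad = []
    for key in raw:
        if key not in _SCHEMA[""]:
            bad.append(key)
    for section, allowed in _SCHEMA.items():
        if not section or section not in raw:
            continue
        sec = raw[section]
        if not isinstance(sec, dict):
            bad.append(section)
            continue
        if section == "covariates":
            continue
        for key in sec:
            if key not in allowed:
                bad.append(f"{section}.{key}")
    if bad:
        raise ConfigError(f"unknown or malformed config keys: {sorted(bad)}")


def load_config(path, seed_override: int | None = None) -> PipelineConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _validate(raw)
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        paths=raw.get("paths", {}) or {},
        preprocessing=raw.get("preprocessing", {}) or {},
        covariates=raw.get("covariates", {}) or {},
        model=raw.get("model", {}) or {},
        simulation=raw.get("simulation", {}) or {},
        inference=raw.get("inference", {}) or {},
        summaries=raw.get("summaries", {}) or {},
        digest=hashlib.sha256(text.encode()).hexdigest()[:16],
        source=str(path),
    )
    if seed_override is not None:
        cfg.seed = int(seed_override)
    return cfg
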