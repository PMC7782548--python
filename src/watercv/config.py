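"""Strict YAML run configuration.

A single config file drives every pipeline stage; one top-level ``seed``
controls all stochastic stages. Unknown keys anywhere are rejected, and the
SHA-256 hash of the canonical config text is embedded in every artifact a
run writes, so results can always be traced back to the exact configuration.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

_SECTION_KEYS: dict[str, set[str]] = {
    "gen_data": {"kind", "n_per_class", "dim", "mean_B", "mean_U", "cov_scale",
                 "n_frames", "n_waters", "state", "out"},
    "descriptors": {"frames", "out", "ligand_label", "axis", "switching"},
    "train_cv": {"table", "replicas", "hidden", "activation", "epochs", "lr",
                 "lambda_reg", "out_prefix"},
    "run_opes": {"landscape", "cvs", "model", "n_steps", "friction", "dt",
                 "stride", "gamma", "barrier_kt", "start", "z_wall", "out"},
    "fes": {"colvar", "cv", "bias_column", "bins", "range", "n_blocks", "out"},
    "deltag": {"fes", "bound_window", "unbound_window", "r_cyl", "temperature",
               "out"},
    "metrics": {"table", "builtin", "calc_column", "exp_column", "out"},
    "rank": {"models", "states", "normalize", "out"},
}
_AXIS_KEYS = {"origin", "direction", "n_points", "spacing", "z_start"}
_SWITCH_KEYS = {"r0", "n_exp", "m_exp"}
_LANDSCAPE_KEYS = {"epsilon_kt", "kappa_kt", "q_bound", "q_unbound", "alpha",
                   "temperature"}
_TOP_KEYS = {"seed"} | set(_SECTION_KEYS)


class ConfigError(ValueError):
    pass


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown config key(s) in {context}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> tuple[dict, str]:
    """Parse and validate a config file; returns (config, sha256 hash)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    for section, keys in _SECTION_KEYS.items():
        if section in cfg and isinstance(cfg[section], dict):
            _check_keys(cfg[section], keys, section)
    if "descriptors" in cfg:
        sec = cfg["descriptors"]
        if isinstance(sec.get("axis"), dict):
            _check_keys(sec["axis"], _AXIS_KEYS, "descriptors.axis")
        if isinstance(sec.get("switching"), dict):
            _check_keys(sec["switching"], _SWITCH_KEYS, "descriptors.switching")
    if "run_opes" in cfg and isinstance(cfg["run_opes"].get("landscape"), dict):
        _check_keys(cfg["run_opes"]["landscape"], _LANDSCAPE_KEYS,
                    "run_opes.landscape")
    digest = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return cfg, digest
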