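"""Configuration files: YAML (or JSON) round-trip for SimulationConfig.

An empty file yields the full published defaults; unknown keys raise, so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .core import CoefficientSet
from .engine import Policy
from .memory import MemoryParams
from .simulate import SimulationConfig

__all__ = ["load_config", "save_config"]

_TOP_KEYS = {
    "initial_time", "final_time", "time_step", "month_length", "seed",
    "memory", "policy", "coefficients",
}
_MEMORY_KEYS = {"S", "Z", "cap", "forget_after"}
_POLICY_KEYS = {"kind", "month_length", "threshold", "absorption", "passive_statistic"}


def _check_keys(given: dict, allowed: set[str], section: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown {section} key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def load_config(path) -> SimulationConfig:
    """Parse a YAML/JSON config file into a validated SimulationConfig."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_KEYS, "config")

    kwargs = {k: raw[k] for k in ("initial_time", "final_time", "time_step", "month_length", "seed") if k in raw}
    if "memory" in raw:
        mem = raw["memory"] or {}
        _check_keys(mem, _MEMORY_KEYS, "memory")
        try:
            kwargs["memory"] = MemoryParams(**mem)
        except ValueError as exc:
            raise ValueError(f"memory: {exc}") from exc
    if "policy" in raw:
        pol = raw["policy"] or {}
        _check_keys(pol, _POLICY_KEYS, "policy")
        try:
            kwargs["policy"] = Policy(**pol)
        except ValueError as exc:
            raise ValueError(f"policy: {exc}") from exc
    if "coefficients" in raw:
        coeffs = raw["coefficients"]
        if not isinstance(coeffs, dict):
            raise ValueError("coefficients must map path labels to numbers")
        kwargs["coefficients"] = CoefficientSet({str(k): float(v) for k, v in coeffs.items()})
    return SimulationConfig(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    """Write a SimulationConfig as YAML (or JSON for a .json path)."""
    path = Path(path)
    doc = {
        "initial_time": config.initial_time,
        "final_time": config.final_time,
        "time_step": config.time_step,
        "month_length": config.month_length,
        "seed": config.seed,
        "memory": asdict(config.memory),
        "policy": asdict(config.policy),
        "coefficients": dict(config.coefficients.paths),
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
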