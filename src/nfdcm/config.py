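"""Configuration loading with unit conversion at the boundary.

Configuration files (YAML or JSON) use the field's printed units —
rate constants in 1/ms, kernel decay in 1/mm, conduction velocity in m/s,
patch radius in mm — and are converted exactly once, here, to the internal
system (SI seconds, normalized patch radius 1).  An empty or absent
``model`` section yields the standard prior expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import (ModelParams, ObservationParams, SpatialParams,
                         SynapticParams)


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending field."""


#: configurable model keys, in the units a config file uses
_MODEL_KEYS = {
    "m_e": "mV", "m_i": "mV",
    "kappa_e": "1/ms", "kappa_i": "1/ms",
    "alpha_13": "", "alpha_23": "", "alpha_31": "", "alpha_32": "",
    "c": "1/mm", "s": "m/s", "ell_mm": "mm",
    "r": "1/mV", "eta": "mV",
    "phi_1": "a.u.", "phi_2": "normalized length^2",
    "alpha_U": "", "beta_U": "", "alpha_N": "", "beta_N": "",
    "n_modes": "",
}

_MODEL_DEFAULTS = {
    "m_e": 8.0, "m_i": 32.0,
    "kappa_e": 0.25, "kappa_i": 1.0 / 28.0,
    "alpha_13": 2000.0, "alpha_23": 8000.0,
    "alpha_31": 2000.0, "alpha_32": 1000.0,
    "c": 0.32, "s": 3.0, "ell_mm": 50.0,
    "r": 0.54, "eta": 0.0,
    "phi_1": 1.0, "phi_2": 0.01,
    "alpha_U": 1.0, "beta_U": 1.0, "alpha_N": 1e-7, "beta_N": 1e-7,
    "n_modes": 32,
}

_SETTINGS_DEFAULTS = {
    "freq_min_hz": 1.0,
    "freq_max_hz": 60.0,
    "freq_step_hz": 0.5,
    "prior_precision": 16.0,
    "seed": 0,
}

_POSITIVE = {"m_e", "m_i", "kappa_e", "kappa_i", "c", "s", "ell_mm", "r",
             "phi_2", "n_modes"}
_NONNEGATIVE = {"alpha_13", "alpha_23", "alpha_31", "alpha_32",
                "alpha_U", "beta_U", "alpha_N", "beta_N"}


@dataclass
class Config:
    """Validated configuration: internal-unit model parameters plus
    inversion/experiment settings."""

    params: ModelParams
    settings: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def freqs_hz(self):
        import numpy as np
        s = self.settings
        return np.arange(s["freq_min_hz"], s["freq_max_hz"] + s["freq_step_hz"] / 2,
                         s["freq_step_hz"])


def _check_section(section: dict, defaults: dict, name: str) -> dict:
    unknown = set(section) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}': {', '.join(sorted(unknown))}")
    merged = {**defaults, **section}
    return merged


def build_params(model: dict | None = None) -> ModelParams:
    """Construct internal-unit :class:`ModelParams` from printed-unit
    values (missing keys default to the standard priors)."""
    m = _check_section(model or {}, _MODEL_DEFAULTS, "model")
    for key in _POSITIVE:
        if not m[key] > 0:
            raise ConfigError(f"model.{key} must be strictly positive")
    for key in _NONNEGATIVE:
        if m[key] < 0:
            raise ConfigError(f"model.{key} must be nonnegative")
    # unit conversions, once: 1/ms -> 1/s; decay per normalized radius;
    # transit time = radius / velocity (mm / (m/s) / 1000 -> s)
    c_norm = m["c"] * m["ell_mm"]
    upsilon = m["ell_mm"] / 1000.0 / m["s"]
    return ModelParams(
        synaptic=SynapticParams(
            m_e=m["m_e"], m_i=m["m_i"],
            kappa_e=m["kappa_e"] * 1000.0, kappa_i=m["kappa_i"] * 1000.0,
            r=m["r"], eta=m["eta"]),
        spatial=SpatialParams(
            alpha_13=m["alpha_13"], alpha_23=m["alpha_23"],
            alpha_31=m["alpha_31"], alpha_32=m["alpha_32"],
            c_13=c_norm, c_23=c_norm, c_31=c_norm,
            upsilon=upsilon),
        observation=ObservationParams(
            phi_1=m["phi_1"], phi_2=m["phi_2"],
            alpha_U=m["alpha_U"], beta_U=m["beta_U"],
            alpha_N=m["alpha_N"], beta_N=m["beta_N"]),
        n_modes=int(m["n_modes"]))


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML/JSON configuration file.

    ``None`` (or an empty file) gives the full default configuration.
    Raises :class:`ConfigError` naming the offending field on unknown
    keys or out-of-range values.
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded
    unknown = set(raw) - {"model", "settings"}
    if unknown:
        raise ConfigError(
            f"unknown top-level section(s): {', '.join(sorted(unknown))}")
    params = build_params(raw.get("model"))
    settings = _check_section(raw.get("settings") or {},
                              _SETTINGS_DEFAULTS, "settings")
    if settings["freq_min_hz"] <= 0:
        raise ConfigError("settings.freq_min_hz must be positive")
    if settings["freq_max_hz"] <= settings["freq_min_hz"]:
        raise ConfigError("settings.freq_max_hz must exceed freq_min_hz")
    if settings["prior_precision"] <= 0:
        raise ConfigError("settings.prior_precision must be positive")
    return Config(params=params, settings=settings, raw=raw)
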