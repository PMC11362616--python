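"""Declarative run configuration for end-to-end pipeline runs.

One YAML file describes every stage; values are validated up front so a bad
config fails before any compute.  Units follow the conventions used
throughout: lengths in nm, protocol times in µs, rates in 1/frame, powers in
mW, pulse durations in fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Parameters for a full simulate→fit→scaling→section→protect→measure run."""

    seed: int = 0
    output_dir: str = "results"
    # simulate
    phantom_width: int = 96
    phantom_height: int = 96
    n_filaments: int = 12
    pixel_size: float = 40.0  # nm
    labels_per_length: float = 0.5  # 1/nm
    activation_power: float = 4.0  # mW
    activation_dwell: float = 100.0  # µs
    readout_dwell: float = 30.0  # µs
    n_cycles: int = 39
    excitation_power: float = 8.0  # mW
    read_noise_background: float = 0.5  # counts/pixel
    # kinetics ground truth for simulation
    k_act: float = 0.5  # 1/frame
    k_bl: float = 0.1  # 1/frame
    photons_per_fluorophore: float = 25.0
    # power scan for the exponent fit
    powers_mw: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
    # optics
    rayleigh_range: float = 350.0  # nm
    chromatic_offset: float = 0.0  # nm
    layer_depths_um: tuple = (6.0, 46.0)
    volume_thickness_um: float = 52.0
    # protection
    n_sted_scans: int = 10
    bleach_fraction: float = 0.1
    layer_spacing_nm: float = 600.0
    # measurement
    k_sigma: float = 3.0

    def validate(self) -> None:
        positive = [
            "pixel_size", "activation_dwell", "readout_dwell", "excitation_power",
            "photons_per_fluorophore", "rayleigh_range", "volume_thickness_um",
            "layer_spacing_nm",
        ]
        non_negative = [
            "activation_power", "read_noise_background", "k_act", "k_bl",
            "bleach_fraction", "k_sigma", "n_sted_scans",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.phantom_width < 1 or self.phantom_height < 1:
            raise ConfigError("phantom dimensions must be >= 1")
        if self.bleach_fraction > 1:
            raise ConfigError("bleach_fraction must be <= 1")
        if any(p <= 0 for p in self.powers_mw):
            raise ConfigError("powers_mw must be strictly positive")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML (if given) with keyword overrides.

    Unknown keys are rejected rather than ignored.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("powers_mw", "layer_depths_um"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
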