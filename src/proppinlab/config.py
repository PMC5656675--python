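"""Flat run configuration shared by all pipeline stages.

One YAML file configures chemistry constants, kinetics defaults, matching
tolerance and seeds.  Unknown keys are rejected by name; precedence is
CLI flag > config file > built-in default, and every run can echo its
resolved configuration next to its outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # chemistry
    lipid_name: str = "DOPE"
    lipid_mass_da: float = 743.36
    linker_name: str = "BS3"
    linker_mass_da: float = 140.074
    tol_ppm: float = 10.0
    max_missed: int = 1
    min_peptide_len: int = 4
    max_peptide_len: int = 40
    # kinetics
    accessible_fraction: float = 0.6
    n_phases: int = 1
    duration_s: float = 10.0
    n_points: int = 500
    noise_sd: float = 0.01
    protein_uM: float = 0.25
    k_on: float = 0.85
    k_off: float = 0.66
    k_oli: float = 0.0
    k_dis: float = 0.0
    concentrations_mM: tuple = (0.1, 0.225, 0.35, 0.475, 0.6)
    replicates: int = 5
    # native MS
    monomer_mass_da: float = 60000.0
    n_max: int = 4
    charge_min: int = 10
    charge_max: int = 20
    nativems_tol_ppm: float = 50.0
    # run
    seed: int = 0
    output_dir: str = "proppinlab_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        if "concentrations_mM" in raw:
            raw["concentrations_mM"] = tuple(raw["concentrations_mM"])
        return cls(**raw)

    def override(self, **kw) -> "RunConfig":
        """Apply non-None keyword overrides (CLI flags beat the file)."""
        data = asdict(self)
        for key, value in kw.items():
            if value is None:
                continue
            if key not in data:
                raise ValueError(f"unknown config key {key!r}")
            data[key] = value
        data["concentrations_mM"] = tuple(data["concentrations_mM"])
        return RunConfig(**data)

    def write_resolved(self, path) -> None:
        data = asdict(self)
        data["concentrations_mM"] = list(data["concentrations_mM"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
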