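"""YAML configuration for model constants and filament classes.

Keys carry explicit units in their names so a config file is unambiguous::

    thermal_energy_pN_nm: 4.28
    load_force_pN: 10.0
    packing_fraction: 0.9069
    boundary_factor: 2.4674
    filaments:
      actin:   {radius_nm: 3.5, persistence_length_nm: 17700.0}
      tubulin: {radius_nm: 14.0, persistence_length_nm: 5.2e6}
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .exceptions import ConfigurationError
from .mechanics import ACTIN, TUBULIN, FilamentClass, ModelConstants

__all__ = ["load_model_config", "dump_model_config", "constants_snapshot"]


def load_model_config(path) -> tuple[ModelConstants, FilamentClass, FilamentClass]:
    """Read (constants, actin, tubulin) from a YAML file; absent keys default."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    constants = ModelConstants(
        thermal_energy=raw.get("thermal_energy_pN_nm", ModelConstants.thermal_energy),
        load_force=raw.get("load_force_pN", ModelConstants.load_force),
        packing_fraction=raw.get("packing_fraction", ModelConstants.packing_fraction),
        boundary_factor=raw.get("boundary_factor", ModelConstants.boundary_factor),
    )
    filaments = raw.get("filaments", {})

    def fil(name: str, default: FilamentClass) -> FilamentClass:
        spec = filaments.get(name, {})
        return FilamentClass(
            name=name,
            radius=spec.get("radius_nm", default.radius),
            persistence_length=spec.get("persistence_length_nm", default.persistence_length),
        )

    return constants, fil("actin", ACTIN), fil("tubulin", TUBULIN)


def constants_snapshot(
    constants: ModelConstants, actin: FilamentClass, tubulin: FilamentClass
) -> dict:
    """JSON-serializable snapshot of the constants actually used."""
    return {
        "thermal_energy_pN_nm": constants.thermal_energy,
        "load_force_pN": constants.load_force,
        "packing_fraction": constants.packing_fraction,
        "boundary_factor": constants.boundary_factor,
        "filaments": {
            f.name: {"radius_nm": f.radius, "persistence_length_nm": f.persistence_length}
            for f in (actin, tubulin)
        },
    }


def dump_model_config(
    path, constants: ModelConstants, actin: FilamentClass, tubulin: FilamentClass
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(constants_snapshot(constants, actin, tubulin), fh, sort_keys=False)
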