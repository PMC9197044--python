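"""System-definition files.

A radical-pair system can be described in a small YAML document::

    field_uT: 55.26
    gamma_e: 1.76085963e11   # optional override
    nuclei:
      - {label: H5, spin: "1/2", hfcc_uT: -802.9, electron: A}
      - {label: 17O, spin: "5/2", hfcc_uT: 1886.8, electron: B}

Spins may be written as fraction strings ("5/2") or numbers.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .constants import GAMMA_E
from .spin import Nucleus, RadicalPairSystem

__all__ = ["load_system", "dump_system"]


def _system_from_mapping(data: dict) -> RadicalPairSystem:
    if not isinstance(data, dict):
        raise ValueError("system definition must be a mapping")
    nuclei = tuple(
        Nucleus(
            label=str(entry["label"]),
            spin=entry["spin"],
            hfcc_ut=float(entry["hfcc_uT"]),
            electron=entry["electron"],
        )
        for entry in data.get("nuclei", [])
    )
    return RadicalPairSystem(
        nuclei=nuclei,
        field_ut=float(data.get("field_uT", 0.0)),
        gamma_e=float(data.get("gamma_e", GAMMA_E)),
    )


def load_system(path: str | Path) -> RadicalPairSystem:
    """Read a YAML system definition from disk."""
    with open(path) as fh:
        return _system_from_mapping(yaml.safe_load(fh))


def dump_system(system: RadicalPairSystem, path: str | Path) -> None:
    """Write a system definition in the schema :func:`load_system` reads."""
    data = {
        "field_uT": system.field_ut,
        "gamma_e": system.gamma_e,
        "nuclei": [
            {
                "label": n.label,
                "spin": n.spin,
                "hfcc_uT": n.hfcc_ut,
                "electron": n.electron,
            }
            for n in system.nuclei
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
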