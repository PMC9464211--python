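"""Configuration files, provenance, and deterministic run manifests.

A config file is a small YAML document with two optional blocks::

    patient:            # flat registry overrides (typo-safe)
      lps: 8.0
    protocol:           # session protocol fields
      duration: 240.0
      priming: discarded

Unknown keys in either block are rejected exhaustively.  The full reference
registry, with units and provenance notes per key, can be emitted with
:func:`reference_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .dialysis import SessionProtocol
from .params import PARAMETER_DEFS, ParameterRegistry, VirtualPatient

_PROTOCOL_FIELDS = {f.name for f in dataclasses.fields(SessionProtocol)}


def load_config(path: str | Path) -> tuple[VirtualPatient, SessionProtocol]:
    """Load a config file into a resolved patient and protocol.

    Every parameter is resolved as default-plus-override; schema violations
    (unknown keys, invalid values) are reported exhaustively by key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    unknown_blocks = sorted(set(raw) - {"patient", "protocol"})
    if unknown_blocks:
        raise KeyError(f"{path}: unknown config blocks {unknown_blocks} "
                       "(expected 'patient' and/or 'protocol')")
    registry = ParameterRegistry(raw.get("patient") or {})
    proto_raw = raw.get("protocol") or {}
    unknown = sorted(set(proto_raw) - _PROTOCOL_FIELDS)
    if unknown:
        raise KeyError(f"{path}: unknown protocol keys {unknown}")
    protocol = SessionProtocol(**proto_raw)
    return VirtualPatient(registry), protocol


def reference_config() -> str:
    """Full default registry as YAML with units and provenance comments."""
    lines = ["# refillsim reference parameter registry",
             "# provenance: 'literature' = published value, "
             "'default' = package reference value",
             "patient:"]
    for key, d in PARAMETER_DEFS.items():
        lines.append(f"  {key}: {d.default}  # [{d.units}] ({d.provenance}) "
                     f"{d.description}")
    lines.append("protocol:")
    proto = SessionProtocol()
    for f in dataclasses.fields(SessionProtocol):
        value = getattr(proto, f.name)
        lines.append(f"  {f.name}: {'null' if value is None else value}")
    return "\n".join(lines) + "\n"


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one run: inputs, code version, outputs."""

    scenario: str
    patient: dict
    protocol: dict
    seed: int | None
    solver_stats: dict
    code_version: str = __version__
    output_hashes: dict = dataclasses.field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.output_hashes[Path(path).name] = digest

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def rebuild_inputs(self) -> tuple[VirtualPatient, SessionProtocol]:
        """Reconstruct the exact patient and protocol this run used."""
        return (VirtualPatient(ParameterRegistry(self.patient)),
                SessionProtocol(**self.protocol))


def manifest_for(scenario: str, registry: ParameterRegistry,
                 protocol: SessionProtocol, solver_stats: dict,
                 seed: int | None = None) -> RunManifest:
    return RunManifest(scenario=scenario, patient=registry.to_dict(),
                       protocol=dataclasses.asdict(protocol), seed=seed,
                       solver_stats=solver_stats)
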