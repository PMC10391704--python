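"""Run configuration: one structured document drives an end-to-end run.

A :class:`RunConfig` bundles the acquisition settings, suspension medium,
population concentrations, dose grid, dose model, detection and gating
parameters, output directory and the single integer seed that governs every
stochastic draw of the run.  Configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dielectric import Medium
from .events import DetectionParams
from .calibrate import GateConfig
from .exceptions import InvalidArgumentError
from .synth import DEFAULT_DOSE_GRID, PC_DOSE_BACTERIA, AcquisitionConfig, DoseModel


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full simulate-process-fit run."""

    seed: int = 0
    output_dir: str = "ampcyt_run"
    duration_s: float = 5.0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    medium: Medium = field(default_factory=lambda: Medium(1.3, 80.0))
    dose_model: DoseModel = field(default_factory=DoseModel)
    detection: DetectionParams = field(default_factory=DetectionParams)
    gate: GateConfig = field(default_factory=GateConfig)
    max_residual: float = 0.3
    min_beads: int = 10
    bead_concentration: float = 2e5
    bacteria_concentration: float = 4e5
    rbc_concentration: float = 3e5
    bacteria_doses: tuple[float, ...] = DEFAULT_DOSE_GRID
    bacteria_pc_dose: float = PC_DOSE_BACTERIA
    rbc_doses: tuple[float, ...] = DEFAULT_DOSE_GRID
    mixed_doses: tuple[float, ...] = (0.0, 0.35)
    run_bacteria: bool = True
    run_rbc: bool = True
    run_mixed: bool = True
    cfu_nc: int = 200

    def __post_init__(self) -> None:
        problems = []
        if not isinstance(self.seed, int):
            problems.append("seed: must be an integer")
        if self.duration_s <= 0:
            problems.append("duration_s: must be > 0")
        if self.max_residual <= 0:
            problems.append("max_residual: must be > 0")
        if self.min_beads < 1:
            problems.append("min_beads: must be >= 1")
        for name in ("bead_concentration", "bacteria_concentration", "rbc_concentration"):
            if getattr(self, name) < 0:
                problems.append(f"{name}: must be >= 0")
        for name in ("bacteria_doses", "rbc_doses", "mixed_doses"):
            if any(d < 0 for d in getattr(self, name)):
                problems.append(f"{name}: doses must be >= 0")
        if self.cfu_nc <= 0:
            problems.append("cfu_nc: must be > 0")
        if problems:
            raise InvalidArgumentError("invalid config: " + "; ".join(problems))

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        """Build a config from a (possibly partial) nested mapping.

        Unknown keys and invalid values are reported together, each prefixed
        with the offending field path.
        """
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        problems: list[str] = []
        nested = {
            "acquisition": AcquisitionConfig,
            "medium": Medium,
            "dose_model": DoseModel,
            "detection": DetectionParams,
            "gate": GateConfig,
        }
        valid_names = {f.name for f in fields(cls)}
        for key, value in raw.items():
            if key not in valid_names:
                problems.append(f"{key}: unknown field")
                continue
            try:
                if key in nested:
                    kwargs[key] = _build_nested(nested[key], value, key, problems)
                elif key in ("bacteria_doses", "rbc_doses", "mixed_doses"):
                    kwargs[key] = tuple(float(v) for v in value)
                else:
                    kwargs[key] = value
            except (TypeError, ValueError) as exc:
                problems.append(f"{key}: {exc}")
        try:
            cfg = cls(**kwargs)
        except InvalidArgumentError as exc:
            problems.append(str(exc).removeprefix("invalid config: "))
            cfg = None
        except TypeError as exc:
            problems.append(str(exc))
            cfg = None
        if problems:
            raise InvalidArgumentError("invalid config: " + "; ".join(problems))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return convert(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build_nested(cls: type, value: Any, key: str, problems: list[str]) -> Any:
    if isinstance(value, cls):
        return value
    if not isinstance(value, Mapping):
        problems.append(f"{key}: expected a mapping")
        return cls()
    value = dict(value)
    if "frequencies" in value:
        value["frequencies"] = tuple(float(f) for f in value["frequencies"])
    valid = {f.name for f in fields(cls)}
    unknown = set(value) - valid
    for u in sorted(unknown):
        problems.append(f"{key}.{u}: unknown field")
        value.pop(u)
    try:
        return cls(**value)
    except (TypeError, ValueError) as exc:
        problems.append(f"{key}: {exc}")
        return cls()
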