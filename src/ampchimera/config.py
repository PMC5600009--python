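"""Pipeline configuration: a plain TOML file mapping onto the stage
parameter dataclasses.  Unknown keys are rejected so typos fail loudly."""
from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields

from .align import ScoringScheme
from .signal import SignalModel
from .synth import SimParams


@dataclass
class PipelineConfig:
    out_dir: str = "ampchimera_out"
    seed: int = 1
    # input paths; when reads is None the simulate stage provides them
    reads: str | None = None
    panel: str | None = None
    barcode_map: str | None = None
    traces: str | None = None
    sim: SimParams = field(default_factory=SimParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    signal_model: SignalModel = field(default_factory=SignalModel)
    max_gap: int = 50
    min_count: int = 5
    max_signal_traces: int = 200  # cap on traces simulated/segmented per run


_SECTION_TYPES = {"sim": SimParams, "scoring": ScoringScheme, "signal_model": SignalModel}
_TOP_KEYS = {"out_dir", "seed", "reads", "panel", "barcode_map", "traces",
             "max_gap", "min_count", "max_signal_traces"}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if f.name == "hairpin_levels":
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - _TOP_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    cfg = PipelineConfig()
    for key in _TOP_KEYS:
        if key in data:
            setattr(cfg, key, data[key])
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            if not isinstance(data[section], dict):
                raise ValueError(f"[{section}] must be a table")
            setattr(cfg, section, _build_section(cls, data[section], section))
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def save_config(cfg: PipelineConfig, path) -> None:
    lines = []
    for key in sorted(_TOP_KEYS):
        v = getattr(cfg, key)
        if v is not None:
            lines.append(f"{key} = {_toml_value(v)}")
    for section, cls in _SECTION_TYPES.items():
        obj = getattr(cfg, section)
        lines.append(f"\n[{section}]")
        subtables = []
        for f in dataclasses.fields(cls):
            v = getattr(obj, f.name)
            if isinstance(v, dict):
                subtables.append((f.name, v))
            else:
                lines.append(f"{f.name} = {_toml_value(v)}")
        for name, table in subtables:
            lines.append(f"\n[{section}.{name}]")
            for k, v in table.items():
                lines.append(f'"{k}" = {_toml_value(v)}')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
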