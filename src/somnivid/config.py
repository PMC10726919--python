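"""Declarative pipeline configuration and run manifests.

A single YAML document holds one section per subcommand (``vibe``,
``scoring``, ``agreement``, ``simulate``, ``video``) whose keys map 1:1 onto
the corresponding parameter dataclasses. Every key is validated against the
dataclass (unknown keys are rejected with the full list of offenders) before
any work starts; CLI flags override file values. Each run writes a manifest
JSON recording the package version, resolved parameters, seed, and input
checksums so artifacts are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .scoring import ScoringParams
from .synthetic import SimSpec, TraceNoiseSpec, VideoSpec
from .vibe import ViBeParams

__all__ = ["PipelineConfig", "load_config", "write_manifest", "sha256_file"]

_SECTION_TYPES = {
    "vibe": ViBeParams,
    "scoring": ScoringParams,
    "simulate": SimSpec,
    "trace_noise": TraceNoiseSpec,
    "video": VideoSpec,
}
_SCALAR_KEYS = {"seed", "out_dir", "log_level"}


@dataclasses.dataclass
class PipelineConfig:
    """Validated parameter blocks for every pipeline stage."""

    vibe: ViBeParams = dataclasses.field(default_factory=ViBeParams)
    scoring: ScoringParams = dataclasses.field(default_factory=ScoringParams)
    simulate: SimSpec = dataclasses.field(default_factory=SimSpec)
    trace_noise: TraceNoiseSpec = dataclasses.field(default_factory=TraceNoiseSpec)
    video: VideoSpec = dataclasses.field(default_factory=VideoSpec)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            **{k: dataclasses.asdict(getattr(self, k)) for k in _SECTION_TYPES},
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }


def _build_section(cls, data: Mapping[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section {section!r}: {unknown}; "
            f"allowed: {sorted(allowed)}"
        )
    # tuple-typed fields arrive from YAML as lists
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Load and validate a YAML config; ``overrides`` maps section.key -> value."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping of sections")
        raw = dict(loaded)
    unknown = sorted(set(raw) - set(_SECTION_TYPES) - _SCALAR_KEYS)
    if unknown:
        raise ValueError(
            f"unknown config section(s): {unknown}; "
            f"allowed: {sorted(set(_SECTION_TYPES) | _SCALAR_KEYS)}"
        )
    sections: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        data = dict(raw.get(name) or {})
        if overrides:
            prefix = name + "."
            for key, val in overrides.items():
                if key.startswith(prefix) and val is not None:
                    data[key[len(prefix):]] = val
        sections[name] = _build_section(cls, data, name)
    cfg = PipelineConfig(
        **sections,
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if overrides:
        for key in ("seed", "out_dir", "log_level"):
            if overrides.get(key) is not None:
                setattr(cfg, key, overrides[key])
    return cfg


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    params: Mapping[str, Any],
    seed: int,
    inputs: Mapping[str, str | Path] | None = None,
    outputs: Mapping[str, str | Path] | None = None,
) -> None:
    """Write a reproducibility manifest next to a run's artifacts."""
    from . import __version__

    manifest = {
        "tool": "somnivid",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": dict(params),
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": {name: str(p) for name, p in (outputs or {}).items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
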