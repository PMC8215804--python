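"""Run configuration and comparison specifications."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ComparisonSpec:
    """One differential-expression contrast: case groups versus reference groups.

    ``case`` and ``reference`` are sample-group labels; the reference may pool
    several groups (e.g. foetal and adult normal cerebellum).
    """

    name: str
    case: tuple[str, ...]
    reference: tuple[str, ...]

    def __post_init__(self):
        case = tuple(self.case) if not isinstance(self.case, tuple) else self.case
        ref = tuple(self.reference) if not isinstance(self.reference, tuple) else self.reference
        object.__setattr__(self, "case", case)
        object.__setattr__(self, "reference", ref)
        if not self.name:
            raise ConfigError("comparison name must be non-empty")
        if not case or not ref:
            raise ConfigError(f"comparison '{self.name}': case and reference must be non-empty")
        if set(case) & set(ref):
            raise ConfigError(f"comparison '{self.name}': case and reference groups overlap")


@dataclass
class RunConfig:
    """Full-pipeline configuration (paths, contrasts, thresholds, output)."""

    expression: Path
    annotation: Path
    probe_map: Path
    orthologs: Path
    ppi: Path
    drugs: Path
    cis_genes: Path
    out_dir: Path
    comparisons: list[ComparisonSpec] | None = None
    alpha: float = 0.05
    min_lfc: float = 0.0
    normalize_steps: tuple[str, ...] = ("zscore_rows", "center_scale")
    include_neighbor_edges: bool = False
    induced_expansion: bool = True
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("expression", "annotation", "probe_map", "orthologs",
                     "ppi", "drugs", "cis_genes", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")

    _INPUT_FIELDS = ("expression", "annotation", "probe_map", "orthologs",
                     "ppi", "drugs", "cis_genes")

    def input_paths(self) -> dict[str, Path]:
        return {name: getattr(self, name) for name in self._INPUT_FIELDS}

    def validate_paths(self) -> None:
        for name, path in self.input_paths().items():
            if not path.exists():
                raise FileNotFoundError(f"input '{name}' not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        comparisons = None
        if raw.get("comparisons"):
            comparisons = [
                ComparisonSpec(
                    name=c["name"],
                    case=tuple(_as_list(c["case"])),
                    reference=tuple(_as_list(c["reference"])),
                )
                for c in raw.pop("comparisons")
            ]
        else:
            raw.pop("comparisons", None)
        kwargs = {}
        for name in cls._INPUT_FIELDS + ("out_dir",):
            if name not in raw:
                raise ConfigError(f"run config missing required key '{name}'")
            kwargs[name] = _resolve(base, raw.pop(name))
        for key in ("alpha", "min_lfc", "include_neighbor_edges",
                    "induced_expansion", "rng_seed", "log_level"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "normalize_steps" in raw:
            kwargs["normalize_steps"] = tuple(_as_list(raw.pop("normalize_steps")))
        if raw:
            raise ConfigError(f"unknown run-config keys: {sorted(raw)}")
        return cls(comparisons=comparisons, **kwargs)


def _as_list(value) -> Sequence[str]:
    if isinstance(value, str):
        return [v.strip() for v in value.split(",") if v.strip()]
    return list(value)


def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p
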