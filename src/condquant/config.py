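"""Run configuration: schema-validated, serializable, reproducible.

A :class:`RunConfig` fully specifies one pipeline stage run; re-executing
a saved config reproduces the outputs bit-identically for deterministic
stages. Unknown keys are rejected with field-level messages (pydantic
``extra="forbid"``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

from pydantic import BaseModel, Field, ValidationError

STAGES = ("simulate", "quantify", "frap", "cellcycle", "gtpase", "report")


class QuantifyParams(BaseModel, extra="forbid"):
    """Segmentation and screening parameters of the image stage."""

    smooth_sigma_px: float = Field(default=1.0, ge=0)
    k_seg: float = Field(default=3.0, ge=0)
    split_touching: bool = False
    min_area_px: int = Field(default=9, ge=1)
    k: float = Field(default=3.0, ge=0)
    mode: Literal["separation", "enrichment", "cv", "network"] = "separation"
    bleedthrough_raw_enrichment: float = 0.0
    condensate_channel: int = 0
    client_channel: int = 1


class FrapParams(BaseModel, extra="forbid"):
    mode: Literal["in_vivo", "in_vitro"] = "in_vivo"


class GtpaseParams(BaseModel, extra="forbid"):
    window_min: float | None = Field(default=20.0, gt=0)
    epsilon: float = Field(default=6220.0, gt=0)
    light_path_cm: float = Field(default=0.248, gt=0)


class RunConfig(BaseModel, extra="forbid"):
    """One stage run: stage name, paths, parameters, seed, version stamp."""

    stage: Literal["simulate", "quantify", "frap", "cellcycle", "gtpase", "report"]
    inputs: list[str] = Field(default_factory=list)
    out: str = "out"
    seed: int = 0
    quantify: QuantifyParams = Field(default_factory=QuantifyParams)
    frap: FrapParams = Field(default_factory=FrapParams)
    gtpase: GtpaseParams = Field(default_factory=GtpaseParams)
    simulate: dict[str, Any] = Field(default_factory=dict)
    version: str = ""

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=2))
        return path


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def load_and_validate_config(path: str | Path) -> RunConfig:
    """Load a JSON config, fill defaults, reject unknown keys.

    Error messages name the offending fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = json.loads(path.read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        fields = "; ".join(
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {fields}") from exc
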