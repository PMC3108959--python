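"""Run configuration: schema, validation, defaulting, baseline parameter set.

A run configuration is a YAML or JSON document with blocks

    tissues:  tumor (required) and normal (optional), each with exactly the
              keys {K, Lp, SV, pv, sigma, pi_v, pi_i, lymph_coeff, pL}
    geometry: R, Rn (default 0), R_out (default: R for isolated runs, 3R for
              embedded runs), n_per_axis for voxel runs
    boundary: kind (isolated | embedded), p_surr (mmHg)
    solver:   method, tolerance, relaxation, max_iter, N, n_per_axis
    analysis: eps, radii, rn_bars
    output:   prefix, formats

Unknown keys are rejected and every applied default is logged, so a report's
embedded resolved configuration is a complete audit trail of the run.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from ._linalg import SolverOptions
from .fvm_radial import BoundarySpec, TumorGeometry1D
from .tissue import TissueParameters

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "baseline_config",
    "baseline_config_path",
]

log = logging.getLogger("tumorifp")


class ConfigError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissueBlock(_Block):
    K: float = Field(gt=0)
    Lp: float = Field(ge=0)
    SV: float = Field(ge=0)
    pv: float
    sigma: float = Field(ge=0, le=1)
    pi_v: float
    pi_i: float
    lymph_coeff: float = Field(ge=0)
    pL: float

    def to_params(self) -> TissueParameters:
        return TissueParameters(**self.model_dump())


class TissuesBlock(_Block):
    tumor: TissueBlock
    normal: Optional[TissueBlock] = None


class GeometryBlock(_Block):
    R: float = Field(gt=0, description="tumor radius, cm")
    Rn: float = Field(default=0.0, ge=0, description="necrotic core radius, cm")
    R_out: Optional[float] = Field(default=None, description="outer domain radius, cm")

    @model_validator(mode="after")
    def _ordered(self):
        if self.Rn > self.R:
            raise ValueError("Rn must not exceed R")
        if self.R_out is not None and self.R_out < self.R:
            raise ValueError("R_out must be >= R")
        return self


class BoundaryBlock(_Block):
    kind: Literal["isolated", "embedded"] = "isolated"
    p_surr: float = 0.0


class SolverBlock(_Block):
    method: Literal["direct", "sor", "cg"] = "direct"
    tolerance: float = Field(default=1e-6, gt=0)
    relaxation: float = Field(default=0.75, gt=0, lt=2)
    max_iter: int = Field(default=200_000, gt=0)
    N: int = Field(default=1000, ge=3, description="radial cell count")
    n_per_axis: int = Field(default=32, ge=16, description="3-D voxels per axis")

    def to_options(self, method: str | None = None) -> SolverOptions:
        return SolverOptions(
            method=method or self.method,
            tolerance=self.tolerance,
            relaxation=self.relaxation,
            max_iter=self.max_iter,
        )


class AnalysisBlock(_Block):
    eps: float = Field(default=0.01, gt=0, lt=0.5)
    radii: list[float] = Field(default=[0.1, 0.25, 0.5, 1.0])
    rn_bars: list[float] = Field(default=[0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


class OutputBlock(_Block):
    prefix: str = "run"
    formats: list[Literal["csv", "json", "vtk"]] = Field(default=["csv", "json"])


class RunConfig(_Block):
    tissues: TissuesBlock
    geometry: GeometryBlock
    boundary: BoundaryBlock = BoundaryBlock()
    solver: SolverBlock = SolverBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    output: OutputBlock = OutputBlock()

    @model_validator(mode="after")
    def _embedded_needs_normal(self):
        if self.boundary.kind == "embedded" and self.tissues.normal is None:
            raise ValueError("boundary.kind 'embedded' requires tissues.normal")
        return self

    def resolved_geometry(self) -> TumorGeometry1D:
        """Geometry with the embedded-case default R_out = 3R applied."""
        R_out = self.geometry.R_out
        if R_out is None and self.boundary.kind == "embedded":
            R_out = 3.0 * self.geometry.R
            log.info("default applied: geometry.R_out = 3*R = %g cm", R_out)
        return TumorGeometry1D(R=self.geometry.R, Rn=self.geometry.Rn, R_out=R_out)

    def boundary_spec(self) -> BoundarySpec:
        return BoundarySpec(kind=self.boundary.kind, p_out=self.boundary.p_surr)


def _log_defaults(model: BaseModel, provided: dict, prefix: str = "") -> None:
    for name in model.__class__.model_fields:
        value = getattr(model, name)
        if name not in (provided or {}):
            if isinstance(value, BaseModel):
                _log_defaults(value, {}, prefix=f"{prefix}{name}.")
            else:
                log.info("default applied: %s%s = %r", prefix, name, value)
        elif isinstance(value, BaseModel):
            _log_defaults(value, provided[name], prefix=f"{prefix}{name}.")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Raises :class:`ConfigError` naming the offending key on any missing or
    unknown key or invariant violation; logs every default that was applied.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration — {locs}") from exc
    _log_defaults(cfg, raw)
    return cfg


def baseline_config_path() -> Path:
    """Path of the shipped baseline parameter file (standard mammary set)."""
    return Path(resources.files("tumorifp").joinpath("data", "baseline.yaml"))


def baseline_config() -> RunConfig:
    return load_config(baseline_config_path())


def baseline_tissues() -> tuple[TissueParameters, TissueParameters]:
    """(tumor, normal) baseline parameter sets."""
    cfg = baseline_config()
    return cfg.tissues.tumor.to_params(), cfg.tissues.normal.to_params()
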