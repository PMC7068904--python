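"""Pipeline configuration: YAML schema, defaults, validation.

A config names the factors (defaulting to the three implantation angles at
their standard levels), selects exactly one response source — ``surrogate``
(the elastic-foundation solver), ``planted`` (the analytic bowl), or
``external`` (a delimited response file such as the packaged nine-run
fixture) — and optionally overrides the surrogate's geometry, liner
material, ligaments, and load case.  Unknown keys are rejected with their
field path; every omitted block falls back to the documented defaults
(1150 N axial load, the component material table, Taguchi L9 factor
levels).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .contact import (
    DEFAULT_LIGAMENTS,
    MATERIALS,
    ArticularGeometry,
    Compartment,
    LigamentSpec,
    LoadCase,
    Material,
    default_geometry,
)
from .design import DEFAULT_FACTORS, FactorSpec
from .planted import PlantedBowl

__all__ = ["PipelineConfig", "ConfigError", "load_config", "dump_config"]

EVALUATORS = ("surrogate", "planted", "external")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message carries the field path."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration with all defaults applied.

    Units throughout: angles in degrees, forces in N, moduli in MPa,
    lengths in mm.
    """

    factors: tuple[FactorSpec, ...] = DEFAULT_FACTORS
    evaluator: str = "surrogate"
    responses_file: str | None = None
    optimum_response_mpa: float | None = None
    direction: str = "minimize"
    precision: int = 2
    seed: int | None = None
    inherent_slope_deg: float = 3.0
    geometry: ArticularGeometry = field(default_factory=default_geometry)
    liner_material: Material = MATERIALS["polyethylene_liner"]
    ligaments: tuple[LigamentSpec, ...] = DEFAULT_LIGAMENTS
    load: LoadCase = field(default_factory=LoadCase)
    free_tilts: tuple[str, ...] = ("varus_valgus",)
    bowl: PlantedBowl = field(default_factory=PlantedBowl)

    def __post_init__(self) -> None:
        if self.evaluator not in EVALUATORS:
            raise ConfigError(f"evaluator: must be one of {EVALUATORS}, got {self.evaluator!r}")
        if self.evaluator == "external" and not self.responses_file:
            raise ConfigError("responses_file: required when evaluator is 'external'")
        if self.evaluator != "external" and self.responses_file:
            raise ConfigError(
                "responses_file: a response file and the "
                f"'{self.evaluator}' evaluator were both specified; choose one response source"
            )
        if self.direction not in ("minimize", "maximize"):
            raise ConfigError(f"direction: must be 'minimize' or 'maximize', got {self.direction!r}")
        if self.precision < 0:
            raise ConfigError("precision: must be non-negative")
        if self.evaluator == "planted" and self.bowl.noise_sd_mpa > 0 and self.seed is None:
            raise ConfigError("seed: required when planted-response noise is enabled")


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


def _build(cls, block: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, names, path)
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _from_dict(raw: dict[str, Any]) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("top level: config must be a mapping")
    allowed = {
        "factors", "evaluator", "responses_file", "optimum_response_mpa",
        "direction", "precision", "seed", "inherent_slope_deg",
        "surrogate", "planted",
    }
    _check_keys(raw, allowed, "top level")

    kwargs: dict[str, Any] = {}
    for key in ("evaluator", "responses_file", "optimum_response_mpa",
                "direction", "precision", "seed", "inherent_slope_deg"):
        if key in raw and raw[key] is not None:
            kwargs[key] = raw[key]

    if "factors" in raw and raw["factors"] is not None:
        factors = []
        for i, fblock in enumerate(raw["factors"]):
            if isinstance(fblock, dict) and "levels" in fblock:
                fblock = dict(fblock)
                fblock["levels"] = tuple(fblock["levels"])
            factors.append(_build(FactorSpec, fblock, f"factors[{i}]"))
        kwargs["factors"] = tuple(factors)

    sur = raw.get("surrogate") or {}
    _check_keys(sur, {"geometry", "liner_material", "ligaments", "load", "free_tilts"}, "surrogate")
    if "geometry" in sur:
        g = dict(sur["geometry"])
        _check_keys(g, {"compartments", "liner_thickness_mm", "grid_spacing_mm", "grid_margin_mm"},
                    "surrogate.geometry")
        if "compartments" in g:
            g["compartments"] = tuple(
                _build(Compartment, c, f"surrogate.geometry.compartments[{i}]")
                for i, c in enumerate(g["compartments"])
            )
        else:
            g["compartments"] = default_geometry().compartments
        kwargs["geometry"] = _build(ArticularGeometry, g, "surrogate.geometry")
    if "liner_material" in sur:
        mat = sur["liner_material"]
        if isinstance(mat, str):
            if mat not in MATERIALS:
                raise ConfigError(
                    f"surrogate.liner_material: unknown material {mat!r} "
                    f"(known: {sorted(MATERIALS)})"
                )
            kwargs["liner_material"] = MATERIALS[mat]
        else:
            kwargs["liner_material"] = _build(Material, mat, "surrogate.liner_material")
    if "ligaments" in sur:
        kwargs["ligaments"] = tuple(
            _build(LigamentSpec, l, f"surrogate.ligaments[{i}]")
            for i, l in enumerate(sur["ligaments"])
        )
    if "load" in sur:
        ld = dict(sur["load"])
        if "application_point_mm" in ld:
            ld["application_point_mm"] = tuple(ld["application_point_mm"])
        kwargs["load"] = _build(LoadCase, ld, "surrogate.load")
    if "free_tilts" in sur:
        kwargs["free_tilts"] = tuple(sur["free_tilts"])

    if raw.get("planted"):
        p = dict(raw["planted"])
        for key in ("optimum_deg", "weights_mpa_per_deg2"):
            if key in p:
                p[key] = tuple(p[key])
        kwargs["bowl"] = _build(PlantedBowl, p, "planted")

    return PipelineConfig(**kwargs)


def _to_dict(config: PipelineConfig) -> dict[str, Any]:
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, list):
            return [plain(v) for v in obj]
        return obj

    return {
        "evaluator": config.evaluator,
        "responses_file": config.responses_file,
        "optimum_response_mpa": config.optimum_response_mpa,
        "direction": config.direction,
        "precision": config.precision,
        "seed": config.seed,
        "inherent_slope_deg": config.inherent_slope_deg,
        "factors": [plain(f) for f in config.factors],
        "surrogate": {
            "geometry": plain(config.geometry),
            "liner_material": plain(config.liner_material),
            "ligaments": [plain(l) for l in config.ligaments],
            "load": plain(config.load),
            "free_tilts": list(config.free_tilts),
        },
        "planted": plain(config.bowl),
    }


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, applying defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return _from_dict(raw)


def dump_config(config: PipelineConfig, path=None) -> str:
    """Serialize a config to YAML; ``dump(load(x))`` is semantically
    identical to ``x`` with defaults made explicit."""
    text = yaml.safe_dump(_to_dict(config), sort_keys=True, default_flow_style=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    """Build a config from an already-parsed mapping (used by tests/CLI)."""
    return _from_dict(raw)
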