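"""Scenario configuration: schema, YAML loading, and stack assembly.

A scenario describes one simulated sensor in the four-layer
prism / silver film / sensing film / air geometry (or an arbitrary
``custom`` stack) together with an angular scan.  Three sensing-film
modes cover the configurations of interest:

``pure_film``
    The film is a single substance (water, or a pure biomaterial).
``no_core_shell``
    The film is a Maxwell-Garnett mixture of biomaterial droplets in
    water at volume fraction ``F`` (inclusion = pure biomaterial).
``with_core_shell``
    The film is a mixture of complex particles — a magnetite-core /
    gold-shell grain wrapped in a biomaterial shell — in water.

Configurations are fully deterministic: no randomness anywhere.
Validation is strict (unknown keys rejected, fields range-checked) and
happens before any computation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .effective_medium import (
    CoreShellGeometry,
    coated_grain_eps,
    coreshell_eps,
    maxwell_garnett_eps,
)
from .fresnel import Layer, LayerStack
from .materials import DEFAULT_WAVELENGTH_NM, MaterialRegistry, OpticalConstant

__all__ = [
    "LayerSpec",
    "CoreShellConfig",
    "CompositeConfig",
    "ScanConfig",
    "ScenarioConfig",
    "load_config",
    "build_stack",
    "sensing_layer_eps",
    "scenario_analyte_n",
]

logger = logging.getLogger(__name__)

Mode = Literal["pure_film", "no_core_shell", "with_core_shell", "custom"]

DEFAULT_ALPHA = 0.73
DEFAULT_FILL_FRACTION = 0.73


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerSpec(_StrictModel):
    """One layer of a ``custom`` stack.

    The optical constants come either from a registry ``material`` name
    or inline as ``n_real``/``n_imag`` or ``eps_real``/``eps_imag``.
    Half-spaces set ``halfspace: true`` and omit the thickness.
    """

    name: Optional[str] = None
    material: Optional[str] = None
    n_real: Optional[float] = None
    n_imag: float = 0.0
    eps_real: Optional[float] = None
    eps_imag: float = 0.0
    thickness_nm: Optional[float] = Field(default=None, ge=0)
    halfspace: bool = False

    @model_validator(mode="after")
    def _check(self) -> "LayerSpec":
        sources = sum(
            x is not None for x in (self.material, self.n_real, self.eps_real)
        )
        if sources != 1:
            raise ValueError(
                "specify exactly one of material, n_real or eps_real per layer"
            )
        if self.halfspace and self.thickness_nm is not None:
            raise ValueError("a halfspace layer must not carry thickness_nm")
        if not self.halfspace and self.thickness_nm is None:
            raise ValueError("finite layers require thickness_nm (or halfspace: true)")
        return self

    def to_layer(self, registry: MaterialRegistry) -> Layer:
        if self.material is not None:
            eps = registry.eps(self.material)
            label = self.name or self.material
        elif self.n_real is not None:
            eps = complex(self.n_real, self.n_imag) ** 2
            label = self.name or "inline"
        else:
            eps = complex(self.eps_real, self.eps_imag)
            label = self.name or "inline"
        return Layer(name=label, eps=eps, thickness_nm=self.thickness_nm)


class CoreShellConfig(_StrictModel):
    """Core-shell geometry by outer radius ``a`` plus either ``b`` or ``f``."""

    a: float = Field(gt=0)
    b: Optional[float] = Field(default=None, gt=0)
    f: Optional[float] = Field(default=None, gt=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "CoreShellConfig":
        if (self.b is None) == (self.f is None):
            raise ValueError("specify exactly one of b (core radius) or f ((b/a)^3)")
        if self.b is not None and self.b > self.a:
            raise ValueError(f"core radius b={self.b} exceeds outer radius a={self.a}")
        return self

    def geometry(self) -> CoreShellGeometry:
        b = self.b if self.b is not None else self.a * self.f ** (1.0 / 3.0)
        return CoreShellGeometry(b=b, a=self.a)


class CompositeConfig(_StrictModel):
    """Mixing parameters of the sensing film."""

    F: float = Field(ge=0, le=1)
    alpha: float = Field(default=DEFAULT_ALPHA, gt=0, le=1)
    biomaterial: str = "hb_cytoplasm"
    mg_variant: Literal["paper", "standard"] = "paper"


class ScanConfig(_StrictModel):
    theta_min_deg: float = 40.0
    theta_max_deg: float = 60.0
    step_deg: float = Field(default=0.005, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "ScanConfig":
        if not self.theta_min_deg < self.theta_max_deg:
            raise ValueError("theta_min_deg must be smaller than theta_max_deg")
        return self


class ScenarioConfig(_StrictModel):
    """A fully validated, deterministic sensor scenario."""

    name: str = "scenario"
    mode: Mode = "pure_film"
    wavelength_nm: float = Field(default=DEFAULT_WAVELENGTH_NM, gt=0)
    prism_material: str = "bk7"
    metal_material: str = "silver"
    ag_thickness_nm: float = Field(default=40.0, gt=0)
    film_thickness_nm: float = Field(default=20.0, ge=0)
    exit_material: str = "air"
    film_material: Optional[str] = None  # pure_film only; defaults to water
    coreshell: Optional[CoreShellConfig] = None
    composite: Optional[CompositeConfig] = None
    scan: ScanConfig = Field(default_factory=ScanConfig)
    layers: Optional[list[LayerSpec]] = None  # custom mode only

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.mode == "custom":
            if not self.layers:
                raise ValueError("custom mode requires an explicit layers list")
        else:
            if self.layers:
                raise ValueError("layers are only allowed in custom mode")
        if self.mode == "with_core_shell":
            if self.coreshell is None or self.composite is None:
                raise ValueError(
                    "with_core_shell mode requires coreshell and composite sections"
                )
        if self.mode == "no_core_shell" and self.composite is None:
            raise ValueError("no_core_shell mode requires a composite section")
        if self.mode == "pure_film" and self.composite is not None:
            raise ValueError("pure_film mode takes no composite section")
        return self


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario file; defaults are filled in.

    Schema violations raise pydantic's itemized ``ValidationError``
    naming each offending field; unknown keys are rejected.
    """
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a YAML mapping")
    return ScenarioConfig.model_validate(data)


def sensing_layer_eps(
    config: ScenarioConfig, registry: MaterialRegistry | None = None
) -> complex:
    """Effective permittivity of the sensing film described by ``config``."""
    if registry is None:
        registry = MaterialRegistry.default(config.wavelength_nm)
    if config.mode == "pure_film":
        return registry.eps(config.film_material or "water")
    if config.mode == "custom":
        raise ValueError("custom stacks have no single sensing layer")
    comp = config.composite
    eps_bio = registry.eps(comp.biomaterial)
    eps_host = registry.eps("water")
    if config.mode == "no_core_shell":
        eps_inclusion = eps_bio
    else:  # with_core_shell
        eps_core, eps_shell = registry.constituents()
        eps_grain = coreshell_eps(config.coreshell.geometry(), eps_core, eps_shell)
        eps_inclusion = coated_grain_eps(eps_bio, eps_grain, comp.alpha)
        logger.info(
            "scenario %s: grain eps_eff=%s, complex-particle eps_n=%s",
            config.name,
            eps_grain,
            eps_inclusion,
        )
    eps_film = maxwell_garnett_eps(
        eps_inclusion, eps_host, comp.F, variant=comp.mg_variant
    )
    logger.info("scenario %s: sensing-film eps=%s", config.name, eps_film)
    return eps_film


def build_stack(
    config: ScenarioConfig, registry: MaterialRegistry | None = None
) -> LayerStack:
    """Assemble the layer stack of a scenario."""
    if registry is None:
        registry = MaterialRegistry.default(config.wavelength_nm)
    if config.mode == "custom":
        return LayerStack(
            wavelength_nm=config.wavelength_nm,
            layers=tuple(spec.to_layer(registry) for spec in config.layers),
        )
    eps_film = sensing_layer_eps(config, registry)
    film_name = (
        config.film_material or "water"
        if config.mode == "pure_film"
        else f"{config.mode}_film"
    )
    return LayerStack(
        wavelength_nm=config.wavelength_nm,
        layers=(
            Layer.from_material(
                config.prism_material, registry.get(config.prism_material)
            ),
            Layer.from_material(
                config.metal_material,
                registry.get(config.metal_material),
                thickness_nm=config.ag_thickness_nm,
            ),
            Layer(name=film_name, eps=eps_film, thickness_nm=config.film_thickness_nm),
            Layer.from_material(
                config.exit_material, registry.get(config.exit_material)
            ),
        ),
    )


def scenario_analyte_n(
    config: ScenarioConfig, registry: MaterialRegistry | None = None
) -> float:
    """Refractive index of the scenario's analyte substance.

    Used for sensitivity comparisons: for composite modes this is the
    biomaterial index, for a pure film the film substance's index.
    """
    if registry is None:
        registry = MaterialRegistry.default(config.wavelength_nm)
    if config.mode in ("no_core_shell", "with_core_shell"):
        return float(registry.n(config.composite.biomaterial).real)
    if config.mode == "pure_film":
        return float(registry.n(config.film_material or "water").real)
    raise ValueError("custom scenarios carry no analyte refractive index")
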