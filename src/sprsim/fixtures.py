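"""Deterministic scenario generator for the sensor configurations of interest.

Enumerates, as validated :class:`~sprsim.config.ScenarioConfig` objects:

* the conventional references — water film, and a pure Hb-cytoplasm
  film at the high-concentration index (the four-layer benchmark whose
  dip sits near 45.4 degrees);
* a no-core-shell mixture per biomaterial at F = 0.1;
* the with-core-shell grid: biomaterial x outer radius a in
  {2.5, 5, 7.5, 10} nm x volume fraction F in {0.1, 0.8}, at fill
  fraction f = 0.73;
* a silver-thickness sweep {20, 30, 40, 50, 60} nm around the optimal
  40 nm film.

The complex-particle ratio alpha = (a/R)**3 is never pinned down by the
source scenarios (R is free); fixtures default to alpha = 0.73,
mirroring f, and every consumer can override it.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .config import (
    DEFAULT_ALPHA,
    DEFAULT_FILL_FRACTION,
    CompositeConfig,
    CoreShellConfig,
    ScenarioConfig,
)

__all__ = [
    "BIOMATERIALS",
    "CORE_SHELL_RADII_NM",
    "VOLUME_FRACTIONS",
    "AG_THICKNESSES_NM",
    "EXPECTED_FIXTURE_COUNT",
    "make_fixtures",
    "write_fixtures",
]

BIOMATERIALS = ("blood_plasma", "hb_cytoplasm", "lecithin")
CORE_SHELL_RADII_NM = (2.5, 5.0, 7.5, 10.0)
VOLUME_FRACTIONS = (0.1, 0.8)
AG_THICKNESSES_NM = (20.0, 30.0, 40.0, 50.0, 60.0)

# 2 references + 3 no-core-shell + 3*4*2 with-core-shell + 5 Ag sweep
EXPECTED_FIXTURE_COUNT = 2 + len(BIOMATERIALS) + len(BIOMATERIALS) * len(
    CORE_SHELL_RADII_NM
) * len(VOLUME_FRACTIONS) + len(AG_THICKNESSES_NM)


def _fmt(x: float) -> str:
    return f"{x:g}"


def make_fixtures(
    alpha: float = DEFAULT_ALPHA, f: float = DEFAULT_FILL_FRACTION
) -> dict[str, ScenarioConfig]:
    """Enumerate every named scenario; keys are the scenario names."""
    out: dict[str, ScenarioConfig] = {}

    def put(cfg: ScenarioConfig) -> None:
        out[cfg.name] = cfg

    put(ScenarioConfig(name="conventional_water", mode="pure_film", film_material="water"))
    put(
        ScenarioConfig(
            name="conventional_hb_film",
            mode="pure_film",
            film_material="hb_cytoplasm_hi",
        )
    )
    for bio in BIOMATERIALS:
        put(
            ScenarioConfig(
                name=f"no_core_shell_{bio}_F0.1",
                mode="no_core_shell",
                composite=CompositeConfig(F=0.1, alpha=alpha, biomaterial=bio),
            )
        )
    for bio in BIOMATERIALS:
        for a in CORE_SHELL_RADII_NM:
            for F in VOLUME_FRACTIONS:
                put(
                    ScenarioConfig(
                        name=f"with_core_shell_{bio}_a{_fmt(a)}_F{_fmt(F)}",
                        mode="with_core_shell",
                        coreshell=CoreShellConfig(a=a, f=f),
                        composite=CompositeConfig(F=F, alpha=alpha, biomaterial=bio),
                    )
                )
    for d in AG_THICKNESSES_NM:
        put(
            ScenarioConfig(
                name=f"ag_sweep_d{_fmt(d)}",
                mode="with_core_shell",
                ag_thickness_nm=d,
                coreshell=CoreShellConfig(a=2.5, f=f),
                composite=CompositeConfig(F=0.1, alpha=alpha, biomaterial="hb_cytoplasm"),
            )
        )
    assert len(out) == EXPECTED_FIXTURE_COUNT
    return out


def write_fixtures(outdir: str | Path, **kwargs) -> list[Path]:
    """Dump every fixture as a YAML scenario file; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cfg in sorted(make_fixtures(**kwargs).items()):
        path = outdir / f"{name}.yaml"
        data = cfg.model_dump(exclude_none=True)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        paths.append(path)
    return paths
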