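"""Optical constants at a fixed wavelength and constituent calibration.

Everything here refers to a single vacuum wavelength — by default the
632.8 nm HeNe line used throughout the sensor model.  Dispersion is out
of scope: a different wavelength means supplying different constants.

The magnetite-core / gold-shell constituent permittivities are not
hard-coded from the literature.  They are *calibrated*: recovered by
root finding from printed effective-permittivity tables of the
core-shell homogenization (see :func:`recover_constituents`), so that
the registry is self-consistent with the homogenization model it feeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize

from .effective_medium import (
    CoreShellGeometry,
    EffectiveMediumPoleError,
    coreshell_eps_f,
)

__all__ = [
    "DEFAULT_WAVELENGTH_NM",
    "OpticalConstant",
    "MaterialRegistry",
    "CalibrationError",
    "DegenerateCalibrationError",
    "n_to_eps",
    "eps_to_n",
    "recover_constituents",
    "TABLE_SHELL_THICKNESS",
    "TABLE_CORE_RADIUS",
    "TABLE_FILL_FRACTION",
    "DEFAULT_CALIBRATION_ROWS",
]

logger = logging.getLogger(__name__)

DEFAULT_WAVELENGTH_NM = 632.8


class CalibrationError(RuntimeError):
    """Constituent recovery failed to converge to the requested residual."""


class DegenerateCalibrationError(ValueError):
    """Calibration rows do not contain two distinct fill fractions."""


def n_to_eps(n: complex) -> complex:
    """Relative permittivity from a complex refractive index: eps = n**2."""
    n = complex(n)
    return n * n


def eps_to_n(eps: complex) -> complex:
    """Complex refractive index from a permittivity, on the passive branch.

    The square root is chosen so that ``Im(n) >= 0`` (absorbing medium).
    """
    n = complex(np.sqrt(complex(eps)))
    if n.imag < 0 or (n.imag == 0 and n.real < 0):
        n = -n
    return n


@dataclass(frozen=True)
class OpticalConstant:
    """A complex refractive index ``n + ik`` at a stated vacuum wavelength.

    The permittivity is derived (``eps = n**2``) so the two
    representations can never drift apart.  Passive media only:
    ``Im(n) >= 0``.
    """

    wavelength_nm: float
    n: complex

    def __post_init__(self) -> None:
        if not (self.wavelength_nm > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        object.__setattr__(self, "n", complex(self.n))
        if self.n.imag < 0:
            raise ValueError(
                f"Im(n) must be >= 0 for a passive medium, got {self.n}"
            )

    @property
    def eps(self) -> complex:
        return n_to_eps(self.n)

    @classmethod
    def from_eps(
        cls, eps: complex, wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    ) -> "OpticalConstant":
        return cls(wavelength_nm=wavelength_nm, n=eps_to_n(eps))


# ----------------------------------------------------------------------
# Printed constants.  The decimal literals are kept as strings so that
# what the registry stores is character-identical to the source values;
# floats are derived from them.
# ----------------------------------------------------------------------

PRINTED_INDEX_LITERALS: Mapping[str, tuple[str, str]] = {
    "bk7": ("1.510", "0"),
    "silver": ("0.13455", "3.98651"),
    "water": ("1.33", "0"),
    "air": ("1.0", "0"),
    "blood_plasma": ("1.3479", "0"),
    "hb_cytoplasm": ("1.3800", "0"),
    "hb_cytoplasm_hi": ("1.3871", "0"),  # higher-concentration Hb variant
    "lecithin": ("1.4838", "0"),
}


# Core-shell effective permittivities of the three characterization grids
# (shell-thickness sweep at b=10 nm; core-radius sweep at 1 nm shell;
# fill-fraction sweep at a=10 nm).  Each row: (b_nm, a_nm, eps_eff).
TABLE_SHELL_THICKNESS: tuple[tuple[float, float, complex], ...] = (
    (10.0, 11.0, 1.0092 + 3.2011j),
    (10.0, 13.0, -2.5021 + 3.0123j),
    (10.0, 15.0, -4.8721 + 2.6948j),
    (10.0, 17.0, -6.4556 + 2.3952j),
    (10.0, 20.0, -7.9297 + 2.0516j),
    (10.0, 30.0, -9.7428 + 1.5407j),
    (10.0, 40.0, -10.212 + 1.3921j),
    (10.0, 100.0, -10.539 + 1.2845j),
)

TABLE_CORE_RADIUS: tuple[tuple[float, float, complex], ...] = (
    (10.0, 11.0, 1.0092 + 3.2011j),
    (12.0, 13.0, 1.3637 + 3.2017j),
    (14.0, 15.0, 1.6230 + 3.2000j),
    (16.0, 17.0, 1.8209 + 3.1975j),
    (18.0, 19.0, 1.9768 + 3.1947j),
    (20.0, 21.0, 2.1028 + 3.1921j),
    (100.0, 101.0, 3.0427 + 3.1587j),
)

TABLE_FILL_FRACTION: tuple[tuple[float, float, complex], ...] = (
    (9.5, 10.0, 2.04008 + 3.19339j),
    (9.0, 10.0, 0.77837 + 3.19889j),
    (8.5, 10.0, -0.49070 + 3.16118j),
    (8.0, 10.0, -1.74550 + 3.08115j),
    (7.5, 10.0, -2.96636 + 2.96227j),
    (7.0, 10.0, -4.13333 + 2.81043j),
    (6.5, 10.0, -5.22780 + 2.63368j),
)

# Default calibration pair: the extreme fill fractions of the
# shell-thickness grid (f = (10/11)^3 ~ 0.75 and f = 1e-3), which
# maximizes the conditioning of the two-unknown system.  All other rows
# are held out for validation.
DEFAULT_CALIBRATION_ROWS: tuple[tuple[tuple[float, float], complex], ...] = (
    ((10.0, 11.0), TABLE_SHELL_THICKNESS[0][2]),
    ((10.0, 100.0), TABLE_SHELL_THICKNESS[-1][2]),
)

CORE_NAME = "fe3o4_core"
SHELL_NAME = "au_shell"

_CalRow = tuple[CoreShellGeometry | tuple[float, float], complex]


def recover_constituents(
    rows: Sequence[_CalRow] | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 400,
) -> tuple[complex, complex]:
    """Back-solve core and shell permittivities from effective-permittivity rows.

    Each row pairs a core-shell geometry (or a ``(b, a)`` tuple) with the
    effective permittivity the homogenization should produce for it.
    With two rows this is a square system of two complex unknowns solved
    by multidimensional root finding; with more rows a least-squares fit
    is performed.

    The solver is initialized from the physics of the thin/thick-shell
    limits: ``eps_shell`` starts at the effective permittivity of the
    smallest-f row (a nearly solid shell sphere) and ``eps_core`` at that
    of the largest-f row.  A consequence of this choice is the
    homogeneous-sphere convention: if every row carries the same
    effective permittivity, the returned core and shell permittivities
    are both equal to it (the system is otherwise underdetermined).

    Returns
    -------
    (eps_core, eps_shell)
        Complex constituent permittivities reproducing every input row
        to within ``tol`` absolute residual (square system).

    Raises
    ------
    DegenerateCalibrationError
        Fewer than two distinct fill fractions among the rows.
    CalibrationError
        Root finding did not converge to the requested residual.
    """
    if rows is None:
        rows = DEFAULT_CALIBRATION_ROWS
    if len(rows) < 2:
        raise DegenerateCalibrationError("need at least two calibration rows")
    geoms = [
        g if isinstance(g, CoreShellGeometry) else CoreShellGeometry(*g)
        for g, _ in rows
    ]
    effs = [complex(e) for _, e in rows]
    if any(not np.isfinite([e.real, e.imag]).all() for e in effs):
        raise ValueError("effective permittivities must be finite")
    fs = [g.f for g in geoms]
    if len(set(fs)) < 2:
        raise DegenerateCalibrationError(
            f"calibration rows share a single fill fraction f={fs[0]}"
        )

    order = sorted(range(len(fs)), key=lambda i: fs[i])
    es0 = effs[order[0]]  # smallest f: eps_eff -> eps_shell
    ec0 = effs[order[-1]]  # largest f: core-dominated

    def residual(x: np.ndarray) -> np.ndarray:
        ec = complex(x[0], x[1])
        es = complex(x[2], x[3])
        out = np.empty(2 * len(rows))
        for k, (f, target) in enumerate(zip(fs, effs)):
            try:
                diff = coreshell_eps_f(f, ec, es) - target
            except EffectiveMediumPoleError:
                diff = 1e6 + 1e6j
            out[2 * k] = diff.real
            out[2 * k + 1] = diff.imag
        return out

    x0 = np.array([ec0.real, ec0.imag, es0.real, es0.imag])
    square = len(rows) == 2
    if square:
        sol = optimize.root(residual, x0, method="hybr", options={"maxfev": max_iter})
        if not sol.success:  # fall back to Levenberg-Marquardt
            sol = optimize.root(residual, x0, method="lm", options={"maxiter": max_iter})
        converged = sol.success
    else:
        sol = optimize.least_squares(residual, x0, max_nfev=max_iter)
        converged = sol.status > 0
    res = float(np.max(np.abs(residual(sol.x))))
    if not converged or (square and res > tol):
        raise CalibrationError(
            f"constituent recovery did not converge (max residual {res:.3e})"
        )
    eps_core = complex(sol.x[0], sol.x[1])
    eps_shell = complex(sol.x[2], sol.x[3])
    logger.info(
        "calibrated constituents: eps_core=%s eps_shell=%s (residual %.3e)",
        eps_core,
        eps_shell,
        res,
    )
    return eps_core, eps_shell


@dataclass
class _Entry:
    optical: OpticalConstant
    calibrated: bool = False
    note: str = ""


@dataclass
class MaterialRegistry:
    """Named optical constants, all at one wavelength.

    The default registry ships the printed sensor constants (prism,
    silver film, water, air, the three biomaterials).  Core and shell
    constituents are added by :meth:`calibrate_core_shell` and carry a
    ``calibrated`` flag plus a note recording the rows used; user-supplied
    literature values can be installed with :meth:`add` instead.
    """

    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    _entries: dict[str, _Entry] = field(default_factory=dict)

    @classmethod
    def default(cls, wavelength_nm: float = DEFAULT_WAVELENGTH_NM) -> "MaterialRegistry":
        reg = cls(wavelength_nm=wavelength_nm)
        for name, (re_s, im_s) in PRINTED_INDEX_LITERALS.items():
            reg.add(
                name,
                OpticalConstant(wavelength_nm, complex(float(re_s), float(im_s))),
            )
        return reg

    def add(
        self,
        name: str,
        optical: OpticalConstant,
        *,
        calibrated: bool = False,
        note: str = "",
    ) -> None:
        self._entries[name] = _Entry(optical, calibrated, note)

    def get(self, name: str) -> OpticalConstant:
        try:
            return self._entries[name].optical
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; available: {sorted(self._entries)}"
            ) from None

    def eps(self, name: str) -> complex:
        return self.get(name).eps

    def n(self, name: str) -> complex:
        return self.get(name).n

    def is_calibrated(self, name: str) -> bool:
        return self._entries[name].calibrated

    def note(self, name: str) -> str:
        return self._entries[name].note

    def names(self) -> list[str]:
        return sorted(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def calibrate_core_shell(
        self, rows: Sequence[_CalRow] | None = None
    ) -> tuple[complex, complex]:
        """Recover and register the core/shell constituent permittivities.

        Results are stored under ``fe3o4_core`` and ``au_shell`` with the
        ``calibrated`` flag set and the calibration rows recorded in the
        entry note.  Returns ``(eps_core, eps_shell)``.
        """
        if rows is None:
            rows = DEFAULT_CALIBRATION_ROWS
        eps_core, eps_shell = recover_constituents(rows)
        geoms = [
            g if isinstance(g, CoreShellGeometry) else CoreShellGeometry(*g)
            for g, _ in rows
        ]
        note = "calibrated from rows " + ", ".join(
            f"(b={g.b}, a={g.a})" for g in geoms
        )
        self.add(
            CORE_NAME,
            OpticalConstant.from_eps(eps_core, self.wavelength_nm),
            calibrated=True,
            note=note,
        )
        self.add(
            SHELL_NAME,
            OpticalConstant.from_eps(eps_shell, self.wavelength_nm),
            calibrated=True,
            note=note,
        )
        return eps_core, eps_shell

    def constituents(self) -> tuple[complex, complex]:
        """Core and shell permittivities, calibrating on first use."""
        if CORE_NAME not in self or SHELL_NAME not in self:
            return self.calibrate_core_shell()
        return self.eps(CORE_NAME), self.eps(SHELL_NAME)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaterialRegistry":
        """Load a registry from a YAML mapping of name -> constants.

        Each entry provides either ``{n_real, n_imag}`` or
        ``{eps_real, eps_imag}`` plus an optional ``wavelength_nm``
        (default 632.8).
        """
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ValueError(f"materials file {path} must be a mapping")
        wl = float(data.pop("wavelength_nm", DEFAULT_WAVELENGTH_NM))
        reg = cls(wavelength_nm=wl)
        for name, spec in data.items():
            if not isinstance(spec, Mapping):
                raise ValueError(f"material {name!r}: expected a mapping, got {spec!r}")
            entry_wl = float(spec.get("wavelength_nm", wl))
            if "n_real" in spec:
                n = complex(float(spec["n_real"]), float(spec.get("n_imag", 0.0)))
                oc = OpticalConstant(entry_wl, n)
            elif "eps_real" in spec:
                eps = complex(float(spec["eps_real"]), float(spec.get("eps_imag", 0.0)))
                oc = OpticalConstant.from_eps(eps, entry_wl)
            else:
                raise ValueError(
                    f"material {name!r}: provide n_real/n_imag or eps_real/eps_imag"
                )
            reg.add(name, oc)
        return reg
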