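"""Quasi-static effective-medium homogenization for core-shell nanocomposites.

Three nested levels of homogenization are provided, all in the
long-wavelength (electrostatic) limit where a particle is small compared
with the wavelength:

1. ``coreshell_eps`` — a spherical dielectric core (radius ``b``,
   permittivity ``eps_core``) coated by a metallic shell (outer radius
   ``a``, permittivity ``eps_shell``) is replaced by an equivalent
   homogeneous sphere.  The result depends on the geometry only through
   the core fill fraction ``f = (b/a)**3``.
2. ``coated_grain_eps`` — the equivalent sphere is itself wrapped in an
   interfacial shell (e.g. a biomolecular corona) of outer radius ``R``;
   the ratio ``alpha = (a/R)**3`` plays the role of the fill fraction.
3. ``composite_eps`` — a dilute suspension of such complex particles in
   a host liquid is homogenized with a Maxwell-Garnett-type mixing rule
   at volume fraction ``F``.

All permittivities are complex relative permittivities with the
``exp(-i*omega*t)`` sign convention: passive (absorbing) media have
``Im(eps) >= 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CoreShellGeometry",
    "CompositeSpec",
    "EffectiveMediumPoleError",
    "NoPhysicalRootError",
    "coreshell_eps",
    "coreshell_eps_f",
    "coated_grain_eps",
    "maxwell_garnett_eps",
    "composite_eps",
    "mg_residual",
]

MGVariant = Literal["paper", "standard"]


class EffectiveMediumPoleError(ZeroDivisionError):
    """The homogenization formula is evaluated at a pole (vanishing denominator)."""


class NoPhysicalRootError(RuntimeError):
    """Neither root of the mixing-rule quadratic is passive.

    Both candidate roots are attached as ``roots``.
    """

    def __init__(self, message: str, roots: tuple[complex, complex]):
        super().__init__(message)
        self.roots = roots


@dataclass(frozen=True)
class CoreShellGeometry:
    """Spherical core-shell geometry: core radius ``b`` inside outer radius ``a``.

    Radii are in nanometres.  The derived fill fraction ``f = (b/a)**3``
    is always computed from the exact radii, never from a rounded value.
    """

    b: float
    a: float

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise ValueError(f"core radius b must be positive, got {self.b}")
        if not (self.a >= self.b):
            raise ValueError(
                f"outer radius a={self.a} must be >= core radius b={self.b}"
            )

    @property
    def f(self) -> float:
        """Core fill fraction (b/a)**3, in (0, 1]."""
        return (self.b / self.a) ** 3

    @property
    def shell_thickness_nm(self) -> float:
        return self.a - self.b


def _check_pole(num: complex, den: complex, what: str) -> None:
    if abs(den) <= 1e-30 * max(1.0, abs(num)):
        raise EffectiveMediumPoleError(
            f"{what}: denominator vanishes (num={num!r}, den={den!r})"
        )


def coreshell_eps_f(f: float, eps_core: complex, eps_shell: complex) -> complex:
    """Effective permittivity of a core-shell sphere from its fill fraction.

    Internal homogenization of a coated sphere::

        eps_eff = eps_s * [(eps_c + 2 eps_s) + 2 f (eps_c - eps_s)]
                        / [(eps_c + 2 eps_s) -   f (eps_c - eps_s)]

    which is the ``a**3, b**3 -> 1, f`` form of the radius-explicit
    expression.  ``f = 0`` returns ``eps_shell`` exactly; ``eps_core ==
    eps_shell`` returns the common value for any ``f``.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fill fraction must lie in [0, 1], got {f}")
    ec = complex(eps_core)
    es = complex(eps_shell)
    if f == 0.0:
        return es
    s = ec + 2.0 * es
    d = ec - es
    num = es * (s + 2.0 * f * d)
    den = s - f * d
    _check_pole(num, den, "coreshell_eps")
    return num / den


def coreshell_eps(
    geom: CoreShellGeometry, eps_core: complex, eps_shell: complex
) -> complex:
    """Effective permittivity of a core-shell sphere with geometry ``geom``.

    Depends on (b, a) only through f = (b/a)**3: geometries with the same
    radius ratio give identical results.
    """
    return coreshell_eps_f(geom.f, eps_core, eps_shell)


def coated_grain_eps(eps1: complex, eps2: complex, alpha: float) -> complex:
    """Equivalent permittivity of a grain (``eps2``) wrapped in a shell (``eps1``).

    ``alpha = (a/R)**3`` is the volume fraction of the grain within the
    complex particle of outer radius ``R``::

        eps_n = eps1 * [(2 eps1 + eps2) + 2 alpha (eps2 - eps1)]
                     / [(2 eps1 + eps2) -   alpha (eps2 - eps1)]

    ``alpha = 1`` (zero-thickness shell) reduces algebraically to
    ``eps2`` — the numerator is ``3 eps1 eps2`` and the denominator
    ``3 eps1`` — and is short-circuited to return it exactly.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    e1 = complex(eps1)
    e2 = complex(eps2)
    if alpha == 1.0:
        return e2
    s = 2.0 * e1 + e2
    d = e2 - e1
    num = e1 * (s + 2.0 * alpha * d)
    den = s - alpha * d
    _check_pole(num, den, "coated_grain_eps")
    return num / den


@dataclass(frozen=True)
class CompositeSpec:
    """Inputs of the composite (complex particle + host) homogenization.

    eps_grain
        Permittivity of the scattered grain (the core-shell's effective
        permittivity).
    eps_shell
        Permittivity of the interfacial shell (the biomaterial).
    eps_host
        Permittivity of the host liquid (water).
    alpha
        Grain-to-complex-particle volume ratio (a/R)**3, in (0, 1].
    F
        Volume fraction of complex particles in the host, in [0, 1].
    """

    eps_grain: complex
    eps_shell: complex
    eps_host: complex
    alpha: float
    F: float
    im_tol: float = field(default=1e-12, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not (0.0 <= self.F <= 1.0):
            raise ValueError(f"volume fraction F must lie in [0, 1], got {self.F}")
        for label, eps in (
            ("eps_grain", self.eps_grain),
            ("eps_shell", self.eps_shell),
            ("eps_host", self.eps_host),
        ):
            if complex(eps).imag < -self.im_tol:
                raise ValueError(f"{label} must be passive (Im >= 0), got {eps}")

    @property
    def eps_n(self) -> complex:
        """Equivalent permittivity of the complex particle (grain + shell)."""
        return coated_grain_eps(self.eps_shell, self.eps_grain, self.alpha)


def _mg_coeffs(
    eps_n: complex, eps_m: complex, F: float, variant: MGVariant
) -> tuple[complex, complex, complex]:
    """Quadratic coefficients A x**2 + B x + C = 0 of the mixing relation.

    variant="paper" clears denominators of

        (1-F)(x - em)/(2x + em) + F (x - en)/(x + en) = 0

    variant="standard" uses the symmetric Maxwell-Garnett second term
    (x - en)/(en + 2x) instead.
    """
    en = complex(eps_n)
    em = complex(eps_m)
    if variant == "paper":
        A = 1.0 + F
        B = en * (1.0 - 3.0 * F) + em * (2.0 * F - 1.0)
        C = -em * en
    elif variant == "standard":
        A = 2.0 + 0.0j
        B = (1.0 - F) * (en - 2.0 * em) + F * (em - 2.0 * en)
        C = -em * en
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown Maxwell-Garnett variant {variant!r}")
    return A, B, C


def mg_residual(
    x: complex, eps_n: complex, eps_m: complex, F: float, variant: MGVariant = "paper"
) -> complex:
    """Residual of the mixing relation at candidate effective permittivity ``x``."""
    en = complex(eps_n)
    em = complex(eps_m)
    second_den = (x + en) if variant == "paper" else (en + 2.0 * x)
    return (1.0 - F) * (x - em) / (2.0 * x + em) + F * (x - en) / second_den


def _quadratic_roots(A: complex, B: complex, C: complex) -> tuple[complex, complex]:
    disc = np.sqrt(complex(B * B - 4.0 * A * C))
    # Citardauq pairing avoids cancellation for small roots.
    if abs(-B + disc) >= abs(-B - disc):
        r1 = (-B + disc) / (2.0 * A)
    else:
        r1 = (-B - disc) / (2.0 * A)
    r2 = C / (A * r1) if r1 != 0 else (-B - disc) / (2.0 * A)
    return r1, r2


def maxwell_garnett_eps(
    eps_inclusion: complex,
    eps_host: complex,
    F: float,
    variant: MGVariant = "paper",
    im_tol: float = 1e-12,
) -> complex:
    """Effective permittivity of inclusions at volume fraction ``F`` in a host.

    The mixing relation is quadratic in the unknown; the physical root is
    chosen by continuity in ``F``: starting from the exact ``F = 0``
    limit (the host itself), ``F`` is marched upward in small steps and
    at each step the root nearest the previous one is kept (homotopy
    tracking).  The selected root must also be passive
    (``Im >= -im_tol``); if the tracked root is not but the other is,
    the passive root is returned.  If neither root is passive a
    :class:`NoPhysicalRootError` carrying both roots is raised.

    Endpoints short-circuit: ``F = 0`` returns ``eps_host`` exactly and
    ``F = 1`` returns ``eps_inclusion`` exactly.
    """
    if not (0.0 <= F <= 1.0):
        raise ValueError(f"volume fraction F must lie in [0, 1], got {F}")
    en = complex(eps_inclusion)
    em = complex(eps_host)
    if F == 0.0:
        return em
    if F == 1.0:
        return en
    n_steps = max(2, int(math.ceil(F / 0.02)) + 1)
    prev = em
    for Fk in np.linspace(0.0, F, n_steps)[1:]:
        r1, r2 = _quadratic_roots(*_mg_coeffs(en, em, float(Fk), variant))
        prev = r1 if abs(r1 - prev) <= abs(r2 - prev) else r2
    r1, r2 = _quadratic_roots(*_mg_coeffs(en, em, F, variant))
    tracked, other = (r1, r2) if abs(r1 - prev) <= abs(r2 - prev) else (r2, r1)
    if tracked.imag < -im_tol:
        if other.imag >= -im_tol:
            tracked = other
        else:
            raise NoPhysicalRootError(
                "both mixing-rule roots have negative imaginary part "
                f"({r1!r}, {r2!r}) — no passive effective permittivity",
                (r1, r2),
            )
    return tracked


def composite_eps(spec: CompositeSpec, variant: MGVariant = "paper") -> complex:
    """Effective permittivity of the complex-particle/host composite.

    Convenience wrapper: homogenizes the grain + interfacial shell into
    the complex-particle permittivity and mixes it into the host at
    volume fraction ``spec.F``.
    """
    return maxwell_garnett_eps(
        spec.eps_n, spec.eps_host, spec.F, variant=variant, im_tol=spec.im_tol
    )
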