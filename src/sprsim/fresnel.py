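"""Plane-wave reflectivity of a stratified stack at fixed wavelength.

Attenuated-total-reflection geometry: the first layer is the incidence
half-space (a lossless prism), followed by any number of finite films,
ending in an exit half-space.  Two independent routes to the same
reflectivity are provided:

* :func:`reflection_coefficient` — the recursive two-interface Fresnel
  combination rule, folded from the exit side inward, with each film
  contributing a round-trip phase ``exp(2i kz d)``;
* :func:`transfer_matrix_reflection` — the classical 2x2 characteristic
  (Abeles) matrix method.

Both handle p- (transverse magnetic) and s- (transverse electric)
polarization; surface-plasmon work uses p.  The complex transverse
wavevector ``kz`` is always taken on the decaying branch
``Im(kz) >= 0`` so evanescent fields fall off away from an interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .materials import OpticalConstant

__all__ = [
    "Layer",
    "LayerStack",
    "AngularSpectrum",
    "GrazingSingularityError",
    "InvalidScanError",
    "kz",
    "interface_rp",
    "interface_rs",
    "reflection_coefficient",
    "reflectivity",
    "transfer_matrix_reflection",
    "transfer_matrix_reflectivity",
    "angular_scan",
]

Polarization = Literal["p", "s"]


class GrazingSingularityError(ZeroDivisionError):
    """An interface Fresnel coefficient has a vanishing denominator."""


class InvalidScanError(ValueError):
    """Angular-scan parameters produce an empty or unordered grid."""


@dataclass(frozen=True)
class Layer:
    """One stratum: a name, a complex permittivity, and a thickness.

    ``thickness_nm=None`` marks a semi-infinite half-space (only valid
    for the first and last layers of a stack).
    """

    name: str
    eps: complex
    thickness_nm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "eps", complex(self.eps))
        if self.thickness_nm is not None and self.thickness_nm < 0:
            raise ValueError(
                f"layer {self.name!r}: thickness must be >= 0, got {self.thickness_nm}"
            )

    @property
    def is_halfspace(self) -> bool:
        return self.thickness_nm is None

    @classmethod
    def from_index(
        cls, name: str, n: complex, thickness_nm: float | None = None
    ) -> "Layer":
        n = complex(n)
        return cls(name=name, eps=n * n, thickness_nm=thickness_nm)

    @classmethod
    def from_material(
        cls, name: str, optical: OpticalConstant, thickness_nm: float | None = None
    ) -> "Layer":
        return cls(name=name, eps=optical.eps, thickness_nm=thickness_nm)


@dataclass(frozen=True)
class LayerStack:
    """Ordered strata from the incidence side: prism, films, exit half-space."""

    wavelength_nm: float
    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not (self.wavelength_nm > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        if len(self.layers) < 2:
            raise ValueError("a stack needs at least two layers (two half-spaces)")
        first, last = self.layers[0], self.layers[-1]
        if not first.is_halfspace or not last.is_halfspace:
            raise ValueError("first and last layers must be half-spaces")
        if any(l.is_halfspace for l in self.layers[1:-1]):
            raise ValueError("interior layers must have a finite thickness")
        if abs(first.eps.imag) > 1e-12 or first.eps.real <= 0:
            raise ValueError(
                "incidence half-space must be a lossless dielectric so the "
                f"incidence angle is well defined; got eps={first.eps}"
            )

    @property
    def k0(self) -> float:
        """Vacuum wavenumber in nm^-1."""
        return 2.0 * np.pi / self.wavelength_nm

    @property
    def n_incident(self) -> float:
        return float(np.sqrt(self.layers[0].eps.real))

    def __iter__(self) -> Iterator[Layer]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)


def kz(eps: complex, kx: np.ndarray | float, k0: float) -> np.ndarray | complex:
    """Transverse wavevector ``sqrt(eps k0^2 - kx^2)`` on the decaying branch.

    The branch is fixed by ``Im(kz) >= 0``; when ``Im(kz) == 0`` (purely
    propagating) the forward branch ``Re(kz) >= 0`` is taken.
    """
    if not k0 > 0:
        raise ValueError(f"k0 must be positive, got {k0}")
    kx = np.asarray(kx, dtype=float)
    z = np.sqrt(complex(eps) * k0 * k0 - kx * kx + 0j)
    flip = (z.imag < 0) | ((z.imag == 0) & (z.real < 0))
    z = np.where(flip, -z, z)
    return z if z.ndim else complex(z)


def interface_rp(
    eps_i: complex, eps_j: complex, kz_i: np.ndarray, kz_j: np.ndarray
) -> np.ndarray:
    """p-polarized Fresnel amplitude at the i|j interface.

    ``r_ij = (kz_i eps_j - kz_j eps_i) / (kz_i eps_j + kz_j eps_i)``.
    """
    num = kz_i * eps_j - kz_j * eps_i
    den = kz_i * eps_j + kz_j * eps_i
    if np.any(den == 0):
        raise GrazingSingularityError("p-polarized interface coefficient pole")
    return num / den


def interface_rs(kz_i: np.ndarray, kz_j: np.ndarray) -> np.ndarray:
    """s-polarized Fresnel amplitude ``(kz_i - kz_j)/(kz_i + kz_j)``."""
    den = kz_i + kz_j
    if np.any(den == 0):
        raise GrazingSingularityError("s-polarized interface coefficient pole")
    return (kz_i - kz_j) / den


def _kx_and_kz(
    stack: LayerStack, theta_deg: np.ndarray | float
) -> tuple[np.ndarray, list[np.ndarray]]:
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(theta_deg < 0) or np.any(theta_deg >= 90):
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    theta = np.radians(theta_deg)
    kx = stack.k0 * stack.n_incident * np.sin(theta)
    kzs = [np.asarray(kz(layer.eps, kx, stack.k0)) for layer in stack]
    return kx, kzs


def reflection_coefficient(
    stack: LayerStack,
    theta_deg: np.ndarray | float,
    polarization: Polarization = "p",
) -> np.ndarray | complex:
    """Complex amplitude reflection coefficient by the recursive Fresnel rule.

    The two-interface combination
    ``r = (r_ij + r_sub e^{2i kz_j d_j}) / (1 + r_ij r_sub e^{2i kz_j d_j})``
    is folded from the exit half-space inward, one film at a time, which
    generalizes the three-medium formula to any number of layers.
    Accepts a scalar angle or an array of angles (degrees, measured in
    the prism).
    """
    scalar = np.isscalar(theta_deg) or np.ndim(theta_deg) == 0
    _, kzs = _kx_and_kz(stack, theta_deg)
    layers = stack.layers
    n = len(layers)

    def r_iface(i: int, j: int) -> np.ndarray:
        if polarization == "p":
            return interface_rp(layers[i].eps, layers[j].eps, kzs[i], kzs[j])
        return interface_rs(kzs[i], kzs[j])

    r = r_iface(n - 2, n - 1)
    for j in range(n - 3, -1, -1):
        phase = np.exp(2j * kzs[j + 1] * layers[j + 1].thickness_nm)
        rj = r_iface(j, j + 1)
        den = 1.0 + rj * r * phase
        if np.any(den == 0):
            raise GrazingSingularityError("recursive combination pole")
        r = (rj + r * phase) / den
    return complex(r) if scalar else r


def reflectivity(
    stack: LayerStack,
    theta_deg: np.ndarray | float,
    polarization: Polarization = "p",
) -> np.ndarray | float:
    """Energy reflectance ``|r|**2`` of the stack at the given angle(s)."""
    r = reflection_coefficient(stack, theta_deg, polarization)
    out = np.abs(np.asarray(r)) ** 2
    return float(out) if out.ndim == 0 else out


def transfer_matrix_reflection(
    stack: LayerStack,
    theta_deg: np.ndarray | float,
    polarization: Polarization = "p",
) -> np.ndarray | complex:
    """Amplitude reflection coefficient via the 2x2 characteristic matrix.

    Independent of the recursive route: the interior films are folded
    into one Abeles matrix ``M`` and the half-spaces closed with their
    tilted admittances ``q = kz/eps`` (p) or ``q = kz`` (s).
    """
    scalar = np.isscalar(theta_deg) or np.ndim(theta_deg) == 0
    _, kzs = _kx_and_kz(stack, theta_deg)
    layers = stack.layers

    def q(j: int) -> np.ndarray:
        return kzs[j] / layers[j].eps if polarization == "p" else kzs[j]

    shape = np.broadcast(kzs[0]).shape
    m00 = np.ones(shape, dtype=complex)
    m01 = np.zeros(shape, dtype=complex)
    m10 = np.zeros(shape, dtype=complex)
    m11 = np.ones(shape, dtype=complex)
    for j in range(1, len(layers) - 1):
        delta = kzs[j] * layers[j].thickness_nm
        c, s = np.cos(delta), np.sin(delta)
        qj = q(j)
        a00, a01 = c, -1j * s / qj
        a10, a11 = -1j * qj * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    qa, qb = q(0), q(len(layers) - 1)
    top = qa * (m00 + m01 * qb) - (m10 + m11 * qb)
    bot = qa * (m00 + m01 * qb) + (m10 + m11 * qb)
    if np.any(bot == 0):
        raise GrazingSingularityError("transfer-matrix closure pole")
    r = top / bot
    return complex(r) if scalar else r


def transfer_matrix_reflectivity(
    stack: LayerStack,
    theta_deg: np.ndarray | float,
    polarization: Polarization = "p",
) -> np.ndarray | float:
    r = transfer_matrix_reflection(stack, theta_deg, polarization)
    out = np.abs(np.asarray(r)) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AngularSpectrum:
    """Sampled reflectivity-versus-incidence-angle curve with scan metadata."""

    angles_deg: np.ndarray
    reflectivity: np.ndarray
    step_deg: float
    polarization: Polarization = "p"
    stack: LayerStack | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        r = np.asarray(self.reflectivity, dtype=float)
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "reflectivity", r)
        if a.shape != r.shape or a.ndim != 1 or a.size == 0:
            raise ValueError("angles and reflectivity must be equal-length 1-D arrays")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("reflectivity must be non-negative")

    def __len__(self) -> int:
        return self.angles_deg.size

    def to_csv(self, path: str | Path) -> None:
        """Write `angle_deg,reflectivity` rows at full double precision."""
        with open(path, "w", newline="\n") as fh:
            fh.write("angle_deg,reflectivity\n")
            for a, r in zip(self.angles_deg, self.reflectivity):
                fh.write(f"{a:.17g},{r:.17g}\n")


def angular_scan(
    stack: LayerStack,
    theta_min_deg: float = 40.0,
    theta_max_deg: float = 60.0,
    step_deg: float = 0.005,
    polarization: Polarization = "p",
) -> AngularSpectrum:
    """Evaluate the reflectivity on a closed uniform angular grid."""
    if not step_deg > 0:
        raise InvalidScanError(f"step must be positive, got {step_deg}")
    if not theta_min_deg < theta_max_deg:
        raise InvalidScanError(
            f"need theta_min < theta_max, got [{theta_min_deg}, {theta_max_deg}]"
        )
    n = int(np.floor((theta_max_deg - theta_min_deg) / step_deg + 1e-9)) + 1
    angles = theta_min_deg + step_deg * np.arange(n)
    refl = np.asarray(reflectivity(stack, angles, polarization))
    return AngularSpectrum(
        angles_deg=angles,
        reflectivity=refl,
        step_deg=step_deg,
        polarization=polarization,
        stack=stack,
    )
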