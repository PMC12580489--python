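"""Rank-2 (quadrupole) tensor algebra for distributed multipoles.

Two equivalent representations are used throughout:

* the five real spherical components ``(Q20, Q21c, Q21s, Q22c, Q22s)``
  in Stone's convention, units e·a0²;
* the symmetric traceless Cartesian tensor in the Buckingham convention,
  ``Θαβ = ½ Σ q (3 rα rβ − r² δαβ)``.

The linear map between them::

    Θzz = Q20            Θxz = (√3/2) Q21c      Θyz = (√3/2) Q21s
    Θxx − Θyy = √3 Q22c  Θxy = (√3/2) Q22s      Θxx + Θyy + Θzz = 0

The central operation is :func:`translate_quadrupole`: the rank-2
moment of a site-based multipole expansion about an arbitrary point.
Because the origin-shifted moment of rank ``l`` depends only on site
moments of rank ``<= l``, site ranks 3 and above never contribute and
are ignored (with a debug note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import to_bohr_factor
from .multipole import MultipoleSite

__all__ = [
    "SphericalQuadrupole",
    "CartesianQuadrupole",
    "angular_factor",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "magnitude",
    "rotate_site",
    "translate_quadrupole",
    "solid_harmonic_moments",
]

log = logging.getLogger(__name__)

_SQRT3 = np.sqrt(3.0)
_EYE = np.eye(3)


@dataclass(frozen=True)
class SphericalQuadrupole:
    """The five real spherical rank-2 components, e·a0²."""

    q20: float
    q21c: float
    q21s: float
    q22c: float
    q22s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q20, self.q21c, self.q21s, self.q22c, self.q22s])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "SphericalQuadrupole":
        a = np.asarray(a, dtype=float)
        if a.shape != (5,):
            raise ValueError("expected five spherical components")
        return cls(*a.tolist())

    @property
    def magnitude(self) -> float:
        """Euclidean norm of the five components (rotation invariant)."""
        return float(np.linalg.norm(self.as_array()))


@dataclass(frozen=True)
class CartesianQuadrupole:
    """Symmetric traceless Cartesian quadrupole (Buckingham convention), e·a0²."""

    xx: float
    yy: float
    zz: float
    xy: float
    xz: float
    yz: float

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.xx, self.xy, self.xz],
                [self.xy, self.yy, self.yz],
                [self.xz, self.yz, self.zz],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, *, rtol: float = 1e-8) -> "CartesianQuadrupole":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 matrix")
        scale = max(1.0, float(np.abs(m).max()))
        if np.abs(m - m.T).max() > rtol * scale:
            raise ValueError("quadrupole matrix must be symmetric")
        if abs(np.trace(m)) > rtol * scale:
            raise ValueError("quadrupole matrix must be traceless")
        return cls(m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2])


def angular_factor(theta):
    """The Legendre P2 weight (3 cos²θ − 1)/2 inside the Θzz integrand.

    Positive inside the cone θ < 54.7356° about the z-axis (and the
    mirror cone θ > 125.2644°), negative near the xy-plane, with range
    [−1/2, 1].
    """
    c = np.cos(theta)
    return 0.5 * (3.0 * c * c - 1.0)


def spherical_to_cartesian(q: SphericalQuadrupole) -> CartesianQuadrupole:
    """Convert spherical components to the traceless Cartesian tensor."""
    zz = q.q20
    xz = 0.5 * _SQRT3 * q.q21c
    yz = 0.5 * _SQRT3 * q.q21s
    xy = 0.5 * _SQRT3 * q.q22s
    xx = 0.5 * (_SQRT3 * q.q22c - q.q20)
    yy = 0.5 * (-_SQRT3 * q.q22c - q.q20)
    return CartesianQuadrupole(xx, yy, zz, xy, xz, yz)


def cartesian_to_spherical(c: CartesianQuadrupole) -> SphericalQuadrupole:
    """Inverse of :func:`spherical_to_cartesian`."""
    return SphericalQuadrupole(
        q20=c.zz,
        q21c=2.0 / _SQRT3 * c.xz,
        q21s=2.0 / _SQRT3 * c.yz,
        q22c=(c.xx - c.yy) / _SQRT3,
        q22s=2.0 / _SQRT3 * c.xy,
    )


def magnitude(q: SphericalQuadrupole) -> float:
    """|Q2|: Euclidean norm of the five spherical components."""
    return q.magnitude


def _check_rotation(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if np.abs(r @ r.T - _EYE).max() > 1e-10:
        raise ValueError("rotation matrix is not orthogonal")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation matrix must be proper (det +1)")
    return r


def rotate_site(site: MultipoleSite, r: np.ndarray) -> MultipoleSite:
    """Rotate a site (position and multipoles of rank <= 2) by ``r``.

    Rank 0 is a scalar; rank 1 rotates as the Cartesian vector
    (Q11c, Q11s, Q10); rank 2 via Cartesian conjugation Θ' = RΘRᵀ.
    Components of rank >= 3 are carried over unrotated (they are never
    used downstream) with a debug-level note.
    """
    r = _check_rotation(r)
    comps = site.components.copy()
    if site.max_rank >= 1:
        mu = r @ site.dipole
        comps[1], comps[2], comps[3] = mu[2], mu[0], mu[1]
    if site.max_rank >= 2:
        theta = spherical_to_cartesian(SphericalQuadrupole.from_array(site.components[4:9]))
        rotated = r @ theta.as_matrix() @ r.T
        comps[4:9] = cartesian_to_spherical(CartesianQuadrupole.from_matrix(rotated)).as_array()
    if site.max_rank >= 3:
        log.debug("site %s: ranks >= 3 left unrotated (unused by rank-2 descriptors)", site.label)
    return MultipoleSite(site.label, r @ site.position, site.max_rank, comps)


def translate_quadrupole(
    sites: Sequence[MultipoleSite],
    point: Sequence[float],
    length_unit: str | None = None,
) -> SphericalQuadrupole:
    """Total rank-2 moment of a site expansion about ``point``.

    With ``a = r_site − point`` (in bohr), charge ``q``, dipole ``μ`` and
    site quadrupole ``Θ(site)``, each site contributes::

        Θαβ(point) = Θαβ(site)
                   + (3/2)(aα μβ + aβ μα) − (a·μ) δαβ
                   + (q/2)(3 aα aβ − |a|² δαβ)

    Contributions sum over sites; the result is returned in spherical
    components (e·a0²).  ``point`` must be given in the same unit as the
    site positions, declared via ``length_unit`` — this is exactly the
    rank-2 moment of the underlying charge distribution about ``point``
    whenever site ranks <= 2 describe it fully.
    """
    if length_unit is None:
        raise ValueError("length_unit metadata is required to translate multipoles")
    scale = to_bohr_factor(length_unit)
    point = np.asarray(point, dtype=float)
    if point.shape != (3,):
        raise ValueError("evaluation point must be a 3-vector")
    total = np.zeros((3, 3))
    saw_high_rank = False
    for site in sites:
        a = (site.position - point) * scale
        q = site.monopole
        mu = site.dipole
        theta_site = spherical_to_cartesian(
            SphericalQuadrupole.from_array(site.quadrupole5)
        ).as_matrix()
        a_outer = np.outer(a, a)
        amu = np.outer(a, mu)
        total += (
            theta_site
            + 1.5 * (amu + amu.T)
            - np.dot(a, mu) * _EYE
            + 0.5 * q * (3.0 * a_outer - np.dot(a, a) * _EYE)
        )
        saw_high_rank = saw_high_rank or site.max_rank >= 3
    if saw_high_rank:
        log.debug("site ranks >= 3 do not contribute to the translated rank-2 moment")
    return cartesian_to_spherical(CartesianQuadrupole.from_matrix(total))


def solid_harmonic_moments(position: Sequence[float]) -> np.ndarray:
    """Regular real solid harmonics through rank 2 at ``position`` (bohr).

    Returns the 9 Stone-ordered values for a unit point charge::

        R00 = 1
        R10 = z, R11c = x, R11s = y
        R20 = (3z² − r²)/2, R21c = √3 xz, R21s = √3 yz,
        R22c = (√3/2)(x² − y²), R22s = √3 xy

    Multiply by a charge q to get that charge's multipole components
    about the expansion origin.
    """
    x, y, z = np.asarray(position, dtype=float)
    r2 = x * x + y * y + z * z
    return np.array(
        [
            1.0,
            z, x, y,
            0.5 * (3.0 * z * z - r2),
            _SQRT3 * x * z,
            _SQRT3 * y * z,
            0.5 * _SQRT3 * (x * x - y * y),
            _SQRT3 * x * y,
        ]
    )
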