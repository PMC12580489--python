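"""The six quadrupole-tensor aromaticity descriptors.

For a ring molecule whose geometric ring center sits at the origin with
the ring in the xy-plane, the descriptors are

==================  =====================================================
``Q2_ring_atoms``   sum over ring atoms of the per-site |Q2| magnitude
``Q2zz_ring_atoms`` sum over ring atoms of the per-site Q20 (= Qzz)
``Q2_origin``       |Q2| of all sites' moments translated to (0,0,0)
``Q2zz_origin``     Q20 of the same translated tensor
``Q2_1``            |Q2| of all sites translated to (0, 0, 1 Å)
``Q2_1zz``          Q20 of the same tensor at (0, 0, 1 Å)
==================  =====================================================

all in e·a0².  ``Q2_1zz`` probes the out-of-plane (π) electron density
1 Å above the ring center.  Raw values are usually reported relative to
a reference molecule (benzene), which then scores exactly 1 on every
descriptor.

The ring-atom sums use per-site magnitudes; the origin / 1 Å values use
the magnitude of the *summed translated* tensor.  The alternative
reading (magnitude of the summed per-ring-atom tensor) is isolated in
:func:`ring_atom_sums` so it can be flipped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import BOHR_PER_ANGSTROM
from .multipole import MoleculeMultipoles
from .quadrupole import rotate_site, translate_quadrupole

__all__ = [
    "DESCRIPTOR_NAMES",
    "DescriptorSet",
    "ZScanProfile",
    "DegenerateRingError",
    "canonicalize",
    "is_canonical",
    "compute_descriptors",
    "normalize",
    "scan_z",
    "descriptor_frame",
]

#: canonical column order of the descriptor report
DESCRIPTOR_NAMES = (
    "Q2_ring_atoms",
    "Q2zz_ring_atoms",
    "Q2_origin",
    "Q2zz_origin",
    "Q2_1",
    "Q2_1zz",
)


class DegenerateRingError(ValueError):
    """Ring atoms are collinear/degenerate: no unique best-fit plane."""


@dataclass
class DescriptorSet:
    """The six descriptors of one molecule, raw and optionally normalized."""

    name: str
    Q2_ring_atoms: float
    Q2zz_ring_atoms: float
    Q2_origin: float
    Q2zz_origin: float
    Q2_1: float
    Q2_1zz: float
    normalized: dict[str, float] | None = None
    reference_name: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in DESCRIPTOR_NAMES])

    def as_series(self) -> pd.Series:
        data = self.as_dict()
        if self.normalized is not None:
            data.update({f"{k}_norm": v for k, v in self.normalized.items()})
        return pd.Series(data, name=self.name)


@dataclass
class ZScanProfile:
    """|Q2| and Q20 of the translated total quadrupole along the ring normal."""

    z: np.ndarray          # grid, angstrom
    q2: np.ndarray         # |Q2|(z), e·a0²
    q2zz: np.ndarray       # Q20(z), e·a0²

    def __post_init__(self) -> None:
        if not (len(self.z) == len(self.q2) == len(self.q2zz)):
            raise ValueError("z-scan series lengths differ")

    @property
    def z_max_q2(self) -> float:
        """Grid z maximizing |Q2|; ties break toward smaller z."""
        return float(self.z[int(np.argmax(self.q2))])

    @property
    def z_max_q2zz(self) -> float:
        """Grid z maximizing Q20; ties break toward smaller z."""
        return float(self.z[int(np.argmax(self.q2zz))])


# ---------------------------------------------------------------------------
# frame canonicalization
# ---------------------------------------------------------------------------

def _ring_plane_normal(centered: np.ndarray) -> np.ndarray:
    """Best-fit plane normal of centered ring coordinates (smallest principal axis)."""
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[1] <= 1e-10 * max(w[2], 1e-30):
        raise DegenerateRingError("ring atoms are collinear or coincident; no unique plane")
    n = v[:, 0]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return n


def _rotation_to_z(n: np.ndarray) -> np.ndarray:
    """Minimal proper rotation mapping unit vector ``n`` onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(np.dot(n, z))
    if s < 1e-14:
        if c > 0:
            return np.eye(3)
        # n = -z: rotate by pi about x
        return np.diag([1.0, -1.0, -1.0])
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / (s * s))


def canonicalize(mol: MoleculeMultipoles, tol: float = 1e-8) -> MoleculeMultipoles:
    """Shift the ring centroid to the origin and rotate the ring plane to xy.

    The plane is the best-fit plane of the ring atoms (smallest principal
    direction of their centered coordinates); its normal is aligned with
    +z with a deterministic sign convention.  All site positions and
    multipole components (ranks <= 2) are moved consistently.
    """
    if not mol.ring_atom_indices:
        raise ValueError(f"{mol.name}: ring_atom_indices must be set before canonicalization")
    ring = mol.positions[mol.ring_atom_indices]
    centroid = ring.mean(axis=0)
    n = _ring_plane_normal(ring - centroid)
    r = _rotation_to_z(n)
    shifted = [replace(s, position=s.position - centroid) for s in mol.sites]
    rotated = [rotate_site(s, r) for s in shifted]
    out = replace(mol, sites=rotated)
    # internal consistency check of the postcondition
    assert is_canonical(out, tol=max(tol, 1e-8)), "canonicalization postcondition failed"
    return out


def is_canonical(mol: MoleculeMultipoles, tol: float = 1e-8) -> bool:
    """True when the ring centroid is at the origin (within ``tol``, in the
    molecule's own unit) and the best-fit ring plane normal is ±z."""
    if not mol.ring_atom_indices:
        return False
    ring = mol.positions[mol.ring_atom_indices]
    centroid = ring.mean(axis=0)
    if np.linalg.norm(centroid) > tol:
        return False
    n = _ring_plane_normal(ring - centroid)
    return abs(abs(n[2]) - 1.0) <= max(tol, 1e-10)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def ring_atom_sums(mol: MoleculeMultipoles) -> tuple[float, float]:
    """(sum of per-ring-atom |Q2|, sum of per-ring-atom Q20).

    This is the single place encoding the per-site-magnitude reading of
    the ring-atom descriptors; switch here to change conventions.
    """
    mag = 0.0
    qzz = 0.0
    for i in mol.ring_atom_indices:
        q5 = mol.sites[i].quadrupole5
        mag += float(np.linalg.norm(q5))
        qzz += float(q5[0])
    return mag, qzz


def compute_descriptors(
    mol: MoleculeMultipoles, *, require_canonical: bool = True
) -> DescriptorSet:
    """Compute the six descriptors of a canonical molecule."""
    if not mol.ring_atom_indices:
        raise ValueError(f"{mol.name}: ring_atom_indices must be set")
    if require_canonical and not is_canonical(mol, tol=1e-6):
        raise ValueError(
            f"{mol.name}: molecule is not canonical (run canonicalize first)"
        )
    ring_mag, ring_qzz = ring_atom_sums(mol)
    at_origin = translate_quadrupole(mol.sites, np.zeros(3), mol.length_unit)
    z1 = 1.0 if mol.length_unit == "angstrom" else BOHR_PER_ANGSTROM
    at_1A = translate_quadrupole(mol.sites, np.array([0.0, 0.0, z1]), mol.length_unit)
    return DescriptorSet(
        name=mol.name,
        Q2_ring_atoms=ring_mag,
        Q2zz_ring_atoms=ring_qzz,
        Q2_origin=at_origin.magnitude,
        Q2zz_origin=at_origin.q20,
        Q2_1=at_1A.magnitude,
        Q2_1zz=at_1A.q20,
    )


def normalize(dset: DescriptorSet, reference: DescriptorSet) -> DescriptorSet:
    """Divide each descriptor by the reference molecule's value.

    The reference normalized against itself scores exactly 1.0 on every
    descriptor.  A zero reference component makes the ratio undefined and
    raises ``ZeroDivisionError`` naming the descriptor.
    """
    normalized = {}
    for key in DESCRIPTOR_NAMES:
        ref = getattr(reference, key)
        if ref == 0.0:
            raise ZeroDivisionError(
                f"reference {reference.name!r} has zero {key}; normalization undefined"
            )
        normalized[key] = getattr(dset, key) / ref
    return replace(dset, normalized=normalized, reference_name=reference.name)


def scan_z(
    mol: MoleculeMultipoles,
    z_min: float = 0.1,
    z_max: float = 3.0,
    step: float = 0.05,
) -> ZScanProfile:
    """Profile |Q2|(z) and Q20(z) on the +z axis above the ring center.

    The grid is ``z_min, z_min + step, ..., z_max`` in angstrom.  Only the
    +z face is scanned; for a ring-plane-symmetric molecule the −z face is
    redundant.
    """
    if not (z_min < z_max) or step <= 0:
        raise ValueError("need z_min < z_max and step > 0")
    count = int(np.floor((z_max - z_min) / step + 1e-9)) + 1
    if count < 1:
        raise ValueError("empty z grid")
    z = z_min + step * np.arange(count)
    unit_scale = 1.0 if mol.length_unit == "angstrom" else BOHR_PER_ANGSTROM
    q2 = np.empty(count)
    q2zz = np.empty(count)
    for i, zi in enumerate(z):
        q = translate_quadrupole(
            mol.sites, np.array([0.0, 0.0, zi * unit_scale]), mol.length_unit
        )
        q2[i] = q.magnitude
        q2zz[i] = q.q20
    return ZScanProfile(z=z, q2=q2, q2zz=q2zz)


def descriptor_frame(dsets: Sequence[DescriptorSet]) -> pd.DataFrame:
    """Assemble descriptor sets into a molecules-by-descriptors DataFrame."""
    if not dsets:
        raise ValueError("no descriptor sets given")
    df = pd.DataFrame([d.as_series() for d in dsets])
    df.index.name = "name"
    return df
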