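"""Synthetic multipole, energy and descriptor generators with exact oracles.

These generators stand in for quantum-chemistry inputs: ring-shaped site
arrangements carrying monopole/dipole/quadrupole moments (with exact
point-charge oracles), in-plane charged substituents that reproduce the
angular-factor sign artifact, energy triples with IP > EA, and a
four-group descriptor matrix with the neutral / quinoidal / cationic /
anionic cluster structure.  Every generator is a pure function of its
seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .descriptors import DESCRIPTOR_NAMES
from .multipole import (
    EnergyRecord,
    MoleculeMultipoles,
    MultipoleSite,
    write_energy_table,
    write_punch,
)
from .quadrupole import solid_harmonic_moments

import pandas as pd

__all__ = [
    "RingSpec",
    "ClusterSpec",
    "GROUP_MEANS",
    "make_point_charge_molecule",
    "make_ring_molecule",
    "make_cluster_dataset",
    "make_energy_records",
    "write_fixture_set",
]


@dataclass
class RingSpec:
    """Specification of a synthetic planar ring molecule.

    The defaults emulate a benzene-like six-site ring of C—C radius
    1.39 Å whose ring atoms each carry an axial site quadrupole
    Q20 = −0.35 e·a0² (negative out-of-plane component, as π density
    above/below each carbon produces).  Options add per-site out-of-plane
    ± charge pairs (a z-dipole per site, giving the translated tensor a
    z-dependence), and one in-plane substituent site carrying net charge
    and/or a dipole at a chosen distance from the ring center.
    """

    n_ring_sites: int = 6
    radius: float = 1.39                    # angstrom
    site_charge: float = 0.0                # e, per ring site
    site_q20: float = -0.35                 # e·a0², per ring site
    pi_pair_charge: float = 0.0             # e: +q at +h, −q at −h per site
    pi_pair_height: float = 0.5             # angstrom
    substituent_distance: float | None = None   # angstrom from ring center
    substituent_charge: float = 0.0         # e
    substituent_dipole: tuple[float, float, float] = (0.0, 0.0, 0.0)  # e·a0
    name: str = "ring"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ring_sites < 3:
            raise ValueError("need at least 3 ring sites")
        if self.radius <= 0:
            raise ValueError("ring radius must be positive")
        if self.substituent_distance is not None and self.substituent_distance <= 0:
            raise ValueError("substituent distance must be positive")


@dataclass
class ClusterSpec:
    """Specification of the four-group synthetic descriptor matrix.

    Group means live in benzene-normalized 6-descriptor space.  The
    defaults place a tight neutral group at ~1, a quinoidal group with
    depressed out-of-plane entries, a cationic group below 1 and an
    anionic group above 1 — the qualitative ordering
    anionic > neutral > quinoidal ≈ cationic.
    """

    means: dict[str, Sequence[float]] = field(default_factory=lambda: dict(GROUP_MEANS))
    sigma: float = 0.01
    sizes: dict[str, int] | int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.means) < 2:
            raise ValueError("need at least two groups")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for g, m in self.means.items():
            if len(m) != len(DESCRIPTOR_NAMES):
                raise ValueError(f"group {g!r}: mean must have {len(DESCRIPTOR_NAMES)} entries")

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.sizes, int):
            return {g: self.sizes for g in self.means}
        return dict(self.sizes)


GROUP_MEANS: dict[str, tuple[float, ...]] = {
    "neutral": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    "quinoidal": (0.95, 0.90, 0.96, 0.92, 0.88, 0.82),
    "cationic": (0.80, 0.72, 0.85, 0.70, 0.78, 0.65),
    "anionic": (1.22, 1.35, 1.18, 1.30, 1.20, 1.40),
}


def _charge_site(label: str, position, q: float) -> MultipoleSite:
    return MultipoleSite(label, np.asarray(position, float), 0, np.array([q]))


def make_point_charge_molecule(
    n: int, box: float = 2.0, seed: int = 0
) -> tuple[MoleculeMultipoles, Callable[[Sequence[float]], np.ndarray]]:
    """Random point charges plus a brute-force quadrupole oracle.

    Returns ``(molecule, oracle)`` where the molecule holds ``n`` rank-0
    sites with positions uniform in ``[−box, box]³`` bohr and charges
    uniform in ``[−1, 1]`` e, and ``oracle(point)`` is the direct charge
    sum ``Θαβ = ½ Σ q (3 aα aβ − |a|² δαβ)`` (3×3 array, e·a0²) about
    ``point`` (bohr) — independent of the multipole-translation code
    path.
    """
    if n < 1:
        raise ValueError("need at least one charge")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-box, box, size=(n, 3))
    q = rng.uniform(-1.0, 1.0, size=n)
    sites = [_charge_site(f"X{i}", pos[i], q[i]) for i in range(n)]
    mol = MoleculeMultipoles(
        name=f"charges{n}", sites=sites, ring_atom_indices=[], length_unit="bohr"
    )

    def oracle(point) -> np.ndarray:
        p = np.asarray(point, float)
        total = np.zeros((3, 3))
        for qi, ri in zip(q, pos):
            a = ri - p
            total += 0.5 * qi * (3.0 * np.outer(a, a) - float(a @ a) * np.eye(3))
        return total

    return mol, oracle


def make_ring_molecule(spec: RingSpec) -> MoleculeMultipoles:
    """Build the canonical planar ring molecule described by ``spec``.

    Ring sites come first (indices ``0 .. n_ring_sites−1``); optional
    π-emulating ± charge pairs and the substituent site follow.  The
    molecule is already canonical: ring centroid at the origin, ring in
    the xy-plane.
    """
    n = spec.n_ring_sites
    angles = 2.0 * np.pi * np.arange(n) / n
    sites: list[MultipoleSite] = []
    for i, a in enumerate(angles):
        pos = np.array([spec.radius * np.cos(a), spec.radius * np.sin(a), 0.0])
        comps = np.zeros(9)
        comps[0] = spec.site_charge
        comps[4] = spec.site_q20
        sites.append(MultipoleSite(f"C{i + 1}", pos, 2, comps))
    if spec.pi_pair_charge != 0.0:
        h = spec.pi_pair_height
        for i, a in enumerate(angles):
            x, y = spec.radius * np.cos(a), spec.radius * np.sin(a)
            sites.append(_charge_site(f"Pu{i + 1}", [x, y, h], spec.pi_pair_charge))
            sites.append(_charge_site(f"Pd{i + 1}", [x, y, -h], -spec.pi_pair_charge))
    net_charge = 0.0
    if spec.substituent_distance is not None:
        comps = np.zeros(9)
        comps[0] = spec.substituent_charge
        mux, muy, muz = spec.substituent_dipole
        comps[1], comps[2], comps[3] = muz, mux, muy
        sites.append(
            MultipoleSite("Sub", np.array([spec.substituent_distance, 0.0, 0.0]), 2, comps)
        )
        net_charge = spec.substituent_charge
    return MoleculeMultipoles(
        name=spec.name,
        sites=sites,
        ring_atom_indices=list(range(n)),
        length_unit="angstrom",
        net_charge=int(round(net_charge)),
    )


def make_cluster_dataset(spec: ClusterSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian descriptor groups emulating the four-cluster structure.

    Returns ``(table, labels)``: a molecules × six-descriptor DataFrame
    and the generating group name per row.  With group separation well
    above ``sigma`` the Ward/k-cut pipeline recovers the labels exactly.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.group_sizes()
    rows, names, labels = [], [], []
    for group, mean in spec.means.items():
        mean = np.asarray(mean, float)
        for i in range(sizes[group]):
            rows.append(rng.normal(mean, spec.sigma))
            names.append(f"{group}_{i + 1:02d}")
            labels.append(group)
    table = pd.DataFrame(rows, index=names, columns=list(DESCRIPTOR_NAMES))
    table.index.name = "name"
    return table, pd.Series(labels, index=names, name="group")


def make_energy_records(n: int, seed: int = 0) -> list[EnergyRecord]:
    """Energy triples (hartree) with IP > EA > unbound range guaranteed.

    Neutral energies spread over a benzene-derivative-like range around
    −230 Ha; IP drawn from U(0.20, 0.40) Ha and EA from U(−0.05, 0.12) Ha
    so that IP > EA (positive hardness) always holds.
    """
    if n < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        e0 = -230.0 - 15.0 * rng.random()
        ip = rng.uniform(0.20, 0.40)
        ea = rng.uniform(-0.05, 0.12)
        records.append(
            EnergyRecord(name=f"mol_{i + 1:02d}", E_neutral=e0, E_cation=e0 + ip, E_anion=e0 - ea)
        )
    return records


def write_fixture_set(outdir, n_variants: int = 15, seed: int = 0) -> dict:
    """Emit a self-contained synthetic study into ``outdir``.

    Writes a benzene-like reference punch file plus ``n_variants``
    perturbed rings (scaled site quadrupoles; a third of them get an
    in-plane charged substituent) and a matching energy table.  Returns
    the molecule names and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    molecules = [make_ring_molecule(RingSpec(name="benzene"))]
    for i in range(n_variants):
        scale = rng.uniform(0.7, 1.3)
        sub_d = None
        sub_q = 0.0
        if i % 3 == 2:
            sub_d = 2.4
            sub_q = float(rng.choice([-0.3, 0.3]))
        molecules.append(
            make_ring_molecule(
                RingSpec(
                    name=f"variant_{i + 1:02d}",
                    site_q20=-0.35 * scale,
                    substituent_distance=sub_d,
                    substituent_charge=sub_q,
                )
            )
        )
    paths = []
    for mol in molecules:
        p = outdir / f"{mol.name}.punch"
        write_punch(mol, p)
        paths.append(p)
    records = make_energy_records(len(molecules), seed=seed)
    for rec, mol in zip(records, molecules):
        rec.name = mol.name
    energy_path = outdir / "energies.csv"
    write_energy_table(records, energy_path)
    return {
        "names": [m.name for m in molecules],
        "punch_files": paths,
        "energy_table": energy_path,
        "reference": "benzene",
    }
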