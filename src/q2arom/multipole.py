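"""Domain types and text I/O for distributed-multipole data.

A molecule is a list of expansion sites, each carrying real spherical
multipole components in Stone ordering::

    rank 0:  Q00
    rank 1:  Q10, Q11c, Q11s
    rank 2:  Q20, Q21c, Q21s, Q22c, Q22s
    rank l:  Ql0, Ql1c, Ql1s, ..., Qllc, Qlls

Components are in atomic units (e·a0^l); positions in angstrom or bohr,
recorded per molecule.

Punch dialect
-------------
The reader/writer speak one precisely documented punch-style grammar:

* ``!`` starts a comment (to end of line); blank lines are ignored.
* Optional metadata lines before the first site, in any order::

      units angstrom|bohr
      name <text>
      charge <integer>
      ring <i> <j> ... (0-based site indices, spaces or commas)

* Per site: a header line ``label  x  y  z  rank k`` followed by
  ``(k+1)**2`` whitespace-separated component values, over any number of
  lines.
* Anything after the last complete site that is not a comment is an
  error, not silently ignored.
* When no ``units`` line is present the positions default to angstrom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, LENGTH_UNITS

__all__ = [
    "MultipoleSite",
    "MoleculeMultipoles",
    "EnergyRecord",
    "PunchParseError",
    "SiteHeaderError",
    "ComponentCountError",
    "UnitError",
    "parse_multipole_file",
    "write_punch",
    "read_punch_file",
    "read_energy_table",
    "write_energy_table",
    "read_descriptor_table",
    "write_descriptor_report",
    "find_ring_atoms",
]


class PunchParseError(ValueError):
    """Malformed punch-dialect input."""


class SiteHeaderError(PunchParseError):
    """A site header line does not match ``label x y z rank k``."""


class ComponentCountError(PunchParseError):
    """Component values inconsistent with a site's declared rank."""


class UnitError(PunchParseError):
    """Unknown length-unit keyword."""


@dataclass
class MultipoleSite:
    """One multipole expansion center.

    Parameters
    ----------
    label : str
        Short identifier, conventionally element symbol plus index.
    position : (3,) array
        Site coordinates; unit owned by the parent molecule.
    max_rank : int
        Highest multipole rank carried (``>= 0``).
    components : ((max_rank+1)**2,) array
        Real spherical components in Stone ordering, atomic units.
    """

    label: str
    position: np.ndarray
    max_rank: int
    components: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"site {self.label!r}: position must be a 3-vector")
        if self.max_rank < 0:
            raise ValueError(f"site {self.label!r}: max_rank must be >= 0")
        n_expected = (self.max_rank + 1) ** 2
        if self.components.shape != (n_expected,):
            raise ValueError(
                f"site {self.label!r}: rank {self.max_rank} requires "
                f"{n_expected} components, got {self.components.shape}"
            )
        low = self.components[: min(9, n_expected)]
        if not np.all(np.isfinite(low)):
            raise ValueError(f"site {self.label!r}: non-finite component of rank <= 2")

    @property
    def monopole(self) -> float:
        """Site charge Q00 (e)."""
        return float(self.components[0])

    @property
    def dipole(self) -> np.ndarray:
        """Cartesian dipole vector (μx, μy, μz) = (Q11c, Q11s, Q10), e·a0."""
        if self.max_rank < 1:
            return np.zeros(3)
        c = self.components
        return np.array([c[2], c[3], c[1]])

    @property
    def quadrupole5(self) -> np.ndarray:
        """The five rank-2 components (Q20, Q21c, Q21s, Q22c, Q22s), e·a0²."""
        if self.max_rank < 2:
            return np.zeros(5)
        return self.components[4:9].copy()


@dataclass
class MoleculeMultipoles:
    """A molecule as a set of multipole sites plus ring designation."""

    name: str
    sites: list[MultipoleSite]
    ring_atom_indices: list[int] = field(default_factory=list)
    length_unit: str = "angstrom"
    net_charge: int = 0

    def __post_init__(self) -> None:
        if self.length_unit not in LENGTH_UNITS:
            raise UnitError(f"unknown length unit {self.length_unit!r}")
        idx = list(self.ring_atom_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("ring_atom_indices must be distinct")
        for i in idx:
            if not 0 <= i < len(self.sites):
                raise ValueError(f"ring atom index {i} out of range")
        self.ring_atom_indices = idx

    @property
    def positions(self) -> np.ndarray:
        """(n_sites, 3) position array in ``length_unit``."""
        return np.array([s.position for s in self.sites])

    def to_unit(self, unit: str) -> "MoleculeMultipoles":
        """Return a copy with positions converted to ``unit``.

        Multipole components are always atomic units and are untouched.
        """
        if unit not in LENGTH_UNITS:
            raise UnitError(f"unknown length unit {unit!r}")
        if unit == self.length_unit:
            return replace(self, sites=[replace(s) for s in self.sites])
        factor = BOHR_PER_ANGSTROM if unit == "bohr" else ANGSTROM_PER_BOHR
        sites = [replace(s, position=s.position * factor) for s in self.sites]
        return replace(self, sites=sites, length_unit=unit)


@dataclass
class EnergyRecord:
    """Total electronic energies (hartree) of one species' three charge states."""

    name: str
    E_neutral: float
    E_cation: float
    E_anion: float

    def __post_init__(self) -> None:
        for attr in ("E_neutral", "E_cation", "E_anion"):
            if not np.isfinite(getattr(self, attr)):
                raise ValueError(f"{self.name}: {attr} is not finite")


# ---------------------------------------------------------------------------
# punch-dialect parsing / writing
# ---------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eEdD][-+]?\d+)?$")


def _is_float(token: str) -> bool:
    return bool(_FLOAT_RE.match(token))


def _to_float(token: str) -> float:
    return float(token.replace("d", "e").replace("D", "E"))


def _logical_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("!", 1)[0].strip()
        if stripped:
            yield lineno, stripped.replace(",", " ").split()


def parse_multipole_file(
    text: str,
    *,
    name: str | None = None,
    ring_atom_indices: Sequence[int] | None = None,
    net_charge: int | None = None,
    default_unit: str = "angstrom",
) -> MoleculeMultipoles:
    """Parse punch-dialect ``text`` into a :class:`MoleculeMultipoles`.

    Keyword arguments override metadata found in the file; metadata in the
    file overrides the defaults (name ``"molecule"``, no ring designation,
    charge 0, positions in ``default_unit``).
    """
    lines = list(_logical_lines(text))
    meta: dict = {}
    i = 0
    while i < len(lines):
        lineno, toks = lines[i]
        kw = toks[0].lower()
        if kw == "units":
            if len(toks) != 2:
                raise UnitError(f"line {lineno}: expected 'units angstrom|bohr'")
            unit = toks[1].lower()
            if unit not in LENGTH_UNITS:
                raise UnitError(f"line {lineno}: unknown unit keyword {toks[1]!r}")
            meta["units"] = unit
        elif kw == "name" and len(toks) >= 2:
            meta["name"] = " ".join(toks[1:])
        elif kw == "charge" and len(toks) == 2:
            try:
                meta["charge"] = int(toks[1])
            except ValueError as exc:
                raise PunchParseError(f"line {lineno}: charge must be an integer") from exc
        elif kw == "ring":
            try:
                meta["ring"] = [int(t) for t in toks[1:]]
            except ValueError as exc:
                raise PunchParseError(f"line {lineno}: ring indices must be integers") from exc
        else:
            break
        i += 1

    sites: list[MultipoleSite] = []
    while i < len(lines):
        lineno, toks = lines[i]
        if len(toks) != 6 or toks[4].lower() != "rank":
            raise SiteHeaderError(
                f"line {lineno}: expected site header 'label x y z rank k' "
                f"(or end of file), got {' '.join(toks)!r}"
            )
        label = toks[0]
        try:
            xyz = [_to_float(t) for t in toks[1:4]]
        except ValueError as exc:
            raise SiteHeaderError(f"line {lineno}: non-numeric coordinate in site header") from exc
        try:
            rank = int(toks[5])
        except ValueError as exc:
            raise SiteHeaderError(f"line {lineno}: rank must be an integer") from exc
        if rank < 0:
            raise SiteHeaderError(f"line {lineno}: rank must be >= 0")
        need = (rank + 1) ** 2
        values: list[float] = []
        i += 1
        while len(values) < need and i < len(lines):
            vlineno, vtoks = lines[i]
            if not all(_is_float(t) for t in vtoks):
                break
            if len(values) + len(vtoks) > need:
                raise ComponentCountError(
                    f"line {vlineno}: site {label!r} (rank {rank}) expects {need} "
                    f"components but more were supplied"
                )
            values.extend(_to_float(t) for t in vtoks)
            i += 1
        if len(values) != need:
            raise ComponentCountError(
                f"line {lineno}: site {label!r} declares rank {rank} "
                f"({need} components) but only {len(values)} were read"
            )
        sites.append(MultipoleSite(label, np.array(xyz), rank, np.array(values)))

    if not sites:
        raise PunchParseError("no multipole sites found")

    return MoleculeMultipoles(
        name=name if name is not None else meta.get("name", "molecule"),
        sites=sites,
        ring_atom_indices=(
            list(ring_atom_indices) if ring_atom_indices is not None else meta.get("ring", [])
        ),
        length_unit=meta.get("units", default_unit),
        net_charge=net_charge if net_charge is not None else meta.get("charge", 0),
    )


def read_punch_file(path, **kwargs) -> MoleculeMultipoles:
    """Read a punch-dialect file from ``path``; see :func:`parse_multipole_file`."""
    with open(path) as fh:
        return parse_multipole_file(fh.read(), **kwargs)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_punch(mol: MoleculeMultipoles, path=None) -> str:
    """Serialize ``mol`` to the punch dialect; re-parsing is bit-faithful."""
    out = [
        "! distributed multipoles, Stone-ordered real spherical components (a.u.)",
        f"name {mol.name}",
        f"units {mol.length_unit}",
        f"charge {mol.net_charge}",
    ]
    if mol.ring_atom_indices:
        out.append("ring " + " ".join(str(i) for i in mol.ring_atom_indices))
    for s in mol.sites:
        x, y, z = s.position
        out.append(f"{s.label} {_fmt(x)} {_fmt(y)} {_fmt(z)} rank {s.max_rank}")
        for l in range(s.max_rank + 1):
            block = s.components[l * l : (l + 1) * (l + 1)]
            out.append("  " + " ".join(_fmt(v) for v in block))
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# tabular I/O: energies and descriptor tables
# ---------------------------------------------------------------------------

_ENERGY_COLS = ["name", "E_neutral", "E_cation", "E_anion"]


def read_energy_table(path) -> list[EnergyRecord]:
    """Read a delimited table with columns name, E_neutral, E_cation, E_anion (hartree)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _ENERGY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"energy table missing columns: {missing}")
    return [
        EnergyRecord(str(r["name"]), float(r["E_neutral"]), float(r["E_cation"]), float(r["E_anion"]))
        for _, r in df.iterrows()
    ]


def write_energy_table(records: Sequence[EnergyRecord], path) -> None:
    df = pd.DataFrame(
        [(r.name, r.E_neutral, r.E_cation, r.E_anion) for r in records],
        columns=_ENERGY_COLS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_descriptor_table(path) -> pd.DataFrame:
    """Read a molecules-by-descriptors table (first column = molecule name)."""
    df = pd.read_csv(path, index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("descriptor table has duplicate column names")
    return df


def write_descriptor_report(table: pd.DataFrame, path) -> None:
    """Write a descriptor table; empty fields mark missing values.

    Column order is preserved exactly; numbers are written with 17
    significant digits so a read-back reproduces them to full precision.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("refusing to write an empty descriptor table")
    table.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# optional ring-atom heuristic (never applied silently)
# ---------------------------------------------------------------------------

def find_ring_atoms(
    mol: MoleculeMultipoles,
    bond_window: tuple[float, float] = (1.20, 1.60),
) -> list[int]:
    """Locate the unique six-membered ring of heavy atoms, if any.

    Heavy-atom sites (labels not beginning with ``H`` or ``X``) whose
    pairwise distances fall inside ``bond_window`` (angstrom) are treated
    as bonded; the heuristic demands exactly one set of six sites whose
    induced bond graph is a single 6-cycle and returns it in ring-walk
    order.  Raises ``ValueError`` otherwise.  This helper is offered for
    convenience only — the pipeline requires explicit ring indices.
    """
    pos = mol.to_unit("angstrom").positions
    heavy = [
        i for i, s in enumerate(mol.sites) if not s.label[:1].upper() in ("H", "X")
    ]
    lo, hi = bond_window
    adj: dict[int, set[int]] = {i: set() for i in heavy}
    for i, j in combinations(heavy, 2):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if lo <= d <= hi:
            adj[i].add(j)
            adj[j].add(i)
    rings = []
    for combo in combinations(heavy, 6):
        sub = {i: adj[i] & set(combo) for i in combo}
        if any(len(v) != 2 for v in sub.values()):
            continue
        # walk the cycle; a single 6-cycle visits all six nodes
        start = combo[0]
        walk = [start]
        prev = None
        while True:
            nxt = [n for n in sub[walk[-1]] if n != prev]
            prev = walk[-1]
            walk.append(nxt[0])
            if walk[-1] == start:
                break
        if len(walk) == 7:
            rings.append(walk[:-1])
    if len(rings) != 1:
        raise ValueError(
            f"ring-atom heuristic found {len(rings)} candidate 6-cycles; "
            "supply ring_atom_indices explicitly"
        )
    return rings[0]
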