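"""Adiabatic IP/EA and conceptual-DFT reactivity indices.

From total energies of the relaxed neutral, cation and anion (hartree):

    IP = E(cation) − E(neutral)        EA = E(neutral) − E(anion)

and, in eV, the global reactivity indices

    χ  = (IP + EA)/2                   electronegativity
    η  = (IP − EA)/2                   chemical hardness
    ω  = (IP + EA)² / (4 (IP − EA))    electrophilicity
    ω− = (3 IP + EA)² / (16 (IP − EA)) electron-donating power
    ω+ = (IP + 3 EA)² / (16 (IP − EA)) electron-accepting power

These satisfy the algebraic identities ω− − ω+ = χ and 2ηω = χ², which
are asserted in the test suite on random inputs.  A negative EA (unbound
anion) is physical and allowed; IP = EA (zero hardness) makes ω, ω−, ω+
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_EV
from .multipole import EnergyRecord

__all__ = [
    "ReactivityParams",
    "REACTIVITY_NAMES",
    "ip_ea",
    "conceptual_dft",
    "reactivity_frame",
    "correlate_reactivity",
]

REACTIVITY_NAMES = ("IP", "EA", "chi", "eta", "omega", "omega_minus", "omega_plus")


@dataclass(frozen=True)
class ReactivityParams:
    """Global reactivity indices of one species, eV."""

    name: str
    IP: float
    EA: float
    chi: float
    eta: float
    omega: float
    omega_minus: float
    omega_plus: float

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in REACTIVITY_NAMES}, name=self.name)


def ip_ea(record: EnergyRecord) -> tuple[float, float]:
    """Adiabatic ionization potential and electron affinity, in eV."""
    ip = (record.E_cation - record.E_neutral) * HARTREE_TO_EV
    ea = (record.E_neutral - record.E_anion) * HARTREE_TO_EV
    return ip, ea


def conceptual_dft(ip: float, ea: float, name: str = "") -> ReactivityParams:
    """Derive χ, η, ω, ω−, ω+ from IP and EA (eV)."""
    if ip == ea:
        raise ZeroDivisionError(
            f"{name or 'species'}: IP = EA (zero hardness); ω, ω−, ω+ undefined"
        )
    chi = 0.5 * (ip + ea)
    eta = 0.5 * (ip - ea)
    gap = ip - ea
    omega = (ip + ea) ** 2 / (4.0 * gap)
    omega_minus = (3.0 * ip + ea) ** 2 / (16.0 * gap)
    omega_plus = (ip + 3.0 * ea) ** 2 / (16.0 * gap)
    return ReactivityParams(name, ip, ea, chi, eta, omega, omega_minus, omega_plus)


def reactivity_frame(records: Sequence[EnergyRecord]) -> pd.DataFrame:
    """Species-by-index reactivity table (eV) from energy records."""
    rows = []
    for rec in records:
        ip, ea = ip_ea(rec)
        rows.append(conceptual_dft(ip, ea, name=rec.name).as_series())
    df = pd.DataFrame(rows)
    df.index.name = "name"
    return df


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero-variance column in correlation")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    return r * r


def correlate_reactivity(
    descriptors: pd.DataFrame, reactivity: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """R² (squared Pearson r) of every descriptor against every reactivity index.

    Molecules are matched by table index; missing cells are dropped
    pairwise-complete.  Returns ``(r2, n)`` DataFrames indexed by
    descriptor column, with reactivity indices as columns; ``n`` records
    the number of molecules behind each cell.  Requires at least three
    shared molecules; a pair with fewer than three complete observations
    gets NaN.
    """
    shared = descriptors.index.intersection(reactivity.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared molecules between tables, found {len(shared)}"
        )
    d = descriptors.loc[shared]
    r = reactivity.loc[shared]
    r2 = pd.DataFrame(index=d.columns, columns=r.columns, dtype=float)
    n = pd.DataFrame(index=d.columns, columns=r.columns, dtype=int)
    for dc in d.columns:
        for rc in r.columns:
            pair = pd.concat([d[dc], r[rc]], axis=1).dropna()
            n.loc[dc, rc] = len(pair)
            if len(pair) < 3:
                r2.loc[dc, rc] = np.nan
                continue
            r2.loc[dc, rc] = _pearson_r2(
                pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            )
    return r2, n
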