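"""Physical constants and unit conversion factors (CODATA 2018)."""

#: bohr radii per angstrom
BOHR_PER_ANGSTROM = 1.8897261254578281

#: angstrom per bohr radius
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: electron-volt per hartree
HARTREE_TO_EV = 27.211386245988

#: recognized length-unit keywords
LENGTH_UNITS = ("angstrom", "bohr")


def to_bohr_factor(unit: str) -> float:
    """Scale factor turning lengths in ``unit`` into bohr."""
    if unit == "bohr":
        return 1.0
    if unit == "angstrom":
        return BOHR_PER_ANGSTROM
    raise ValueError(f"unknown length unit {unit!r}; expected one of {LENGTH_UNITS}")
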