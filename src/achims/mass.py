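"""Exact monoisotopic mass and ion m/z computation.

Targeted MSI starts from theory: the m/z at which an ion is expected is
computed from its elemental formula using most-abundant-isotope masses.
Two conventions coexist in the literature for singly charged cations:

* the *neutral-formula* convention, which reports the plain monoisotopic
  mass of the formula (acetylcholine's intrinsic cation C7H16NO2+ is
  conventionally quoted as 146.1181 this way), and
* the *electron-corrected* convention, which subtracts the electron mass
  per positive charge (the protonated DHB matrix ion is quoted as
  155.03389 this way).

Both are supported via :class:`MoleculeSpec.electron_correction`; nothing
is hidden inside a default that cannot be switched off.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "ELECTRON_MASS",
    "PROTON_ADDUCT_MASS",
    "FormulaError",
    "MoleculeSpec",
    "isotope_masses",
    "parse_formula",
    "formula_to_hill",
    "monoisotopic_mass",
    "ion_mz",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.00054858

#: Mass added by protonation before electron correction: one hydrogen atom.
PROTON_ADDUCT_MASS = 1.007825

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed elemental formula or unknown element symbol."""


def _load_isotope_table() -> Mapping[str, float]:
    text = (
        resources.files("achims").joinpath("data/isotope_masses.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        mass_da = float(mass)
        if mass_da <= 0:
            raise ValueError(f"non-positive isotope mass for {symbol}")
        table[symbol] = mass_da
    return MappingProxyType(table)


#: Immutable element symbol -> most-abundant-isotope mass (Da).
_ISOTOPE_MASSES = _load_isotope_table()


def isotope_masses() -> Mapping[str, float]:
    """Return the read-only element -> monoisotopic mass table (Da)."""
    return _ISOTOPE_MASSES


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element-count mapping.

    Implicit counts are 1 (``"C7H16NO2"`` -> ``{C: 7, H: 16, N: 1, O: 2}``).
    Repeated element symbols accumulate. Isotope labels (e.g. deuterium)
    are not supported.

    Raises
    ------
    FormulaError
        If the string is empty, contains characters outside the
        element-count grammar, or names an element absent from the
        isotope table.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    pos = 0
    composition: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r} at position {pos}: "
                f"{text[pos:match.start()]!r}"
            )
        pos = match.end()
        symbol, count_str = match.groups()
        if symbol not in _ISOTOPE_MASSES:
            raise FormulaError(f"unknown element {symbol!r} in {text!r}")
        count = int(count_str) if count_str else 1
        if count < 1:
            raise FormulaError(f"element count < 1 for {symbol!r} in {text!r}")
        composition[symbol] = composition.get(symbol, 0) + count
    if pos != len(text):
        raise FormulaError(f"trailing garbage in formula {text!r}: {text[pos:]!r}")
    if not composition:
        raise FormulaError(f"no elements parsed from {text!r}")
    return composition


def formula_to_hill(composition: Mapping[str, int]) -> str:
    """Serialize a composition in Hill order (C, H, then alphabetical)."""

    def key(sym: str) -> tuple[int, str]:
        if "C" in composition:
            if sym == "C":
                return (0, "")
            if sym == "H":
                return (1, "")
        return (2, sym)

    parts = []
    for sym in sorted(composition, key=key):
        n = composition[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a composition, in Da.

    The empty composition has mass 0. Counts must be positive integers.
    """
    total = 0.0
    for symbol, count in composition.items():
        try:
            mass = _ISOTOPE_MASSES[symbol]
        except KeyError:
            raise FormulaError(f"element {symbol!r} absent from isotope table")
        if count < 1:
            raise FormulaError(f"element count < 1 for {symbol!r}")
        total += count * mass
    return total


@dataclass(frozen=True)
class MoleculeSpec:
    """A target ion: elemental formula plus charge/adduct conventions.

    Parameters
    ----------
    formula
        Hill-notation string or element-count mapping of the *neutral
        formula* (for intrinsic cations such as acetylcholine this is the
        formula of the cation itself, e.g. ``"C7H16NO2"``).
    charge
        Signed integer charge; must be nonzero to compute an m/z.
    adduct
        ``"none"`` for intrinsic cations, ``"protonated"`` to add one
        hydrogen atom (1.007825 Da) before charge correction.
    electron_correction
        Subtract ``charge * ELECTRON_MASS`` when True. Leave False to
        reproduce neutral-formula "theoretical exact mass" figures.
    """

    formula: Mapping[str, int] | str
    charge: int = 1
    adduct: str = "none"
    electron_correction: bool = True
    composition: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        comp = (
            parse_formula(self.formula)
            if isinstance(self.formula, str)
            else dict(self.formula)
        )
        for sym, n in comp.items():
            if sym not in _ISOTOPE_MASSES:
                raise FormulaError(f"unknown element {sym!r}")
            if n < 1:
                raise FormulaError(f"element count < 1 for {sym!r}")
        if self.adduct not in ("none", "protonated"):
            raise ValueError(f"adduct must be 'none' or 'protonated', got {self.adduct!r}")
        object.__setattr__(self, "composition", MappingProxyType(comp))

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def mz(self) -> float:
        return ion_mz(self)


def ion_mz(spec: MoleculeSpec) -> float:
    """m/z of an ion in Da per unit charge.

    ``(M + adduct - z * m_e * [correction]) / |z|`` where ``M`` is the
    monoisotopic mass of the formula, the adduct mass is 1.007825 Da for
    protonation and 0 otherwise, and ``m_e`` is the electron mass.

    Raises
    ------
    ValueError
        If the charge is zero.
    """
    if spec.charge == 0:
        raise ValueError("cannot compute m/z for charge 0")
    mass = monoisotopic_mass(spec.composition)
    if spec.adduct == "protonated":
        mass += PROTON_ADDUCT_MASS
    if spec.electron_correction:
        mass -= spec.charge * ELECTRON_MASS
    return mass / abs(spec.charge)


#: Acetylcholine's intrinsic quaternary-ammonium cation, quoted by the
#: neutral-formula convention (146.1181).
ACETYLCHOLINE = MoleculeSpec("C7H16NO2", charge=1, adduct="none",
                             electron_correction=False)

#: Protonated 2,5-dihydroxybenzoic acid (DHB matrix ion), electron
#: corrected (155.03389): lock-mass calibrant and internal standard.
DHB_PROTONATED = MoleculeSpec("C7H6O4", charge=1, adduct="protonated",
                              electron_correction=True)
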