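"""Molecular-formula parsing, monoisotopic masses, adduct m/z and ppm arithmetic.

Every annotation decision downstream rests on this module: a putative
identification window of 2 ppm at m/z 600 is a 0.0012 Da interval, so the
element mass table is embedded at sub-micro-Dalton precision and adduct
shifts use electron-corrected cation masses rather than neutral-atom masses
(the electron's 0.000549 Da is ~1 ppm at m/z 550).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "MolecularFormula",
    "AdductSpec",
    "MassMatch",
    "BUILTIN_ADDUCTS",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "get_adduct",
]

# Monoisotopic masses of the most abundant isotope, Da.
# Values from the IUPAC/CIAAW atomic mass evaluation (AME2020), truncated to
# 6-7 decimal places -- far below the 2-ppm matching window at any m/z in
# the 50-1000 Da instrument range.
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737616,
    "S": 31.9720710,
    "Cl": 34.9688527,
    "Na": 22.9897693,
    "K": 38.9637065,
    "F": 18.9984032,
    "Br": 78.9183376,
    "I": 126.9044719,
    "Si": 27.9769265,
    "Se": 79.9165218,
    "Fe": 55.9349375,
    "Mg": 23.9850417,
    "Ca": 39.9625909,
    "Zn": 63.9291420,
    "B": 11.0093054,
}

#: Mass of a proton, Da (electron-corrected: 1.0078250 - 0.0005486).
PROTON_MASS = 1.007276


class FormulaError(ValueError):
    """Raised for malformed or unknown-element molecular formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map, e.g. losartan ``C22H23ClN6O``.

    Counts are non-negative; an empty formula is valid and has mass zero.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symbol, count in self.element_counts.items():
            if symbol not in MONOISOTOPIC_MASSES:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            if count < 0:
                raise FormulaError(f"negative count for element {symbol!r}: {count}")
        # freeze the mapping so the dataclass is hashable/safe to share
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.element_counts)
        for symbol, count in other.element_counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return MolecularFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, then H, then the rest alphabetically
        symbols = sorted(
            self.element_counts,
            key=lambda s: (s != "C", s != "H", s),
        )
        parts = []
        for symbol in symbols:
            count = self.element_counts[symbol]
            if count == 0:
                continue
            parts.append(symbol if count == 1 else f"{symbol}{count}")
        return "".join(parts)


@dataclass(frozen=True)
class AdductSpec:
    """A cation adduct: the detected species is (M + cation) / charge.

    ``mass_shift`` is the electron-corrected cation mass in Da.
    """

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


#: The positive-mode singly charged adducts formed in electrospray from
#: plasma extracts: protonated, sodiated and potassiated molecules.
BUILTIN_ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", 1.007276, 1),
    "[M+Na]+": AdductSpec("[M+Na]+", 22.989218, 1),
    "[M+K]+": AdductSpec("[M+K]+", 38.963158, 1),
}


def get_adduct(name: str) -> AdductSpec:
    """Look up a built-in adduct by its square-bracket label."""
    try:
        return BUILTIN_ADDUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; built-ins are {sorted(BUILTIN_ADDUCTS)}"
        ) from None


@dataclass(frozen=True)
class MassMatch:
    """An observed/theoretical m/z pair with its signed ppm deviation."""

    observed_mz: float
    theoretical_mz: float

    @property
    def ppm_error(self) -> float:
        return ppm_error(self.observed_mz, self.theoretical_mz)


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C22H23ClN6O"``.

    Element symbols are one uppercase letter optionally followed by one
    lowercase letter; an absent count means 1. The empty string is the
    empty formula.

    Raises
    ------
    FormulaError
        If a token is malformed (with its character position) or an element
        symbol is not in the embedded mass table.
    """
    counts: Dict[str, int] = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic neutral mass in Da: sum of count x most-abundant-isotope mass."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(
        count * MONOISOTOPIC_MASSES[symbol]
        for symbol, count in formula.element_counts.items()
    )


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of the adduct ion: (M + cation mass) / charge.

    >>> round(adduct_mz(422.16219, "[M+H]+"), 3)
    423.169
    """
    if neutral_mass < 0:
        raise ValueError(f"neutral mass must be >= 0, got {neutral_mass}")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return (neutral_mass + adduct.mass_shift) / adduct.charge


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical_mz}")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6
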