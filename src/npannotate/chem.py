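"""Elemental-formula arithmetic and adduct m/z computation.

All mass arithmetic in the package runs through this module.  Masses are
monoisotopic and computed at full double precision; values intended for
display or comparison with instrument printouts are rounded to four
decimals with :func:`round_mass` (half away from zero, the convention of
vendor software).

Adduct m/z values use the neutral-atom convention: a protonated species is
``M + m(H atom)`` and a deprotonated one ``M - m(H atom)``, with the
electron mass ignored.  This matches how exact masses are tabulated in the
natural-product literature this package targets.  Electron-corrected
(true ion mass) arithmetic is available via ``electron_corrected=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "Formula",
    "AdductSpec",
    "ADDUCTS",
    "MassError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_mass",
    "mass_error",
    "combine_formulas",
    "round_mass",
]

#: IUPAC monoisotopic atomic masses (Da) for the supported elements.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "S": 31.9720707,
    "Na": 22.9897693,
}

ELECTRON_MASS = 0.00054858  # Da

# Hill order: C, H first, then the rest alphabetically.
_HILL_ORDER = ["C", "H", "N", "Na", "O", "P", "S"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or negative element counts."""


@dataclass(frozen=True)
class Formula:
    """An elemental formula as an element -> count mapping.

    Counts are non-negative integers; zero-count entries are dropped so
    equality is plain element-wise comparison.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unsupported element: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    @property
    def mass(self) -> float:
        return sum(ATOMIC_MASS[el] * n for el, n in self.counts.items())

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            new = merged.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction would give negative count for {el}: "
                    f"{self} - {other}"
                )
            merged[el] = new
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError("multiplier must be a non-negative integer")
        return Formula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        parts = []
        for el in _HILL_ORDER:
            n = self.counts.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Formula({str(self) or 'empty'})"


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string, e.g. ``"C21H20O12"``.

    Repeated element symbols accumulate.  Unknown elements and stray
    characters raise :class:`FormulaError`.
    """
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return Formula(counts)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


def combine_formulas(a: Formula, b: Formula, sign: str = "+") -> Formula:
    """Element-wise sum (``sign='+'``) or difference (``sign='-'``)."""
    if sign == "+":
        return a + b
    if sign == "-":
        return a - b
    raise ValueError(f"sign must be '+' or '-', got {sign!r}")


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged adduct: name, polarity and mass delta (Da)."""

    name: str
    polarity: str  # "positive" | "negative"
    delta: float
    #: electron count change of the ion relative to the neutral (for the
    #: optional electron-corrected arithmetic): -1 for cations, +1 for anions.
    electrons: int = 0


_H = ATOMIC_MASS["H"]
_HCOO = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["O"] + _H
_NH4 = ATOMIC_MASS["N"] + 4 * _H

#: The five adducts used throughout; deltas follow the neutral-atom convention.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", "positive", +_H, electrons=-1),
    "[M+Na]+": AdductSpec("[M+Na]+", "positive", +ATOMIC_MASS["Na"], electrons=-1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", "positive", +_NH4, electrons=-1),
    "[M-H]-": AdductSpec("[M-H]-", "negative", -_H, electrons=+1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", "negative", +_HCOO, electrons=+1),
}

# Accept common unicode-minus spellings on lookup.
_ADDUCT_ALIASES = {
    "[M−H]−": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M+HCOO]−": "[M+HCOO]-",
}

#: Default adduct sets per polarity for known-compound precursor expansion.
POSITIVE_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M+NH4]+")
NEGATIVE_ADDUCTS = ("[M-H]-", "[M+HCOO]-")
#: Combinatorial / metabolite libraries omit [M+NH4]+.
COMBINATORIAL_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M-H]-", "[M+HCOO]-")


def get_adduct(name: str) -> AdductSpec:
    name = _ADDUCT_ALIASES.get(name, name)
    try:
        return ADDUCTS[name]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}") from None


def adduct_mz(f: Formula | str, adduct: str | AdductSpec,
              electron_corrected: bool = False) -> float:
    """m/z of the singly charged adduct of neutral formula ``f``."""
    if isinstance(f, str):
        f = parse_formula(f)
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    mz = f.mass + adduct.delta
    if electron_corrected:
        mz += adduct.electrons * ELECTRON_MASS
    return mz


def neutral_mass(mz: float, adduct: str | AdductSpec,
                 electron_corrected: bool = False) -> float:
    """Invert :func:`adduct_mz`: neutral monoisotopic mass from an ion m/z."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    m = mz - adduct.delta
    if electron_corrected:
        m -= adduct.electrons * ELECTRON_MASS
    return m


@dataclass(frozen=True)
class MassError:
    """Signed mass error between a measured and a theoretical m/z."""

    mda: float  # milli-Dalton
    ppm: float

    def __neg__(self) -> "MassError":
        return MassError(-self.mda, -self.ppm)


def mass_error(measured: float, theoretical: float) -> MassError:
    """Signed error of ``measured`` against ``theoretical`` (mDa and ppm)."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    d = measured - theoretical
    return MassError(mda=d * 1e3, ppm=d / theoretical * 1e6)


def round_mass(x: float, ndigits: int = 4) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Python's builtin ``round`` is banker's rounding; instrument software
    rounds half up, which matters at the fourth decimal of printed masses.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
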