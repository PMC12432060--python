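"""Molecular-formula algebra and monoisotopic mass/ion conventions.

Everything downstream (suspect database, screening, fragment rules) works in
terms of :class:`Formula` objects and the negative-mode deprotonation
convention defined here.  Masses are monoisotopic throughout; isotope
envelopes and charge states > 1 are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "SULFATE_DELTA_MASS",
    "Formula",
    "IonConvention",
    "parse_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "neutral_mass_from_mz",
    "ppm_error",
]

#: Monoisotopic masses (Da) of the elements handled by default, fixed to
#: 7 decimals (IUPAC/CODATA values).  C is exactly 12 by definition.
ELEMENT_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.0,
        "H": 1.0078250,
        "N": 14.0030740,
        "O": 15.9949146,
        "P": 30.9737615,
        "S": 31.9720707,
        "Na": 22.9897693,
        "K": 38.9637065,
        "Cl": 34.9688527,
    }
)

PROTON_MASS = 1.0072765
ELECTRON_MASS = 0.0005486

#: Mass added by one sulfation (+SO3 on a hydroxyl), ~79.9568 Da.
SULFATE_DELTA_MASS = ELEMENT_MASSES["S"] + 3 * ELEMENT_MASSES["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or invalid formula arithmetic."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition: immutable element -> count mapping.

    Counts are strictly positive integers; an element with count zero is
    simply absent.  Addition and subtraction are elementwise; subtraction
    that would drive any count negative raises :class:`FormulaError`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(f"invalid count for {element}: {count!r}")
            if count > 0:
                clean[element] = count
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            left = merged.get(element, 0) - count
            if left < 0:
                raise FormulaError(
                    f"subtraction would give negative {element} count "
                    f"({self.hill()} - {other.hill()})"
                )
            if left == 0:
                merged.pop(element, None)
            else:
                merged[element] = left
        return Formula(merged)

    def __mul__(self, n: int) -> "Formula":
        if not isinstance(n, int) or n < 0:
            raise FormulaError(f"formula multiplier must be a non-negative int: {n!r}")
        return Formula({e: c * n for e, c in self.counts.items()})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Canonical Hill-notation string: C, then H, then others A-Z."""
        parts = []
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        for element in order:
            count = self.counts[element]
            parts.append(element if count == 1 else f"{element}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string such as ``"C6H6O6S"``.

    Element symbols may carry an optional positive integer count; a bare
    symbol means count 1.  Explicit zero counts (``"C0"``) are rejected, as
    are unknown symbols and any leftover characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return Formula(counts)


def monoisotopic_mass(formula: Formula) -> float:
    """Monoisotopic mass (Da) of a neutral formula; empty formula -> 0.0."""
    return sum(ELEMENT_MASSES[e] * c for e, c in formula.counts.items())


@dataclass(frozen=True)
class IonConvention:
    """Ionization convention for m/z computation.

    Only negative-mode deprotonation ([M-H]-) is supported: the instrument
    method behind this workflow runs heated-ESI in negative ion mode and all
    reported species are singly deprotonated.  ``electron_correction`` adds
    the electron mass on top of the proton subtraction, making the (small,
    ~0.5 mDa) constant-choice ambiguity explicit and testable.
    """

    mode: str = "[M-H]-"
    electron_correction: bool = False

    def __post_init__(self) -> None:
        if self.mode != "[M-H]-":
            raise ValueError(f"unsupported ion mode: {self.mode!r}")

    @property
    def mass_shift(self) -> float:
        """Signed shift applied to a neutral mass to obtain m/z."""
        shift = -PROTON_MASS
        if self.electron_correction:
            shift += ELECTRON_MASS
        return shift

    def describe(self) -> dict:
        """Convention metadata recorded in output files."""
        return {
            "mode": self.mode,
            "proton_mass": PROTON_MASS,
            "electron_mass": ELECTRON_MASS,
            "electron_correction": self.electron_correction,
        }


def mz_deprotonated(neutral_mass: float, conv: IonConvention | None = None) -> float:
    """[M-H]- m/z of a neutral monoisotopic mass.

    Raises ``ValueError`` when the neutral mass does not exceed the proton
    mass (the resulting m/z would be non-positive or meaningless).
    """
    conv = conv or IonConvention()
    mz = neutral_mass + conv.mass_shift
    if mz <= 0:
        raise ValueError(
            f"neutral mass {neutral_mass} too small for deprotonation"
        )
    return mz


def neutral_mass_from_mz(mz: float, conv: IonConvention | None = None) -> float:
    """Inverse of :func:`mz_deprotonated` (experimental neutral mass)."""
    conv = conv or IonConvention()
    return mz - conv.mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
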