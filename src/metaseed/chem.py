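"""Elemental constants, molecular formulas, and exact-mass arithmetic.

Monoisotopic masses drive every ppm-tolerance comparison in the pipeline,
so nuclide masses and abundances are hard-coded here to >=6 decimals from
the IUPAC/NIST atomic-weights compilation (CIAAW 2013 isotopic abundances,
AME2012 nuclide masses) rather than looked up at run time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementIsotopeTable",
    "DEFAULT_ISOTOPES",
    "Formula",
    "monoisotopic_mass",
    "neutral_mass_from_mz",
    "ppm_error",
]

#: Mass of a proton in Da (CODATA).
PROTON_MASS = 1.00727646688

#: Mass of an electron in Da (CODATA).
ELECTRON_MASS = 0.00054857990946


class UnknownElementError(KeyError):
    """Raised when a formula references an element absent from the isotope table."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return f"unknown element {self.element!r}: not present in the isotope table"


@dataclass(frozen=True)
class ElementIsotopeTable:
    """Per-element nuclide masses (Da) and natural abundances (fractions).

    Nuclides are stored in increasing-mass order; for the organic elements
    (C, H, N, O, P, S) the lightest nuclide is also the principal one, so
    the monoisotopic mass of a formula is the abundance-weighted mode of
    its isotopologue distribution.
    """

    isotopes: Mapping[str, Tuple[Tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for elem, nuclides in self.isotopes.items():
            masses = [m for m, _ in nuclides]
            if masses != sorted(masses):
                raise ValueError(f"{elem}: nuclide masses must be increasing")
            total = sum(a for _, a in nuclides)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{elem}: abundances sum to {total}, not 1")

    def __contains__(self, element: str) -> bool:
        return element in self.isotopes

    def elements(self) -> List[str]:
        return list(self.isotopes)

    def nuclides(self, element: str) -> Tuple[Tuple[float, float], ...]:
        try:
            return self.isotopes[element]
        except KeyError:
            raise UnknownElementError(element) from None

    def principal_mass(self, element: str) -> float:
        """Mass of the lightest (for CHNOPS: most abundant) nuclide."""
        return self.nuclides(element)[0][0]


DEFAULT_ISOTOPES = ElementIsotopeTable(
    {
        # element: ((nuclide mass, abundance), ...) lightest first
        "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
        "C": ((12.0, 0.9893), (13.00335483780, 0.0107)),
        "N": ((14.00307400480, 0.99636), (15.00010889820, 0.00364)),
        "O": (
            (15.99491461956, 0.99757),
            (16.99913170, 0.00038),
            (17.99916100, 0.00205),
        ),
        "P": ((30.97376163, 1.0),),
        "S": (
            (31.97207100, 0.9499),
            (32.97145876, 0.0075),
            (33.96786690, 0.0425),
            (35.96708076, 0.0001),
        ),
        "Na": ((22.98976928, 1.0),),
        "Cl": ((34.96885268, 0.7576), (36.96590259, 0.2424)),
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition with non-negative integer counts.

    The string form uses Hill order (C, then H, then the rest
    alphabetically; purely alphabetical when no carbon is present) and
    round-trips losslessly: ``Formula.parse(str(f)) == f``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for elem, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {elem}")
            if n > 0:
                cleaned[elem] = int(n)
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
            pos = match.end()
            elem = match.group(1)
            n = int(match.group(2)) if match.group(2) else 1
            counts[elem] = counts.get(elem, 0) + n
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def atom_count(self) -> int:
        return sum(self.counts.values())

    def hill_order(self) -> List[str]:
        elems = set(self.counts)
        if "C" in elems:
            ordered = ["C"] + (["H"] if "H" in elems else [])
            ordered += sorted(elems - {"C", "H"})
        else:
            ordered = sorted(elems)
        return ordered

    def __str__(self) -> str:
        parts = []
        for elem in self.hill_order():
            n = self.counts[elem]
            parts.append(elem if n == 1 else f"{elem}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"


def monoisotopic_mass(
    formula: Formula, isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES
) -> float:
    """Exact mass (Da) of the all-principal-nuclide isotopologue."""
    return sum(
        n * isotopes.principal_mass(elem) for elem, n in formula.counts.items()
    )


def neutral_mass_from_mz(mz: float, polarity: str = "negative", charge: int = 1) -> float:
    """Neutral monoisotopic mass from an observed m/z.

    Only the deprotonated, singly charged species [M-H]- is supported:
    M = m/z + m(proton). Negative-mode, z=1 data are the pipeline's scope.
    """
    if polarity != "negative":
        raise ValueError(f"unsupported polarity {polarity!r}; only 'negative'")
    if charge != 1:
        raise ValueError(f"unsupported charge {charge}; only singly charged ions")
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz + PROTON_MASS


def mz_from_neutral_mass(mass: float) -> float:
    """[M-H]- m/z for a neutral monoisotopic mass."""
    return mass - PROTON_MASS


def ppm_error(observed: float, reference: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed - reference) / reference * 1e6
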