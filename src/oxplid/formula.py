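"""Elemental compositions and monoisotopic mass arithmetic.

The composition object is the unit of account for everything downstream:
lipid construction, fragment prediction, adduct m/z values and isotope
patterns all reduce to integer element counts plus a charge.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# conventional ordering for formula strings: C, H, then alphabetical
_HILL_ORDER = {"C": 0, "H": 1}


class ElementalComposition(Mapping[str, int]):
    """Immutable element -> count map with an integer charge.

    Supports ``+``/``-`` (element-wise, charge-wise) and integer ``*``.
    Counts must stay non-negative; zero counts are dropped.
    """

    __slots__ = ("_counts", "charge")

    def __init__(self, counts: Mapping[str, int] | None = None, charge: int = 0):
        clean: dict[str, int] = {}
        for el, n in (counts or {}).items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        self._counts = dict(sorted(clean.items(), key=_hill_key))
        self.charge = int(charge)

    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "ElementalComposition":
        """Parse a plain formula string such as ``C45H85NO11P``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"malformed formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"malformed formula {text!r} at {text[pos:]!r}")
        return cls(counts, charge)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, el: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(el, default)

    # -- arithmetic --------------------------------------------------------
    def _combine(self, other: Mapping[str, int], sign: int, charge: int):
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + sign * n
        return ElementalComposition(counts, charge)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self._combine(other, +1, self.charge + getattr(other, "charge", 0))

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self._combine(other, -1, self.charge - getattr(other, "charge", 0))

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self._counts.items()}, self.charge * k)

    __rmul__ = __mul__

    def replace_charge(self, charge: int) -> "ElementalComposition":
        return ElementalComposition(self._counts, charge)

    # -- derived quantities ------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass in u, including electrons for charged species."""
        m = sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())
        return m - self.charge * ELECTRON_MASS

    @property
    def mz(self) -> float:
        """m/z of the ion; requires a non-zero charge."""
        if self.charge == 0:
            raise ValueError("m/z undefined for a neutral composition")
        return self.monoisotopic_mass / abs(self.charge)

    def formula(self) -> str:
        """Hill-convention formula string (charge not shown)."""
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self._counts.items()
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ElementalComposition)
            and self._counts == other._counts
            and self.charge == other.charge
        )

    def __hash__(self) -> int:
        return hash((tuple(self._counts.items()), self.charge))

    def __repr__(self) -> str:
        q = ""
        if self.charge:
            sign = "-" if self.charge < 0 else "+"
            q = sign if abs(self.charge) == 1 else f"{abs(self.charge)}{sign}"
        return f"ElementalComposition({self.formula()}{q})"


def _hill_key(item: tuple[str, int]):
    el = item[0]
    return (_HILL_ORDER.get(el, 2), el)


def comp(text: str, charge: int = 0) -> ElementalComposition:
    """Shorthand constructor: ``comp("C16H31O2", charge=-1)``."""
    return ElementalComposition.from_string(text, charge)
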