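"""Isotope-pattern prediction by per-element binomial expansion.

For a composition E1_n1 E2_n2 ... the isotopologue envelope, truncated at
M+2, is the product over elements of (p0 + p1 x + p2 x^2)^n keeping terms
up to x^2, where p_i is the abundance of the isotope i mass units above
the principal one.  The truncated power has the closed (binomial /
Maclaurin) form

    c0 = p0^n
    c1 = n p0^(n-1) p1
    c2 = n p0^(n-1) p2 + C(n,2) p0^(n-2) p1^2

and the reported pattern is r_i = c_i / c_0 after the cross-element
product.  Monoisotopic elements (phosphorus) contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import ISOTOPES
from .formula import ElementalComposition


@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopologue intensities r_i = I(M+i) / I(M)."""

    r1: float
    r2: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.r1, self.r2)


def _element_poly(el: str, n: int) -> tuple[float, float, float]:
    """Coefficients (c0, c1, c2) of the truncated abundance polynomial for
    ``n`` atoms of element ``el``; nominal-mass offsets index the terms."""
    if el not in ISOTOPES:
        raise ValueError(f"no isotope data for element {el!r}")
    isotopes = ISOTOPES[el]
    base_mass = isotopes[0][0]
    p = [0.0, 0.0, 0.0]
    for mass, ab in isotopes:
        offset = round(mass - base_mass)
        if offset <= 2:
            p[offset] += ab
    p0, p1, p2 = p
    if n == 0:
        return 1.0, 0.0, 0.0
    c0 = p0**n
    c1 = n * p0 ** (n - 1) * p1
    c2 = n * p0 ** (n - 1) * p2 + (n * (n - 1) / 2) * p0 ** (n - 2) * p1**2
    return c0, c1, c2


def predict_isotope_pattern(composition: ElementalComposition) -> IsotopePattern:
    """M+1 and M+2 relative intensities for a composition.

    The charge state does not enter: electrons carry no isotopes.
    """
    total = (1.0, 0.0, 0.0)
    for el, n in composition.items():
        e0, e1, e2 = _element_poly(el, n)
        t0, t1, t2 = total
        total = (
            t0 * e0,
            t0 * e1 + t1 * e0,
            t0 * e2 + t1 * e1 + t2 * e0,
        )
    c0, c1, c2 = total
    if c0 <= 0:
        raise ValueError("degenerate composition: zero monoisotopic abundance")
    return IsotopePattern(r1=c1 / c0, r2=c2 / c0)
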