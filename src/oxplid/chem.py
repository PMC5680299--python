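"""Molecular construction for glycerophospholipids and their oxidation products.

Elemental compositions are computed by atom counting on the
glycerophosphate scaffold plus per-residue increments; structures are
emitted as SMILES line notation built from the same residue
descriptions, so the two representations can be cross-checked
(``tests`` parse every generated SMILES with RDKit and compare
formulas).
"""

from __future__ import annotations

import warnings

from .constants import MONOISOTOPIC_MASS
from .formula import ElementalComposition, comp
from .nomenclature import (
    FattyAcylResidue,
    LipidSpecies,
    ModificationDescriptor,
    Prostane,
)

# ---------------------------------------------------------------------------
# double-bond position defaults (delta numbering, from the carboxyl carbon)

#: positions for the common PUFA/MUFA chains; n-3 isomer is the default
#: where several natural isomers share c:d.
DOUBLE_BOND_POSITIONS: dict[str, tuple[int, ...]] = {
    "16:1": (9,),
    "18:1": (9,),
    "18:2": (9, 12),
    "18:3": (9, 12, 15),  # alpha-linolenic (n-3)
    "18:3(n-6)": (6, 9, 12),  # gamma-linolenic
    "20:3": (8, 11, 14),  # dihomo-gamma-linolenic (n-6)
    "20:4": (5, 8, 11, 14),  # arachidonic (n-6)
    "20:5": (5, 8, 11, 14, 17),  # EPA (n-3)
    "22:4": (7, 10, 13, 16),  # adrenic (n-6)
    "22:5": (7, 10, 13, 16, 19),  # DPA (n-3)
    "22:5(n-6)": (4, 7, 10, 13, 16),
    "22:6": (4, 7, 10, 13, 16, 19),  # DHA (n-3)
}


def resolve_positions(res: FattyAcylResidue) -> tuple[int, ...]:
    """Double-bond positions for a residue.

    Explicit positions win; otherwise the shipped table is consulted; as
    a last resort double bonds are placed methyl-end-first at n-3
    spacing (with a warning), which matches the predominant natural
    methylene-interrupted pattern.
    """
    if res.double_bonds == 0:
        return ()
    if res.positions:
        return res.positions
    key = f"{res.carbons}:{res.double_bonds}"
    if key in DOUBLE_BOND_POSITIONS:
        return DOUBLE_BOND_POSITIONS[key]
    first = res.carbons - 3 - 3 * (res.double_bonds - 1)
    if first < 2:
        raise ValueError(f"cannot place {res.double_bonds} double bonds on {key}")
    warnings.warn(
        f"no double-bond positions tabulated for {key}; "
        "assuming methyl-end n-3 methylene-interrupted spacing",
        stacklevel=2,
    )
    return tuple(first + 3 * i for i in range(res.double_bonds))


# ---------------------------------------------------------------------------
# compositions

#: glycerophosphate scaffold (glycerol + phosphoric acid - H2O)
_CORE = comp("C3H9O6P")
_H2O = comp("H2O")

#: head-group increment relative to phosphatidic acid
HEAD_DELTA: dict[str, ElementalComposition] = {
    "PA": ElementalComposition(),
    "PC": comp("C5H11N"),
    "PE": comp("C2H5N"),
    "PG": comp("C3H6O2"),
    "PS": comp("C3H5NO2"),
}

# prostane ring templates: per ring class, (extra plain C=C, rings,
# keto groups, oxygens added beyond the carboxyl pair)
_PROSTANE_DELTAS = {
    "F": (0, 1, 0, 3),
    "E": (0, 1, 1, 3),
    "D": (0, 1, 1, 3),
    "A": (1, 1, 1, 2),
    "H": (0, 2, 0, 3),
}


def residue_acid_composition(
    res: FattyAcylResidue, mod: ModificationDescriptor | None
) -> ElementalComposition:
    """Composition of the residue as the free (modified) fatty acid."""
    if res.is_lyso:
        return ElementalComposition()
    c = res.carbons
    if mod is None or mod.is_plain():
        return ElementalComposition({"C": c, "H": 2 * c - 2 * res.double_bonds, "O": 2})
    if mod.prostane is not None:
        extra_cc, rings, keto, extra_o = _PROSTANE_DELTAS[mod.prostane.ring]
        cc = mod.residual_double_bonds + extra_cc
        h = 2 * c - 2 * cc - 2 * rings - 2 * keto
        return ElementalComposition({"C": c, "H": h, "O": 2 + extra_o})
    # each plain C=C, each keto C=O and each epoxide ring costs one H2
    h = 2 * c - 2 * (mod.residual_double_bonds + mod.epoxy) - 2 * mod.keto
    o = 2 + mod.oh + 2 * mod.ooh + mod.keto + mod.epoxy
    if mod.truncation is not None:
        h -= 2
        o += 1 if mod.truncation.terminal == "CHO" else 2
    return ElementalComposition({"C": c, "H": h, "O": o})


def species_composition(sp: LipidSpecies) -> ElementalComposition:
    """Neutral monoisotopic composition of a (possibly modified) species."""
    total = _CORE + HEAD_DELTA[sp.pl_class]
    for res, mod in ((sp.sn1, sp.mod1), (sp.sn2, sp.mod2)):
        if res.is_lyso:
            continue
        total = total + residue_acid_composition(res, mod) - _H2O
    return total


# ---------------------------------------------------------------------------
# adducts

ADDUCTS = ("[M-H]-", "[M+HCOO]-")
_FORMATE = comp("CHO2")
_H = comp("H")


def adduct_composition(
    composition: ElementalComposition, adduct: str
) -> ElementalComposition:
    """Ion composition for a supported negative-mode adduct."""
    if composition.charge != 0:
        raise ValueError("adduct formation expects a neutral composition")
    if adduct == "[M-H]-":
        return (composition - _H).replace_charge(-1)
    if adduct == "[M+HCOO]-":
        return (composition + _FORMATE).replace_charge(-1)
    raise ValueError(f"unsupported adduct {adduct!r}")


def adduct_mz(composition: ElementalComposition, adduct: str) -> float:
    """Monoisotopic m/z of the adduct ion (electron mass included)."""
    return adduct_composition(composition, adduct).mz


def default_adduct_for(sp: LipidSpecies) -> str:
    """Expected negative-mode adduct for a species.

    PC species ionize as formate adducts, except chains truncated to a
    terminal carboxylic acid, which deprotonate; the other classes
    deprotonate.
    """
    if sp.pl_class != "PC":
        return "[M-H]-"
    for mod in (sp.mod1, sp.mod2):
        if mod is not None and mod.truncation is not None and mod.truncation.terminal == "COOH":
            return "[M-H]-"
    return "[M+HCOO]-"


def species_adduct_mz(sp: LipidSpecies, adduct: str | None = None) -> float:
    adduct = adduct or default_adduct_for(sp)
    return adduct_mz(species_composition(sp), adduct)


# ---------------------------------------------------------------------------
# SMILES construction

_HEAD_TAIL = {
    "PA": "O",
    "PE": "OCCN",
    "PG": "OCC(O)CO",
    "PS": "OCC(C(=O)O)N",
}


def _assign_oap_sites(
    positions: tuple[int, ...], mod: ModificationDescriptor, carbons: int
) -> tuple[dict[int, str], set[int]]:
    """Place merged (site-free) modifications on concrete representative
    sites: epoxides consume double bonds from the carboxyl end, the
    remaining groups go to the allylic carbon two past each remaining
    double bond, in canonical type order.  Sites that would land on the
    chain terminus or on an occupied carbon fall back toward the
    carboxyl end."""
    epoxy_at = set(positions[: mod.epoxy])
    remaining = [p for p in positions if p not in epoxy_at]
    groups: list[str] = (
        ["KETO"] * mod.keto + ["OH"] * mod.oh + ["OOH"] * mod.ooh
    )
    if len(groups) > len(remaining):
        raise ValueError("more substituents than available double-bond units")
    db_carbons = {q for p in positions for q in (p, p + 1)}
    sub: dict[int, str] = {}
    for g, p in zip(groups, remaining):
        site = p + 2
        while site >= carbons or site in sub or site in db_carbons:
            site -= 1
            if site < 2:
                raise ValueError("no free carbon for substituent placement")
        sub[site] = g
    return sub, epoxy_at


def _chain_tokens(
    c: int,
    cc: set[int],
    sub: dict[int, str],
    epoxy_at: set[int],
    terminal: str | None,
    ring_base: int,
) -> str:
    """SMILES for carbons 2..c of an acyl chain whose C1 carbonyl token is
    emitted by the caller.  ``cc`` holds positions p with a C=C between
    p and p+1; ``sub`` maps carbon -> OH/OOH/KETO."""
    out: list[str] = []
    ring = ring_base
    open_epoxy: dict[int, int] = {}
    for i in range(2, c + 1):
        bond = "=" if (i - 1) in cc else ""
        if i in epoxy_at:
            ring += 1
            open_epoxy[i + 1] = ring
            out.append(f"{bond}C{ring}O")
            continue
        if i in open_epoxy:
            out.append(f"C{open_epoxy.pop(i)}")
            continue
        branch = ""
        g = sub.get(i)
        if g == "OH":
            branch = "(O)"
        elif g == "OOH":
            branch = "(OO)"
        elif g == "KETO":
            branch = "(=O)"
        if i == c and terminal == "CHO":
            out.append(f"{bond}C=O")
        elif i == c and terminal == "COOH":
            out.append(f"{bond}C(=O)O")
        else:
            out.append(f"{bond}C{branch}")
    return "".join(out)


def _prostane_tokens(c: int, positions: tuple[int, ...], pro: Prostane, ring_base: int) -> str:
    """Representative structure for a prostane-type residue built on the
    three-double-bond window starting at ``pro.window``."""
    w = pro.window
    cc = {p for p in positions if p < w or p > w + 6}
    cc.add(w + 5)
    sub: dict[int, str] = {}
    rings: dict[int, list[str]] = {}

    def ring_pair(a: int, b: int, digit: int, bridge: str = "") -> None:
        rings.setdefault(a, []).append(f"{digit}{bridge}")
        rings.setdefault(b, []).append(f"{digit}")

    d1 = ring_base + 1
    ring_pair(w, w + 4, d1)
    ring = pro.ring
    if ring == "F":
        sub[w + 1] = "(O)"
        sub[w + 3] = "(O)"
        sub[w + 7] = "(O)"
    elif ring == "E":
        sub[w + 1] = "(=O)"
        sub[w + 3] = "(O)"
        sub[w + 7] = "(O)"
    elif ring == "D":
        sub[w + 1] = "(O)"
        sub[w + 3] = "(=O)"
        sub[w + 7] = "(O)"
    elif ring == "A":
        sub[w + 1] = "(=O)"
        cc.add(w + 2)
        sub[w + 7] = "(O)"
    elif ring == "H":
        # endoperoxide bridge between w+1 and w+3
        d2 = ring_base + 2
        rings.setdefault(w + 1, []).append(f"{d2}")
        rings.setdefault(w + 3, []).append(f"(OO{d2})")
        sub[w + 7] = "(O)"

    out: list[str] = []
    for i in range(2, c + 1):
        bond = "=" if (i - 1) in cc else ""
        ringtok = "".join(rings.get(i, []))
        out.append(f"{bond}C{ringtok}{sub.get(i, '')}")
    return "".join(out)


def residue_smiles(
    res: FattyAcylResidue, mod: ModificationDescriptor | None, ring_base: int = 0
) -> str:
    """Acyl-group SMILES fragment (starting at the carbonyl carbon) for a
    residue; attach via an ester oxygen.  Lyso positions have no acyl."""
    if res.is_lyso:
        raise ValueError("lyso position has no acyl chain")
    if mod is None or mod.is_plain():
        positions = resolve_positions(res)
        body = _chain_tokens(res.carbons, set(positions), {}, set(), None, ring_base)
        return "C(=O)" + body
    if mod.prostane is not None:
        positions = resolve_positions(res)
        return "C(=O)" + _prostane_tokens(res.carbons, positions, mod.prostane, ring_base)
    if mod.truncation is not None:
        # residual C=C of a truncated chain keep the parent positions below
        # the cleavage site when the engine recorded them; otherwise a
        # representative methyl-end placement is used
        n_db = mod.residual_double_bonds + mod.epoxy
        if res.positions:
            positions = res.positions
        else:
            positions = tuple(
                sorted(res.carbons - 2 - 3 * i for i in range(n_db))
            )
        sub, epoxy_at = _assign_oap_sites(positions, mod, res.carbons)
        body = _chain_tokens(
            res.carbons, set(positions) - epoxy_at, sub, epoxy_at,
            mod.truncation.terminal, ring_base,
        )
        return "C(=O)" + body
    positions = resolve_positions(res)
    sub, epoxy_at = _assign_oap_sites(positions, mod, res.carbons)
    body = _chain_tokens(
        res.carbons, set(positions) - epoxy_at, sub, epoxy_at, None, ring_base
    )
    return "C(=O)" + body


def build_structure(sp: LipidSpecies) -> str:
    """SMILES line notation for a species (representative positional isomer).

    PC is written as the phosphocholine zwitterion, so the net formula
    equals the neutral species formula.
    """
    sn1 = "O" if sp.sn1.is_lyso else "O" + residue_smiles(sp.sn1, sp.mod1, ring_base=0)
    sn2 = "O" if sp.sn2.is_lyso else "O" + residue_smiles(sp.sn2, sp.mod2, ring_base=4)
    if sp.pl_class == "PC":
        phos = "P(=O)([O-])OCC[N+](C)(C)C"
    else:
        phos = "P(=O)(O)" + _HEAD_TAIL[sp.pl_class]
    return f"C({sn1})C({sn2})CO{phos}"
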