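"""Rule-driven enumeration of oxidized phospholipid products.

Each C=C double bond together with one neighboring (bis-)allylic carbon
is treated as one oxidizable unit.  Oxygen-addition products (OAP) are
enumerated as multisets of modification types over those units (at most
one per unit) under the level's oxygen budget; positional isomers with
the same type multiset collapse to a single entry.  Oxidative cleavage
products (OCP) truncate the chain at each double-bond position with an
aldehyde or carboxyl terminal and, when enough double bonds remain, are
further decorated by the same OAP enumeration.  Cyclic (prostane-type)
products are instantiated from ring templates on each window of three
consecutive methylene-interrupted double bonds and are *not* merged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chem import resolve_positions
from .nomenclature import (
    OAP_OXYGENS,
    FattyAcylResidue,
    LipidSpecies,
    ModificationDescriptor,
    Prostane,
    Truncation,
    format_residue,
)

_FAMILY_BY_CHAIN = {18: "phytoP", 20: "IsoP"}


@dataclass(frozen=True)
class DoubleBondUnit:
    """One oxidizable core unit: a double bond plus its allylic carbon."""

    db_position: int
    allylic_site: int


@dataclass(frozen=True)
class Transform:
    name: str
    kind: str  # OAP type, or OCP terminal
    target: str
    shifted: bool
    delta_o: int
    delta_h: int
    pattern: str = ""
    replacement: str = ""


@dataclass(frozen=True)
class LevelLimits:
    oap_types: tuple[str, ...]
    max_total_mods: int
    max_oxygens: int
    ocp_terminals: tuple[str, ...]
    shifted_cleavage: bool
    ocp_decoration: bool
    decoration_min_residual: int
    prostane_rings: tuple[str, ...]

    def permits(self, other: "LevelLimits") -> bool:
        """True if every product allowed by ``other`` is allowed here."""
        return (
            set(other.oap_types) <= set(self.oap_types)
            and other.max_total_mods <= self.max_total_mods
            and other.max_oxygens <= self.max_oxygens
            and set(other.ocp_terminals) <= set(self.ocp_terminals)
            and (self.shifted_cleavage or not other.shifted_cleavage)
            and (self.ocp_decoration or not other.ocp_decoration)
            and self.decoration_min_residual <= other.decoration_min_residual
            and set(other.prostane_rings) <= set(self.prostane_rings)
        )


@dataclass
class OxidationRuleSet:
    oap_transforms: list[Transform]
    ocp_transforms: list[Transform]
    prostane_templates: tuple[str, ...]
    levels: dict[int, LevelLimits]
    default_level: int = 2
    include_lyso: bool = False

    def __post_init__(self):
        for t in self.oap_transforms:
            expect_o = OAP_OXYGENS[t.kind]
            expect_h = -2 if t.kind == "KETO" else 0
            if (t.delta_o, t.delta_h) != (expect_o, expect_h):
                raise ValueError(f"transform {t.name!r} is not formula-balanced")
        keys = sorted(self.levels)
        for lo, hi in zip(keys, keys[1:]):
            if not self.levels[hi].permits(self.levels[lo]):
                raise ValueError(f"level {hi} does not contain level {lo}")

    def limits(self, level: int | None = None) -> LevelLimits:
        level = self.default_level if level is None else level
        if level not in self.levels:
            raise ValueError(f"unknown oxidation level {level}")
        return self.levels[level]


# ---------------------------------------------------------------------------
# per-residue enumeration

def decompose_units(residue: FattyAcylResidue) -> list[DoubleBondUnit]:
    """One core unit per double bond, ordered by position; saturated
    residues decompose to nothing."""
    if residue.is_lyso or residue.double_bonds == 0:
        return []
    return [DoubleBondUnit(p, p + 2) for p in resolve_positions(residue)]


def _oap_multisets(
    n_units: int, limits: LevelLimits
) -> list[tuple[tuple[str, int], ...]]:
    """All admissible modification-type multisets (sorted count tuples)."""
    out = []
    types = limits.oap_types
    max_size = min(n_units, limits.max_total_mods)
    for size in range(1, max_size + 1):
        for combo in itertools.combinations_with_replacement(types, size):
            oxy = sum(OAP_OXYGENS[t] for t in combo)
            if oxy > limits.max_oxygens:
                continue
            counts = tuple(sorted((t, combo.count(t)) for t in set(combo)))
            out.append(counts)
    return sorted(set(out))


def _descriptor_from_multiset(
    counts: tuple[tuple[str, int], ...],
    double_bonds: int,
    truncation: Truncation | None = None,
) -> ModificationDescriptor:
    by = dict(counts)
    return ModificationDescriptor(
        keto=by.get("KETO", 0),
        oh=by.get("OH", 0),
        ooh=by.get("OOH", 0),
        epoxy=by.get("EPOXY", 0),
        residual_double_bonds=double_bonds - by.get("EPOXY", 0),
        truncation=truncation,
    )


def enumerate_oap(
    residue: FattyAcylResidue, rules: OxidationRuleSet, level: int | None = None
) -> list[ModificationDescriptor]:
    """Merged oxygen-addition products of one residue."""
    limits = rules.limits(level)
    units = decompose_units(residue)
    if not units:
        return []
    return [
        _descriptor_from_multiset(ms, residue.double_bonds)
        for ms in _oap_multisets(len(units), limits)
    ]


def enumerate_ocp(
    residue: FattyAcylResidue, rules: OxidationRuleSet, level: int | None = None
) -> list[tuple[FattyAcylResidue, ModificationDescriptor]]:
    """Truncated products: (truncated chain, descriptor) pairs.

    The truncated chain keeps the parent double bonds strictly below the
    cleavage site; their positions are carried along for structure
    generation.
    """
    limits = rules.limits(level)
    positions = resolve_positions(residue) if residue.double_bonds else ()
    if not positions:
        return []
    sites = {p for p in positions}
    if limits.shifted_cleavage:
        sites |= {p - 1 for p in positions}
    out: list[tuple[FattyAcylResidue, ModificationDescriptor]] = []
    for site in sorted(sites):
        if site < 2:
            continue
        kept = tuple(p for p in positions if p < site)
        r = len(kept)
        for terminal in limits.ocp_terminals:
            trunc = Truncation(site, terminal)
            chain = FattyAcylResidue(site, r, kept)
            out.append((chain, _descriptor_from_multiset((), r, trunc)))
            if limits.ocp_decoration and r >= limits.decoration_min_residual:
                for ms in _oap_multisets(r, limits):
                    out.append((chain, _descriptor_from_multiset(ms, r, trunc)))
    return out


def enumerate_prostanes(
    residue: FattyAcylResidue, rules: OxidationRuleSet, level: int | None = None
) -> list[ModificationDescriptor]:
    """Ring products for residues with >=3 consecutive double bonds.

    Positional isomers (one per three-double-bond window) are retained
    and abbreviated separately.
    """
    limits = rules.limits(level)
    if residue.double_bonds < 3 or not limits.prostane_rings:
        return []
    positions = resolve_positions(residue)
    family = _FAMILY_BY_CHAIN.get(residue.carbons)
    if residue.carbons == 22:
        family = "neuroP" if residue.double_bonds >= 6 else "dihomo-IsoP"
    if family is None:
        return []
    out = []
    for i in range(len(positions) - 2):
        w = positions[i]
        if positions[i + 1] != w + 3 or positions[i + 2] != w + 6:
            continue
        for ring in limits.prostane_rings:
            if ring not in rules.prostane_templates:
                continue
            out.append(
                ModificationDescriptor(
                    residual_double_bonds=residue.double_bonds - 2,
                    prostane=Prostane(ring, family, w),
                )
            )
    return out


# ---------------------------------------------------------------------------
# species-level prediction

@dataclass(frozen=True)
class PredictedLPP:
    """One predicted oxidation product of a parent species."""

    parent: LipidSpecies
    species: LipidSpecies
    lpp_class_tag: str = field(default="")

    @property
    def abbreviation(self) -> str:
        return self.species.abbreviation


def _residue_products(
    residue: FattyAcylResidue, rules: OxidationRuleSet, level: int | None
) -> list[tuple[FattyAcylResidue, ModificationDescriptor]]:
    prods: list[tuple[FattyAcylResidue, ModificationDescriptor]] = []
    for mod in enumerate_oap(residue, rules, level):
        prods.append((residue, mod))
    prods.extend(enumerate_ocp(residue, rules, level))
    for mod in enumerate_prostanes(residue, rules, level):
        prods.append((residue, mod))
    return prods


def predict_species_products(
    sp: LipidSpecies, rules: OxidationRuleSet, level: int | None = None
) -> list[PredictedLPP]:
    """All predicted products of one species: each residue oxidized in turn
    against the unmodified partner, plus (optionally) lyso species; entries
    whose residue abbreviations coincide after swapping sn positions are
    merged."""
    if sp.mod1 is not None or sp.mod2 is not None:
        raise ValueError("input lipidome species must be unmodified")
    seen: dict[tuple, PredictedLPP] = {}

    def _add(candidate: LipidSpecies) -> None:
        key = (
            candidate.pl_class,
            tuple(
                sorted(
                    (
                        format_residue(candidate.sn1, candidate.mod1),
                        format_residue(candidate.sn2, candidate.mod2),
                    )
                )
            ),
        )
        if key not in seen:
            seen[key] = PredictedLPP(sp, candidate, candidate.lpp_class_tag)

    if rules.include_lyso:
        for sn in (1, 2):
            res = sp.sn1 if sn == 1 else sp.sn2
            if res.is_lyso:
                continue
            lyso = FattyAcylResidue(0, 0)
            keep = sp.sn2 if sn == 1 else sp.sn1
            _add(LipidSpecies(sp.pl_class, keep, lyso))

    for sn in (1, 2):
        res = sp.sn1 if sn == 1 else sp.sn2
        if res.is_lyso:
            continue
        for chain, mod in _residue_products(res, rules, level):
            if sn == 1:
                cand = LipidSpecies(sp.pl_class, chain, sp.sn2, mod, None)
            else:
                cand = LipidSpecies(sp.pl_class, sp.sn1, chain, None, mod)
            _add(cand)

    return sorted(seen.values(), key=lambda p: p.abbreviation)


def predict_oxidized_lipidome(
    lipidome: list[LipidSpecies],
    rules: OxidationRuleSet,
    level: int | None = None,
    on_error: str = "report",
) -> tuple[list[PredictedLPP], list[str]]:
    """Predict the oxidized lipidome for a list of native species.

    Returns (products sorted by abbreviation, error messages for species
    that failed).  Duplicate products arising from different parents are
    kept once per parent species.
    """
    products: list[PredictedLPP] = []
    errors: list[str] = []
    for sp in lipidome:
        try:
            products.extend(predict_species_products(sp, rules, level))
        except Exception as exc:  # noqa: BLE001 - species-level isolation
            if on_error == "raise":
                raise
            errors.append(f"{sp.abbreviation}: {exc}")
    products.sort(key=lambda p: p.abbreviation)
    return products, errors
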