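"""Shorthand nomenclature for native and oxidized glycerophospholipids.

The grammar extends the LIPID MAPS discrete species notation with two
modification name spaces on each fatty-acyl residue:

* ``[kxDB, mxMOD, ...]`` — square brackets carry the residual number of
  plain C=C double bonds (``DB``) and counts of oxygen-addition
  modifications (``KETO``, ``OH``, ``OOH``, ``EPOXY``),
  e.g. ``PC(18:0/18:1[1xDB,1xKETO])``.
* ``<CHO@Cn>`` / ``<COOH@Cn>`` — angle brackets mark an oxidatively
  truncated chain with its terminal group; ``Cn`` is the number of
  carbons retained, the terminal sits on carbon *n*,
  e.g. ``PE(18:0/5:0<CHO@C5>)``.

Cyclic (prostane-type) residues are written ``{w}-{R}{s}-{family}``,
e.g. ``8-F2-IsoP``: ring class ``R`` in {A, D, E, F, H}, series ``s``
(= residual double bonds), family by parent chain (phytoP from 18:3,
IsoP from C20 PUFA, dihomo-IsoP/neuroP from C22), and ``w`` the carbon
position of the first double bond of the three-double-bond window used
to build the ring.  A lyso position is written ``0:0``.

Parsing is whitespace-insensitive; formatting emits no spaces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

PL_CLASSES = ("PA", "PC", "PE", "PG", "PS")

#: oxygen-addition modification types, in canonical bracket order
OAP_TYPES = ("KETO", "OH", "OOH", "EPOXY")

#: oxygen atoms added per modification type
OAP_OXYGENS = {"KETO": 1, "OH": 1, "OOH": 2, "EPOXY": 1}

PROSTANE_RINGS = ("A", "D", "E", "F", "H")
PROSTANE_FAMILIES = ("phytoP", "IsoP", "dihomo-IsoP", "neuroP")


class AbbreviationError(ValueError):
    """Raised when a lipid abbreviation does not match the grammar."""


@dataclass(frozen=True)
class Truncation:
    """Oxidative chain truncation: ``site`` carbons retained, aldehyde or
    carboxyl terminal on the last carbon."""

    site: int
    terminal: str  # "CHO" | "COOH"

    def __post_init__(self):
        if self.terminal not in ("CHO", "COOH"):
            raise AbbreviationError(f"unknown truncation terminal {self.terminal!r}")
        if self.site < 2:
            raise AbbreviationError(f"truncation site C{self.site} too short")


@dataclass(frozen=True)
class Prostane:
    """Cyclopentane-ring oxidation product descriptor."""

    ring: str  # A/D/E/F/H
    family: str  # phytoP/IsoP/dihomo-IsoP/neuroP
    window: int  # position of the first double bond of the 3-DB core window

    def __post_init__(self):
        if self.ring not in PROSTANE_RINGS:
            raise AbbreviationError(f"unknown prostane ring type {self.ring!r}")
        if self.family not in PROSTANE_FAMILIES:
            raise AbbreviationError(f"unknown prostane family {self.family!r}")


@dataclass(frozen=True)
class ModificationDescriptor:
    """Modification state of one fatty-acyl residue.

    ``residual_double_bonds`` counts the plain C=C bonds remaining in the
    (possibly truncated) chain; keto C=O and the epoxide ring are carried
    in their own counters.
    """

    keto: int = 0
    oh: int = 0
    ooh: int = 0
    epoxy: int = 0
    residual_double_bonds: int = 0
    truncation: Truncation | None = None
    prostane: Prostane | None = None

    @property
    def oap_counts(self) -> dict[str, int]:
        return {"KETO": self.keto, "OH": self.oh, "OOH": self.ooh, "EPOXY": self.epoxy}

    @property
    def total_oap(self) -> int:
        return self.keto + self.oh + self.ooh + self.epoxy

    @property
    def oxygens_added(self) -> int:
        """Number of oxygen atoms introduced by oxygen-addition groups."""
        return sum(OAP_OXYGENS[t] * n for t, n in self.oap_counts.items())

    def is_plain(self) -> bool:
        return self.total_oap == 0 and self.truncation is None and self.prostane is None


@dataclass(frozen=True)
class FattyAcylResidue:
    """A discrete fatty-acyl chain.

    ``carbons``/``double_bonds`` describe the chain as written in the
    abbreviation; ``positions`` (delta positions, counted from the
    carboxyl carbon) are required for oxidation enumeration but optional
    for parsing and mass computation.  ``carbons == 0`` is the lyso
    sentinel (no acyl chain).
    """

    carbons: int
    double_bonds: int
    positions: tuple[int, ...] = field(default=())

    def __post_init__(self):
        c, d = self.carbons, self.double_bonds
        if c == 0:
            if d != 0 or self.positions:
                raise AbbreviationError("lyso residue must be 0:0")
            return
        if c < 2:
            raise AbbreviationError(f"residue needs >=2 carbons, got {c}")
        if not 0 <= d <= 6:
            raise AbbreviationError(f"double bond count {d} outside 0..6")
        if self.positions:
            if len(self.positions) != d:
                raise AbbreviationError(
                    f"{len(self.positions)} positions for {d} double bonds"
                )
            if any(p < 2 or p >= c for p in self.positions):
                raise AbbreviationError(f"double bond position outside chain: {self.positions}")
            if list(self.positions) != sorted(set(self.positions)):
                raise AbbreviationError(f"positions not strictly increasing: {self.positions}")

    @property
    def is_lyso(self) -> bool:
        return self.carbons == 0

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A glycerophospholipid with discrete sn-1/sn-2 composition, each
    residue optionally carrying a modification descriptor."""

    pl_class: str
    sn1: FattyAcylResidue
    sn2: FattyAcylResidue
    mod1: ModificationDescriptor | None = None
    mod2: ModificationDescriptor | None = None

    def __post_init__(self):
        if self.pl_class not in PL_CLASSES:
            raise AbbreviationError(f"unknown lipid class {self.pl_class!r}")
        for res, mod, sn in ((self.sn1, self.mod1, "sn1"), (self.sn2, self.mod2, "sn2")):
            if res.is_lyso and mod is not None:
                raise AbbreviationError(f"{sn}: lyso position cannot carry modifications")
            if mod is not None and mod.truncation is not None:
                if mod.truncation.site != res.carbons:
                    raise AbbreviationError(
                        f"{sn}: truncation site C{mod.truncation.site} does not match "
                        f"chain length {res.carbons}"
                    )
        if self.sn1.is_lyso and self.sn2.is_lyso:
            raise AbbreviationError("both positions lyso")

    @property
    def abbreviation(self) -> str:
        return format_species(self)

    @property
    def is_lyso(self) -> bool:
        return self.sn1.is_lyso or self.sn2.is_lyso

    @property
    def lpp_class_tag(self) -> str:
        """One of native / lysoPL / OAP / OCP / prostane."""
        mods = [m for m in (self.mod1, self.mod2) if m is not None and not m.is_plain()]
        if self.is_lyso:
            return "lysoPL"
        if not mods:
            return "native"
        m = mods[0]
        if m.prostane is not None:
            return "prostane"
        if m.truncation is not None:
            return "OCP"
        return "OAP"

    def __str__(self) -> str:
        return self.abbreviation


# ---------------------------------------------------------------------------
# formatting

def format_residue(res: FattyAcylResidue, mod: ModificationDescriptor | None) -> str:
    if res.is_lyso:
        return "0:0"
    if mod is None or mod.is_plain():
        return f"{res.carbons}:{res.double_bonds}"
    if mod.prostane is not None:
        series = mod.residual_double_bonds
        p = mod.prostane
        prefix = f"{p.window}-" if p.window else ""
        return f"{prefix}{p.ring}{series}-{p.family}"
    parts = []
    if mod.residual_double_bonds:
        parts.append(f"{mod.residual_double_bonds}xDB")
    for t in OAP_TYPES:
        n = mod.oap_counts[t]
        if n:
            parts.append(f"{n}x{t}")
    if mod.truncation is not None:
        head = f"{res.carbons}:{mod.residual_double_bonds}"
        bracket = f"[{','.join(parts)}]" if mod.total_oap else ""
        t = mod.truncation
        return f"{head}{bracket}<{t.terminal}@C{t.site}>"
    return f"{res.carbons}:{res.double_bonds}[{','.join(parts)}]"


def format_species(sp: LipidSpecies) -> str:
    r1 = format_residue(sp.sn1, sp.mod1)
    r2 = format_residue(sp.sn2, sp.mod2)
    return f"{sp.pl_class}({r1}/{r2})"


# ---------------------------------------------------------------------------
# parsing

_CHAIN_RE = re.compile(
    r"^(?P<c>\d+):(?P<d>\d+)"
    r"(?:\[(?P<bracket>[^\]]*)\])?"
    r"(?:<(?P<term>CHO|COOH)@C(?P<site>\d+)>)?$"
)
_BRACKET_ITEM_RE = re.compile(r"^(\d+)x(DB|KETO|OH|OOH|EPOXY)$")
_PROSTANE_RE = re.compile(
    r"^(?:(?P<w>\d+)-)?(?P<ring>[ADEFH])(?P<series>\d)-(?P<family>phytoP|IsoP|dihomo-IsoP|neuroP)$"
)

#: parent chains implied by each prostane family (carbons; series = d - 2)
FAMILY_CARBONS = {"phytoP": 18, "IsoP": 20, "dihomo-IsoP": 22, "neuroP": 22}


def parse_residue(text: str) -> tuple[FattyAcylResidue, ModificationDescriptor | None]:
    """Parse one residue abbreviation into (residue, descriptor)."""
    token = re.sub(r"\s+", "", text)
    if token == "0:0":
        return FattyAcylResidue(0, 0), None

    pm = _PROSTANE_RE.match(token)
    if pm:
        family = pm.group("family")
        series = int(pm.group("series"))
        window = int(pm.group("w")) if pm.group("w") else 0
        res = FattyAcylResidue(FAMILY_CARBONS[family], series + 2)
        mod = ModificationDescriptor(
            residual_double_bonds=series,
            prostane=Prostane(pm.group("ring"), family, window),
        )
        return res, mod

    m = _CHAIN_RE.match(token)
    if not m:
        raise AbbreviationError(f"cannot parse residue {token!r}")
    c, d = int(m.group("c")), int(m.group("d"))
    counts = {"DB": None, "KETO": 0, "OH": 0, "OOH": 0, "EPOXY": 0}
    if m.group("bracket") is not None:
        for item in m.group("bracket").split(","):
            item = item.strip()
            im = _BRACKET_ITEM_RE.match(item)
            if not im:
                raise AbbreviationError(f"bad bracket item {item!r} in {token!r}")
            n, kind = int(im.group(1)), im.group(2)
            if kind == "DB":
                if counts["DB"] is not None:
                    raise AbbreviationError(f"duplicate DB item in {token!r}")
                counts["DB"] = n
            else:
                counts[kind] += n

    trunc = None
    if m.group("term"):
        site = int(m.group("site"))
        if site != c:
            raise AbbreviationError(
                f"truncation site C{site} does not match chain length {c} in {token!r}"
            )
        trunc = Truncation(site, m.group("term"))

    n_oap = counts["KETO"] + counts["OH"] + counts["OOH"] + counts["EPOXY"]
    if counts["DB"] is None and n_oap == 0 and trunc is None:
        return FattyAcylResidue(c, d), None

    if trunc is not None:
        # for a truncated chain, c:d already describes the retained chain
        residual = d if counts["DB"] is None else counts["DB"]
        if residual != d:
            raise AbbreviationError(
                f"bracket {residual}xDB contradicts chain {c}:{d} in {token!r}"
            )
        res = FattyAcylResidue(c, d)
    else:
        residual = counts["DB"] if counts["DB"] is not None else d - counts["EPOXY"]
        if residual > d:
            raise AbbreviationError(f"residual double bonds exceed {c}:{d} in {token!r}")
        res = FattyAcylResidue(c, d)
    mod = ModificationDescriptor(
        keto=counts["KETO"],
        oh=counts["OH"],
        ooh=counts["OOH"],
        epoxy=counts["EPOXY"],
        residual_double_bonds=residual,
        truncation=trunc,
    )
    return res, mod


_SPECIES_RE = re.compile(r"^(?P<cls>[A-Za-z]+)\((?P<body>.*)\)$")


def parse_abbreviation(text: str) -> LipidSpecies:
    """Parse a full species abbreviation such as ``PC(16:0/20:4)``.

    Sum compositions (``PC(36:4)``) are rejected: the workflow requires a
    discrete, defined fatty-acyl composition per position.
    """
    token = re.sub(r"\s+", "", text)
    m = _SPECIES_RE.match(token)
    if not m:
        raise AbbreviationError(f"cannot parse species {text!r}")
    cls = m.group("cls")
    if cls not in PL_CLASSES:
        raise AbbreviationError(f"unknown lipid class {cls!r} in {text!r}")
    body = m.group("body")
    if "/" not in body:
        raise AbbreviationError(
            f"{text!r} has no sn-1/sn-2 separator; sum compositions are not accepted"
        )
    left, _, right = body.partition("/")
    sn1, mod1 = parse_residue(left)
    sn2, mod2 = parse_residue(right)
    return LipidSpecies(cls, sn1, sn2, mod1, mod2)
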