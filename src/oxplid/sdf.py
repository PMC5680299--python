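"""Structure-library I/O: SDF (V2000) export/import, summary tables and
lipidome input files.

Each SDF record carries the representative structure plus a descriptor
block (abbreviation, class tags, formula, exact mass, adduct, residue
summaries, modification counts and the predicted spectrum/fingerprint as
JSON), so the library is self-describing for downstream tools.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import build_structure, default_adduct_for, species_adduct_mz, species_composition
from .fragmentation import FingerprintList, PredictedSpectrum
from .nomenclature import LipidSpecies, format_residue, parse_abbreviation
from .oxidation import PredictedLPP


def _descriptor_fields(lpp: PredictedLPP) -> dict[str, str]:
    sp = lpp.species
    compo = species_composition(sp)
    adduct = default_adduct_for(sp)
    fields = {
        "ABBREVIATION": sp.abbreviation,
        "PARENT": lpp.parent.abbreviation,
        "PL_CLASS": sp.pl_class,
        "LPP_CLASS": lpp.lpp_class_tag,
        "FORMULA": compo.formula(),
        "EXACT_MASS": f"{compo.monoisotopic_mass:.6f}",
        "ADDUCT": adduct,
        "ADDUCT_MZ": f"{species_adduct_mz(sp, adduct):.6f}",
        "SN1": format_residue(sp.sn1, sp.mod1),
        "SN2": format_residue(sp.sn2, sp.mod2),
    }
    for sn, res, mod in (("SN1", sp.sn1, sp.mod1), ("SN2", sp.sn2, sp.mod2)):
        from .chem import residue_acid_composition

        fields[f"{sn}_FORMULA"] = (
            "" if res.is_lyso else residue_acid_composition(res, mod).formula()
        )
    mods = [m for m in (sp.mod1, sp.mod2) if m is not None]
    fields["N_KETO"] = str(sum(m.keto for m in mods))
    fields["N_OH"] = str(sum(m.oh for m in mods))
    fields["N_OOH"] = str(sum(m.ooh for m in mods))
    fields["N_EPOXY"] = str(sum(m.epoxy for m in mods))
    truncs = [m.truncation for m in mods if m.truncation is not None]
    fields["TRUNCATION"] = (
        f"{truncs[0].terminal}@C{truncs[0].site}" if truncs else ""
    )
    return fields


def export_sdf(
    lpps: list[PredictedLPP],
    path: str | Path,
    spectra: dict[str, PredictedSpectrum] | None = None,
    fingerprints: dict[str, FingerprintList] | None = None,
) -> None:
    """Write predicted species to a V2000 SDF with descriptor data items.

    Deterministic: two runs over the same input produce identical bytes.
    """
    if not lpps:
        raise ValueError("no predicted species to export")
    with open(path, "w") as fh:
        for lpp in lpps:
            smiles = build_structure(lpp.species)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"generated structure failed to parse: {smiles}")
            mol.SetProp("_Name", lpp.abbreviation)
            block = Chem.MolToMolBlock(mol, kekulize=True)
            fh.write(block)
            fields = _descriptor_fields(lpp)
            fields["SMILES"] = Chem.MolToSmiles(mol)
            if spectra and lpp.abbreviation in spectra:
                fields["SPECTRUM_JSON"] = spectra[lpp.abbreviation].to_json()
            if fingerprints and lpp.abbreviation in fingerprints:
                fp = fingerprints[lpp.abbreviation]
                fields["FINGERPRINT_MZ"] = " ".join(f"{v:.4f}" for v in fp.mz_values)
            for key, value in fields.items():
                fh.write(f">  <{key}>\n{value}\n\n")
            fh.write("$$$$\n")


def import_sdf(path: str | Path) -> list[PredictedLPP]:
    """Re-read an exported library; species are rebuilt from the
    ABBREVIATION field (the authoritative descriptor)."""
    out: list[PredictedLPP] = []
    supplier = Chem.SDMolSupplier(str(path))
    for mol in supplier:
        if mol is None:
            continue
        abbrev = mol.GetProp("ABBREVIATION")
        parent = mol.GetProp("PARENT") if mol.HasProp("PARENT") else abbrev
        sp = parse_abbreviation(abbrev)
        out.append(PredictedLPP(parse_abbreviation(parent), sp, sp.lpp_class_tag))
    return out


def summary_frame(lpps: list[PredictedLPP]) -> pd.DataFrame:
    rows = []
    for lpp in lpps:
        f = _descriptor_fields(lpp)
        rows.append(
            {
                "abbreviation": f["ABBREVIATION"],
                "parent": f["PARENT"],
                "pl_class": f["PL_CLASS"],
                "lpp_class": f["LPP_CLASS"],
                "formula": f["FORMULA"],
                "exact_mass": float(f["EXACT_MASS"]),
                "adduct": f["ADDUCT"],
                "adduct_mz": float(f["ADDUCT_MZ"]),
                "sn1": f["SN1"],
                "sn2": f["SN2"],
            }
        )
    return pd.DataFrame(rows)


def export_summary_table(lpps: list[PredictedLPP], path: str | Path) -> None:
    if not lpps:
        raise ValueError("no predicted species to export")
    path = Path(path)
    frame = summary_frame(lpps)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_lipidome(path: str | Path) -> list[LipidSpecies]:
    """Read a lipidome table (CSV or XLSX) with an ``abbreviation`` column."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "abbreviation" not in cols:
        raise ValueError(f"{path} has no 'abbreviation' column")
    return [parse_abbreviation(a) for a in frame[cols["abbreviation"]].astype(str)]


def check_structure(lpp: PredictedLPP) -> bool:
    """RDKit cross-check: the generated SMILES must carry the formula the
    composition arithmetic predicts."""
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    mol = Chem.MolFromSmiles(build_structure(lpp.species))
    if mol is None:
        return False
    rd = CalcMolFormula(mol)
    # strip charge suffixes RDKit appends for zwitterions
    rd = rd.replace("+", "").replace("-", "")
    return rd == species_composition(lpp.species).formula()
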