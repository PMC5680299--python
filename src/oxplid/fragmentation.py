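"""In-silico CID spectra and fingerprint m/z lists for predicted species.

The predicted spectrum holds the *main* structure-related signals:
head-group fragments and neutral losses, the sn-1/sn-2 carboxylate
anions (at their modified masses), residue neutral losses as ketene and
as free acid, and modification-specific losses (water per hydroxyl,
hydrogen peroxide per hydroperoxide, CO2 for a carboxyl truncation
terminal).  Keto and epoxy groups emit no specific loss.

The fingerprint list is the exhaustive white list used by the
intensity-independent score: every base ion expanded by cumulative water
losses up to the residue's OH+OOH count, deduplicated and sorted.

PC formate adducts fragment through the demethylated species
[M+HCOO-CH3-HCOOH]- = [M-CH3]-, which serves as the precursor surrogate
for all subsequent losses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .chem import (
    adduct_composition,
    default_adduct_for,
    residue_acid_composition,
    species_composition,
)
from .constants import MASS_CO2, MASS_H2O, MASS_H2O2
from .formula import ElementalComposition, comp
from .nomenclature import LipidSpecies

# class-diagnostic head-group fragment ions (composition, anions)
_HEAD_FRAGMENTS: dict[str, tuple[tuple[str, str], ...]] = {
    "PA": (("glycerophosphate-H2O", "C3H6O5P"), ("PO3", "O3P")),
    "PC": (
        ("phosphocholine-CH3", "C4H11NO4P"),
        ("glycerophosphocholine-CH3-H2O", "C7H15NO5P"),
    ),
    "PE": (
        ("phosphoethanolamine", "C2H7NO4P"),
        ("glycerophosphoethanolamine-H2O", "C5H11NO5P"),
    ),
    "PG": (("glycerophosphate-H2O", "C3H6O5P"), ("glycerophosphoglycerol-H2O", "C6H12O7P")),
    "PS": (("glycerophosphate-H2O", "C3H6O5P"), ("PO3", "O3P")),
}

_SERINE = comp("C3H5NO2")
_CH3 = comp("CH3")
_H = comp("H")
_H2O = comp("H2O")


@dataclass(frozen=True)
class FragmentIon:
    mz: float
    relative_intensity: int  # 0..999
    ion_type: str
    signal_class: str  # sn1 | sn2 | head | precursor
    composition: ElementalComposition | None = None


@dataclass
class PredictedSpectrum:
    abbreviation: str
    adduct: str
    precursor_mz: float
    ions: list[FragmentIon]

    def peak_list(self) -> list[tuple[float, float]]:
        return [(ion.mz, float(ion.relative_intensity)) for ion in self.ions]

    def white_list(self) -> list[tuple[float, str]]:
        """(mz, signal_class) entries used by the rank score."""
        return [(ion.mz, ion.signal_class) for ion in self.ions]

    def to_json(self) -> str:
        return json.dumps(
            {
                "abbreviation": self.abbreviation,
                "adduct": self.adduct,
                "precursor_mz": round(self.precursor_mz, 6),
                "ions": [
                    {
                        "mz": round(i.mz, 6),
                        "i": i.relative_intensity,
                        "type": i.ion_type,
                        "class": i.signal_class,
                    }
                    for i in self.ions
                ],
            }
        )


@dataclass
class FingerprintList:
    abbreviation: str
    adduct: str
    precursor_mz: float
    mz_values: list[float]
    labels: list[str]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.mz_values, self.mz_values[1:])):
            raise ValueError("fingerprint m/z values must be strictly increasing")


class FragmentationProfile(dict):
    """ion_type -> relative intensity (0..999); missing types default 100."""

    def intensity(self, ion_type: str) -> int:
        return int(self.get(ion_type, 100))


def load_profile(path: str | Path | None = None) -> FragmentationProfile:
    if path is None:
        ref = resources.files("oxplid.data") / "default_profile.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return FragmentationProfile(raw)


# ---------------------------------------------------------------------------

def _base_ions(
    sp: LipidSpecies, adduct: str
) -> tuple[float, list[tuple[str, str, float, ElementalComposition | None]]]:
    """(precursor m/z, [(ion_type, signal_class, mz, composition), ...])."""
    neutral = species_composition(sp)
    precursor = adduct_composition(neutral, adduct)
    precursor_mz = precursor.mz

    ions: list[tuple[str, str, float, ElementalComposition | None]] = []

    # precursor surrogate: the species all residue/head losses start from
    if sp.pl_class == "PC" and adduct == "[M+HCOO]-":
        surrogate = (neutral - _CH3).replace_charge(-1)
        ions.append(("precursor_surrogate", "precursor", surrogate.mz, surrogate))
    else:
        surrogate = (neutral - _H).replace_charge(-1)

    for name, formula in _HEAD_FRAGMENTS[sp.pl_class]:
        frag = comp(formula, charge=-1)
        ions.append((f"head_fragment:{name}", "head", frag.mz, frag))
    if sp.pl_class == "PS":
        loss = (surrogate - _SERINE)
        ions.append(("head_neutral_loss:serine", "head", loss.mz, loss))

    for sn, res, mod in (("sn1", sp.sn1, sp.mod1), ("sn2", sp.sn2, sp.mod2)):
        if res.is_lyso:
            continue
        acid = residue_acid_composition(res, mod)
        carbox = (acid - _H).replace_charge(-1)
        ions.append((f"{sn}_carboxylate", sn, carbox.mz, carbox))
        nl_acid = surrogate - acid
        ions.append((f"sn_neutral_loss_acid:{sn}", sn, nl_acid.mz, nl_acid))
        nl_ketene = surrogate - (acid - _H2O)
        ions.append((f"sn_neutral_loss_ketene:{sn}", sn, nl_ketene.mz, nl_ketene))

        if mod is not None:
            waters = mod.oh + mod.ooh
            for j in range(1, waters + 1):
                ions.append(
                    (f"water_loss:{sn}_carboxylate-{j}xH2O", sn, carbox.mz - j * MASS_H2O, None)
                )
            if mod.ooh:
                ions.append(
                    ("peroxide_loss:precursor-H2O2", "precursor", surrogate.mz - MASS_H2O2, None)
                )
            if mod.truncation is not None and mod.truncation.terminal == "COOH":
                ions.append(
                    (f"co2_loss:{sn}_carboxylate-CO2", sn, carbox.mz - MASS_CO2, None)
                )
    return precursor_mz, ions


def generate_spectrum(
    sp: LipidSpecies,
    adduct: str | None = None,
    profile: FragmentationProfile | None = None,
) -> PredictedSpectrum:
    """Predict the CID spectrum of a species for the given (or default)
    adduct.  The profile sets relative intensities only; the ion
    inventory is structural."""
    adduct = adduct or default_adduct_for(sp)
    profile = profile if profile is not None else load_profile()
    precursor_mz, raw = _base_ions(sp, adduct)
    best: dict[float, FragmentIon] = {}
    for ion_type, signal_class, mz, composition in raw:
        if not 0 < mz < precursor_mz:
            continue
        rel = profile.intensity(ion_type.split(":")[0])
        key = round(mz, 4)
        if key not in best or best[key].relative_intensity < rel:
            best[key] = FragmentIon(mz, rel, ion_type, signal_class, composition)
    ions = sorted(best.values(), key=lambda i: i.mz)
    if not any(i.signal_class == "head" for i in ions):
        raise ValueError(f"no head-group diagnostic ion for {sp.abbreviation}")
    return PredictedSpectrum(sp.abbreviation, adduct, precursor_mz, ions)


def generate_fingerprint(
    sp: LipidSpecies, adduct: str | None = None
) -> FingerprintList:
    """Exhaustive modification-aware m/z white list for a species.

    Every base ion is expanded by cumulative water losses up to the
    species' total OH+OOH count; duplicates within 0.1 mDa collapse.
    """
    adduct = adduct or default_adduct_for(sp)
    precursor_mz, raw = _base_ions(sp, adduct)
    waters = sum(
        m.oh + m.ooh for m in (sp.mod1, sp.mod2) if m is not None
    )
    entries: list[tuple[float, str]] = []
    for ion_type, _cls, mz, _compo in raw:
        for j in range(waters + 1):
            value = mz - j * MASS_H2O
            if not 0 < value < precursor_mz + 1.0:
                continue
            label = ion_type if j == 0 else f"{ion_type}-{j}xH2O"
            entries.append((value, label))
    entries.sort()
    mz_values: list[float] = []
    labels: list[str] = []
    for mz, label in entries:
        if mz_values and abs(mz - mz_values[-1]) < 1e-4:
            continue
        mz_values.append(mz)
        labels.append(label)
    return FingerprintList(sp.abbreviation, adduct, precursor_mz, mz_values, labels)


# ---------------------------------------------------------------------------
# MSP export (NIST text dialect)

def export_msp(spectra: list[PredictedSpectrum], path: str | Path) -> None:
    if not spectra:
        raise ValueError("no spectra to export")
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write(f"Name: {sp.abbreviation} {sp.adduct}\n")
            fh.write(f"PrecursorMZ: {sp.precursor_mz:.4f}\n")
            fh.write(f"Num Peaks: {len(sp.ions)}\n")
            for ion in sp.ions:
                fh.write(f"{ion.mz:.4f} {ion.relative_intensity}\n")
            fh.write("\n")


def read_msp(path: str | Path) -> list[PredictedSpectrum]:
    """Minimal MSP reader for round-trip checks of exported libraries."""
    spectra: list[PredictedSpectrum] = []
    name = ""
    precursor = 0.0
    peaks: list[tuple[float, int]] = []

    def _flush():
        if name:
            abbrev, _, adduct = name.rpartition(" ")
            ions = [
                FragmentIon(mz, inten, "unknown", "unknown") for mz, inten in peaks
            ]
            spectra.append(PredictedSpectrum(abbrev, adduct, precursor, ions))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                _flush()
                name, precursor, peaks = "", 0.0, []
                continue
            if line.startswith("Name:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("PrecursorMZ:"):
                precursor = float(line.split(":", 1)[1])
            elif line.startswith("Num Peaks:"):
                continue
            elif name:
                mz_s, int_s = line.split()
                peaks.append((float(mz_s), int(int_s)))
    _flush()
    return spectra
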