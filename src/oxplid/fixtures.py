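"""Synthetic, fully self-contained DDA fixtures.

A fixture run plants chosen library species as Gaussian chromatographic
peaks: every survey scan carries their isotope-resolved M..M+2 envelopes
(optionally perturbed), and data-dependent MS2 events are triggered on
the most intense eligible survey peaks, carrying the predicted spectrum
plus impurity peaks and a noise floor.  Impurity and floor peaks are
kept away from every fingerprint m/z window so that they are impurities
in the scoring sense, not accidental structure signals.

Decoy candidates are residue-reshuffled isomers of library species: the
same head group and elemental composition (hence precursor m/z), but
fatty-acyl chains whose carboxylate ions match nothing planted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chem import residue_acid_composition
from .config import ScoringConfig
from .formula import comp
from .mzml_io import SpectrumRecord, write_mzml
from .nomenclature import FattyAcylResidue, LipidSpecies, Truncation
from .oxidation import PredictedLPP
from .pipeline import LibraryEntry, SpectralLibrary

_H = comp("H")


@dataclass(frozen=True)
class PlantedLPP:
    abbreviation: str
    rt_apex_min: float
    precursor_intensity: float
    peak_scale: float = 1.0


@dataclass
class FixtureSpec:
    """Parameters of one synthetic DDA run.

    Defaults mirror a negative-mode RPLC-DDA acquisition: survey range
    m/z 200-1200, MS2 range 50-1200, 12 MS2 events per cycle, precursor
    threshold 1000 counts, 0.2 min FWHM chromatographic peaks.
    """

    planted: list[PlantedLPP]
    seed: int = 0
    rt_start_min: float = 0.5
    rt_end_min: float = 12.0
    cycle_min: float = 0.05
    fwhm_min: float = 0.2
    top_n: int = 12
    min_precursor_intensity: float = 1000.0
    dynamic_exclusion_min: float = 0.3
    noise_floor_peaks: int = 0
    impurity_peaks: int = 0
    isotope_epsilon: float = 0.0
    ms1_range: tuple[float, float] = (200.0, 1200.0)
    ms2_range: tuple[float, float] = (50.0, 1200.0)


def _gauss(rt: float, apex: float, fwhm: float) -> float:
    sigma = fwhm / 2.3548200450309493
    return float(np.exp(-0.5 * ((rt - apex) / sigma) ** 2))


def _excluded(mz: float, forbidden: np.ndarray, half_width: float = 0.05) -> bool:
    if forbidden.size == 0:
        return False
    i = np.searchsorted(forbidden, mz)
    for j in (i - 1, i):
        if 0 <= j < forbidden.size and abs(forbidden[j] - mz) <= half_width:
            return True
    return False


def make_dda_run(
    spec: FixtureSpec, library: SpectralLibrary, path: str | Path
) -> dict[str, list[int]]:
    """Write a synthetic DDA mzML file; returns the ground truth as a map
    abbreviation -> list of MS2 scan numbers fragmenting that species."""
    by_abbrev = {e.abbreviation: e for e in library.entries}
    entries: list[tuple[PlantedLPP, LibraryEntry]] = []
    for planted in spec.planted:
        if planted.abbreviation not in by_abbrev:
            raise ValueError(f"planted species {planted.abbreviation!r} not in library")
        entry = by_abbrev[planted.abbreviation]
        lo, hi = spec.ms1_range
        if not lo <= entry.mz <= hi:
            raise ValueError(
                f"planted precursor m/z {entry.mz:.4f} outside survey range {lo}-{hi}"
            )
        entries.append((planted, entry))

    rng = np.random.default_rng(spec.seed)
    forbidden = np.sort(
        np.concatenate(
            [np.asarray(e.fingerprint.mz_values) for e in library.entries]
            + [np.array([e.mz, e.mz + 1.0034, e.mz + 2.0067]) for e in library.entries]
        )
    )

    # per-planted isotope ratios, optionally perturbed once per species
    ratios: dict[str, tuple[float, float]] = {}
    for planted, entry in entries:
        r1, r2 = entry.isotope_pattern.r1, entry.isotope_pattern.r2
        if spec.isotope_epsilon:
            r1 *= 1.0 + spec.isotope_epsilon * rng.uniform(-1, 1)
            r2 *= 1.0 + spec.isotope_epsilon * rng.uniform(-1, 1)
        ratios[planted.abbreviation] = (r1, r2)

    records: list[SpectrumRecord] = []
    truth: dict[str, list[int]] = {p.abbreviation: [] for p, _ in entries}
    last_fragmented: dict[str, float] = {}
    rt = spec.rt_start_min
    while rt <= spec.rt_end_min + 1e-9:
        mz_list: list[float] = []
        int_list: list[float] = []
        eligible: list[tuple[float, PlantedLPP, LibraryEntry]] = []
        for planted, entry in entries:
            height = planted.precursor_intensity * _gauss(
                rt, planted.rt_apex_min, spec.fwhm_min
            )
            if height < 1.0:
                continue
            r1, r2 = ratios[planted.abbreviation]
            mz_list.extend([entry.mz, entry.mz + 1.0033548, entry.mz + 2.0067096])
            int_list.extend([height, height * r1, height * r2])
            if height >= spec.min_precursor_intensity:
                eligible.append((height, planted, entry))
        for _ in range(spec.noise_floor_peaks):
            mz = rng.uniform(*spec.ms1_range)
            if _excluded(mz, forbidden):
                continue
            mz_list.append(mz)
            int_list.append(rng.uniform(1.0, 50.0))
        order = np.argsort(mz_list)
        records.append(
            SpectrumRecord(
                1, rt, np.asarray(mz_list)[order], np.asarray(int_list)[order]
            )
        )

        # DDA: fragment the top-N eligible precursors not recently picked
        eligible.sort(key=lambda t: (-t[0], t[1].abbreviation))
        picked = 0
        for height, planted, entry in eligible:
            if picked >= spec.top_n:
                break
            last = last_fragmented.get(planted.abbreviation)
            if last is not None and rt - last < spec.dynamic_exclusion_min:
                continue
            last_fragmented[planted.abbreviation] = rt
            picked += 1
            ms2_rt = rt + spec.cycle_min * (picked / (spec.top_n + 1))
            mzs = []
            ints = []
            for ion in entry.spectrum.ions:
                if spec.ms2_range[0] <= ion.mz <= spec.ms2_range[1]:
                    mzs.append(ion.mz)
                    ints.append(ion.relative_intensity * planted.peak_scale)
            top_int = max(ints)
            for _ in range(spec.impurity_peaks):
                mz = rng.uniform(*spec.ms2_range)
                if _excluded(mz, forbidden) or mz >= entry.mz - 0.5:
                    continue
                mzs.append(mz)
                ints.append(rng.uniform(0.05, 2.0) * top_int)
            order = np.argsort(mzs)
            records.append(
                SpectrumRecord(
                    2,
                    ms2_rt,
                    np.asarray(mzs)[order],
                    np.asarray(ints)[order],
                    precursor_mz=entry.mz,
                    precursor_intensity=height,
                )
            )
            truth[planted.abbreviation].append(len(records))
        rt += spec.cycle_min

    write_mzml(records, path)
    return truth


# ---------------------------------------------------------------------------
# decoys

def _species_carboxylates(sp: LipidSpecies) -> list[float]:
    vals = []
    for res, mod in ((sp.sn1, sp.mod1), (sp.sn2, sp.mod2)):
        if res.is_lyso:
            continue
        vals.append((residue_acid_composition(res, mod) - _H).replace_charge(-1).mz)
    return vals


def _carboxylate_mzs(entries: list[LibraryEntry]) -> np.ndarray:
    vals = []
    for e in entries:
        vals.extend(_species_carboxylates(e.species))
    return np.sort(np.array(vals))


def _shift_residue(res: FattyAcylResidue, mod, delta: int):
    """Move ``delta`` carbons into/out of a residue, preserving its
    double-bond and modification pattern; None when impossible."""
    c = res.carbons + delta
    if c < 4 or res.is_lyso:
        return None
    if mod is not None and mod.truncation is not None:
        if mod.residual_double_bonds:
            return None  # keep decoy truncations simple: saturated chains only
        new_mod = replace(mod, truncation=Truncation(c, mod.truncation.terminal))
        return FattyAcylResidue(c, 0), new_mod
    if res.double_bonds and res.positions:
        positions = tuple(p + delta for p in res.positions)
        if any(p < 2 or p >= c for p in positions):
            return None
        return FattyAcylResidue(c, res.double_bonds, positions), mod
    if res.double_bonds:
        key_pos = 2 + res.double_bonds * 3
        if c < key_pos:
            return None
    return FattyAcylResidue(c, res.double_bonds), mod


def make_decoy_candidates(
    library: SpectralLibrary, count: int, seed: int
) -> list[PredictedLPP]:
    """Isomeric decoys: same class and composition as a library species but
    a different carbon split across sn-1/sn-2, so the precursor m/z is
    preserved while no carboxylate ion m/z coincides with the library's."""
    if count == 0:
        return []
    if not len(library):
        raise ValueError("empty library")
    rng = np.random.default_rng(seed)
    own_carbox = _carboxylate_mzs(library.entries)
    existing = {e.abbreviation for e in library.entries}
    decoys: list[PredictedLPP] = []
    pool = sorted(library.entries, key=lambda e: e.abbreviation)
    order = rng.permutation(len(pool))
    deltas = [2, -2, 3, -3, 4, -4]
    for idx in list(order) * len(deltas):
        if len(decoys) >= count:
            break
        src = pool[int(idx)].species
        for delta in deltas:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = _shift_residue(src.sn1, src.mod1, delta)
                b = _shift_residue(src.sn2, src.mod2, -delta)
                if a is None or b is None:
                    continue
                try:
                    cand = LipidSpecies(src.pl_class, a[0], b[0], a[1], b[1])
                except Exception:  # noqa: BLE001 - invalid reshuffle
                    continue
                if cand.abbreviation in existing:
                    continue
                cmzs = _species_carboxylates(cand)
            if any(np.min(np.abs(own_carbox - v)) < 0.01 for v in cmzs):
                continue
            existing.add(cand.abbreviation)
            decoys.append(PredictedLPP(cand, cand, cand.lpp_class_tag))
            break
    if len(decoys) < count:
        raise ValueError(f"could only construct {len(decoys)} of {count} decoys")
    return decoys
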