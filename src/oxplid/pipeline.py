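"""End-to-end identification of oxidized phospholipids from DDA runs.

The pipeline matches recorded MS2 precursor m/z values against the
predicted library, verifies the precursor's isotope envelope in the
linked survey scan, scores every candidate/spectrum pair with the
five-score system and reports candidates that clear all thresholds,
ranked per spectrum by overall score.
"""

from __future__ import annotations

import concurrent.futures
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import default_adduct_for, species_adduct_mz, species_composition
from .config import ScoringConfig
from .constants import ISOTOPE_SPACING
from .formula import ElementalComposition
from .fragmentation import (
    FingerprintList,
    FragmentationProfile,
    PredictedSpectrum,
    generate_fingerprint,
    generate_spectrum,
)
from .isotopes import IsotopePattern, predict_isotope_pattern
from .mzml_io import DdaRun, Ms1Scan, ObservedSpectrum, read_dda_run
from .nomenclature import LipidSpecies
from .oxidation import PredictedLPP
from .scoring import (
    ScoreBundle,
    fingerprint_score,
    isotope_score,
    match_targets,
    overall_score,
    rank_score,
    similarity_score,
)

#: fixed m/z window (Th) for the M-1 isotope-overlap guard; deliberately not
#: tied to ms1_ppm so that tightening the tolerance never adds candidates
GUARD_WINDOW = 0.01


@dataclass
class LibraryEntry:
    species: LipidSpecies
    abbreviation: str
    adduct: str
    mz: float
    ion_composition: ElementalComposition
    spectrum: PredictedSpectrum
    fingerprint: FingerprintList
    isotope_pattern: IsotopePattern


class SpectralLibrary:
    """Predicted spectra + fingerprints, sorted by precursor m/z."""

    def __init__(self, entries: list[LibraryEntry]):
        self.entries = sorted(entries, key=lambda e: (e.mz, e.abbreviation))
        self._mz = np.array([e.mz for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def candidates_for(self, precursor_mz: float, ppm: float) -> list[LibraryEntry]:
        tol = precursor_mz * ppm * 1e-6
        lo = np.searchsorted(self._mz, precursor_mz - tol, side="left")
        hi = np.searchsorted(self._mz, precursor_mz + tol, side="right")
        return list(self.entries[lo:hi])


def build_library(
    predicted: list[PredictedLPP] | list[LipidSpecies],
    profile: FragmentationProfile | None = None,
) -> SpectralLibrary:
    """Turn predicted species into a scoring-ready spectral library."""
    from .chem import adduct_composition

    entries = []
    for item in predicted:
        sp = item.species if isinstance(item, PredictedLPP) else item
        adduct = default_adduct_for(sp)
        neutral = species_composition(sp)
        ion = adduct_composition(neutral, adduct)
        entries.append(
            LibraryEntry(
                species=sp,
                abbreviation=sp.abbreviation,
                adduct=adduct,
                mz=ion.mz,
                ion_composition=ion,
                spectrum=generate_spectrum(sp, adduct, profile),
                fingerprint=generate_fingerprint(sp, adduct),
                isotope_pattern=predict_isotope_pattern(ion),
            )
        )
    return SpectralLibrary(entries)


# ---------------------------------------------------------------------------

def match_precursors(
    library: SpectralLibrary, run: DdaRun, cfg: ScoringConfig
) -> list[tuple[ObservedSpectrum, list[LibraryEntry]]]:
    """Candidate library entries per MS2 event.

    A candidate is dropped when the linked survey scan shows a stronger
    peak one isotope spacing below the precursor (the recorded precursor
    is then likely the M+1 of a lighter species).
    """
    out = []
    for ms2 in run.ms2_scans:
        cands = library.candidates_for(ms2.precursor_mz, cfg.ms1_ppm)
        if not cands:
            continue
        survey = run.survey_for(ms2)
        if survey is not None and _m1_pickup(survey, ms2.precursor_mz):
            continue
        out.append((ms2, cands))
    return out


def _m1_pickup(survey: Ms1Scan, precursor_mz: float) -> bool:
    own = _peak_intensity(survey, precursor_mz, GUARD_WINDOW)
    below = _peak_intensity(survey, precursor_mz - ISOTOPE_SPACING, GUARD_WINDOW)
    return below > own > 0


def _peak_intensity(scan: Ms1Scan, mz: float, window: float) -> float:
    mask = np.abs(scan.mz - mz) <= window
    return float(scan.intensity[mask].max()) if mask.any() else 0.0


def extract_xic(
    ms1_scans: list[Ms1Scan], target_mz: float, ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-scan summed intensity within +-ppm of the target m/z."""
    if not ms1_scans:
        raise ValueError("no MS1 scans")
    tol = target_mz * ppm * 1e-6
    rt = np.array([s.rt_min for s in ms1_scans])
    inten = np.array(
        [
            float(s.intensity[np.abs(s.mz - target_mz) <= tol].sum())
            for s in ms1_scans
        ]
    )
    return rt, inten


def measure_isotope_pattern(
    survey: Ms1Scan, mono_mz: float, cfg: ScoringConfig
) -> IsotopePattern | None:
    """Observed r1/r2 at the theoretical isotopologue positions; None when
    the monoisotopic peak itself is absent."""
    tol = mono_mz * cfg.ms1_ppm * 1e-6
    i0 = _peak_intensity(survey, mono_mz, tol)
    if i0 <= 0:
        return None
    i1 = _peak_intensity(survey, mono_mz + ISOTOPE_SPACING, tol)
    i2 = _peak_intensity(survey, mono_mz + 2 * ISOTOPE_SPACING, tol)
    return IsotopePattern(r1=i1 / i0, r2=i2 / i0)


# ---------------------------------------------------------------------------

@dataclass
class IdentificationResult:
    abbreviation: str
    lpp_class_tag: str
    formula: str
    adduct: str
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    rt_min: float
    scan_number: int
    dda_rank: int
    survey_scan: int
    scores: ScoreBundle
    overall: float
    rank_in_spectrum: int = 0
    n_matched_signals: int = 0

    def row(self) -> dict:
        d = {
            "abbreviation": self.abbreviation,
            "lpp_class": self.lpp_class_tag,
            "formula": self.formula,
            "adduct": self.adduct,
            "theoretical_mz": round(self.theoretical_mz, 4),
            "observed_mz": round(self.observed_mz, 4),
            "ppm_error": round(self.ppm_error, 2),
            "rt_min": self.rt_min,
            "scan_number": self.scan_number,
            "dda_rank": self.dda_rank,
            "survey_scan": self.survey_scan,
            "rank_in_spectrum": self.rank_in_spectrum,
            "n_matched_signals": self.n_matched_signals,
            "overall_score": round(self.overall, 2),
        }
        for name, value in self.scores.as_dict().items():
            d[f"{name}_score"] = round(value, 2)
        return d


RESULT_COLUMNS = [
    "abbreviation", "lpp_class", "formula", "adduct", "theoretical_mz",
    "observed_mz", "ppm_error", "rt_min", "scan_number", "dda_rank",
    "survey_scan", "rank_in_spectrum", "n_matched_signals", "overall_score",
    "similarity_score", "rank_score", "fingerprint_score",
    "specificity_score", "isotope_score",
]


def identify(
    run: DdaRun, library: SpectralLibrary, cfg: ScoringConfig | None = None
) -> list[IdentificationResult]:
    """Score all candidate/spectrum pairs of a run and keep survivors."""
    from .scoring import specificity_score

    cfg = cfg or ScoringConfig()
    results: list[IdentificationResult] = []
    for ms2, cands in match_precursors(library, run, cfg):
        survey = run.survey_for(ms2)
        if survey is None:
            continue
        peaks = ms2.peaks
        # observed peaks matched per candidate (for the specificity split)
        matched_idx: dict[str, set[int]] = {}
        prelim = []
        for entry in cands:
            obs_pattern = measure_isotope_pattern(survey, entry.mz, cfg)
            if obs_pattern is None:
                continue
            wl = entry.spectrum.white_list()
            matches = match_targets(
                [mz for mz, _ in wl], ms2.mz, ms2.intensity, cfg.ms2_ppm
            )
            peak_ids = {
                int(np.argmin(np.abs(ms2.mz - m.observed_mz))) for m in matches
            }
            matched_idx[entry.abbreviation] = peak_ids
            prelim.append((entry, obs_pattern, matches))
        for entry, obs_pattern, matches in prelim:
            mine = matched_idx[entry.abbreviation]
            others: set[int] = set()
            for abbr, ids in matched_idx.items():
                if abbr != entry.abbreviation:
                    others |= ids
            specific = float(ms2.intensity[sorted(mine)].sum()) if mine else 0.0
            unspecific = float(ms2.intensity[sorted(others - mine)].sum())
            bundle = ScoreBundle(
                similarity=similarity_score(entry.spectrum.peak_list(), peaks, cfg),
                rank=rank_score(entry.spectrum.white_list(), peaks, cfg),
                fingerprint=fingerprint_score(entry.fingerprint.mz_values, peaks, cfg),
                specificity=specificity_score(specific, unspecific, cfg),
                isotope=isotope_score(entry.isotope_pattern, obs_pattern),
                matched_signals=matches,
            )
            overall = overall_score(bundle, cfg)
            if overall is None:
                continue
            ppm_err = (ms2.precursor_mz - entry.mz) / entry.mz * 1e6
            results.append(
                IdentificationResult(
                    abbreviation=entry.abbreviation,
                    lpp_class_tag=entry.species.lpp_class_tag,
                    formula=entry.ion_composition.formula(),
                    adduct=entry.adduct,
                    theoretical_mz=entry.mz,
                    observed_mz=ms2.precursor_mz,
                    ppm_error=ppm_err,
                    rt_min=ms2.rt_min,
                    scan_number=ms2.scan_number,
                    dda_rank=ms2.dda_rank,
                    survey_scan=ms2.survey_scan,
                    scores=bundle,
                    overall=overall,
                    n_matched_signals=len(matches),
                )
            )
    # rank survivors within each spectrum by overall score
    by_scan: dict[int, list[IdentificationResult]] = {}
    for r in results:
        by_scan.setdefault(r.scan_number, []).append(r)
    ordered: list[IdentificationResult] = []
    for scan in sorted(by_scan):
        group = sorted(by_scan[scan], key=lambda r: (-r.overall, r.abbreviation))
        for i, r in enumerate(group, start=1):
            r.rank_in_spectrum = i
            ordered.append(r)
    return ordered


# ---------------------------------------------------------------------------
# output

def results_frame(results: list[IdentificationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results], columns=RESULT_COLUMNS)


def write_results(results: list[IdentificationResult], path: str | Path) -> None:
    """Write the result table as CSV; an .xlsx sibling is written too."""
    path = Path(path)
    frame = results_frame(results)
    frame.to_csv(path, index=False)
    try:
        frame.to_excel(path.with_suffix(".xlsx"), index=False)
    except ModuleNotFoundError:  # openpyxl is optional at runtime
        pass


def write_report(
    results: list[IdentificationResult],
    run: DdaRun,
    library: SpectralLibrary,
    out_dir: str | Path,
    plots: bool = False,
) -> None:
    """JSON log plus (optionally) a plot bundle per identification."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(results, out / "identifications.csv")
    log = {
        "run": run.path,
        "n_ms1": len(run.ms1_scans),
        "n_ms2": len(run.ms2_scans),
        "n_skipped_scans": run.skipped,
        "n_identifications": len(results),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    if plots:
        from .plotting import plot_identification

        by_abbrev = {e.abbreviation: e for e in library.entries}
        for i, r in enumerate(results):
            entry = by_abbrev[r.abbreviation]
            plot_identification(
                r, run, entry, out / f"id_{i + 1:03d}_{r.scan_number}.png"
            )


def run_batch(
    paths: list[str | Path],
    library: SpectralLibrary,
    cfg: ScoringConfig | None = None,
    workers: int = 1,
) -> dict[str, list[IdentificationResult] | Exception]:
    """Identify over several runs; results keyed by path, input order.

    Results are independent of the worker count (runs are processed in
    isolation and merged in input order); a failing run is reported as an
    exception without aborting the batch.
    """
    cfg = cfg or ScoringConfig()

    def one(p):
        return identify(read_dda_run(p), library, cfg)

    out: dict[str, list[IdentificationResult] | Exception] = {}
    if workers <= 1:
        for p in paths:
            try:
                out[str(p)] = one(p)
            except Exception as exc:  # noqa: BLE001 - batch isolation
                out[str(p)] = exc
    else:
        with concurrent.futures.ThreadPoolExecutor(max_workers=workers) as pool:
            futures = {str(p): pool.submit(one, p) for p in paths}
            for p, fut in futures.items():
                try:
                    out[p] = fut.result()
                except Exception as exc:  # noqa: BLE001
                    out[p] = exc
    return out
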