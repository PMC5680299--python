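"""Static plot bundle for manual review of identifications: XIC, survey
scan isotope zoom and annotated MS/MS, one PNG per identification."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .constants import ISOTOPE_SPACING  # noqa: E402
from .pipeline import (  # noqa: E402
    DdaRun,
    IdentificationResult,
    LibraryEntry,
    extract_xic,
)


def plot_identification(
    result: IdentificationResult,
    run: DdaRun,
    entry: LibraryEntry,
    path: str | Path,
    ppm: float = 10.0,
) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))

    rt, inten = extract_xic(run.ms1_scans, entry.mz, ppm)
    axes[0].plot(rt, inten, lw=1)
    axes[0].axvline(result.rt_min, color="r", ls="--", lw=0.8)
    axes[0].set_xlabel("RT (min)")
    axes[0].set_ylabel("intensity")
    axes[0].set_title(f"XIC m/z {entry.mz:.4f}")

    survey = next(
        (s for s in run.ms1_scans if s.scan_number == result.survey_scan), None
    )
    if survey is not None:
        lo, hi = entry.mz - 1.5, entry.mz + 2 * ISOTOPE_SPACING + 1.5
        mask = (survey.mz >= lo) & (survey.mz <= hi)
        axes[1].stem(
            survey.mz[mask], survey.intensity[mask], basefmt=" ", markerfmt=" "
        )
        for i in range(3):
            axes[1].axvline(
                entry.mz + i * ISOTOPE_SPACING, color="r", ls=":", lw=0.6
            )
    axes[1].set_xlabel("m/z")
    axes[1].set_title(f"survey scan (isotope score {result.scores.isotope:.1f})")

    ms2 = next(
        (s for s in run.ms2_scans if s.scan_number == result.scan_number), None
    )
    if ms2 is not None:
        axes[2].stem(ms2.mz, ms2.intensity, basefmt=" ", markerfmt=" ")
        for m in result.scores.matched_signals:
            axes[2].plot(m.observed_mz, m.observed_intensity, "rv", ms=4)
    axes[2].set_xlabel("m/z")
    axes[2].set_title(f"{result.abbreviation}  score {result.overall:.1f}")

    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
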