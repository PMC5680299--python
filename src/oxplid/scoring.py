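"""The five-score identification system.

For one (candidate, observed MS/MS spectrum) pair the system computes:

* Spectra Similarity — reverse dot product of Stein-style weights
  W = intensity^m * mz^n over *library* ions only; unmatched observed
  (impurity) peaks do not enter the normalisation.
* Rank Score — intensity-ranked comparison of observed peaks against the
  candidate's white list of residue/head-group signals; rank index i
  contributes (10-(i-1))/10, weighted per signal class and normalised by
  the candidate's maximum attainable sum.
* Fingerprint Score — cosine of the observed 0/1 match vector against
  the all-ones vector over the exhaustive fingerprint m/z list,
  100*sqrt(k/N) for k matches out of N.
* Specificity Score — decibel signal-to-noise ratio of summed
  candidate-specific vs unspecific intensity, amplified so a 3:1 ratio
  scores 100, clamped to [0, 100].
* Isotope Score — 100*(1 - sum |r_obs,i - r_lib,i|) over the M+1/M+2
  relative intensities, clamped at 0.

The overall score is the plain mean of the five, assigned only when every
sub-score clears its configured threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ScoringConfig
from .isotopes import IsotopePattern

#: signal classes eligible for intensity ranking (fatty-acyl evidence)
RANKED_CLASSES = ("sn1", "sn2")


@dataclass(frozen=True)
class PeakMatch:
    """One predicted signal matched to an observed peak."""

    target_index: int
    target_mz: float
    observed_mz: float
    observed_intensity: float
    ppm_error: float


def match_targets(
    target_mz: np.ndarray | list[float],
    peaks_mz: np.ndarray | list[float],
    peaks_intensity: np.ndarray | list[float],
    ppm: float,
) -> list[PeakMatch]:
    """Match each target m/z to the nearest observed peak within ``ppm``.

    Deterministic: nearest peak wins; exact distance ties resolve to the
    lower-m/z peak (the left neighbour found by bisection).
    """
    tmz = np.asarray(target_mz, dtype=float)
    pmz = np.asarray(peaks_mz, dtype=float)
    pint = np.asarray(peaks_intensity, dtype=float)
    out: list[PeakMatch] = []
    if pmz.size == 0 or tmz.size == 0:
        return out
    order = np.argsort(pmz, kind="stable")
    pmz, pint = pmz[order], pint[order]
    idx = np.searchsorted(pmz, tmz)
    for i, t in enumerate(tmz):
        best_j = -1
        best_d = math.inf
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < pmz.size:
                d = abs(pmz[j] - t)
                if d < best_d:
                    best_d, best_j = d, j
        if best_j >= 0 and best_d <= t * ppm * 1e-6:
            out.append(
                PeakMatch(
                    target_index=i,
                    target_mz=float(t),
                    observed_mz=float(pmz[best_j]),
                    observed_intensity=float(pint[best_j]),
                    ppm_error=float((pmz[best_j] - t) / t * 1e6),
                )
            )
    return out


def weight(intensity: float, mz: float, cfg: ScoringConfig) -> float:
    """Stein-style peak weight W = intensity^m * mz^n."""
    if intensity < 0 or mz <= 0:
        raise ValueError("intensity must be >=0 and mz positive")
    return intensity**cfg.m * mz**cfg.n


def similarity_score(
    library: list[tuple[float, float]],
    observed: list[tuple[float, float]],
    cfg: ScoringConfig,
) -> float:
    """Reverse dot-product spectral similarity, 0..100.

    ``library`` and ``observed`` are (mz, intensity) lists.  Only library
    ions and their matched observed partners enter the sums; a library
    ion without a partner contributes W_obs = 0.
    """
    if not library:
        raise ValueError("empty predicted spectrum")
    if not observed:
        return 0.0
    lib_mz = [mz for mz, _ in library]
    matches = {
        m.target_index: m
        for m in match_targets(
            lib_mz, [p[0] for p in observed], [p[1] for p in observed], cfg.ms2_ppm
        )
    }
    w_lib = np.array([weight(inten, mz, cfg) for mz, inten in library])
    w_obs = np.zeros_like(w_lib)
    for i, m in matches.items():
        w_obs[i] = weight(m.observed_intensity, m.observed_mz, cfg)
    denom = float(np.sum(w_lib**2) * np.sum(w_obs**2))
    if denom == 0:
        return 0.0
    num = float(np.sum(w_lib * w_obs)) ** 2
    # Cauchy-Schwarz bounds num/denom by 1; guard the float overshoot
    return min(100.0, 100.0 * num / denom)


def rank_score(
    white_list: list[tuple[float, str]],
    observed: list[tuple[float, float]],
    cfg: ScoringConfig,
) -> float:
    """Intensity-rank score over the candidate's signal white list, 0..100.

    ``white_list`` holds (mz, signal_class) entries; per-class weights come
    from the configuration (default 1).  Only fatty-acyl signal classes
    (sn1/sn2: carboxylates, residue neutral losses, modification losses)
    are ranked — head-group ions are shared across all candidates of a
    class and carry no residue evidence.  The ten most intense matched
    signals are ranked (intensity ties break toward lower m/z) and the
    weighted rank factors are normalised by the candidate's maximum
    attainable sum.
    """
    if not white_list:
        raise ValueError("empty white list")
    rankable = [(mz, cls) for mz, cls in white_list if cls in RANKED_CLASSES]
    if not rankable or not observed:
        return 0.0
    matches = match_targets(
        [mz for mz, _ in rankable],
        [p[0] for p in observed],
        [p[1] for p in observed],
        cfg.ms2_ppm,
    )
    if not matches:
        return 0.0
    ranked = sorted(matches, key=lambda m: (-m.observed_intensity, m.observed_mz))[:10]
    raw = 0.0
    for i, m in enumerate(ranked):
        r_frag = (10 - i) / 10.0
        raw += cfg.weight_for(rankable[m.target_index][1]) * r_frag
    weights = sorted(
        (cfg.weight_for(cls) for _, cls in rankable), reverse=True
    )[:10]
    best = sum(w * (10 - i) / 10.0 for i, w in enumerate(weights))
    if best <= 0:
        return 0.0
    return 100.0 * min(raw / best, 1.0)


def fingerprint_score(
    fingerprint: list[float],
    observed: list[tuple[float, float]],
    cfg: ScoringConfig,
) -> float:
    """Cosine of the 0/1 fingerprint match vector vs all-ones: 100*sqrt(k/N)."""
    n = len(fingerprint)
    if n == 0:
        raise ValueError("empty fingerprint")
    if not observed:
        return 0.0
    matches = match_targets(
        fingerprint, [p[0] for p in observed], [p[1] for p in observed], cfg.ms2_ppm
    )
    k = len({m.target_index for m in matches})
    return 100.0 * math.sqrt(k / n)


def specificity_score(
    specific_intensity: float, unspecific_intensity: float, cfg: ScoringConfig
) -> float:
    """Amplified decibel ratio of supporting vs competing intensity, 0..100."""
    if specific_intensity < 0 or unspecific_intensity < 0:
        raise ValueError("intensity sums must be non-negative")
    if unspecific_intensity == 0:
        return 100.0
    if specific_intensity == 0:
        return 0.0
    score = cfg.f_amplify * 20.0 * math.log10(specific_intensity / unspecific_intensity)
    return float(min(100.0, max(0.0, score)))


def isotope_score(predicted: IsotopePattern, observed: IsotopePattern) -> float:
    """100*(1 - sum of absolute deviations of r1, r2), clamped at 0."""
    dev = abs(observed.r1 - predicted.r1) + abs(observed.r2 - predicted.r2)
    return float(max(0.0, 100.0 * (1.0 - dev)))


@dataclass
class ScoreBundle:
    """Five sub-scores plus bookkeeping for one candidate/spectrum pair."""

    similarity: float
    rank: float
    fingerprint: float
    specificity: float
    isotope: float
    matched_signals: list[PeakMatch] = field(default_factory=list)
    unmatched_library_mz: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "similarity": self.similarity,
            "rank": self.rank,
            "fingerprint": self.fingerprint,
            "specificity": self.specificity,
            "isotope": self.isotope,
        }

    def passes(self, cfg: ScoringConfig) -> bool:
        return (
            self.similarity >= cfg.min_similarity
            and self.rank >= cfg.min_rank
            and self.fingerprint >= cfg.min_fingerprint
            and self.specificity >= cfg.min_specificity
            and self.isotope >= cfg.min_isotope
        )


def overall_score(bundle: ScoreBundle, cfg: ScoringConfig) -> float | None:
    """Mean of the five sub-scores, or None when any threshold fails
    (including the overall threshold): rejection, not a low score."""
    if not bundle.passes(cfg):
        return None
    mean = (
        bundle.similarity
        + bundle.rank
        + bundle.fingerprint
        + bundle.specificity
        + bundle.isotope
    ) / 5.0
    return mean if mean >= cfg.min_overall else None
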