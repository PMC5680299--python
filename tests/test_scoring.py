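"""Closed forms, invariances and bounds of the five scores."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxplid.config import ScoringConfig
from oxplid.isotopes import IsotopePattern
from oxplid.scoring import (
    ScoreBundle,
    fingerprint_score,
    isotope_score,
    overall_score,
    rank_score,
    similarity_score,
    specificity_score,
    weight,
)

CFG = ScoringConfig()


class TestWeight:
    def test_unit_inputs(self):
        assert weight(1.0, 1.0, CFG) == 1.0

    def test_direct_arithmetic(self):
        assert weight(100, 200, CFG) == pytest.approx(100**0.6 * 200**3)

    def test_zero_intensity(self):
        assert weight(0.0, 500.0, CFG) == 0.0


SPECTRUM = [(168.0431, 400.0), (255.2330, 999.0), (480.3096, 250.0), (694.43, 120.0)]


class TestSimilarity:
    def test_identical_spectra(self):
        assert similarity_score(SPECTRUM, SPECTRUM, CFG) == pytest.approx(100.0)

    def test_uniform_scaling_invariance(self):
        doubled = [(mz, 2 * i) for mz, i in SPECTRUM]
        assert similarity_score(SPECTRUM, doubled, CFG) == pytest.approx(100.0)

    def test_impurity_peak_does_not_penalize(self):
        with_impurity = SPECTRUM + [(401.77, 5e6)]
        assert similarity_score(SPECTRUM, with_impurity, CFG) == pytest.approx(100.0)

    def test_empty_observed(self):
        assert similarity_score(SPECTRUM, [], CFG) == 0.0

    def test_perturbation_never_increases(self):
        base = similarity_score(SPECTRUM, SPECTRUM, CFG)
        for factor in (0.2, 0.5, 2.0, 5.0):
            perturbed = [
                (mz, i * (factor if k == 1 else 1.0))
                for k, (mz, i) in enumerate(SPECTRUM)
            ]
            assert similarity_score(SPECTRUM, perturbed, CFG) <= base + 1e-9


class TestRank:
    def test_full_match_normalizes_to_100(self):
        wl = [(100.0, "sn1"), (200.0, "sn2"), (300.0, "head")]
        obs = [(100.0, 50.0), (200.0, 999.0), (300.0, 400.0)]
        assert rank_score(wl, obs, CFG) == pytest.approx(100.0)

    def test_no_match_is_zero(self):
        wl = [(100.0, "sn1")]
        assert rank_score(wl, [(500.0, 10.0)], CFG) == 0.0

    def test_partial_match_uses_rank_factors(self):
        # 10 whitelist signals, only the most intense observed matches:
        # raw = 1.0, best = 1.0+0.9+...+0.1 = 5.5
        wl = [(100.0 + 10 * i, "sn2") for i in range(10)]
        obs = [(100.0, 999.0)]
        assert rank_score(wl, obs, CFG) == pytest.approx(100.0 / 5.5)


class TestFingerprint:
    def test_closed_form_against_cosine_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            # grid spacing far above the ppm tolerance: one observed peak
            # can never match two fingerprint entries
            fp = sorted(
                float(v) for v in rng.choice(np.arange(100.0, 900.0, 0.5), n, replace=False)
            )
            observed = [(v, 10.0) for v in sorted(rng.choice(fp, size=k, replace=False))]
            score = fingerprint_score(fp, observed, CFG)
            ones = np.ones(n)
            hits = np.zeros(n)
            hits[:k] = 1.0
            if k == 0:
                expected = 0.0
            else:
                expected = 100.0 * float(
                    hits @ ones / (np.linalg.norm(hits) * np.linalg.norm(ones))
                )
            assert score == pytest.approx(expected, abs=1e-9)
            assert score == pytest.approx(100.0 * math.sqrt(k / n), abs=1e-9)

    def test_extremes(self):
        fp = [100.0, 200.0, 300.0, 400.0]
        assert fingerprint_score(fp, [(v, 1.0) for v in fp], CFG) == 100.0
        assert fingerprint_score(fp, [(900.0, 1.0)], CFG) == 0.0
        assert fingerprint_score(fp, [(100.0, 1.0)], CFG) == pytest.approx(50.0)


class TestSpecificity:
    def test_ratio_three_reaches_100(self):
        assert specificity_score(3.0, 1.0, CFG) == pytest.approx(100.0, abs=0.01)

    def test_ratio_one_is_zero(self):
        assert specificity_score(1.0, 1.0, CFG) == 0.0

    def test_no_unspecific_signal_is_100(self):
        assert specificity_score(5.0, 0.0, CFG) == 100.0

    def test_no_specific_signal_is_zero(self):
        assert specificity_score(0.0, 5.0, CFG) == 0.0

    def test_strictly_increasing_before_clamp(self):
        ratios = np.linspace(1.05, 2.9, 20)
        scores = [specificity_score(r, 1.0, CFG) for r in ratios]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestIsotopeScore:
    def test_exact_match(self):
        p = IsotopePattern(0.5, 0.12)
        assert isotope_score(p, p) == 100.0

    def test_quarter_deviation(self):
        assert isotope_score(
            IsotopePattern(0.5, 0.2), IsotopePattern(0.65, 0.3)
        ) == pytest.approx(75.0)

    def test_clamped_at_zero(self):
        assert isotope_score(IsotopePattern(0.1, 0.1), IsotopePattern(1.5, 0.1)) == 0.0


class TestOverall:
    def _bundle(self, *scores):
        return ScoreBundle(*scores)

    def test_perfect(self):
        assert overall_score(self._bundle(100, 100, 100, 100, 100), CFG) == 100.0

    def test_mean_with_zero_threshold(self):
        cfg = ScoringConfig(min_isotope=0.0, min_overall=0.0)
        assert overall_score(self._bundle(100, 100, 100, 100, 0), cfg) == pytest.approx(80.0)

    def test_subthreshold_is_rejection_not_low_score(self):
        # isotope 59 < default threshold 60: no overall score at all
        assert overall_score(self._bundle(100, 100, 100, 100, 59.0), CFG) is None


@st.composite
def spectra(draw):
    n = draw(st.integers(1, 12))
    mzs = draw(
        st.lists(
            st.floats(60.0, 1100.0, allow_nan=False),
            min_size=n, max_size=n, unique=True,
        )
    )
    ints = draw(
        st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=n, max_size=n)
    )
    return list(zip(sorted(mzs), ints))


class TestBounds:
    @given(lib=spectra(), obs=spectra())
    def test_all_scores_bounded(self, lib, obs):
        cfg = CFG
        for value in (
            similarity_score(lib, obs, cfg),
            rank_score([(mz, "sn1") for mz, _ in lib], obs, cfg),
            fingerprint_score([mz for mz, _ in lib], obs, cfg),
        ):
            assert 0.0 <= value <= 100.0

    @given(
        spec=st.floats(0, 1e9, allow_nan=False),
        unspec=st.floats(0, 1e9, allow_nan=False),
    )
    def test_specificity_bounded(self, spec, unspec):
        assert 0.0 <= specificity_score(spec, unspec, CFG) <= 100.0

    @given(
        r=st.tuples(st.floats(0, 5), st.floats(0, 5)),
        s=st.tuples(st.floats(0, 5), st.floats(0, 5)),
    )
    def test_isotope_bounded(self, r, s):
        value = isotope_score(IsotopePattern(*r), IsotopePattern(*s))
        assert 0.0 <= value <= 100.0
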