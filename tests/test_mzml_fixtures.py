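"""mzML writer/reader round trips and synthetic fixture generation."""

import numpy as np
import pytest

from oxplid.fixtures import (
    FixtureSpec,
    PlantedLPP,
    make_dda_run,
    make_decoy_candidates,
)
from oxplid.mzml_io import SpectrumRecord, read_dda_run, write_mzml
from oxplid.pipeline import build_library


def _records():
    recs = []
    for i in range(3):
        recs.append(
            SpectrumRecord(
                1,
                1.0 + 0.1 * i,
                np.array([400.0, 700.1234, 701.1268]),
                np.array([10.0, 100.0, 45.0]),
            )
        )
        if i < 2:
            for j in range(2 + i):
                recs.append(
                    SpectrumRecord(
                        2,
                        1.01 + 0.1 * i + 0.01 * j,
                        np.array([255.2330, 171.1027]),
                        np.array([999.0, 500.0]),
                        precursor_mz=700.1234,
                        precursor_intensity=100.0,
                    )
                )
    return recs


class TestMzmlRoundTrip:
    def test_scan_partition(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml(_records(), path)
        run = read_dda_run(path)
        assert len(run.ms1_scans) == 3
        assert len(run.ms2_scans) == 5
        assert run.skipped == 0

    def test_retention_times_minutes_four_decimals(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml(_records(), path)
        run = read_dda_run(path)
        assert run.ms1_scans[1].rt_min == pytest.approx(1.1, abs=1e-4)
        assert run.ms2_scans[0].rt_min == pytest.approx(1.01, abs=1e-4)

    def test_ms2_links_to_preceding_survey_and_dda_rank(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml(_records(), path)
        run = read_dda_run(path)
        first = run.ms2_scans[0]
        assert first.survey_scan == run.ms1_scans[0].scan_number
        ranks = [s.dda_rank for s in run.ms2_scans]
        assert ranks == [1, 2, 1, 2, 3]

    def test_ms2_without_precursor_skipped_and_counted(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml(_records(), path)
        text = path.read_text()
        # strip the selected-ion annotation from the first MS2 scan
        idx = text.find("selectedIonList")
        start = text.rfind("<", 0, idx)
        end = text.find("</selectedIonList>") + len("</selectedIonList>")
        broken = tmp_path / "broken.mzML"
        broken.write_text(text[:start] + text[end:])
        run = read_dda_run(broken)
        assert run.skipped == 1
        assert len(run.ms2_scans) == 4

    def test_peaks_sorted_by_mz(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml(
            [
                SpectrumRecord(
                    2,
                    0.5,
                    np.array([500.0, 100.0, 300.0]),
                    np.array([1.0, 2.0, 3.0]),
                    precursor_mz=700.0,
                )
            ],
            path,
        )
        run = read_dda_run(path)
        assert list(run.ms2_scans[0].mz) == [100.0, 300.0, 500.0]
        assert list(run.ms2_scans[0].intensity) == [2.0, 3.0, 1.0]


@pytest.fixture(scope="module")
def small_library(predicted):
    chosen = [
        "PE(18:0/5:0<CHO@C5>)",
        "PC(16:0/9:0<CHO@C9>)",
        "PE(18:0/20:4[4xDB,1xOH])",
    ]
    return build_library([p for p in predicted if p.abbreviation in chosen])


class TestFixtures:
    def test_seeded_runs_are_byte_identical(self, small_library, tmp_path):
        spec = FixtureSpec(
            planted=[
                PlantedLPP(e.abbreviation, 1.0 + i, 5e4)
                for i, e in enumerate(small_library.entries)
            ],
            seed=11,
            rt_end_min=4.0,
            noise_floor_peaks=15,
            impurity_peaks=8,
        )
        a, b = tmp_path / "a.mzML", tmp_path / "b.mzML"
        assert make_dda_run(spec, small_library, a) == make_dda_run(spec, small_library, b)
        assert a.read_bytes() == b.read_bytes()

    def test_fixture_readable_with_zero_skips(self, small_library, tmp_path):
        spec = FixtureSpec(
            planted=[PlantedLPP(small_library.entries[0].abbreviation, 1.0, 5e4)],
            seed=3,
            rt_end_min=2.5,
        )
        path = tmp_path / "run.mzML"
        truth = make_dda_run(spec, small_library, path)
        run = read_dda_run(path)
        assert run.skipped == 0
        assert sum(len(v) for v in truth.values()) == len(run.ms2_scans)

    def test_out_of_range_precursor_rejected(self, small_library, tmp_path):
        spec = FixtureSpec(
            planted=[PlantedLPP(small_library.entries[0].abbreviation, 1.0, 5e4)],
            ms1_range=(200.0, 300.0),
        )
        with pytest.raises(ValueError, match="outside survey range"):
            make_dda_run(spec, small_library, tmp_path / "x.mzML")

    def test_unknown_planted_species_rejected(self, small_library, tmp_path):
        spec = FixtureSpec(planted=[PlantedLPP("PC(16:0/18:1)", 1.0, 5e4)])
        with pytest.raises(ValueError, match="not in library"):
            make_dda_run(spec, small_library, tmp_path / "x.mzML")


class TestDecoys:
    def test_zero_count(self, small_library):
        assert make_decoy_candidates(small_library, 0, seed=1) == []

    def test_decoys_isomeric_with_disjoint_carboxylates(self, small_library):
        from oxplid.chem import species_adduct_mz
        from oxplid.fixtures import _carboxylate_mzs, _species_carboxylates

        decoys = make_decoy_candidates(small_library, 2, seed=1)
        assert len(decoys) == 2
        own = _carboxylate_mzs(small_library.entries)
        lib_mzs = np.array([e.mz for e in small_library.entries])
        for d in decoys:
            # precursor m/z within 0.02 Th of a planted precursor
            assert np.min(np.abs(lib_mzs - species_adduct_mz(d.species))) <= 0.02
            for cmz in _species_carboxylates(d.species):
                assert np.min(np.abs(own - cmz)) >= 0.01
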