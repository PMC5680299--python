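"""Predicted CID spectra, fingerprint expansion and MSP export."""

import numpy as np
import pytest

from oxplid import parse_abbreviation
from oxplid.constants import MASS_H2O, MASS_H2O2
from oxplid.fragmentation import (
    FragmentationProfile,
    export_msp,
    generate_fingerprint,
    generate_spectrum,
    read_msp,
)


def ion_types(spectrum):
    return {i.ion_type.split(":")[0] for i in spectrum.ions}


class TestSpectrum:
    def test_truncated_pc_residue_ions(self):
        sp = generate_spectrum(parse_abbreviation("PC(16:0/9:0<CHO@C9>)"))
        mzs = np.array([i.mz for i in sp.ions])
        # palmitate C16H31O2- and oxo-nonanoate C9H15O3-
        assert np.min(np.abs(mzs - 255.2330)) < 1e-3
        assert np.min(np.abs(mzs - 171.1027)) < 1e-3

    def test_head_group_diagnostics_per_class(self):
        expectations = {
            "PA(16:0/18:1)": 152.9958,
            "PE(18:0/20:4)": 196.0380,
            "PG(16:0/18:1)": 152.9958,
            "PC(16:0/18:1)": 168.0431,
        }
        for abbrev, head_mz in expectations.items():
            sp = generate_spectrum(parse_abbreviation(abbrev))
            mzs = np.array([i.mz for i in sp.ions])
            assert np.min(np.abs(mzs - head_mz)) < 1e-3, abbrev

    def test_serine_loss_for_ps(self):
        sp = generate_spectrum(parse_abbreviation("PS(18:0/22:6)"))
        assert "head_neutral_loss" in ion_types(sp)

    def test_hydroxyl_gives_water_loss(self):
        sp = generate_spectrum(parse_abbreviation("PC(16:0/18:2[2xDB,1xOH])"))
        carbox = next(i for i in sp.ions if i.ion_type == "sn2_carboxylate")
        mzs = np.array([i.mz for i in sp.ions])
        assert np.min(np.abs(mzs - (carbox.mz - MASS_H2O))) < 1e-3

    def test_hydroperoxide_gives_peroxide_loss(self):
        species = parse_abbreviation("PE(18:0/18:2[2xDB,1xOOH])")
        sp = generate_spectrum(species)
        losses = [i for i in sp.ions if i.ion_type.startswith("peroxide_loss")]
        assert losses
        # the loss sits one H2O2 below the deprotonated precursor
        assert losses[0].mz == pytest.approx(sp.precursor_mz - MASS_H2O2, abs=1e-3)

    def test_keto_epoxy_emit_no_specific_loss(self):
        for abbrev in ("PC(16:0/18:2[2xDB,1xKETO])", "PC(16:0/18:2[1xDB,1xEPOXY])"):
            kinds = ion_types(generate_spectrum(parse_abbreviation(abbrev)))
            assert "water_loss" not in kinds
            assert "peroxide_loss" not in kinds

    def test_neutral_loss_mass_balance(self):
        """mz(fragment) + mass(lost neutral) must recover the species the
        loss started from, within 1 mDa."""
        from oxplid.chem import residue_acid_composition, species_composition
        from oxplid.formula import comp

        species = parse_abbreviation("PE(18:0/20:4)")
        sp = generate_spectrum(species)
        surrogate_mz = (species_composition(species) - comp("H")).replace_charge(-1).mz
        acid1 = residue_acid_composition(species.sn1, None)
        nl = next(i for i in sp.ions if i.ion_type == "sn_neutral_loss_acid:sn1")
        assert nl.mz + acid1.monoisotopic_mass == pytest.approx(surrogate_mz, abs=1e-3)

    def test_ions_sorted_below_precursor(self, predicted):
        for lpp in predicted[::25]:
            sp = generate_spectrum(lpp.species)
            mzs = [i.mz for i in sp.ions]
            assert mzs == sorted(mzs)
            assert all(0 < mz < sp.precursor_mz for mz in mzs)

    def test_profile_changes_intensities_not_inventory(self):
        species = parse_abbreviation("PC(16:0/18:2)")
        a = generate_spectrum(species, profile=FragmentationProfile())
        b = generate_spectrum(
            species, profile=FragmentationProfile(sn1_carboxylate=5, head_fragment=900)
        )
        assert [i.mz for i in a.ions] == [i.mz for i in b.ions]
        assert [i.relative_intensity for i in a.ions] != [
            i.relative_intensity for i in b.ions
        ]


class TestFingerprint:
    def test_no_oxygenation_no_water_expansion(self):
        fp = generate_fingerprint(parse_abbreviation("PC(16:0/18:1)"))
        assert not any("xH2O" in lab for lab in fp.labels)

    def test_two_hydroxyls_expand_each_base_ion(self):
        species = parse_abbreviation("PE(18:0/18:2[2xDB,2xOH])")
        fp = generate_fingerprint(species)
        values = np.array(fp.mz_values)
        base = [v for v, lab in zip(fp.mz_values, fp.labels) if "xH2O" not in lab]
        # brute-force oracle: every base ion must appear at -1x and -2x H2O
        for v in base:
            for j in (1, 2):
                assert np.min(np.abs(values - (v - j * MASS_H2O))) < 1e-3

    def test_strictly_sorted_unique(self, predicted):
        for lpp in predicted[::40]:
            fp = generate_fingerprint(lpp.species)
            diffs = np.diff(fp.mz_values)
            assert (diffs > 0).all()

    def test_spectrum_subset_of_fingerprint(self, predicted):
        for lpp in predicted[::25]:
            sp = generate_spectrum(lpp.species)
            fp = np.array(generate_fingerprint(lpp.species).mz_values)
            for ion in sp.ions:
                assert np.min(np.abs(fp - ion.mz)) < 2e-4, lpp.abbreviation


class TestMsp:
    def test_export_and_round_trip(self, tmp_path):
        species = [
            generate_spectrum(parse_abbreviation(a))
            for a in ("PC(16:0/18:2)", "PE(18:0/20:4)")
        ]
        path = tmp_path / "lib.msp"
        export_msp(species, path)
        text = path.read_text()
        assert f"Num Peaks: {len(species[0].ions)}" in text
        back = read_msp(path)
        assert len(back) == 2
        for orig, re in zip(species, back):
            assert re.abbreviation == orig.abbreviation
            assert re.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
            for a, b in zip(orig.ions, re.ions):
                assert b.mz == pytest.approx(a.mz, abs=1e-4)

    def test_empty_export_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            export_msp([], tmp_path / "x.msp")
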