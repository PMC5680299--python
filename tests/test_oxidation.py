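"""Enumeration engine: unit decomposition, brute-force oracle equivalence,
worked counts, level monotonicity and SDF round trips."""

import itertools
import warnings

import pytest

from oxplid import (
    decompose_units,
    enumerate_oap,
    enumerate_ocp,
    enumerate_prostanes,
    parse_abbreviation,
    predict_oxidized_lipidome,
    predict_species_products,
)
from oxplid.nomenclature import OAP_OXYGENS, FattyAcylResidue
from oxplid.oxidation import LevelLimits


def _limits(**kw):
    base = dict(
        oap_types=("KETO", "OH", "OOH", "EPOXY"),
        max_total_mods=3,
        max_oxygens=3,
        ocp_terminals=("CHO", "COOH"),
        shifted_cleavage=False,
        ocp_decoration=True,
        decoration_min_residual=2,
        prostane_rings=("A", "D", "E", "F", "H"),
    )
    base.update(kw)
    return LevelLimits(**base)


class TestUnits:
    @pytest.mark.parametrize(
        "abbrev, expected",
        [("18:2", 2), ("20:4", 4), ("16:0", 0)],
    )
    def test_one_unit_per_double_bond(self, abbrev, expected):
        c, d = map(int, abbrev.split(":"))
        units = decompose_units(FattyAcylResidue(c, d))
        assert len(units) == expected
        positions = [u.db_position for u in units]
        assert positions == sorted(positions)
        for u in units:
            assert abs(u.allylic_site - u.db_position) <= 2


class TestOapEnumeration:
    def test_single_modification_two_types(self, rules):
        limits = _limits(oap_types=("KETO", "OH"), max_total_mods=1, max_oxygens=1)
        rules_1 = _patched(rules, limits)
        out = enumerate_oap(FattyAcylResidue(18, 1), rules_1)
        assert len(out) == 2
        kinds = {("KETO" if m.keto else "OH") for m in out}
        assert kinds == {"KETO", "OH"}
        assert all(m.residual_double_bonds == 1 for m in out)

    def test_saturated_residue_empty(self, rules):
        assert enumerate_oap(FattyAcylResidue(16, 0), rules) == []

    def test_oxygen_budget_respected(self, rules):
        for mod in enumerate_oap(FattyAcylResidue(20, 4), rules):
            assert mod.oxygens_added <= rules.limits().max_oxygens

    @pytest.mark.parametrize("double_bonds", [1, 2])
    @pytest.mark.parametrize("max_mods", [1, 2])
    def test_brute_force_oracle_equivalence(self, rules, double_bonds, max_mods):
        """Independent oracle: enumerate explicit (unit, type) assignments,
        then merge by type multiset; counts must match the engine."""
        limits = _limits(max_total_mods=max_mods)
        residue = FattyAcylResidue(18, double_bonds)
        engine = enumerate_oap(residue, _patched(rules, limits))

        types = limits.oap_types
        merged = set()
        units = range(double_bonds)
        for size in range(1, max_mods + 1):
            for sites in itertools.combinations(units, size):
                for assignment in itertools.product(types, repeat=size):
                    oxygens = sum(OAP_OXYGENS[t] for t in assignment)
                    if oxygens > limits.max_oxygens:
                        continue
                    merged.add(tuple(sorted(assignment)))
        assert len(engine) == len(merged)


class TestOcpEnumeration:
    def test_linoleate_truncations_at_c9(self, rules):
        out = enumerate_ocp(FattyAcylResidue(18, 2), rules)
        labels = {
            f"{chain.carbons}:{mod.residual_double_bonds}"
            f"<{mod.truncation.terminal}@C{mod.truncation.site}>"
            for chain, mod in out
            if mod.total_oap == 0
        }
        assert "9:0<CHO@C9>" in labels
        assert "9:0<COOH@C9>" in labels

    def test_arachidonate_gives_five_carbon_product(self, rules):
        out = enumerate_ocp(FattyAcylResidue(20, 4), rules)
        assert any(chain.carbons == 5 for chain, _ in out)

    def test_residual_double_bonds_below_cleavage_site(self, rules):
        residue = FattyAcylResidue(18, 2)  # delta 9, 12
        for chain, mod in enumerate_ocp(residue, rules):
            below = [p for p in (9, 12) if p < mod.truncation.site]
            assert mod.residual_double_bonds + mod.epoxy == len(below)
            assert chain.positions == tuple(below)

    def test_saturated_residue_no_cleavage(self, rules):
        assert enumerate_ocp(FattyAcylResidue(18, 0), rules) == []


class TestProstanes:
    def test_phytoprostane_from_18_3(self, rules):
        out = enumerate_prostanes(FattyAcylResidue(18, 3), rules)
        assert out
        assert all(m.prostane.family == "phytoP" for m in out)

    def test_no_ring_below_three_double_bonds(self, rules):
        assert enumerate_prostanes(FattyAcylResidue(18, 2), rules) == []

    def test_isoprostanes_from_20_4_windows_kept_separately(self, rules):
        out = enumerate_prostanes(FattyAcylResidue(20, 4), rules)
        assert all(m.prostane.family == "IsoP" for m in out)
        windows = {m.prostane.window for m in out}
        assert windows == {5, 8}  # one entry per window, not merged
        assert len(out) == len(set((m.prostane.ring, m.prostane.window) for m in out))


class TestSpeciesPrediction:
    def test_dilinoleoyl_pc_seventeen_products(self, rules):
        sp = parse_abbreviation("PC(18:2/18:2)")
        assert len(predict_species_products(sp, rules)) == 17

    def test_palmitoyl_arachidonoyl_pc_at_least_104(self, rules):
        sp = parse_abbreviation("PC(16:0/20:4)")
        assert len(predict_species_products(sp, rules)) >= 104

    def test_saturated_species_without_lyso_is_empty(self, rules):
        sp = parse_abbreviation("PC(16:0/18:0)")
        assert predict_species_products(sp, rules) == []

    def test_level_monotonicity(self, rules):
        sp = parse_abbreviation("PC(16:0/20:4)")
        previous: set[str] = set()
        for level in (1, 2, 3):
            current = {p.abbreviation for p in predict_species_products(sp, rules, level)}
            assert previous <= current
            previous = current

    def test_deterministic_sorted_output(self, predicted):
        abbrevs = [p.abbreviation for p in predicted]
        assert abbrevs == sorted(abbrevs)

    def test_failing_species_reported_not_fatal(self, rules):
        good = parse_abbreviation("PC(16:0/18:2)")
        bad = parse_abbreviation("PE(18:0/18:2)")
        # sabotage: positions that cannot host the declared double bonds
        object.__setattr__(bad.sn2, "carbons", 3)
        products, errors = predict_oxidized_lipidome([bad, good], rules)
        assert len(errors) == 1
        assert any(p.parent.abbreviation == "PC(16:0/18:2)" for p in products)


class TestSdfExport:
    def test_round_trip_and_determinism(self, predicted, tmp_path):
        from oxplid.chem import species_composition
        from oxplid.sdf import export_sdf, import_sdf
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        sample = predicted[:12]
        p1, p2 = tmp_path / "a.sdf", tmp_path / "b.sdf"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            export_sdf(sample, p1)
            export_sdf(sample, p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical output
        back = import_sdf(p1)
        assert [b.abbreviation for b in back] == [s.abbreviation for s in sample]
        for orig, re in zip(sample, back):
            assert (
                species_composition(re.species).formula()
                == species_composition(orig.species).formula()
            )

    def test_empty_export_is_error(self, tmp_path):
        from oxplid.sdf import export_sdf

        with pytest.raises(ValueError):
            export_sdf([], tmp_path / "x.sdf")
        assert not (tmp_path / "x.sdf").exists()


def _patched(rules, limits):
    import copy

    patched = copy.copy(rules)
    patched.levels = dict(rules.levels)
    patched.levels[rules.default_level] = limits
    return patched
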