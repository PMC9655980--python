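"""Checkers, standardizers, duplicate/scaffold analysis and the BBB
curation preset."""

import pytest

from qsarkit import curation
from qsarkit.curation import (
    StandardizerRule,
    apply_standardizers,
    check_structures,
    curate_bbb,
    find_duplicates,
    resolve_duplicates,
    scaffold_analysis,
)
from qsarkit.errors import ConfigurationError, RuleError
from qsarkit.fixtures import MISSING_H_VALENCE, NITRO_VARIANTS, STEREO_PAIR
from qsarkit.molio import MoleculeTable

NITRO_CUSTOM_RULE = (
    "[N;D3:1](~[O;D1:2])(~[O;D1:3])>>[*+0;H0:1](=[*+0;H0:2])=[*+0;H0:3]"
)


def table(*smiles, **cols):
    return MoleculeTable.from_smiles(list(smiles), **cols)


class TestCheckers:
    def test_missing_hydrogen_carbon_flags_unusual_valence(self):
        report = check_structures(table(MISSING_H_VALENCE))
        assert "unusual_valence" in report.flags[0]

    def test_noble_gas_atom_flags(self):
        report = check_structures(table("[Kr]"))
        assert {"nonstandard_atom_set", "no_carbon"} <= report.flags[0]

    def test_salt_mixture_flags(self):
        report = check_structures(table("CC.[Na+]"))
        assert {"multiple_structures", "charged_atom", "total_charge"} <= report.flags[0]

    def test_isotope_and_radical(self):
        report = check_structures(table("[13CH4]", "[CH3]"))
        assert "isotope" in report.flags[0]
        assert "radical_atom" in report.flags[1]

    def test_covalent_ionic_bond(self):
        report = check_structures(table("O([Na])c1cccc(-c2ccccc2)c1"))
        assert "covalent_ionic_bond" in report.flags[0]

    def test_aromaticity_problem(self):
        report = check_structures(table("c1cccc1"))
        assert "aromaticity" in report.flags[0]

    def test_unknown_checker_rejected(self):
        with pytest.raises(ConfigurationError):
            check_structures(table("CC"), ["bogus"])

    def test_clean_molecule_unflagged(self):
        report = check_structures(table("CCO"))
        assert report.flags[0] == set()


class TestStandardizers:
    def test_custom_nitro_rule_yields_neutral_form(self):
        out = apply_standardizers(
            table("[O-][N+](=O)C1CCCC1"),
            [StandardizerRule("custom", NITRO_CUSTOM_RULE)],
        )
        assert out.smiles() == ["O=N(=O)C1CCCC1"]

    def test_rule_order_changes_product(self):
        covalent = "O([Na])c1cccc(-c2ccccc2)c1"
        remove_then_convert = apply_standardizers(
            table(covalent), ["remove_monoatomic_fragments", "covalent_to_ionic"]
        )
        convert_then_remove = apply_standardizers(
            table(covalent), ["covalent_to_ionic", "remove_monoatomic_fragments"]
        )
        assert remove_then_convert.smiles() != convert_then_remove.smiles()
        assert "[Na+]" in remove_then_convert.smiles()[0]
        assert "Na" not in convert_then_remove.smiles()[0]

    def test_retain_biggest_fragment(self):
        out = apply_standardizers(table("CC.[Na+]"), ["retain_biggest_fragment"])
        assert out.smiles() == ["CC"]

    def test_nitro_variants_converge(self):
        out = apply_standardizers(
            table(*NITRO_VARIANTS), ["standardize_nitro_neutral"]
        )
        keys = set(out.smiles())
        assert len(keys) == 1

    def test_builtin_rules_are_idempotent(self, toy_table):
        rules = ["standardize_nitro_neutral", "retain_biggest_fragment",
                 "clear_isotopes", "clear_chirality"]
        once = apply_standardizers(toy_table, rules)
        twice = apply_standardizers(once, rules)
        assert once.smiles() == twice.smiles()

    def test_quaternary_nitrogen_charge(self):
        out = apply_standardizers(
            table("C[N](C)(C)C"), ["add_charge_to_quaternary_nitrogen"]
        )
        assert out.smiles() == ["C[N+](C)(C)C"]

    def test_bad_custom_pattern_raises_with_pattern(self):
        with pytest.raises(RuleError, match="not-a-smirks"):
            apply_standardizers(
                table("CC"), [StandardizerRule("custom", "not-a-smirks")]
            )

    def test_unknown_builtin_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_standardizers(table("CC"), ["bogus_rule"])


class TestDuplicates:
    def test_stereo_pair_grouped_only_when_stereo_ignored(self):
        t = table(*STEREO_PAIR)
        assert len(find_duplicates(t, ignore_stereo=True)) == 1
        assert find_duplicates(t, ignore_stereo=True).groups[0] == [0, 1]
        assert len(find_duplicates(t, ignore_stereo=False)) == 0

    def test_triplicate(self):
        groups = find_duplicates(table("CCO", "OCC", "C(O)C"))
        assert groups.groups == [[0, 1, 2]]

    def test_loosening_options_never_shrinks_groups(self, toy_table):
        strict = find_duplicates(toy_table)
        loose = find_duplicates(
            toy_table, ignore_stereo=True, ignore_charge=True,
            ignore_isotope=True, ignore_h_count=True,
        )
        n_strict = sum(len(g) for g in strict.groups)
        n_loose = sum(len(g) for g in loose.groups)
        assert n_loose >= n_strict

    def test_conflicting_group_removed_entirely(self):
        t = table("CCO", "OCC", "CCN", BBB=["BBB+", "BBB-", "BBB+"])
        groups = find_duplicates(t)
        out, log = resolve_duplicates(t, groups, "BBB")
        assert out.smiles() == ["CCN"]
        assert log[0]["action"] == "removed_all"

    def test_agreeing_group_keeps_first(self):
        t = table("CCO", "OCC", "CCN", BBB=["BBB+", "BBB+", "BBB-"])
        out, _ = resolve_duplicates(t, find_duplicates(t), "BBB")
        assert len(out) == 2

    def test_missing_endpoint_counts_as_disagreement(self):
        t = table("CCO", "OCC", BBB=["BBB+", ""])
        out, log = resolve_duplicates(t, find_duplicates(t), "BBB")
        assert len(out) == 0
        assert log[0]["reason"] == "endpoint_missing"

    def test_no_groups_leaves_table_unchanged(self):
        t = table("CCO", "CCN", BBB=["BBB+", "BBB-"])
        out, log = resolve_duplicates(t, find_duplicates(t), "BBB")
        assert len(out) == 2 and log == []


class TestScaffolds:
    def test_toluene_gives_benzene_scaffold(self):
        counts, ring_free = scaffold_analysis(table("Cc1ccccc1"))
        assert counts == {"c1ccccc1": 1} and ring_free == 0

    def test_hexane_counted_ring_free(self):
        counts, ring_free = scaffold_analysis(table("CCCCCC"))
        assert counts == {} and ring_free == 1

    def test_biphenyl_linker_retained(self):
        counts, _ = scaffold_analysis(table("c1ccc(-c2ccccc2)cc1CCO"))
        assert list(counts) == ["c1ccc(-c2ccccc2)cc1"]


class TestBBBPreset:
    def test_recipe_fixture(self):
        # 10 molecules: one disconnected, one valence error, one single
        # atom, one agreeing duplicate pair -> 6 survivors, 4 log steps
        t = table(
            "CC.[Na+]", MISSING_H_VALENCE, "[Kr]",
            "CCO", "OCC", "CCN", "CCC", "c1ccccc1", "CCCC", "CCCCC",
            BBB=["BBB+", "BBB+", "BBB+", "BBB+", "BBB+",
                 "BBB-", "BBB+", "BBB-", "BBB+", "BBB-"],
        )
        out, log = curate_bbb(t)
        assert len(out) == 6
        assert [e["step"] for e in log] == [
            "multiple_structures", "unusual_valence", "single_atom", "duplicates",
        ]
        assert all(e["n_removed"] == 1 for e in log)

    def test_clean_input_untouched(self):
        t = table("CCO", "CCN", BBB=["BBB+", "BBB-"])
        out, log = curate_bbb(t)
        assert len(out) == 2 and log == []

    def test_idempotent(self):
        t = table(
            "CC.[Na+]", MISSING_H_VALENCE, "CCO", "OCC", "CCN",
            BBB=["BBB+", "BBB+", "BBB+", "BBB-", "BBB+"],
        )
        once, _ = curate_bbb(t)
        twice, log2 = curate_bbb(once)
        assert len(twice) == len(once) and log2 == []

    def test_post_curation_checks_clean(self):
        t = table(
            "CC.[Na+]", MISSING_H_VALENCE, "[Kr]", "CCO", "CCN",
            BBB=["BBB+"] * 5,
        )
        out, _ = curate_bbb(t)
        report = check_structures(
            out, ("multiple_structures", "unusual_valence")
        )
        assert all(f == set() for f in report.flags)
        assert all(m.GetNumHeavyAtoms() > 1 for m in out.mols)
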