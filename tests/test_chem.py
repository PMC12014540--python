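"""Mass bookkeeping and digestion, checked against a per-atom oracle and
an independent digestion implementation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import parser as pt_parser

from carbsite.chem import (
    ACETYL,
    C13_MINUS_C12,
    CARBAMIDOMETHYL,
    CARBAMYL,
    DEAMIDATION,
    OXIDATION,
    PROTEIN_NTERM,
    ModifiedPeptide,
    digest,
    modification_table,
    parse_mods,
    peptide_key,
    peptide_neutral_mass,
    variable_mod_combinations,
)

# frozen monoisotopic atomic masses (CODATA/AME): the independent oracle
ATOM = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196,
        "S": 31.97207100}

# residue compositions (amino acid minus water)
RESIDUE_FORMULA = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO", "V": "C5H9NO",
    "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO", "I": "C6H11NO", "N": "C4H6N2O2",
    "D": "C4H5NO3", "Q": "C5H8N2O2", "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS",
    "H": "C6H7N3O", "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def formula_mass(formula: str) -> float:
    import re

    total = 0.0
    for elem, count in re.findall(r"([A-Z])(\d*)", formula):
        total += ATOM[elem] * (int(count) if count else 1)
    return total


def oracle_peptide_mass(sequence: str) -> float:
    return sum(formula_mass(RESIDUE_FORMULA[a]) for a in sequence) + formula_mass("H2O")


class TestModificationTable:
    def test_exact_deltas_against_atomic_composition(self):
        expected = {
            "carbamidomethyl": ("CH2CONH2 minus H", formula_mass("C2H3NO")),
            "carbamyl": ("HNCO addition", formula_mass("CHNO")),
            "acetyl": ("C2H2O addition", formula_mass("C2H2O")),
            "oxidation": ("one oxygen", formula_mass("O")),
            "deamidation": ("O for NH", formula_mass("O") - formula_mass("NH")),
        }
        table = {m.name: m for m in modification_table()}
        assert set(table) == set(expected)
        for name, (_, delta) in expected.items():
            assert table[name].delta_mass == pytest.approx(delta, abs=1e-5)

    def test_table_contents_and_targets(self):
        table = {m.name: m for m in modification_table()}
        assert table["carbamidomethyl"].fixed and table["carbamidomethyl"].targets == {"C"}
        assert not table["carbamyl"].fixed and table["carbamyl"].targets == {"K"}
        assert table["acetyl"].targets == {"K", PROTEIN_NTERM}
        assert table["oxidation"].targets == {"M"}
        assert table["deamidation"].targets == {"N", "Q"}

    def test_carbamyl_precursor_shift_is_43_da_at_integer_precision(self):
        assert round(CARBAMYL.delta_mass) == 43

    def test_isotope_discrimination_identities(self):
        # the two constants that make carbamyl/13C-acetyl discrimination work
        assert CARBAMYL.delta_mass - ACETYL.delta_mass == pytest.approx(0.99524, abs=1e-4)
        gap = ACETYL.delta_mass + C13_MINUS_C12 - CARBAMYL.delta_mass
        assert gap == pytest.approx(0.00811, abs=1e-4)


class TestPeptideNeutralMass:
    @pytest.mark.parametrize(
        "sequence, mods, expected",
        [
            ("AFKAWAVAR", (), 1018.5712),
            ("AFKAWAVAR", ((3, CARBAMYL),), 1061.5770),
        ],
    )
    def test_albumin_k236_peptide(self, sequence, mods, expected):
        p = ModifiedPeptide(sequence=sequence, mods=mods)
        assert peptide_neutral_mass(p) == pytest.approx(expected, abs=2e-4)

    def test_no_mods_equals_unmodified_mass(self):
        assert peptide_neutral_mass(
            ModifiedPeptide(sequence="TAYIAK", mods=())
        ) == peptide_neutral_mass("TAYIAK")

    def test_unknown_residue_is_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            ModifiedPeptide(sequence="ABBA")

    @settings(max_examples=100, derandomize=True)
    @given(
        st.text(alphabet=sorted(RESIDUE_FORMULA), min_size=1, max_size=30)
    )
    def test_mass_additivity_against_atomic_oracle(self, sequence):
        assert peptide_neutral_mass(sequence) == pytest.approx(
            oracle_peptide_mass(sequence), abs=1e-4
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        st.text(alphabet=sorted(RESIDUE_FORMULA), min_size=1, max_size=15),
        st.text(alphabet=sorted(RESIDUE_FORMULA), min_size=1, max_size=15),
    )
    def test_concatenation_additivity(self, left, right):
        # concatenation adds one water less than the sum of the parts
        from carbsite.chem import WATER

        assert peptide_neutral_mass(left + right) == pytest.approx(
            peptide_neutral_mass(left) + peptide_neutral_mass(right) - WATER, abs=1e-9
        )


class TestDigest:
    def test_enumerated_products(self):
        got = {p.sequence for p in digest("MKTAYIAKQR")}
        assert got == {"TAYIAK", "MKTAYIAK", "TAYIAKQR", "MKTAYIAKQR"}

    def test_no_cleavage_site_yields_whole_protein(self):
        [p] = digest("AAAAAA")
        assert p.sequence == "AAAAAA" and p.start_pos == 1 and p.missed_cleavages == 0

    def test_all_products_below_min_length(self):
        assert digest("MKRK") == []

    def test_start_positions_are_correct_substrings(self):
        seq = "MKWVTFISLLFKRPSSAYSRGVFRK"
        for p in digest(seq):
            assert seq[p.start_pos - 1 : p.start_pos - 1 + len(p.sequence)] == p.sequence

    def test_zero_missed_products_tile_the_protein(self):
        seq = "MKWVTFISLLFKRPSSAYSRGVFRKAAAAAA"
        pieces = sorted(
            (p for p in digest(seq, max_missed=0, min_length=1)),
            key=lambda p: p.start_pos,
        )
        assert "".join(p.sequence for p in pieces) == seq

    def test_agrees_with_reference_cleavage_rule(self):
        # independent oracle: pyteomics trypsin rule (no cleavage before P)
        seq = "MKWVTFISLLFKRPSSAYSRGVFRKAPKMKQEPERNECFLQHKDDNPNLPR"
        got = {p.sequence for p in digest(seq, max_missed=2, min_length=6)}
        expected = pt_parser.cleave(
            seq, pt_parser.expasy_rules["trypsin"], missed_cleavages=2, min_length=6
        )
        assert got == set(expected)

    def test_proline_rule_switch(self):
        seq = "AAAKPAAAKAAA"
        classic = {p.sequence for p in digest(seq, min_length=1)}
        trypsin_p = {p.sequence for p in digest(seq, min_length=1, cleave_before_proline=True)}
        assert "AAAKPAAAK" in classic  # K|P suppressed
        assert "AAAK" in trypsin_p and "PAAAK" in trypsin_p


class TestVariableModCombinations:
    def test_single_site_two_forms(self):
        [p] = [q for q in digest("MKTAYIAKQR") if q.sequence == "TAYIAK"]
        forms = variable_mod_combinations(p, [CARBAMYL])
        keys = {peptide_key(f) for f in forms}
        assert keys == {"TAYIAK", "TAYIAK|6:carbamyl"}

    def test_one_variable_mod_per_position(self, carb_afkawavar):
        base = ModifiedPeptide(sequence="AFKAWAVAR", protein_accession="P02768",
                               start_pos=234, missed_cleavages=1)
        forms = variable_mod_combinations(base, [CARBAMYL, ACETYL])
        keys = {peptide_key(f) for f in forms}
        assert keys == {
            "AFKAWAVAR",
            "AFKAWAVAR|3:carbamyl",
            "AFKAWAVAR|3:acetyl",
        }

    def test_fixed_carbamidomethyl_always_applied(self):
        p = ModifiedPeptide(sequence="ACDEFK", start_pos=5)
        for form in variable_mod_combinations(p):
            assert (2, CARBAMIDOMETHYL) in form.mods

    def test_nterm_acetyl_only_at_protein_start(self):
        internal = ModifiedPeptide(sequence="TAYIAK", start_pos=10)
        initial = ModifiedPeptide(sequence="TAYIAK", start_pos=1)
        assert not any(
            any(pos == PROTEIN_NTERM for pos, _ in f.mods)
            for f in variable_mod_combinations(internal, [ACETYL])
        )
        assert any(
            any(pos == PROTEIN_NTERM for pos, _ in f.mods)
            for f in variable_mod_combinations(initial, [ACETYL])
        )

    def test_max_mods_cap(self):
        p = ModifiedPeptide(sequence="NQNQNQNQ")
        forms = variable_mod_combinations(p, [DEAMIDATION], max_mods_per_peptide=2)
        assert max(len(f.mods) for f in forms) == 2
        # sum_{j<=2} C(8, j) subsets
        assert len(forms) == 1 + 8 + 28


def test_peptide_key_round_trips_through_parse_mods():
    p = ModifiedPeptide(
        sequence="ACKMNR",
        mods=((2, CARBAMIDOMETHYL), (3, CARBAMYL), (4, OXIDATION)),
    )
    key = peptide_key(p)
    seq, _, mods_text = key.partition("|")
    assert seq == "ACKMNR"
    assert parse_mods(mods_text) == p.mods
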