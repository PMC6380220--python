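import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structaudit import examples
from structaudit.layers import (
    InChIError,
    InChILayers,
    charged_species_formula,
    core_parent_formula,
    expand_components,
    has_ambiguous_stereo,
    hill_format,
    net_charge,
    normalize_inchi_text,
    parse_formula_string,
    parse_inchi,
    proton_delta,
    serialize,
)

FIG2A = examples.CHARGED_FORMULA_EXAMPLES["91929631"]
FIG2B = examples.CHARGED_FORMULA_EXAMPLES["91124997"]
FIG4_DEPOSITED = examples.INCHI_DISCREPANCY_EXAMPLES["2179800"]["deposited"]
FIG5_DEPOSITED = examples.INCHI_DISCREPANCY_EXAMPLES["1551886"]["deposited"]

WATER_INCHI = "InChI=1S/H2O/h1H2"  # delegate output for the water fixture
SALT_INCHI = "InChI=1S/C2H4O2.Na/c1-2(3)4;/h1H3,(H,3,4);/q;+1/p-1"


class TestParse:
    def test_fig2b_layers(self):
        ly = parse_inchi(FIG2B["inchi"])
        assert ly.standard
        assert ly.formula == ({"C": 15, "H": 16, "N": 1},)
        assert ly.q_layer == "+1"
        assert ly.t_layer == "12-"
        assert ly.m_layer == "0"
        assert ly.s_layer == "1"
        assert ly.p_layer == ""

    def test_fig2a_layers(self):
        ly = parse_inchi(FIG2A["inchi"])
        assert ly.p_layer == "+1"
        assert ly.q_layer == ""
        assert net_charge(ly) == 0
        assert "(H3,16,17)(H,19,20)" in ly.h_layer

    def test_water(self):
        ly = parse_inchi(WATER_INCHI)
        assert ly.formula == ({"H": 2, "O": 1},)
        for layer in ("q", "p", "b", "t", "m", "s", "i"):
            assert getattr(ly, f"{layer}_layer") == ""

    def test_typeset_noise_normalized(self):
        assert normalize_inchi_text("InChI = 1 S/H2O/h1H2") == WATER_INCHI
        assert parse_inchi(" InChI = 1 S/H2O/ h1H2 ").source == WATER_INCHI

    def test_missing_prefix_rejected(self):
        with pytest.raises(InChIError):
            parse_inchi("1S/H2O/h1H2")

    def test_non_standard_flagged_not_rejected(self):
        ly = parse_inchi("InChI=1/C2H6O/c1-2-3/h3H,2H2,1H3")
        assert not ly.standard
        assert ly.version == "1"

    def test_multi_component_salt(self):
        ly = parse_inchi(SALT_INCHI)
        assert ly.n_components == 2
        assert ly.q_values == (0, 1)
        assert proton_delta(ly) == -1
        assert net_charge(ly) == 1

    def test_repeated_component_multiplier(self):
        ly = parse_inchi("InChI=1S/2H2O/h2*1H2")
        assert ly.formula == ({"H": 2, "O": 1}, {"H": 2, "O": 1})
        assert expand_components(ly.h_layer) == ["1H2", "1H2"]


class TestSerialize:
    @pytest.mark.parametrize("text", examples.all_printed_inchis())
    def test_printed_strings_round_trip(self, text):
        assert serialize(parse_inchi(text)) == normalize_inchi_text(text)

    @pytest.mark.parametrize("text", examples.all_printed_inchis())
    def test_idempotence(self, text):
        once = serialize(parse_inchi(text))
        assert serialize(parse_inchi(once)) == once

    def test_empty_formula_errors(self):
        ly = InChILayers(version="1S", standard=True, formula_text="", formula=())
        with pytest.raises(InChIError):
            serialize(ly)


class TestChargeArithmetic:
    def test_fig2b_charges(self):
        ly = parse_inchi(FIG2B["inchi"])
        assert net_charge(ly) == 1
        assert proton_delta(ly) == 0

    def test_fig4_deposited_proton_delta(self):
        ly = parse_inchi(FIG4_DEPOSITED)
        assert proton_delta(ly) == -1
        assert net_charge(ly) == 0

    def test_both_absent(self):
        ly = parse_inchi(WATER_INCHI)
        assert (net_charge(ly), proton_delta(ly)) == (0, 0)

    def test_fig2a_core_vs_charged(self):
        ly = parse_inchi(FIG2A["inchi"])
        core = core_parent_formula(ly)
        chg = charged_species_formula(ly)
        assert core.composition == {"C": 15, "H": 16, "N": 4, "O": 3, "S": 1}
        assert chg.composition == {"C": 15, "H": 17, "N": 4, "O": 3, "S": 1}
        assert (core.charge, chg.charge) == (0, 1)

    def test_fig2b_core_equals_charged(self):
        ly = parse_inchi(FIG2B["inchi"])
        assert core_parent_formula(ly).composition == charged_species_formula(ly).composition
        assert charged_species_formula(ly).charge == 1

    def test_neutral_core_equals_charged(self):
        ly = parse_inchi(WATER_INCHI)
        assert core_parent_formula(ly) == charged_species_formula(ly)

    def test_overdeprotonation_errors(self):
        ly = parse_inchi("InChI=1S/CH4/h1H4/p-9")
        with pytest.raises(InChIError):
            charged_species_formula(ly)

    @pytest.mark.parametrize("text", examples.all_printed_inchis())
    def test_arithmetic_identity_printed(self, text):
        ly = parse_inchi(text)
        core, chg = core_parent_formula(ly), charged_species_formula(ly)
        assert chg.composition.get("H", 0) - core.composition.get("H", 0) == proton_delta(ly)
        assert chg.charge == net_charge(ly) + proton_delta(ly)


class TestHillFormat:
    def test_paper_formula(self):
        assert hill_format({"C": 15, "H": 16, "N": 4, "O": 3, "S": 1}, 0) == "C15H16N4O3S"

    def test_no_carbon_alphabetical(self):
        assert hill_format({"H": 2, "O": 1}, 0) == "H2O"
        assert hill_format({"O": 1, "Cl": 1, "H": 1}, 0) == "ClHO"

    def test_count_one_elided(self):
        assert hill_format({"C": 1, "H": 3, "Cl": 1}, 0) == "CH3Cl"

    def test_charge_suffixes(self):
        assert hill_format({"Na": 1}, 1) == "Na+"
        assert hill_format({"O": 4, "S": 1}, -2) == "O4S-2"

    def test_invalid_counts(self):
        with pytest.raises(InChIError):
            hill_format({}, 0)
        with pytest.raises(InChIError):
            hill_format({"C": 0}, 0)

    @given(
        comp=st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Cl", "Na", "P", "Br", "F"]),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=10,
        ),
        charge=st.integers(min_value=-4, max_value=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_hill_order_against_sort_oracle_and_bijectivity(self, comp, charge):
        text = hill_format(comp, charge)
        # brute-force ordering oracle for the Hill rule
        if "C" in comp:
            expected = ["C"] + (["H"] if "H" in comp else []) + sorted(
                e for e in comp if e not in ("C", "H")
            )
        else:
            expected = sorted(comp)
        import re

        seen = re.findall(r"[A-Z][a-z]?", re.sub(r"[+\-0-9]+$", "", text))
        assert seen == expected
        back_comp, back_charge, _ = parse_formula_string(text)
        assert back_comp == comp
        assert back_charge == charge


class TestParseFormulaString:
    def test_fig2a_archived(self):
        assert parse_formula_string("C15H17N4O3S+") == (
            {"C": 15, "H": 17, "N": 4, "O": 3, "S": 1},
            1,
            True,
        )

    def test_fig2b_archived_with_parens(self):
        assert parse_formula_string("(C15H16N+)") == ({"C": 15, "H": 16, "N": 1}, 1, True)

    def test_neutral(self):
        assert parse_formula_string("H2O") == ({"H": 2, "O": 1}, 0, False)

    @pytest.mark.parametrize(
        "text,charge",
        [("Na+", 1), ("Cl-", -1), ("SO4-2", -2), ("Fe+3", 3)],
    )
    def test_charge_dialects(self, text, charge):
        _, got, was = parse_formula_string(text)
        assert was and got == charge

    def test_bare_sign_keeps_digits_as_counts(self):
        assert parse_formula_string("O2-") == ({"O": 2}, -1, True)

    def test_multi_component(self):
        comp, charge, _ = parse_formula_string("C2H4O2.Na")
        assert comp == {"C": 2, "H": 4, "O": 2, "Na": 1}
        assert charge == 0

    @pytest.mark.parametrize("bad", ["", "   ", "Xx5", "123", "+", "2+"])
    def test_errors(self, bad):
        with pytest.raises(InChIError):
            parse_formula_string(bad)


class TestAmbiguousStereo:
    def test_fig5_ambiguous(self):
        assert has_ambiguous_stereo(parse_inchi(FIG5_DEPOSITED))

    def test_fig2b_defined(self):
        assert not has_ambiguous_stereo(parse_inchi(FIG2B["inchi"]))

    def test_empty_layers(self):
        assert not has_ambiguous_stereo(parse_inchi(WATER_INCHI))


class TestGeneratedInChIs:
    def test_arithmetic_identity_on_builtins(self, builtin_inchis):
        for inchi in builtin_inchis.values():
            ly = parse_inchi(inchi)
            core, chg = core_parent_formula(ly), charged_species_formula(ly)
            assert chg.composition.get("H", 0) - core.composition.get("H", 0) == proton_delta(ly)
            assert chg.charge == net_charge(ly) + proton_delta(ly)
            assert serialize(parse_inchi(inchi)) == inchi

    def test_salt_charged_species(self):
        species = charged_species_formula(parse_inchi(SALT_INCHI))
        assert species.composition == {"C": 2, "H": 3, "O": 2, "Na": 1}
        assert species.charge == 0
        assert species.text == "C2H3NaO2"
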