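"""Curated real-world discrepancy examples from the PubChem Compound archive.

Each record keeps the identifier strings exactly as they circulate in print —
including inserted spaces ("InChI = 1 S/"), emphasis markers (``**``) and
stray trailing punctuation — so they double as regression inputs for the
typesetting normalizer. ``expected_diff`` is the layer set an audit of the
derived-vs-deposited pair must report.
"""

from __future__ import annotations

CHARGED_FORMULA_EXAMPLES = {
    # charge carried by protonation: archived formula counts the extra proton,
    # the InChI formula layer records the core parent and /p carries the charge
    "91929631": {
        "archived_formula": "C15H17N4O3S+",
        "inchi": (
            "InChI = 1 S/C15H16N4O3S/c16-15(17)11-5-4-8-13(9-11)23(21,22)18-10-"
            "14(20)19-12-6-2-1-3-7-12/h1-9,18 H,10H2,(H3,16,17)(H,19,20)/**p + 1**"
        ),
        "core_hill": "C15H16N4O3S",
        "charge_mode": "protonation",
    },
    # intrinsic covalent charge: quaternary nitrogen, /q layer, H counts agree
    "91124997": {
        "archived_formula": "C15H16N+",
        "inchi": (
            "InChI = 1 S/C15H16N/c1-11-6-5-9-15-14-8-4-3-7-13(14)10-12(2)16(11)15/"
            "h3-9,12 H,10H2,1-2H3/**q + 1**/t12-/m0/s1"
        ),
        "core_hill": "C15H16N",
        "charge_mode": "intrinsic",
    },
}

INCHI_DISCREPANCY_EXAMPLES = {
    # heavy-atom connectivity mismatch (/c only; /h layers identical)
    "12300268": {
        "derived": (
            "InChI = 1 S/C26H26/**c1-2-20-4-3-19(1)9-13-23-17-26-16-12-22-7-5-"
            "21(6-8-22)11-15-25(23)18-24(26)14-10-20**/h1-8,17-18 H,9-16H2"
        ),
        "deposited": (
            "InChI = 1 S/C26H26/**c1-2-20-4-3-19(1)9-13-23-17-24(14-10-20)26-16-"
            "12-22-7-5-21(6-8-22)11-15-25(23)18-26**/h1-8,17-18 H,9-16H2"
        ),
        "expected_diff": {"c"},
        "expected_categories": {"atom_connectivity"},
    },
    # charge-state mismatch: deposited expresses the anion via formula+/p,
    # the structure carries it intrinsically via /q (charged species agree)
    "2179800": {
        "deposited": (
            "InChI = 1 S/C15H9N3O5/c19-13-6-5-10(18(22)23)7-9(13)8-16-17-14(20)"
            "11-3-1-2-4-12(11)15(17)21/h1-8,19 H/**p-1**"
        ),
        "derived": (
            "InChI = 1 S/C15H8N3O5/c19-13-6-5-10(18(22)23)7-9(13)8-16-17-14(20)"
            "11-3-1-2-4-12(11)15(17)21/h1-8H/**q-1**"
        ),
        "expected_diff": {"h", "p", "q"},
        "expected_categories": {"atom_connectivity", "charge"},
    },
    # double-bond geometry: archived string holds a '?' in /b (ambiguous),
    # the structure shows the trans configuration
    "1551886": {
        "deposited": (
            "InChI = 1 S/C17H10N4O7S2/c22-13-3-1-11(20(25)26)5-9(13)7-15-16(24)"
            "19(17(29)30-15)18-8-10-6-12(21(27)28)2-4-14(10)23/h1-8,22-23 H/p-2"
            "**/b15-7-,18-8?**"
        ),
        "expected_diff": None,  # derived counterpart not printed
        "expected_categories": None,
    },
    # chirality: archived string lacks the /t layer the structure requires
    "130156427": {
        "deposited": (
            "InChI = 1 S/C25H30N2O6/c1-25(2,3)33-24(30)27-21(22(28)31-4)13-14-"
            "26-23(29)32-15-20-18-11-7-5-9-16(18)17-10-6-8-12-19(17)20/h5-12,"
            "20-21 H,13-15H2,1-4H3,(H,26,29)(H,27,30)"
        ),
        "derived": (
            "InChI = 1 S/C25H30N2O6/c1-25(2,3)33-24(30)27-21(22(28)31-4)13-14-"
            "26-23(29)32-15-20-18-11-7-5-9-16(18)17-10-6-8-12-19(17)20/h5-12,"
            "20-21 H,13-15H2,1-4H3,(H,26,29)(H,27,30)/**t21-**/m0/s1."
        ),
        "expected_diff": {"t", "m", "s"},
        "expected_categories": {"stereochemistry"},
    },
}


def all_printed_inchis() -> list[str]:
    """Every InChI string in the example set, in a stable order."""
    out = [rec["inchi"] for _, rec in sorted(CHARGED_FORMULA_EXAMPLES.items())]
    for _, rec in sorted(INCHI_DISCREPANCY_EXAMPLES.items()):
        for key in ("derived", "deposited"):
            if rec.get(key):
                out.append(rec[key])
    return out
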