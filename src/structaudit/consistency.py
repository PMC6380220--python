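"""Layer-wise InChI diffing, discrepancy categorization, formula reconciliation.

Category map (layer → discrepancy category):

    /c, /h       → atom_connectivity
    /p, /q       → charge
    /b, /t, /m, /s → stereochemistry
    /i           → isotope
    formula      → formula

/m and /s are folded into stereochemistry (a /t value is meaningless without
them); the raw differing-layer set is always kept on the report so stricter
per-layer tallies remain computable.

The formula layer is flagged only when the two strings are irreconcilable:
iff the core-parent compositions differ AND the charged-species views
(core H + /p, charge /q + /p) also differ. A pure protonation-bookkeeping
difference therefore flags /p (and usually /h) but not the formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import labeling, layers as L
from .mol import Molecule

__all__ = [
    "CATEGORY_MAP",
    "DiscrepancyReport",
    "diff_layers",
    "categorize",
    "reconcile_formula",
    "check_entry",
]

CATEGORY_MAP: dict[str, str] = {
    "c": "atom_connectivity",
    "h": "atom_connectivity",
    "p": "charge",
    "q": "charge",
    "b": "stereochemistry",
    "t": "stereochemistry",
    "m": "stereochemistry",
    "s": "stereochemistry",
    "i": "isotope",
    "formula": "formula",
}


@dataclass
class DiscrepancyReport:
    cid: str = ""
    differing_layers: set[str] = field(default_factory=set)
    categories: set[str] = field(default_factory=set)
    ambiguous_stereo: bool = False
    non_standard_deposited: bool = False
    notes: list[str] = field(default_factory=list)
    derived_inchi: str = ""
    deposited_inchi: str = ""

    @property
    def flagged(self) -> bool:
        return bool(self.categories)

    def to_row(self) -> dict[str, str]:
        return {
            "cid": self.cid,
            "differing_layers": "|".join(sorted(self.differing_layers)),
            "categories": "|".join(sorted(self.categories)),
            "ambiguous_stereo": str(int(self.ambiguous_stereo)),
            "non_standard_deposited": str(int(self.non_standard_deposited)),
            "notes": "; ".join(self.notes),
        }


def _padded(values: tuple[int, ...], n: int) -> tuple[int, ...]:
    return values + (0,) * (n - len(values))


def _expanded(text: str) -> str:
    return ";".join(L.expand_components(text))


def diff_layers(derived: L.InChILayers, deposited: L.InChILayers) -> set[str]:
    """Names of layers whose normalized, component-expanded content differs."""
    diff: set[str] = set()

    core_d, core_p = L.core_parent_formula(derived), L.core_parent_formula(deposited)
    try:
        chg_d, chg_p = L.charged_species_formula(derived), L.charged_species_formula(deposited)
        charged_differ = chg_d != chg_p
    except L.InChIError:
        charged_differ = True
    if core_d.composition != core_p.composition and charged_differ:
        diff.add("formula")

    for name in ("c", "h", "b", "t", "m", "s"):
        if _expanded(getattr(derived, f"{name}_layer")) != _expanded(
            getattr(deposited, f"{name}_layer")
        ):
            diff.add(name)
    n = max(derived.n_components, deposited.n_components)
    if _padded(derived.q_values, n) != _padded(deposited.q_values, n):
        diff.add("q")
    if _padded(derived.p_values, n) != _padded(deposited.p_values, n):
        diff.add("p")
    if derived.i_layer != deposited.i_layer:
        diff.add("i")
    return diff


def categorize(differing_layers: set[str]) -> set[str]:
    """Map differing layer names to discrepancy categories (union over layers)."""
    cats: set[str] = set()
    for name in differing_layers:
        if name not in CATEGORY_MAP:
            raise ValueError(f"unknown layer name {name!r}")
        cats.add(CATEGORY_MAP[name])
    return cats


def reconcile_formula(deposited_formula: str, derived: L.InChILayers) -> tuple[bool, str]:
    """Compare a deposited formula string against the structure-derived species.

    Consistent iff composition and charge both equal the charged-species view
    of the derived InChI. The explanation distinguishes charge-via-protonation
    (deposited H = core H + /p) from intrinsic covalent charge (/q, H equal).
    """
    try:
        comp, charge, was_charged = L.parse_formula_string(deposited_formula)
    except L.InChIError as exc:
        return False, f"unparseable deposited formula: {exc}"
    species = L.charged_species_formula(derived)
    p, q = L.proton_delta(derived), L.net_charge(derived)
    mode = (
        f"charge via protonation (/p {p:+d}: deposited H = core H {p:+d})"
        if p
        else ("intrinsic covalent charge (/q)" if q else "neutral species")
    )
    if comp == species.composition and charge == species.charge:
        return True, f"consistent; {mode}"
    deposited = L.hill_format(comp, charge)
    return False, (
        f"deposited {deposited} vs structure-derived {species.text}; {mode}"
    )


def check_entry(
    mol: Molecule,
    deposited_inchi: str = "",
    deposited_formula: str = "",
    derived_inchi: str | None = None,
) -> DiscrepancyReport:
    """Audit one entry: derive the InChI from the structure and compare it to
    the deposited identifier and formula. Empty deposited fields are skipped.

    ``derived_inchi`` lets callers that already ran the delegate avoid a
    second run.
    """
    report = DiscrepancyReport(cid=mol.cid)
    if derived_inchi is None:
        try:
            derived_inchi = labeling.generate_inchi(mol).inchi
        except labeling.InChIGenerationError as exc:
            report.notes.append(f"delegate error: {exc}")
            return report
    report.derived_inchi = derived_inchi
    derived = L.parse_inchi(derived_inchi)
    report.ambiguous_stereo = L.has_ambiguous_stereo(derived)

    if deposited_inchi and deposited_inchi.strip():
        try:
            deposited = L.parse_inchi(deposited_inchi)
        except L.InChIError as exc:
            report.notes.append(f"deposited InChI unparseable: {exc}")
            deposited = None
        if deposited is not None:
            report.deposited_inchi = L.serialize(deposited)
            report.ambiguous_stereo |= L.has_ambiguous_stereo(deposited)
            if not deposited.standard:
                report.non_standard_deposited = True
                report.notes.append(
                    f"deposited InChI is non-standard (version {deposited.version}); "
                    "excluded from layer diffing"
                )
            else:
                report.differing_layers |= diff_layers(derived, deposited)

    if deposited_formula and deposited_formula.strip():
        consistent, why = reconcile_formula(deposited_formula, derived)
        if not consistent:
            report.differing_layers.add("formula")
            report.notes.append(why)

    report.categories = categorize(report.differing_layers)
    return report
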