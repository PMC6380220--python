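"""Standard-InChI generation (delegated) and canonical atom labeling.

The InChI canonicalization algorithm is never reimplemented: structures are
handed to the IUPAC InChI library bundled with RDKit, and the delegate's
name/version is stamped into every result so version drift is visible.

Atom labels are derived from the AuxInfo ``/N:`` layer, which lists original
heavy-atom indices in canonical order: a heavy atom is labeled by element
symbol plus its canonical number; hydrogens borrow the number of their heavy
neighbor, with geometric suffixes a,b,… when a heavy atom bears several.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .mol import Molecule

__all__ = [
    "InChIGenerationError",
    "InChIResult",
    "AtomLabelMap",
    "delegate_version",
    "generate_inchi",
    "parse_auxinfo_numbering",
    "parse_auxinfo_equivalence",
    "assign_labels",
    "make_label_map",
]


class InChIGenerationError(RuntimeError):
    """The InChI delegate failed to produce an identifier."""


@dataclass(frozen=True)
class InChIResult:
    inchi: str
    auxinfo: str
    warnings: str = ""
    delegate: str = ""


@dataclass
class AtomLabelMap:
    """Bijection between original 1-based atom indices and unique labels."""

    entries: dict[int, str]
    inverse: dict[str, int]
    component_of: dict[int, int]
    order: list[int]  # original indices in canonical output order
    warnings: list[str] = field(default_factory=list)

    def to_csv(self) -> str:
        lines = ["original_index,label"]
        lines += [f"{idx},{self.entries[idx]}" for idx in sorted(self.entries)]
        return "\n".join(lines) + "\n"

    def component_csv(self) -> str:
        lines = ["original_index,component,label"]
        lines += [
            f"{idx},{self.component_of[idx]},{self.entries[idx]}"
            for idx in sorted(self.entries)
        ]
        return "\n".join(lines) + "\n"


def delegate_version() -> str:
    import rdkit

    return f"rdkit-{rdkit.__version__}"


def _to_rdkit(mol: Molecule):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        if a.isotope:
            atom.SetIsotope(a.isotope)
        atom.SetNoImplicit(True)  # explicit-H input: never synthesize hydrogens
        rw.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in mol.bonds:
        rw.AddBond(b.a1 - 1, b.a2 - 1, order_map[b.order])
    m = rw.GetMol()
    conf = Chem.Conformer(m.GetNumAtoms())
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, Point3D(a.x, a.y, a.z))
    m.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(m)
    if mol.is_3d:
        Chem.AssignStereochemistryFrom3D(m)
    return m


def generate_inchi(mol: Molecule, ignore_stereo: bool = False) -> InChIResult:
    """Run the delegate on ``mol`` and return (InChI, AuxInfo, warnings).

    ``ignore_stereo`` strips perceived stereochemistry first (used to build
    deposited-side fixtures that lack /b and /t layers). Delegate warnings are
    captured, not raised; hard failures raise :class:`InChIGenerationError`.
    """
    if not mol.atoms:
        raise InChIGenerationError("cannot generate an InChI for an empty molecule")
    from rdkit import Chem, rdBase
    from rdkit.Chem import rdinchi

    try:
        rmol = _to_rdkit(mol)
        if ignore_stereo:
            # the delegate re-perceives stereo from 3D coordinates, so the
            # conformer must go along with the perceived tags
            Chem.RemoveStereochemistry(rmol)
            rmol.RemoveAllConformers()
    except Exception as exc:
        raise InChIGenerationError(f"structure rejected by delegate: {exc}") from exc
    with rdBase.BlockLogs():
        inchi, retcode, message, log, auxinfo = rdinchi.MolToInchi(rmol)
    if not inchi or retcode >= 2:
        raise InChIGenerationError(f"delegate failed (code {retcode}): {message}")
    if not inchi.startswith("InChI=1S"):
        raise InChIGenerationError(f"delegate produced a non-standard InChI: {inchi!r}")
    return InChIResult(
        inchi=inchi,
        auxinfo=auxinfo or "",
        warnings=message or "",
        delegate=delegate_version(),
    )


_N_LAYER = re.compile(r"/N:([0-9,;]+)")
_E_LAYER = re.compile(r"/E:([^/]*)")


def parse_auxinfo_numbering(auxinfo: str) -> list[dict[int, int]]:
    """Extract the /N: layer: per component, canonical position → original index."""
    m = _N_LAYER.search(auxinfo)
    if not m:
        raise ValueError(f"AuxInfo has no /N: numbering layer: {auxinfo[:60]!r}")
    components: list[dict[int, int]] = []
    for comp_text in m.group(1).split(";"):
        if not comp_text:
            raise ValueError(f"empty component in /N: layer {m.group(1)!r}")
        components.append(
            {pos + 1: int(tok) for pos, tok in enumerate(comp_text.split(","))}
        )
    return components


def parse_auxinfo_equivalence(auxinfo: str) -> list[list[tuple[int, ...]]]:
    """Extract the /E: layer: per component, groups of exchangeable canonical
    positions. The canonical numbering is unique only up to these groups, so
    callers must break the tie deterministically. Missing layer → no groups.
    """
    m = _E_LAYER.search(auxinfo)
    if not m:
        return []
    components: list[list[tuple[int, ...]]] = []
    for comp_text in m.group(1).split(";"):
        groups: list[tuple[int, ...]] = []
        for body in re.findall(r"\(([0-9,\-]+)\)", comp_text):
            members: list[int] = []
            for tok in body.split(","):
                if "-" in tok:
                    lo, hi = tok.split("-")
                    members.extend(range(int(lo), int(hi) + 1))
                else:
                    members.append(int(tok))
            groups.append(tuple(members))
        components.append(groups)
    return components


def make_label_map(mol: Molecule, result: InChIResult | None = None) -> AtomLabelMap:
    """Full labeling pipeline: delegate → numbering + equivalence → labels."""
    res = result if result is not None else generate_inchi(mol)
    return assign_labels(
        mol,
        parse_auxinfo_numbering(res.auxinfo),
        parse_auxinfo_equivalence(res.auxinfo),
    )


def _suffixes(n: int) -> list[str]:
    out = []
    for k in range(n):
        s = ""
        k += 1
        while k:
            k, r = divmod(k - 1, 26)
            s = chr(ord("a") + r) + s
        out.append(s)
    return out


def assign_labels(
    mol: Molecule,
    numbering: list[dict[int, int]],
    equivalence: list[list[tuple[int, ...]]] | None = None,
) -> AtomLabelMap:
    """Turn the canonical numbering into unique, permutation-invariant labels.

    Canonical numbers run sequentially across components in canonical
    component order, so labels stay globally unique for multi-component
    entries. The delegate's numbering is unique only up to its equivalence
    groups (symmetric or mobile-H-equivalent atoms); within each group the
    assignment is re-sorted by coordinates so it cannot depend on input atom
    order. Hydrogen suffix order is likewise fixed by geometry (distance to
    the parent heavy atom, then lexicographic coordinates).
    """
    atoms = {a.index: a for a in mol.atoms}
    heavy = {i for i, a in atoms.items() if a.element != "H"}

    if not heavy:
        # hydrogen-only species (H2, lone H-): no canonical heavy numbering
        entries_h: dict[int, str] = {}
        order_h = sorted(atoms, key=lambda i: (atoms[i].x, atoms[i].y, atoms[i].z))
        for n, idx in enumerate(order_h, start=1):
            entries_h[idx] = f"H{n}"
        return AtomLabelMap(
            entries=entries_h,
            inverse={v: k for k, v in entries_h.items()},
            component_of={i: 1 for i in atoms},
            order=order_h,
            warnings=["hydrogen-only molecule: sequential hydrogen labels"],
        )

    numbered = [idx for comp in numbering for idx in comp.values()]
    if sorted(numbered) != sorted(heavy):
        raise ValueError(
            f"numbering covers atoms {sorted(numbered)} but heavy atoms are {sorted(heavy)}"
        )

    # geometric tie-break inside each exchangeable-position group
    if equivalence:
        def coord_key(orig: int):
            a = atoms[orig]
            return (round(a.x, 6), round(a.y, 6), round(a.z, 6))

        for comp, groups in zip(numbering, equivalence):
            for group in groups:
                positions = sorted(p for p in group if p in comp)
                origs = sorted((comp[p] for p in positions), key=coord_key)
                for pos, orig in zip(positions, origs):
                    comp[pos] = orig

    entries: dict[int, str] = {}
    component_of: dict[int, int] = {}
    warnings: list[str] = []
    canon_number: dict[int, int] = {}
    offset = 0
    for comp_ord, comp in enumerate(numbering, start=1):
        for pos in sorted(comp):
            orig = comp[pos]
            canon_number[orig] = offset + pos
            component_of[orig] = comp_ord
            entries[orig] = f"{atoms[orig].element}{offset + pos}"
        offset += len(comp)

    # hydrogens: grouped under their heavy neighbor
    neighbors: dict[int, list[int]] = {i: [] for i in atoms}
    for b in mol.bonds:
        neighbors[b.a1].append(b.a2)
        neighbors[b.a2].append(b.a1)
    h_of_heavy: dict[int, list[int]] = {}
    orphans: list[int] = []
    for i, a in atoms.items():
        if a.element != "H":
            continue
        heavies = [j for j in neighbors[i] if atoms[j].element != "H"]
        if heavies:
            # bridging H (rare): attach to the lowest-canonical heavy neighbor
            parent = min(heavies, key=lambda j: canon_number[j])
            h_of_heavy.setdefault(parent, []).append(i)
        else:
            orphans.append(i)

    def geo_key(parent: int):
        p = atoms[parent]

        def key(h: int):
            a = atoms[h]
            d = math.dist((a.x, a.y, a.z), (p.x, p.y, p.z))
            return (round(d, 6), round(a.x, 6), round(a.y, 6), round(a.z, 6))

        return key

    order: list[int] = []
    for parent in sorted(canon_number, key=canon_number.get):
        order.append(parent)
        hs = sorted(h_of_heavy.get(parent, []), key=geo_key(parent))
        if len(hs) == 1:
            entries[hs[0]] = f"H{canon_number[parent]}"
        else:
            for h, suf in zip(hs, _suffixes(len(hs))):
                entries[h] = f"H{canon_number[parent]}{suf}"
        for h in hs:
            component_of[h] = component_of[parent]
        order.extend(hs)

    next_num = offset + 1
    for h in sorted(orphans, key=lambda i: (atoms[i].x, atoms[i].y, atoms[i].z)):
        entries[h] = f"H{next_num}"
        component_of[h] = 0
        order.append(h)
        next_num += 1
        warnings.append(f"atom {h}: hydrogen without a heavy neighbor; sequential label")

    inverse = {lab: idx for idx, lab in entries.items()}
    if len(inverse) != len(entries) or len(entries) != len(atoms):
        raise ValueError("label assignment is not a bijection over the atoms")
    return AtomLabelMap(
        entries=entries,
        inverse=inverse,
        component_of=component_of,
        order=order,
        warnings=warnings,
    )
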