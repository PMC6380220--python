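"""Synthetic molecules and controlled perturbations with ground-truth labels.

Every audit path is testable offline: a dozen hand-frozen 3D structures with
explicit hydrogens, plus seeded perturbations that inject exactly one known
discrepancy class each. Deposited-side strings are always generated from a
modified structure by the InChI delegate — never hand-edited text — so the
ground truth cannot drift from the canonicalizer.
"""

from __future__ import annotations

import csv
import io
import math
import random
from dataclasses import dataclass, replace
from pathlib import Path

from . import labeling
from . import layers as L
from .mol import Atom, Bond, Molecule, write_sdf

__all__ = [
    "PerturbationSpec",
    "PerturbedEntry",
    "InapplicablePerturbation",
    "builtin_molecules",
    "perturb",
    "make_corpus",
    "PERTURBATION_KINDS",
]

# (element, formal_charge, x, y, z), bonds as (a1, a2, order); 1-based indices
_BUILTINS: dict[str, tuple[list[tuple], list[tuple[int, int, int]]]] = {
    "water": (
        [
            ("O", 0, -0.006, 0.3872, 0.0),
            ("H", 0, -0.794, -0.1958, 0.0),
            ("H", 0, 0.8, -0.1914, 0.0),
        ],
        [(1, 2, 1), (1, 3, 1)],
    ),
    "methane": (
        [
            ("C", 0, 0.0126, -0.0225, 0.001),
            ("H", 0, -0.7437, -0.2571, -0.7723),
            ("H", 0, 0.1358, 1.0839, -0.0078),
            ("H", 0, -0.4033, -0.3463, 0.9759),
            ("H", 0, 0.9986, -0.4581, -0.1968),
        ],
        [(1, 2, 1), (1, 3, 1), (1, 4, 1), (1, 5, 1)],
    ),
    "ethanol": (
        [
            ("C", 0, -0.9086, 0.2872, 0.0621),
            ("C", 0, 0.4208, -0.3722, -0.2088),
            ("O", 0, 1.4292, 0.5509, 0.0661),
            ("H", 0, -1.6643, -0.1481, -0.64),
            ("H", 0, -0.8904, 1.3899, -0.1288),
            ("H", 0, -1.2502, 0.0921, 1.1087),
            ("H", 0, 0.4695, -1.2429, 0.4943),
            ("H", 0, 0.5, -0.8121, -1.2178),
            ("H", 0, 1.894, 0.2552, 0.8915),
        ],
        [(1, 2, 1), (2, 3, 1), (1, 4, 1), (1, 5, 1), (1, 6, 1), (2, 7, 1), (2, 8, 1), (3, 9, 1)],
    ),
    "glycine": (
        [
            ("N", 0, -0.9376, 0.7341, -0.6877),
            ("C", 0, -0.6549, -0.4126, 0.1296),
            ("C", 0, 0.7904, -0.392, 0.4837),
            ("O", 0, 1.2349, -1.3331, 1.2086),
            ("O", 0, 1.6615, 0.6012, 0.0596),
            ("H", 0, -1.329, 0.5117, -1.6219),
            ("H", 0, -1.3352, 1.5546, -0.2028),
            ("H", 0, -1.2517, -0.3559, 1.0468),
            ("H", 0, -0.8544, -1.3579, -0.4148),
            ("H", 0, 2.676, 0.4498, -0.0012),
        ],
        [(1, 2, 1), (2, 3, 1), (3, 4, 2), (3, 5, 1), (1, 6, 1), (1, 7, 1), (2, 8, 1), (2, 9, 1), (5, 10, 1)],
    ),
    "glycine_zwitterion": (
        [
            ("N", 1, -1.1035, 0.118, 0.0582),
            ("C", 0, 0.1377, -0.5468, -0.2108),
            ("C", 0, 1.2358, 0.3976, 0.125),
            ("O", 0, 0.9171, 1.5452, 0.5599),
            ("O", -1, 2.5532, 0.0067, -0.0427),
            ("H", 0, -1.6193, -0.4191, 0.7789),
            ("H", 0, -1.6673, 0.1288, -0.826),
            ("H", 0, -0.9809, 1.0775, 0.4678),
            ("H", 0, 0.2211, -0.8454, -1.2923),
            ("H", 0, 0.3061, -1.4624, 0.382),
        ],
        [(1, 2, 1), (2, 3, 1), (3, 4, 2), (3, 5, 1), (1, 6, 1), (1, 7, 1), (1, 8, 1), (2, 9, 1), (2, 10, 1)],
    ),
    "l_alanine": (
        [
            ("N", 0, -0.6478, 1.1202, -0.7649),
            ("C", 0, -0.3301, 0.3165, 0.3803),
            ("C", 0, -1.1027, -0.9864, 0.223),
            ("C", 0, 1.1146, -0.0193, 0.4662),
            ("O", 0, 1.6328, -0.7004, 1.3625),
            ("O", 0, 1.9615, 0.4659, -0.5362),
            ("H", 0, -0.1254, 0.8607, -1.6122),
            ("H", 0, -0.7209, 2.1282, -0.5694),
            ("H", 0, -0.6219, 0.8191, 1.3032),
            ("H", 0, -0.5265, -1.859, 0.6009),
            ("H", 0, -2.033, -0.9019, 0.8325),
            ("H", 0, -1.3663, -1.1597, -0.8485),
            ("H", 0, 2.7657, -0.0839, -0.8374),
        ],
        [(1, 2, 1), (2, 3, 1), (2, 4, 1), (4, 5, 2), (4, 6, 1), (1, 7, 1), (1, 8, 1), (2, 9, 1), (3, 10, 1), (3, 11, 1), (3, 12, 1), (6, 13, 1)],
    ),
    "d_alanine": (
        [
            ("N", 0, -1.032, 1.3062, 0.1842),
            ("C", 0, -0.2711, 0.1893, -0.2968),
            ("C", 0, -0.9471, -1.1295, 0.0465),
            ("C", 0, 1.1337, 0.2359, 0.1353),
            ("O", 0, 1.5604, 1.1973, 0.8596),
            ("O", 0, 2.0061, -0.7657, -0.2414),
            ("H", 0, -1.2429, 2.0129, -0.5551),
            ("H", 0, -0.6193, 1.7505, 1.0339),
            ("H", 0, -0.2727, 0.2552, -1.4155),
            ("H", 0, -0.1687, -1.8825, 0.2986),
            ("H", 0, -1.6198, -0.973, 0.9323),
            ("H", 0, -1.5396, -1.5113, -0.8093),
            ("H", 0, 3.0128, -0.6854, -0.1723),
        ],
        [(1, 2, 1), (2, 3, 1), (2, 4, 1), (4, 5, 2), (4, 6, 1), (1, 7, 1), (1, 8, 1), (2, 9, 1), (3, 10, 1), (3, 11, 1), (3, 12, 1), (6, 13, 1)],
    ),
    "cis_2_butene": (
        [
            ("C", 0, 1.4463, -0.5326, -0.0702),
            ("C", 0, 0.7092, 0.7439, -0.1153),
            ("C", 0, -0.6096, 0.849, -0.0252),
            ("C", 0, -1.5056, -0.3061, 0.1321),
            ("H", 0, 2.2179, -0.4265, 0.7278),
            ("H", 0, 1.9481, -0.6814, -1.0613),
            ("H", 0, 0.8526, -1.4055, 0.1435),
            ("H", 0, 1.3041, 1.6547, -0.231),
            ("H", 0, -1.0342, 1.8674, -0.0733),
            ("H", 0, -1.0962, -1.1229, 0.7562),
            ("H", 0, -2.4148, 0.0465, 0.6732),
            ("H", 0, -1.8179, -0.6865, -0.8565),
        ],
        [(1, 2, 1), (2, 3, 2), (3, 4, 1), (1, 5, 1), (1, 6, 1), (1, 7, 1), (2, 8, 1), (3, 9, 1), (4, 10, 1), (4, 11, 1), (4, 12, 1)],
    ),
    "trans_2_butene": (
        [
            ("C", 0, 1.8942, 0.1555, -0.0535),
            ("C", 0, 0.4521, 0.2141, -0.4705),
            ("C", 0, -0.4317, -0.2179, 0.4371),
            ("C", 0, -1.8978, -0.1863, 0.0827),
            ("H", 0, 2.1727, -0.9057, 0.0325),
            ("H", 0, 2.0937, 0.7474, 0.8581),
            ("H", 0, 2.475, 0.63, -0.8772),
            ("H", 0, 0.1385, 0.5805, -1.4403),
            ("H", 0, -0.1457, -0.588, 1.4107),
            ("H", 0, -2.3782, 0.3239, 0.9401),
            ("H", 0, -2.3023, -1.1942, -0.107),
            ("H", 0, -2.0704, 0.4406, -0.8127),
        ],
        [(1, 2, 1), (2, 3, 2), (3, 4, 1), (1, 5, 1), (1, 6, 1), (1, 7, 1), (2, 8, 1), (3, 9, 1), (4, 10, 1), (4, 11, 1), (4, 12, 1)],
    ),
    "tetramethylammonium": (
        [
            ("C", 0, -0.1808, -0.7258, -1.2708),
            ("N", 1, 0.0359, -0.0581, -0.0054),
            ("C", 0, -0.0729, 1.3919, -0.158),
            ("C", 0, -1.0704, -0.4245, 0.8827),
            ("C", 0, 1.3265, -0.3522, 0.5649),
            ("H", 0, -0.6732, -0.0462, -2.0035),
            ("H", 0, -0.7988, -1.644, -1.0987),
            ("H", 0, 0.8278, -1.0015, -1.6692),
            ("H", 0, 0.667, 1.8906, 0.5034),
            ("H", 0, -1.0778, 1.7786, 0.0966),
            ("H", 0, 0.1572, 1.6874, -1.1974),
            ("H", 0, -1.9877, -0.1971, 0.273),
            ("H", 0, -1.0647, -1.4709, 1.1755),
            ("H", 0, -1.1158, 0.2758, 1.759),
            ("H", 0, 1.7403, -1.3176, 0.2433),
            ("H", 0, 2.0395, 0.4541, 0.2347),
            ("H", 0, 1.248, -0.2406, 1.6698),
        ],
        [(1, 2, 1), (2, 3, 1), (2, 4, 1), (2, 5, 1), (1, 6, 1), (1, 7, 1), (1, 8, 1), (3, 9, 1), (3, 10, 1), (3, 11, 1), (4, 12, 1), (4, 13, 1), (4, 14, 1), (5, 15, 1), (5, 16, 1), (5, 17, 1)],
    ),
    "sodium_acetate": (
        [
            ("C", 0, -0.662, -0.0782, 0.0251),
            ("C", 0, 0.818, 0.0284, -0.0014),
            ("O", 0, 1.5506, -0.9985, -0.0747),
            ("O", -1, 1.3817, 1.2975, 0.0569),
            ("Na", 1, 3.5, 0.0, 0.0),
            ("H", 0, -1.0863, 0.2839, 0.9764),
            ("H", 0, -0.9344, -1.1161, -0.1958),
            ("H", 0, -1.0675, 0.583, -0.7865),
        ],
        [(1, 2, 1), (2, 3, 2), (2, 4, 1), (1, 6, 1), (1, 7, 1), (1, 8, 1)],
    ),
    "propan_1_ol": (
        [
            ("C", 0, -1.1675, 0.7562, 0.118),
            ("C", 0, -0.4108, -0.4573, -0.334),
            ("C", 0, 0.9135, -0.583, 0.3942),
            ("O", 0, 1.7373, 0.4905, 0.1938),
            ("H", 0, -2.2464, 0.6163, -0.0944),
            ("H", 0, -0.8222, 1.6867, -0.3932),
            ("H", 0, -1.064, 0.9526, 1.2028),
            ("H", 0, -1.0047, -1.372, -0.1695),
            ("H", 0, -0.2617, -0.3488, -1.4371),
            ("H", 0, 0.6475, -0.5919, 1.4911),
            ("H", 0, 1.3899, -1.5678, 0.2159),
            ("H", 0, 2.2893, 0.4184, -0.6432),
        ],
        [(1, 2, 1), (2, 3, 1), (3, 4, 1), (1, 5, 1), (1, 6, 1), (1, 7, 1), (2, 8, 1), (2, 9, 1), (3, 10, 1), (3, 11, 1), (4, 12, 1)],
    ),
}

PERTURBATION_KINDS = (
    "protonate",
    "deprotonate",
    "set_formal_charge",
    "rewire_bond",
    "invert_chiral_center",
    "flip_double_bond_geometry",
    "drop_stereo",
    "permute_atoms",
)

# expected differing layers per (kind, builtin); categories follow the layer map
_EXPECTED_LAYERS: dict[str, dict[str, frozenset[str]]] = {
    "protonate": {m: frozenset({"p"}) for m in ("glycine", "l_alanine", "d_alanine")},
    # only acids whose anion the InChI normalizer folds back into /p:
    # carboxylates and hydroxide; plain alkoxides keep an intrinsic /q
    "deprotonate": {
        m: frozenset({"p"}) for m in ("glycine", "l_alanine", "d_alanine", "water")
    },
    "set_formal_charge": {"sodium_acetate": frozenset({"q"})},
    "rewire_bond": {"propan_1_ol": frozenset({"c", "h"})},
    "invert_chiral_center": {m: frozenset({"m"}) for m in ("l_alanine", "d_alanine")},
    "flip_double_bond_geometry": {
        m: frozenset({"b"}) for m in ("cis_2_butene", "trans_2_butene")
    },
    "drop_stereo": {
        "l_alanine": frozenset({"t", "m", "s"}),
        "d_alanine": frozenset({"t", "m", "s"}),
        "cis_2_butene": frozenset({"b"}),
        "trans_2_butene": frozenset({"b"}),
    },
    "permute_atoms": {m: frozenset() for m in _BUILTINS},
}

_CATEGORY_OF_KIND = {
    "protonate": frozenset({"charge"}),
    "deprotonate": frozenset({"charge"}),
    "set_formal_charge": frozenset({"charge"}),
    "rewire_bond": frozenset({"atom_connectivity"}),
    "invert_chiral_center": frozenset({"stereochemistry"}),
    "flip_double_bond_geometry": frozenset({"stereochemistry"}),
    "drop_stereo": frozenset({"stereochemistry"}),
    "permute_atoms": frozenset(),
}

_ATOMIC_WEIGHT = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Br": 79.904,
}
_MONOISOTOPIC = {
    "H": 1.00783, "C": 12.0, "N": 14.00307, "O": 15.99491, "F": 18.99840,
    "Na": 22.98977, "P": 30.97376, "S": 31.97207, "Cl": 34.96885,
    "K": 38.96371, "Br": 78.91834,
}


class InapplicablePerturbation(ValueError):
    """The requested perturbation kind does not apply to this molecule."""


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    seed: int = 0
    expected_layers: frozenset[str] = frozenset()
    expected_categories: frozenset[str] = frozenset()


@dataclass
class PerturbedEntry:
    structure: Molecule
    deposited_inchi: str
    truth: PerturbationSpec


def _make_molecule(cid: str, atoms: list[tuple], bonds: list[tuple[int, int, int]]) -> Molecule:
    return Molecule(
        cid=cid,
        atoms=[
            Atom(element=el, formal_charge=q, x=x, y=y, z=z, index=i + 1)
            for i, (el, q, x, y, z) in enumerate(atoms)
        ],
        bonds=[Bond(a1=a, a2=b, order=o) for a, b, o in bonds],
        is_3d=True,
        name=cid,
    )


def builtin_molecules() -> dict[str, Molecule]:
    """Fresh copies of the named builtin structures (explicit H, 3D coords)."""
    return {
        name: _make_molecule(f"FIX_{name}", atoms, bonds)
        for name, (atoms, bonds) in _BUILTINS.items()
    }


# -- structural edits (operate on mutable (atoms, bonds) views) -------------


def _views(mol: Molecule) -> tuple[list[list], list[list[int]]]:
    atoms = [[a.element, a.formal_charge, a.isotope, a.x, a.y, a.z] for a in mol.atoms]
    bonds = [[b.a1, b.a2, b.order] for b in mol.bonds]
    return atoms, bonds


def _from_views(cid: str, atoms: list[list], bonds: list[list[int]]) -> Molecule:
    return Molecule(
        cid=cid,
        atoms=[
            Atom(element=el, formal_charge=q, isotope=iso, x=x, y=y, z=z, index=i + 1)
            for i, (el, q, iso, x, y, z) in enumerate(atoms)
        ],
        bonds=[Bond(a1=a, a2=b, order=o) for a, b, o in bonds],
        is_3d=True,
        name=cid,
    )


def _neighbors(bonds: list[list[int]], idx: int) -> list[int]:
    out = []
    for a, b, _ in bonds:
        if a == idx:
            out.append(b)
        elif b == idx:
            out.append(a)
    return out


def _protonate(mol: Molecule) -> Molecule:
    atoms, bonds = _views(mol)
    site = next(
        (i for i, a in enumerate(atoms, 1) if a[0] == "N" and a[1] == 0), None
    )
    if site is None:
        raise InapplicablePerturbation("protonate needs a neutral nitrogen")
    nbrs = _neighbors(bonds, site)
    sx, sy, sz = atoms[site - 1][3:6]
    cx = sum(atoms[j - 1][3] for j in nbrs) / len(nbrs)
    cy = sum(atoms[j - 1][4] for j in nbrs) / len(nbrs)
    cz = sum(atoms[j - 1][5] for j in nbrs) / len(nbrs)
    dx, dy, dz = sx - cx, sy - cy, sz - cz
    norm = math.sqrt(dx * dx + dy * dy + dz * dz) or 1.0
    atoms[site - 1][1] = +1
    atoms.append(["H", 0, None, sx + dx / norm, sy + dy / norm, sz + dz / norm])
    bonds.append([site, len(atoms), 1])
    return _from_views(mol.cid, atoms, bonds)


def _deprotonate(mol: Molecule) -> Molecule:
    atoms, bonds = _views(mol)
    target = None
    for a, b, order in bonds:
        i, j = (a, b) if atoms[a - 1][0] == "O" else (b, a)
        if atoms[i - 1][0] == "O" and atoms[j - 1][0] == "H" and atoms[i - 1][1] == 0:
            target = (i, j)
            break
    if target is None:
        raise InapplicablePerturbation("deprotonate needs a neutral O-H group")
    o_idx, h_idx = target
    atoms[o_idx - 1][1] = -1
    del atoms[h_idx - 1]

    def shift(k: int) -> int:
        return k - 1 if k > h_idx else k

    bonds = [
        [shift(a), shift(b), o] for a, b, o in bonds if h_idx not in (a, b)
    ]
    return _from_views(mol.cid, atoms, bonds)


def _neutralize_counter_ion(mol: Molecule) -> Molecule:
    atoms, bonds = _views(mol)
    bonded = {k for a, b, _ in bonds for k in (a, b)}
    site = next(
        (i for i, a in enumerate(atoms, 1) if a[1] == +1 and i not in bonded), None
    )
    if site is None:
        raise InapplicablePerturbation(
            "set_formal_charge needs an unbonded +1 counter-ion"
        )
    atoms[site - 1][1] = 0
    return _from_views(mol.cid, atoms, bonds)


def _rewire_bond(mol: Molecule) -> Molecule:
    atoms, bonds = _views(mol)
    o_site = None
    for i, a in enumerate(atoms, 1):
        if a[0] != "O":
            continue
        nbrs = _neighbors(bonds, i)
        cs = [j for j in nbrs if atoms[j - 1][0] == "C"]
        if len(cs) == 1:
            o_site = (i, cs[0])
            break
    if o_site is None:
        raise InapplicablePerturbation("rewire_bond needs a C-O(H) group")
    o_idx, c_old = o_site
    o_nbrs = set(_neighbors(bonds, o_idx))
    candidates = []
    for j, a in enumerate(atoms, 1):
        if a[0] != "C" or j == c_old or j in o_nbrs:
            continue
        hs = [k for k in _neighbors(bonds, j) if atoms[k - 1][0] == "H"]
        if hs:
            candidates.append((j, hs[0]))
    original = labeling.generate_inchi(mol).inchi
    for c_new, h_moved in candidates:
        new_bonds = [list(b) for b in bonds]
        for bond in new_bonds:
            a, b, _ = bond
            if {a, b} == {o_idx, c_old}:
                bond[0], bond[1] = o_idx, c_new
            elif {a, b} == {c_new, h_moved}:
                bond[0], bond[1] = c_old, h_moved
        # swap coordinates so the moved groups sit near their new attachment
        new_atoms = [list(a) for a in atoms]
        new_atoms[o_idx - 1][3:6], new_atoms[h_moved - 1][3:6] = (
            atoms[h_moved - 1][3:6],
            atoms[o_idx - 1][3:6],
        )
        out = _from_views(mol.cid, new_atoms, new_bonds)
        # a symmetric swap (terminal→terminal) can rebuild the same molecule
        if labeling.generate_inchi(out).inchi != original:
            return out
    raise InapplicablePerturbation("rewire_bond found no constitution-changing move")


def _mirror(mol: Molecule) -> Molecule:
    atoms, bonds = _views(mol)
    for a in atoms:
        a[3] = -a[3]
    return _from_views(mol.cid, atoms, bonds)


def _flip_double_bond(mol: Molecule) -> Molecule:
    atoms, bonds = _views(mol)
    for a, b, order in bonds:
        if order != 2 or atoms[a - 1][0] != "C" or atoms[b - 1][0] != "C":
            continue
        for end, other in ((a, b), (b, a)):
            subs = [j for j in _neighbors(bonds, end) if j != other]
            if len(subs) == 2:
                s1, s2 = subs
                atoms[s1 - 1][3:6], atoms[s2 - 1][3:6] = (
                    atoms[s2 - 1][3:6],
                    atoms[s1 - 1][3:6],
                )
                return _from_views(mol.cid, atoms, bonds)
    raise InapplicablePerturbation(
        "flip_double_bond_geometry needs a C=C bond with two substituents on one end"
    )


def _permute(mol: Molecule, rng: random.Random) -> Molecule:
    n = mol.n_atoms
    perm = list(range(1, n + 1))
    rng.shuffle(perm)  # perm[new_pos-1] = old index
    old_to_new = {old: new for new, old in enumerate(perm, start=1)}
    atoms, bonds = _views(mol)
    new_atoms = [atoms[old - 1] for old in perm]
    new_bonds = [[old_to_new[a], old_to_new[b], o] for a, b, o in bonds]
    return _from_views(mol.cid, new_atoms, new_bonds)


def perturb(mol: Molecule, spec: PerturbationSpec, builtin_name: str | None = None) -> PerturbedEntry:
    """Apply one perturbation; return the audited structure, the deposited
    InChI string, and the ground-truth expectation.

    Structure-side kinds return the modified structure with the *original*
    molecule's InChI deposited; ``drop_stereo`` keeps the structure and
    deposits a stereo-stripped string; ``permute_atoms`` must never flag.
    Inapplicable kinds raise :class:`InapplicablePerturbation`.
    """
    if spec.kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind {spec.kind!r}")
    rng = random.Random(spec.seed)
    original_inchi = labeling.generate_inchi(mol).inchi

    if spec.kind == "protonate":
        structure, deposited = _protonate(mol), original_inchi
    elif spec.kind == "deprotonate":
        structure, deposited = _deprotonate(mol), original_inchi
    elif spec.kind == "set_formal_charge":
        structure, deposited = _neutralize_counter_ion(mol), original_inchi
    elif spec.kind == "rewire_bond":
        structure, deposited = _rewire_bond(mol), original_inchi
    elif spec.kind == "invert_chiral_center":
        structure, deposited = _mirror(mol), original_inchi
    elif spec.kind == "flip_double_bond_geometry":
        structure, deposited = _flip_double_bond(mol), original_inchi
    elif spec.kind == "drop_stereo":
        stripped = labeling.generate_inchi(mol, ignore_stereo=True).inchi
        if stripped == original_inchi:
            raise InapplicablePerturbation("molecule carries no stereo layers to drop")
        structure, deposited = mol, stripped
    else:  # permute_atoms
        structure, deposited = _permute(mol, rng), original_inchi

    if spec.kind not in ("permute_atoms", "drop_stereo"):
        if labeling.generate_inchi(structure).inchi == original_inchi:
            raise InapplicablePerturbation(
                f"{spec.kind} left the canonical identifier unchanged"
            )

    name = builtin_name or (mol.cid[4:] if mol.cid.startswith("FIX_") else mol.cid)
    expected_layers = _EXPECTED_LAYERS[spec.kind].get(name)
    if expected_layers is None:
        # not a catalogued pairing: derive presence-difference for stereo drops,
        # otherwise leave the catalogue gap loud
        if spec.kind == "drop_stereo":
            have = L.parse_inchi(original_inchi)
            lost = {
                x
                for x in ("b", "t", "m", "s")
                if getattr(have, f"{x}_layer") and not getattr(L.parse_inchi(deposited), f"{x}_layer")
            }
            expected_layers = frozenset(lost)
        else:
            raise InapplicablePerturbation(
                f"{spec.kind} has no ground-truth catalogue entry for {name!r}"
            )
    truth = replace(
        spec,
        expected_layers=frozenset(expected_layers),
        expected_categories=_CATEGORY_OF_KIND[spec.kind],
    )
    return PerturbedEntry(structure=structure, deposited_inchi=deposited, truth=truth)


def applicable_pairs() -> list[tuple[str, str]]:
    """(builtin name, kind) pairs that inject a discrepancy, stable order."""
    pairs = []
    for kind in PERTURBATION_KINDS:
        if kind == "permute_atoms":
            continue
        pairs.extend((name, kind) for name in sorted(_EXPECTED_LAYERS[kind]))
    return pairs


def make_corpus(
    n: int,
    seed: int,
    discrepancy_rate: float,
    out_dir: str | Path,
    records_per_file: int = 25,
) -> dict:
    """Write an n-entry SDF corpus with ``⌊rate·n⌋`` injected discrepancies.

    Each record carries PubChem-style property items (CID, deposited InChI,
    formula, weight, exact mass, synonyms) plus a truth CSV with the expected
    differing layers and categories per entry. Byte-reproducible under seed.
    """
    if not 0 <= discrepancy_rate <= 1:
        raise ValueError("discrepancy_rate must be within [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    builtins = builtin_molecules()
    pairs = applicable_pairs()
    clean_names = sorted(_BUILTINS)
    n_perturbed = int(discrepancy_rate * n)
    perturbed_idx = set(rng.sample(range(n), n_perturbed)) if n else set()

    truth_rows = []
    records = []
    for i in range(n):
        cid = str(90000001 + i)
        entry_seed = rng.randrange(2**31)
        if i in perturbed_idx:
            name, kind = pairs[rng.randrange(len(pairs))]
        else:
            name = clean_names[rng.randrange(len(clean_names))]
            kind = "permute_atoms"
        base = builtins[name]
        base = Molecule(
            cid=cid, atoms=base.atoms, bonds=base.bonds, is_3d=True, name=cid
        )
        entry = perturb(base, PerturbationSpec(kind=kind, seed=entry_seed), builtin_name=name)
        structure = entry.structure
        derived = L.parse_inchi(labeling.generate_inchi(structure).inchi)
        species = L.charged_species_formula(derived)
        weight = sum(
            _ATOMIC_WEIGHT[a.element] for a in structure.atoms
        )
        mass = sum(_MONOISOTOPIC[a.element] for a in structure.atoms)
        props = {
            "PUBCHEM_COMPOUND_CID": cid,
            "PUBCHEM_IUPAC_INCHI": entry.deposited_inchi,
            "PUBCHEM_MOLECULAR_FORMULA": species.text,
            "PUBCHEM_MOLECULAR_WEIGHT": f"{weight:.3f}",
            "PUBCHEM_EXACT_MASS": f"{mass:.5f}",
            "SYNONYMS": f"{name};{name} (synthetic)",
        }
        records.append(write_sdf(structure, properties=props))
        truth_rows.append(
            {
                "cid": cid,
                "molecule": name,
                "kind": kind,
                "expected_layers": "|".join(sorted(entry.truth.expected_layers)),
                "expected_categories": "|".join(sorted(entry.truth.expected_categories)),
            }
        )

    files = []
    n_files = (len(records) + records_per_file - 1) // records_per_file
    for k in range(n_files):
        path = out_dir / f"corpus_{k:03d}.sdf"
        chunk = records[k * records_per_file : (k + 1) * records_per_file]
        path.write_text("".join(chunk))
        files.append(str(path))

    truth_path = out_dir / "truth.csv"
    buf = io.StringIO()
    writer = csv.DictWriter(
        buf,
        fieldnames=["cid", "molecule", "kind", "expected_layers", "expected_categories"],
        lineterminator="\n",
    )
    writer.writeheader()
    writer.writerows(truth_rows)
    truth_path.write_text(buf.getvalue())
    return {
        "n": n,
        "n_perturbed": n_perturbed,
        "files": files,
        "truth": str(truth_path),
    }
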