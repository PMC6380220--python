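"""Toolkit-neutral molecule model and structure-file I/O.

Reads multi-record SDF V2000 (transparently gunzipped), writes SDF, XYZ and
PDB. The I/O layer is deliberately lossless: no valence model, no implicit
hydrogens, no aromatic perception — the structure file is taken at face
value and everything chemical is delegated downstream.
"""

from __future__ import annotations

import gzip
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "SdfError",
    "SdfRecordError",
    "LabelCoverageError",
    "read_sdf",
    "write_sdf",
    "write_labeled_sdf",
    "write_xyz",
    "write_pdb",
    "atom_counts",
]

# IUPAC element symbols (118 elements + D/T aliases are not accepted here;
# deuterium is expressed as H with an isotope mass number).
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

# V2000 legacy atom-block charge column codes (superseded by M  CHG lines).
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    isotope: int | None = None
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    index: int = 0  # 1-based position in the source record


@dataclass(frozen=True)
class Bond:
    a1: int  # 1-based atom indices
    a2: int
    order: int = 1
    stereo_mark: int = 0  # raw wedge/hash flag from the bond block


@dataclass
class Molecule:
    cid: str = ""
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)
    is_3d: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if b.a1 == b.a2 or not (1 <= b.a1 <= n and 1 <= b.a2 <= n):
                raise ValueError(f"bond ({b.a1},{b.a2}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


class SdfRecordError(ValueError):
    """Raised internally while parsing a single record."""

    def __init__(self, message: str, code: str = "malformed"):
        super().__init__(message)
        self.code = code


@dataclass
class SdfError:
    """Per-record parse failure; the surrounding stream keeps going."""

    record_index: int
    message: str
    code: str
    raw_text: str = ""


class LabelCoverageError(ValueError):
    """A label map does not cover every atom of the molecule."""


Source = Union[str, Path, bytes, io.IOBase]


def _read_text(source: Source) -> str:
    if isinstance(source, Path):
        data = source.read_bytes()
    elif isinstance(source, str):
        # a newline-free string is a path if it names one, else raw content
        if "\n" not in source and source and Path(source).is_file():
            data = Path(source).read_bytes()
        else:
            return source
    elif isinstance(source, bytes):
        data = source
    else:  # file-like
        data = source.read()
        if isinstance(data, str):
            return data
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode("utf-8", errors="replace")


def _parse_record(lines: list[str], record_index: int) -> Molecule:
    if len(lines) < 4:
        raise SdfRecordError("truncated record: missing header/counts line", "truncated")
    name = lines[0].strip()
    dim_field = lines[1][20:22] if len(lines[1]) >= 22 else ""
    counts = lines[3]
    version = counts[33:39].strip() if len(counts) >= 35 else ""
    if version.upper() == "V3000":
        raise SdfRecordError("V3000 records are not supported", "v3000-unsupported")
    if version.upper() != "V2000":
        raise SdfRecordError(f"missing/unknown version tag {version!r}", "bad-version")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise SdfRecordError(f"malformed counts line {counts!r}", "bad-counts") from exc
    if n_atoms < 0 or n_bonds < 0:
        raise SdfRecordError("negative counts", "bad-counts")
    if len(lines) < 4 + n_atoms + n_bonds:
        raise SdfRecordError("truncated record: atom/bond block short", "truncated")

    atoms: list[Atom] = []
    legacy_charges: dict[int, int] = {}
    for i in range(n_atoms):
        ln = lines[4 + i]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            element = ln[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise SdfRecordError(f"malformed atom line {i + 1}: {ln!r}", "bad-atom") from exc
        if element not in ELEMENTS:
            raise SdfRecordError(f"unknown element {element!r} on atom line {i + 1}", "bad-atom")
        code = ln[36:39].strip()
        if code and code.isdigit() and int(code) in _CHARGE_CODES:
            legacy_charges[i + 1] = _CHARGE_CODES[int(code)]
        atoms.append(Atom(element=element, x=x, y=y, z=z, index=i + 1))

    bonds: list[Bond] = []
    for i in range(n_bonds):
        ln = lines[4 + n_atoms + i]
        try:
            a1, a2 = int(ln[0:3]), int(ln[3:6])
            order = int(ln[6:9])
            stereo = int(ln[9:12]) if ln[9:12].strip() else 0
        except (ValueError, IndexError) as exc:
            raise SdfRecordError(f"malformed bond line {i + 1}: {ln!r}", "bad-bond") from exc
        if order not in (1, 2, 3):
            raise SdfRecordError(f"unsupported bond order {order}", "bad-bond")
        if a1 == a2 or not (1 <= a1 <= n_atoms and 1 <= a2 <= n_atoms):
            raise SdfRecordError(f"bond indices ({a1},{a2}) out of range", "bad-bond")
        bonds.append(Bond(a1=a1, a2=a2, order=order, stereo_mark=stereo))

    # M-block: CHG/ISO property lines supersede the legacy charge column.
    charges: dict[int, int] = {}
    isotopes: dict[int, int] = {}
    saw_chg = False
    pos = 4 + n_atoms + n_bonds
    while pos < len(lines):
        ln = lines[pos]
        pos += 1
        if ln.startswith("M  END"):
            break
        if ln.startswith("M  CHG") or ln.startswith("M  ISO"):
            try:
                count = int(ln[6:9])
                vals = ln[9:].split()
                pairs = [(int(vals[2 * k]), int(vals[2 * k + 1])) for k in range(count)]
            except (ValueError, IndexError) as exc:
                raise SdfRecordError(f"malformed M line {ln!r}", "bad-mblock") from exc
            target = charges if ln.startswith("M  CHG") else isotopes
            if ln.startswith("M  CHG"):
                saw_chg = True
            for idx, val in pairs:
                if not 1 <= idx <= n_atoms:
                    raise SdfRecordError(f"M line atom index {idx} out of range", "bad-mblock")
                target[idx] = val
    if not saw_chg:
        charges = legacy_charges

    if charges or isotopes:
        atoms = [
            Atom(
                element=a.element,
                formal_charge=charges.get(a.index, 0),
                isotope=isotopes.get(a.index),
                x=a.x,
                y=a.y,
                z=a.z,
                index=a.index,
            )
            for a in atoms
        ]

    properties: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for ln in lines[pos:]:
        m = re.match(r">\s*<([^>]+)>", ln)
        if m:
            if key is not None:
                properties[key] = "\n".join(buf).rstrip("\n")
            key = m.group(1)
            buf = []
        elif key is not None:
            if ln.strip() == "":
                properties[key] = "\n".join(buf).rstrip("\n")
                key = None
                buf = []
            else:
                buf.append(ln.rstrip("\n"))
    if key is not None:
        properties[key] = "\n".join(buf).rstrip("\n")

    is_3d = dim_field == "3D" or any(abs(a.z) > 1e-8 for a in atoms)
    return Molecule(
        cid=name, atoms=atoms, bonds=bonds, properties=properties, is_3d=is_3d, name=name
    )


def read_sdf(source: Source) -> Iterator[Molecule | SdfError]:
    """Parse a multi-record SDF stream, yielding molecules and per-record errors.

    ``source`` may be a path, raw text, bytes (gzip detected by magic number),
    or a file-like object. Record order is preserved; a malformed record
    yields an :class:`SdfError` and parsing continues with the next one.
    """
    text = _read_text(source)
    lines = text.split("\n")
    record: list[str] = []
    index = 0
    for ln in lines:
        if ln.strip() == "$$$$":
            yield _finish_record(record, index)
            index += 1
            record = []
        else:
            record.append(ln)
    if any(ln.strip() for ln in record):
        yield _finish_record(record, index)


def _finish_record(record: list[str], index: int) -> Molecule | SdfError:
    try:
        return _parse_record(record, index)
    except SdfRecordError as exc:
        return SdfError(
            record_index=index, message=str(exc), code=exc.code, raw_text="\n".join(record)
        )


# ---------------------------------------------------------------------------
# writers


def _sdf_body(mol: Molecule, atoms: list[Atom], bonds: list[Bond], title: str) -> list[str]:
    out = [title, "  struaudt          " + ("3D" if mol.is_3d else "2D"), ""]
    out.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in atoms:
        out.append(f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in bonds:
        out.append(f"{b.a1:3d}{b.a2:3d}{b.order:3d}{b.stereo_mark:3d}")
    charged = [(i + 1, a.formal_charge) for i, a in enumerate(atoms) if a.formal_charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k : k + 8]
        out.append("M  CHG%3d" % len(chunk) + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    iso = [(i + 1, a.isotope) for i, a in enumerate(atoms) if a.isotope]
    for k in range(0, len(iso), 8):
        chunk = iso[k : k + 8]
        out.append("M  ISO%3d" % len(chunk) + "".join(f"{i:4d}{m:4d}" for i, m in chunk))
    out.append("M  END")
    return out


def write_sdf(mol: Molecule, properties: dict[str, str] | None = None) -> str:
    """Serialize one molecule as a V2000 record in its stored atom order."""
    if not mol.atoms:
        raise ValueError("cannot write an empty molecule")
    out = _sdf_body(mol, mol.atoms, mol.bonds, mol.cid or mol.name)
    props = dict(mol.properties)
    if properties:
        props.update(properties)
    for key, value in props.items():
        out.append(f"> <{key}>")
        out.append(value)
        out.append("")
    out.append("$$$$")
    return "\n".join(out) + "\n"


def _ordered_atoms(mol: Molecule, labels) -> tuple[list[Atom], list[Bond], list[str]]:
    missing = [a.index for a in mol.atoms if a.index not in labels.entries]
    if missing:
        raise LabelCoverageError(f"label map missing atoms {missing}")
    order = list(labels.order)
    if sorted(order) != sorted(a.index for a in mol.atoms):
        raise LabelCoverageError("label order is not a permutation of the atom indices")
    by_index = {a.index: a for a in mol.atoms}
    new_pos = {orig: i + 1 for i, orig in enumerate(order)}
    atoms = [by_index[orig] for orig in order]
    bonds = sorted(
        (
            Bond(
                a1=min(new_pos[b.a1], new_pos[b.a2]),
                a2=max(new_pos[b.a1], new_pos[b.a2]),
                order=b.order,
                stereo_mark=0,
            )
            for b in mol.bonds
        ),
        key=lambda b: (b.a1, b.a2),
    )
    ordered_labels = [labels.entries[orig] for orig in order]
    return atoms, bonds, ordered_labels


def write_labeled_sdf(mol: Molecule, labels) -> str:
    """V2000 record with atoms reordered canonically per the label map.

    The ``ATOM_LABELS`` data item carries the per-atom labels in file order,
    so two permutations of the same structure serialize byte-identically;
    the original-index→label map is the label map's own CSV artifact.
    """
    if not mol.atoms:
        raise ValueError("cannot write an empty molecule")
    atoms, bonds, ordered_labels = _ordered_atoms(mol, labels)
    out = _sdf_body(
        Molecule(cid=mol.cid, atoms=mol.atoms, bonds=[], is_3d=mol.is_3d),
        atoms,
        bonds,
        mol.cid or mol.name,
    )
    out.append("> <ATOM_LABELS>")
    out.append(",".join(ordered_labels))
    out.append("")
    out.append("$$$$")
    return "\n".join(out) + "\n"


def write_xyz(mol: Molecule, labels) -> str:
    """Standard XYZ text; the atom label rides in a trailing comment column."""
    if not mol.atoms:
        raise ValueError("cannot write an empty molecule")
    atoms, _, ordered_labels = _ordered_atoms(mol, labels)
    out = [str(len(atoms)), mol.cid or mol.name]
    for a, lab in zip(atoms, ordered_labels):
        out.append(f"{a.element:<3s}{a.x:12.4f}{a.y:12.4f}{a.z:12.4f}  # {lab}")
    return "\n".join(out) + "\n"


def write_pdb(mol: Molecule, labels) -> str:
    """HETATM-style PDB text with the label in the atom-name field."""
    if not mol.atoms:
        raise ValueError("cannot write an empty molecule")
    atoms, _, ordered_labels = _ordered_atoms(mol, labels)
    out = []
    for i, (a, lab) in enumerate(zip(atoms, ordered_labels), start=1):
        name = lab[:4]
        out.append(
            f"HETATM{i:5d} {name:<4s} LIG A   1    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    out.append("END")
    return "\n".join(out) + "\n"


def atom_counts(mol: Molecule) -> dict[str, int]:
    """Explicit atom counts by element (no implicit-hydrogen synthesis)."""
    return dict(Counter(a.element for a in mol.atoms))
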