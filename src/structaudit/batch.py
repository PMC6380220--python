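"""Desk-scale batch workflow: shard, dedupe, audit, and emit flat-file tables.

The relational layout is mirrored as three CSVs (outputs / meta_data / names)
plus a discrepancy table and per-layer / per-category flagged-CID lists.
Every output file is rewritten from a cid-sorted record map on each run, so
results are byte-identical regardless of worker count, shard assignment, or
resumption — and no timestamps are ever written.
"""

from __future__ import annotations

import csv
import io
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import consistency, labeling
from . import layers as L
from .consistency import CATEGORY_MAP
from .mol import Molecule, SdfError, read_sdf, write_labeled_sdf, write_pdb, write_sdf, write_xyz

__all__ = [
    "BatchConfig",
    "EntryRecord",
    "MetadataRecord",
    "plan_shards",
    "dedupe_obsolete",
    "run_batch",
]

OUTPUT_COLUMNS = [
    "cid",
    "input_structure",
    "sdf_out",
    "pdb_out",
    "xyz_out",
    "inchi",
    "derived_formula",
    "warnings",
    "errors",
    "atom_map",
    "multi_compound_map",
]
META_COLUMNS = ["cid", "formula", "molecular_weight", "exact_mass"]
NAME_COLUMNS = ["cid", "first_synonym", "synonym_count"]
DISCREPANCY_COLUMNS = [
    "cid",
    "differing_layers",
    "categories",
    "ambiguous_stereo",
    "non_standard_deposited",
    "notes",
]
LAYERS = ["formula", "c", "h", "q", "p", "b", "t", "m", "s", "i"]
CATEGORIES = sorted(set(CATEGORY_MAP.values()))


@dataclass(frozen=True)
class BatchConfig:
    workers: int = 1
    chunk_size: int = 18
    cid_key: str = "PUBCHEM_COMPOUND_CID"
    inchi_key: str = "PUBCHEM_IUPAC_INCHI"
    formula_key: str = "PUBCHEM_MOLECULAR_FORMULA"
    weight_key: str = "PUBCHEM_MOLECULAR_WEIGHT"
    mass_key: str = "PUBCHEM_EXACT_MASS"
    synonyms_key: str = "SYNONYMS"
    seed: int = 0


@dataclass
class EntryRecord:
    """The per-compound 11-field output bundle."""

    cid: str
    input_structure: str = ""
    sdf_out: str = ""
    pdb_out: str = ""
    xyz_out: str = ""
    inchi: str = ""
    derived_formula: str = ""
    warnings: str = ""
    errors: str = ""
    atom_map: str = ""
    multi_compound_map: str = ""


@dataclass
class MetadataRecord:
    cid: str
    formula: str = ""
    molecular_weight: str = ""
    exact_mass: str = ""


def plan_shards(files: list, workers: int, chunk_size: int = 18) -> dict[int, list]:
    """Deterministic round-robin of fixed-size chunks over worker slots."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    assignment: dict[int, list] = {w: [] for w in range(workers)}
    for i in range(0, len(files), chunk_size):
        assignment[(i // chunk_size) % workers].extend(files[i : i + chunk_size])
    return assignment


def dedupe_obsolete(records):
    """Last occurrence per cid wins; earlier ones are superseded, not processed.

    ``records`` is an ordered iterable of ``(cid, payload)``. Returns
    ``(survivors, superseded)`` where survivors is a cid→payload map and
    superseded a list of (cid, position) for the obsoleted occurrences.
    """
    last: dict[str, int] = {}
    items = list(records)
    for pos, (cid, _) in enumerate(items):
        last[cid] = pos
    survivors: dict[str, object] = {}
    superseded: list[tuple[str, int]] = []
    for pos, (cid, payload) in enumerate(items):
        if pos == last[cid]:
            survivors[cid] = payload
        else:
            superseded.append((cid, pos))
    return survivors, superseded


def _cid_sort_key(cid: str):
    return (0, int(cid), "") if cid.isdigit() else (1, 0, cid)


def _process_molecule(mol: Molecule, cfg: BatchConfig) -> dict:
    """Audit a single entry; returns the output/meta/name/discrepancy rows."""
    props = mol.properties
    cid = props.get(cfg.cid_key, "").strip() or mol.cid or mol.name
    mol.cid = cid
    entry = EntryRecord(cid=cid, input_structure=write_sdf(mol))
    report_row = {c: "" for c in DISCREPANCY_COLUMNS}
    report_row["cid"] = cid
    try:
        res = labeling.generate_inchi(mol)
        labels = labeling.make_label_map(mol, res)
        derived = L.parse_inchi(res.inchi)
        entry.inchi = res.inchi
        entry.derived_formula = L.charged_species_formula(derived).text
        entry.sdf_out = write_labeled_sdf(mol, labels)
        entry.pdb_out = write_pdb(mol, labels)
        entry.xyz_out = write_xyz(mol, labels)
        entry.atom_map = labels.to_csv()
        if derived.n_components > 1:
            entry.multi_compound_map = labels.component_csv()
        entry.warnings = "; ".join(
            w for w in [res.warnings, *labels.warnings] if w
        )
        report = consistency.check_entry(
            mol,
            deposited_inchi=props.get(cfg.inchi_key, ""),
            deposited_formula=props.get(cfg.formula_key, ""),
            derived_inchi=res.inchi,
        )
        report_row = report.to_row()
    except (labeling.InChIGenerationError, L.InChIError, ValueError) as exc:
        entry.errors = str(exc)
        report_row["notes"] = f"entry errored: {exc}"

    synonyms = [s for s in props.get(cfg.synonyms_key, "").split(";") if s.strip()]
    return {
        "output": asdict(entry),
        "meta": {
            "cid": cid,
            "formula": props.get(cfg.formula_key, ""),
            "molecular_weight": props.get(cfg.weight_key, ""),
            "exact_mass": props.get(cfg.mass_key, ""),
        },
        "name": {
            "cid": cid,
            "first_synonym": synonyms[0].strip() if synonyms else "",
            "synonym_count": str(len(synonyms)),
        },
        "discrepancy": report_row,
    }


def _process_chunk(mols: list[Molecule], cfg: BatchConfig) -> list[dict]:
    return [_process_molecule(m, cfg) for m in mols]


def _write_csv(path: Path, columns: list[str], rows: list[dict]) -> None:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=columns, lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    path.write_text(buf.getvalue())


def _read_csv(path: Path) -> list[dict]:
    if not path.exists():
        return []
    with path.open(newline="") as fh:
        return list(csv.DictReader(fh))


def run_batch(input_dir: str | Path, output_dir: str | Path, config: BatchConfig | None = None) -> dict:
    """Audit every entry in a directory of .sdf / .sdf.gz files.

    Resumable: cids already present in ``output_dir``'s tables are reused, not
    reprocessed. All tables and flagged lists are rewritten cid-sorted, so a
    rerun over a completed directory is byte-identical.
    """
    cfg = config or BatchConfig()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    files = sorted(
        p for p in input_dir.iterdir()
        if p.name.endswith(".sdf") or p.name.endswith(".sdf.gz")
    ) if input_dir.exists() else []
    shards = plan_shards(files, cfg.workers, cfg.chunk_size)

    parse_errors: list[dict] = []
    ordered: list[tuple[str, Molecule]] = []
    skipped_2d: list[str] = []
    for worker in sorted(shards):
        for path in shards[worker]:
            try:
                parsed = list(read_sdf(path))
            except OSError as exc:
                parse_errors.append(
                    {"source": path.name, "record_index": "", "code": "unreadable",
                     "message": str(exc)}
                )
                continue
            for item in parsed:
                if isinstance(item, SdfError):
                    parse_errors.append(
                        {"source": path.name, "record_index": str(item.record_index),
                         "code": item.code, "message": item.message}
                    )
                    continue
                cid = item.properties.get(cfg.cid_key, "").strip() or item.cid or item.name
                if not cid:
                    parse_errors.append(
                        {"source": path.name, "record_index": "", "code": "missing-cid",
                         "message": "record has no compound identifier"}
                    )
                    continue
                item.cid = cid
                ordered.append((cid, item))

    survivors, superseded = dedupe_obsolete(ordered)

    processable: dict[str, Molecule] = {}
    for cid, mol in survivors.items():
        if mol.is_3d:
            processable[cid] = mol
        else:
            skipped_2d.append(cid)

    # resume support: reuse completed rows keyed by cid
    prior = {
        "output": {r["cid"]: r for r in _read_csv(output_dir / "outputs.csv")},
        "meta": {r["cid"]: r for r in _read_csv(output_dir / "meta_data.csv")},
        "name": {r["cid"]: r for r in _read_csv(output_dir / "names.csv")},
        "discrepancy": {r["cid"]: r for r in _read_csv(output_dir / "discrepancies.csv")},
    }
    done = set(prior["output"]) & set(prior["discrepancy"])
    todo = [cid for cid in processable if cid not in done]
    todo.sort(key=_cid_sort_key)

    results: dict[str, dict] = {}
    if cfg.workers > 1 and len(todo) > 1:
        chunks = plan_shards(todo, cfg.workers, max(1, len(todo) // cfg.workers + 1))
        with ProcessPoolExecutor(max_workers=cfg.workers) as pool:
            futures = [
                pool.submit(_process_chunk, [processable[c] for c in chunks[w]], cfg)
                for w in sorted(chunks)
                if chunks[w]
            ]
            for fut in futures:
                for res in fut.result():
                    results[res["output"]["cid"]] = res
    else:
        for cid in todo:
            res = _process_molecule(processable[cid], cfg)
            results[res["output"]["cid"]] = res

    all_cids = sorted(set(done) | set(results), key=_cid_sort_key)

    def row(kind: str, cid: str) -> dict:
        return results[cid][kind] if cid in results else prior[kind].get(cid, {"cid": cid})

    _write_csv(output_dir / "outputs.csv", OUTPUT_COLUMNS, [row("output", c) for c in all_cids])
    _write_csv(output_dir / "meta_data.csv", META_COLUMNS, [row("meta", c) for c in all_cids])
    _write_csv(output_dir / "names.csv", NAME_COLUMNS, [row("name", c) for c in all_cids])
    disc_rows = [row("discrepancy", c) for c in all_cids]
    _write_csv(output_dir / "discrepancies.csv", DISCREPANCY_COLUMNS, disc_rows)

    per_layer = {name: [] for name in LAYERS}
    per_category = {name: [] for name in CATEGORIES}
    for r in disc_rows:
        for layer in filter(None, (r.get("differing_layers") or "").split("|")):
            per_layer[layer].append(r["cid"])
        for cat in filter(None, (r.get("categories") or "").split("|")):
            per_category[cat].append(r["cid"])
    for name, cids in per_layer.items():
        (output_dir / f"flagged_layer_{name}.txt").write_text(
            "".join(f"{c}\n" for c in cids)
        )
    for name, cids in per_category.items():
        (output_dir / f"flagged_category_{name}.txt").write_text(
            "".join(f"{c}\n" for c in cids)
        )

    (output_dir / "superseded.txt").write_text(
        "".join(f"{cid}\t{pos}\n" for cid, pos in superseded)
    )
    (output_dir / "skipped_2d_only.txt").write_text(
        "".join(f"{c}\n" for c in sorted(skipped_2d, key=_cid_sort_key))
    )
    _write_csv(
        output_dir / "errors.csv",
        ["source", "record_index", "code", "message"],
        parse_errors,
    )

    errored = sum(1 for c in all_cids if (row("output", c).get("errors") or "").strip())
    flagged = sorted(
        {c for cids in per_category.values() for c in cids}, key=_cid_sort_key
    )
    # the persisted summary carries only run-independent facts, so a resumed
    # or re-sharded rerun stays byte-identical
    persisted = {
        "entries_processed": len(all_cids),
        "errored": errored,
        "parse_errors": len(parse_errors),
        "skipped_2d_only": len(skipped_2d),
        "superseded": len(superseded),
        "flagged_total": len(flagged),
        "flagged_per_category": {k: len(v) for k, v in per_category.items()},
        "flagged_per_layer": {k: len(v) for k, v in per_layer.items()},
        "delegate": labeling.delegate_version(),
        "seed": cfg.seed,
    }
    (output_dir / "summary.json").write_text(
        json.dumps(persisted, indent=2, sort_keys=True) + "\n"
    )
    log_lines = [
        f"delegate={labeling.delegate_version()}",
        f"seed={cfg.seed}",
        f"input_files={len(files)}",
        f"entries={len(all_cids)}",
        f"flagged={len(flagged)} errored={errored} skipped_2d={len(skipped_2d)} superseded={len(superseded)}",
    ]
    (output_dir / "run.log").write_text("".join(f"{ln}\n" for ln in log_lines))
    return {**persisted, "new_entries": len(results),
            "reused_entries": len(all_cids) - len(results), "workers": cfg.workers}
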