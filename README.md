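# structaudit

Structure-vs-identifier consistency auditing for small-molecule SDF archives.

Given 3D structure records (SDF V2000, optionally gzipped) that carry a
deposited InChI string and molecular formula, `structaudit`:

1. generates the standard InChI and AuxInfo for each structure by delegating
   to the IUPAC InChI library bundled with RDKit (the canonicalization
   algorithm is never reimplemented; the delegate version is stamped into
   every output),
2. derives unique, reproducible per-atom labels from the AuxInfo canonical
   numbering (heavy atoms: element + canonical number, e.g. `C7`; hydrogens:
   `H7`, or `H7a`/`H7b`… ordered geometrically; exchangeable canonical
   positions are tie-broken by coordinates so labels are invariant under
   input atom permutation),
3. diffs the derived InChI against the deposited one layer by layer
   (formula, `/c`, `/h`, `/q`, `/p`, `/b`, `/t`, `/m`, `/s`, `/i`) and maps
   differing layers to discrepancy categories:
   `/c,/h` → atom connectivity, `/p,/q` → charge, `/b,/t,/m,/s` →
   stereochemistry, `/i` → isotope, plus a formula category,
4. reconciles deposited formula strings (including charged suffix dialects
   such as `C15H17N4O3S+`) against the structure-derived species using the
   core-parent arithmetic `H(species) = H(core) + /p`,
   `charge(species) = /q + /p`, and
5. writes flat-file result tables: an 11-column per-entry outputs CSV
   (labeled SDF/PDB/XYZ, InChI, Hill formula, warnings/errors, atom maps),
   metadata and names CSVs, a discrepancy table, and per-layer /
   per-category flagged-CID lists.

A synthetic-fixture module generates small molecules with frozen 3D
coordinates and seeded, ground-truth-labeled perturbations (protonation
changes, counter-ion charge edits, bond rewiring, chirality inversion,
double-bond geometry flips, stereo dropping, atom permutation) so the whole
pipeline is testable offline.

## CLI

```sh
# audit a directory of .sdf / .sdf.gz files
audit run --input IN_DIR --output OUT_DIR [--workers N] [--chunk-size 18] \
          [--inchi-key PUBCHEM_IUPAC_INCHI] [--formula-key PUBCHEM_MOLECULAR_FORMULA] \
          [--seed S]

# audit a single record (exit code 2 when flagged)
audit check-one FILE.sdf --deposited-inchi 'InChI=1S/...' --deposited-formula 'C2H6O'

# write a synthetic corpus with a truth table
audit fixtures --n 50 --seed 1 --rate 0.2 --out CORPUS_DIR
```

`audit run` is resumable (already-audited CIDs are reused) and its outputs
are byte-identical across reruns, worker counts, and shard assignments.
Obsoleted duplicate records (same CID repeated; last occurrence wins) are
logged to `superseded.txt`; 2D-only records are listed in
`skipped_2d_only.txt` and not processed.

## Layout

| module | role |
| --- | --- |
| `structaudit.mol` | SDF V2000 read (gzip-transparent, per-record errors), SDF/XYZ/PDB writers, toolkit-neutral `Molecule` |
| `structaudit.layers` | InChI layer parsing/serialization, Hill formulas, charge arithmetic, formula-string grammar |
| `structaudit.labeling` | InChI/AuxInfo delegation, canonical numbering + equivalence parsing, atom label assignment |
| `structaudit.consistency` | layer diffing, category mapping, formula reconciliation, per-entry reports |
| `structaudit.batch` | sharding, obsoleted-record dedupe, resumable batch runs, CSV/flagged-list emission |
| `structaudit.fixtures` | builtin molecules, seeded perturbations, corpus generator with truth tables |
| `structaudit.examples` | curated real-world discrepancy strings (kept verbatim, typesetting included) |
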