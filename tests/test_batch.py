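import csv
import json
from pathlib import Path

import pytest
from click.testing import CliRunner

from structaudit import cli, fixtures
from structaudit.batch import BatchConfig, dedupe_obsolete, plan_shards, run_batch
from structaudit.mol import write_sdf


class TestPlanShards:
    def test_paper_chunking_constant(self):
        files = [f"f{i:02d}" for i in range(36)]
        shards = plan_shards(files, workers=2)
        assert shards[0] == files[:18]
        assert shards[1] == files[18:]

    def test_single_file_many_workers(self):
        shards = plan_shards(["only"], workers=8)
        assert shards[0] == ["only"]
        assert all(not shards[w] for w in range(1, 8))

    def test_multiset_union_preserved(self):
        files = [f"f{i}" for i in range(100)]
        shards = plan_shards(files, workers=7)
        together = [f for w in sorted(shards) for f in shards[w]]
        assert sorted(together) == sorted(files)

    def test_validation(self):
        with pytest.raises(ValueError):
            plan_shards([], workers=0)
        with pytest.raises(ValueError):
            plan_shards([], workers=1, chunk_size=0)


class TestDedupe:
    def test_last_occurrence_wins(self):
        survivors, superseded = dedupe_obsolete(
            [("1", "a"), ("1", "b"), ("1", "c")]
        )
        assert survivors == {"1": "c"}
        assert superseded == [("1", 0), ("1", 1)]

    def test_all_distinct_identity(self):
        survivors, superseded = dedupe_obsolete([("1", "a"), ("2", "b")])
        assert survivors == {"1": "a", "2": "b"}
        assert superseded == []

    def test_interleaved_duplicates_stable(self):
        records = [("1", "a1"), ("2", "b1"), ("1", "a2"), ("2", "b2"), ("1", "a3")]
        survivors, superseded = dedupe_obsolete(records)
        assert survivors == {"1": "a3", "2": "b2"}
        assert len(superseded) == 3


@pytest.fixture(scope="module")
def corpus(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    info = fixtures.make_corpus(n=30, seed=17, discrepancy_rate=0.2, out_dir=out)
    return out, info


class TestRunBatch:
    def test_empty_input_dir(self, tmp_path):
        (tmp_path / "in").mkdir()
        summary = run_batch(tmp_path / "in", tmp_path / "out")
        assert summary["entries_processed"] == 0
        assert summary["flagged_total"] == 0
        assert (tmp_path / "out" / "outputs.csv").exists()

    def test_corpus_recovery_and_conservation(self, corpus, tmp_path):
        corpus_dir, info = corpus
        out = tmp_path / "out"
        summary = run_batch(corpus_dir, out, BatchConfig(seed=17))
        assert summary["entries_processed"] == 30
        assert summary["errored"] == 0

        truth = {r["cid"]: r for r in csv.DictReader(open(info["truth"]))}
        disc = {r["cid"]: r for r in csv.DictReader(open(out / "discrepancies.csv"))}
        for cid, t in truth.items():
            expected = set(filter(None, t["expected_categories"].split("|")))
            got = set(filter(None, disc[cid]["categories"].split("|")))
            assert got == expected, cid

        # conservation: summary counts equal the flagged-list row counts
        for cat, count in summary["flagged_per_category"].items():
            lines = (out / f"flagged_category_{cat}.txt").read_text().splitlines()
            assert len(lines) == count
        for layer, count in summary["flagged_per_layer"].items():
            lines = (out / f"flagged_layer_{layer}.txt").read_text().splitlines()
            assert len(lines) == count

    def test_rerun_idempotent_and_skipping(self, corpus, tmp_path):
        corpus_dir, _ = corpus
        out = tmp_path / "out"
        run_batch(corpus_dir, out, BatchConfig(seed=17))
        snapshot = {p.name: p.read_bytes() for p in out.iterdir()}
        summary = run_batch(corpus_dir, out, BatchConfig(seed=17))
        assert summary["new_entries"] == 0
        assert summary["reused_entries"] == 30
        for p in out.iterdir():
            assert p.read_bytes() == snapshot[p.name], p.name

    def test_output_independent_of_workers(self, corpus, tmp_path):
        corpus_dir, _ = corpus
        a, b = tmp_path / "w1", tmp_path / "w2"
        run_batch(corpus_dir, a, BatchConfig(seed=17, workers=1))
        run_batch(corpus_dir, b, BatchConfig(seed=17, workers=2, chunk_size=3))
        for p in sorted(a.iterdir()):
            assert p.read_bytes() == (b / p.name).read_bytes(), p.name

    def test_obsoleted_duplicates_logged_not_processed(self, builtins, tmp_path):
        indir = tmp_path / "in"
        indir.mkdir()
        mol = builtins["water"]
        rec = write_sdf(mol, properties={"PUBCHEM_COMPOUND_CID": "77"})
        (indir / "dup.sdf").write_text(rec + rec + rec)
        out = tmp_path / "out"
        summary = run_batch(indir, out)
        assert summary["entries_processed"] == 1
        assert summary["superseded"] == 2
        assert len((out / "superseded.txt").read_text().splitlines()) == 2

    def test_2d_records_skipped(self, builtins, tmp_path):
        from dataclasses import replace

        indir = tmp_path / "in"
        indir.mkdir()
        mol = builtins["water"]
        flat = type(mol)(
            cid="88",
            atoms=[replace(a, z=0.0) for a in mol.atoms],
            bonds=mol.bonds,
            is_3d=False,
            name="88",
        )
        (indir / "flat.sdf").write_text(
            write_sdf(flat, properties={"PUBCHEM_COMPOUND_CID": "88"})
        )
        out = tmp_path / "out"
        summary = run_batch(indir, out)
        assert summary["skipped_2d_only"] == 1
        assert summary["entries_processed"] == 0
        assert (out / "skipped_2d_only.txt").read_text() == "88\n"

    def test_malformed_record_logged_run_continues(self, builtins, tmp_path, water_sdf_text):
        indir = tmp_path / "in"
        indir.mkdir()
        good = write_sdf(builtins["ethanol"], properties={"PUBCHEM_COMPOUND_CID": "5"})
        bad = water_sdf_text.replace("  3  2", "  ?  2")
        (indir / "mix.sdf").write_text(good + bad)
        summary = run_batch(indir, tmp_path / "out")
        assert summary["entries_processed"] == 1
        assert summary["parse_errors"] == 1


class TestCli:
    def test_fixtures_then_run(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli.main,
            ["fixtures", "--n", "6", "--seed", "2", "--rate", "0.5",
             "--out", str(tmp_path / "corp")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli.main,
            ["run", "--input", str(tmp_path / "corp"), "--output", str(tmp_path / "out")],
        )
        assert res.exit_code == 0, res.output
        summary = json.loads(res.output)
        assert summary["entries_processed"] == 6
        assert summary["flagged_total"] == 3

    def test_check_one_clean_and_flagged(self, builtins, builtin_inchis, tmp_path):
        runner = CliRunner()
        path = tmp_path / "one.sdf"
        path.write_text(
            write_sdf(
                builtins["ethanol"],
                properties={"PUBCHEM_IUPAC_INCHI": builtin_inchis["ethanol"]},
            )
        )
        res = runner.invoke(cli.main, ["check-one", str(path)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli.main,
            ["check-one", str(path), "--deposited-inchi", builtin_inchis["water"]],
        )
        assert res.exit_code == 2
        payload = json.loads(res.output)
        assert "formula" in payload["differing_layers"]
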