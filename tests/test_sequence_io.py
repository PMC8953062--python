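"""FASTQ/PAF/Newick/taxonomy round-trips and parse-error behaviour."""

import numpy as np
import pytest

from vagitax import sequence_io as sio
from vagitax.sequence_io import (
    AlignmentHit,
    FastqParseError,
    PafParseError,
    ReadRecord,
    TaxonomyError,
)
from vagitax.synthetic_data import ErrorModel, make_reference_fixture, simulate_reads


class TestFastq:
    def test_single_record_phred33(self, tmp_path):
        p = tmp_path / "a.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        (rec,) = sio.read_fastq(p)
        assert rec.read_id == "r1"
        assert rec.seq == "ACGT"
        assert rec.quals == (40, 40, 40, 40)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        assert sio.read_fastq(p) == []

    def test_roundtrip_simulated_batch(self, tmp_path, mock_fixture):
        refdb, _tax, _tree = mock_fixture
        taxa = sorted(refdb.taxa())
        reads, _ = simulate_reads(refdb, {t: 1 / len(taxa) for t in taxa}, 50, "V3-4", seed=3)
        p = tmp_path / "sim.fastq"
        sio.write_fastq(reads, p)
        assert sio.read_fastq(p) == reads

    def test_truncated_record_names_line(self, tmp_path):
        p = tmp_path / "trunc.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACG\n")
        with pytest.raises(FastqParseError, match="line 5"):
            sio.read_fastq(p)

    def test_length_mismatch_is_record_error(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIII\n")
        with pytest.raises(FastqParseError, match="quality length 3"):
            sio.read_fastq(p)

    def test_write_zero_records_and_qual_zero(self, tmp_path):
        p = tmp_path / "o.fastq"
        sio.write_fastq([], p)
        assert p.read_text() == ""
        sio.write_fastq([ReadRecord("r", "A", (0,))], p)
        assert p.read_text() == "@r\nA\n+\n!\n"

    def test_unencodable_quality_refused(self, tmp_path):
        rec = ReadRecord.__new__(ReadRecord)  # bypass validation to hit writer guard
        object.__setattr__(rec, "read_id", "r")
        object.__setattr__(rec, "seq", "A")
        object.__setattr__(rec, "quals", (94,))
        with pytest.raises(ValueError, match="not encodable"):
            sio.write_fastq([rec], tmp_path / "x.fastq")

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "ACG", (40, 40))
        with pytest.raises(ValueError):
            ReadRecord("", "A", (40,))
        with pytest.raises(ValueError):
            ReadRecord("r", "AXG", (1, 1, 1))


class TestPaf:
    PAF = "q1\t100\t0\t100\t+\tt1\t200\t50\t150\t{nm}\t100\t60{tags}\n"

    def test_as_tag_preferred(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(self.PAF.format(nm=90, tags="\tAS:i:87"))
        (hit,) = sio.read_paf(p)
        assert hit.score == 87
        assert hit.n_match == 90

    def test_residue_match_fallback(self, tmp_path):
        p = tmp_path / "b.paf"
        p.write_text("q1\t2000\t0\t1600\t+\tt1\t1600\t0\t1600\t1500\t1600\t60\n")
        (hit,) = sio.read_paf(p)
        assert hit.score == 1500
        assert hit.query_span == (0, 1600) and hit.strand == "+"

    def test_malformed_line_named(self, tmp_path):
        p = tmp_path / "c.paf"
        good = self.PAF.format(nm=90, tags="")
        p.write_text(good + "q2\t100\tbroken\n" + good.replace("q1", "q3"))
        with pytest.raises(PafParseError, match="line 2"):
            sio.read_paf(p)

    def test_roundtrip_via_write_paf(self, tmp_path):
        hits = [
            AlignmentHit("q1", "t1", 87, (0, 100), (50, 150), "+", 90, 100),
            AlignmentHit("q2", "t2", 55, (5, 95), (0, 90), "-", 80, 90),
        ]
        p = tmp_path / "rt.paf"
        sio.write_paf(hits, p, query_lens={"q1": 100, "q2": 100}, target_lens={"t1": 200, "t2": 90})
        assert sio.read_paf(p) == hits


class TestNewick:
    def test_two_leaf(self):
        tree = sio.parse_newick("(A:1,B:1):0;")
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"A": 1.0, "B": 1.0}

    def test_internal_branch(self):
        tree = sio.parse_newick("((A:1,B:1):0.5,C:2):0;")
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]
        internal = [n for n in tree.non_tips() if n.parent is not None]
        assert internal[0].length == 0.5

    def test_missing_lengths_default_zero(self):
        tree = sio.parse_newick("(A,B);")
        assert all(t.length == 0.0 for t in tree.tips())

    def test_unbalanced_parentheses(self):
        with pytest.raises(ValueError, match="parentheses"):
            sio.parse_newick("((A:1,B:1):0;")

    def test_roundtrip_random_fixture_trees(self, tmp_path):
        rng = np.random.default_rng(0)
        for i in range(5):
            n = int(rng.integers(2, 8))
            leaves = ",".join(f"L{j}:{rng.uniform(0.1, 2):.3f}" for j in range(n))
            text = f"({leaves})root;"
            tree = sio.parse_newick(text)
            path = tmp_path / f"t{i}.nwk"
            sio.write_newick(tree, path)
            again = sio.parse_newick(path.read_text())
            assert {(t.name, round(t.length, 6)) for t in tree.tips()} == {
                (t.name, round(t.length, 6)) for t in again.tips()
            }


class TestTaxonomy:
    def _write(self, tmp_path, nodes, names):
        np_, nm = tmp_path / "nodes.dmp", tmp_path / "names.dmp"
        np_.write_text(nodes)
        nm.write_text(names)
        return np_, nm

    def test_three_level_fixture(self, tmp_path):
        nodes = "1\t|\t1\t|\tno rank\t|\n2\t|\t1\t|\tgenus\t|\n3\t|\t2\t|\tspecies\t|\n"
        names = (
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tGenusX\t|\t\t|\tscientific name\t|\n"
            "3\t|\tGenusX speciesY\t|\t\t|\tscientific name\t|\n"
        )
        tree = sio.load_taxonomy(*self._write(tmp_path, nodes, names))
        assert tree.root_id == 1
        assert tree.rank(3) == "species" and tree.parent(3) == 2
        assert tree.name(2) == "GenusX"

    def test_orphan_parent_listed(self, tmp_path):
        nodes = "1\t|\t1\t|\tno rank\t|\n2\t|\t99\t|\tgenus\t|\n"
        names = "1\t|\troot\t|\t\t|\tscientific name\t|\n2\t|\tG\t|\t\t|\tscientific name\t|\n"
        with pytest.raises(TaxonomyError, match="99"):
            sio.load_taxonomy(*self._write(tmp_path, nodes, names))

    def test_duplicate_taxon_id(self, tmp_path):
        nodes = "1\t|\t1\t|\tno rank\t|\n1\t|\t1\t|\tgenus\t|\n"
        names = "1\t|\troot\t|\t\t|\tscientific name\t|\n"
        with pytest.raises(TaxonomyError, match="duplicate"):
            sio.load_taxonomy(*self._write(tmp_path, nodes, names))

    def test_generator_fixture_roundtrip_counts(self, tmp_path):
        n_genera = 4
        _refdb, tax, _tree = make_reference_fixture(n_genera=n_genera, species_per_genus=2, seed=2)
        sio.write_taxonomy(tax, tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        loaded = sio.load_taxonomy(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        genus_nodes = [t for t in loaded.nodes if loaded.rank(t) == "genus"]
        assert len(genus_nodes) == n_genera
        assert loaded.nodes == tax.nodes

    def test_every_taxon_reachable_from_root(self, small_fixture):
        _refdb, tax, _tree = small_fixture
        for tid in tax.nodes:
            cur, hops = tid, 0
            while cur != tax.root_id:
                cur = tax.parent(cur)
                hops += 1
                assert hops < 100
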