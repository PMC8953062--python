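"""Alignment scoring against brute-force oracles, host screening, and
best-hit assignment with even tie allocation."""

import numpy as np
import pytest

import oracles
from vagitax.classifier import (
    ReadAssignment,
    ReferenceDB,
    ScoringScheme,
    builtin_hits,
    classify_batch,
    classify_read,
    local_align_score,
    screen_host,
)
from vagitax.sequence_io import ReadRecord, read_paf, write_paf
from vagitax.synthetic_data import ErrorModel, simulate_reads


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _read(seq, rid="r"):
    return ReadRecord(rid, seq, (12,) * len(seq))


class TestLocalAlignScore:
    def test_identity_is_match_times_length(self):
        rng = np.random.default_rng(0)
        s = _rand_seq(rng, 100)
        assert local_align_score(s, s) == 200

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        t = _rand_seq(rng, 80)
        assert local_align_score(oracles.revcomp(t), t) == local_align_score(t, t)

    def test_matches_bruteforce_dp_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = _rand_seq(rng, 60), _rand_seq(rng, 60)
            assert local_align_score(a, b) == oracles.affine_local_score(a, b)

    def test_matches_dp_on_mutated_pairs_with_n(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = list(_rand_seq(rng, 60))
            b = a.copy()
            for pos in rng.choice(60, 8, replace=False):
                b[pos] = rng.choice(list("ACGTN"))
            del b[5:8]  # indel
            a, b = "".join(a), "".join(b)
            assert local_align_score(a, b) == oracles.affine_local_score(a, b)

    def test_agrees_with_biopython_aligner(self):
        from Bio import Align

        scheme = ScoringScheme()
        aligner = Align.PairwiseAligner(
            mode="local",
            match_score=scheme.match,
            mismatch_score=scheme.mismatch,
            open_gap_score=scheme.gap_open + scheme.gap_extend,
            extend_gap_score=scheme.gap_extend,
        )
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = _rand_seq(rng, 70), _rand_seq(rng, 90)
            expected = max(aligner.score(a, b), aligner.score(oracles.revcomp(a), b))
            assert local_align_score(a, b) == expected

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            local_align_score("", "ACGT")


class TestScreenHost:
    def _host_db(self, rng, n=2):
        return ReferenceDB({f"h{i}": (_rand_seq(rng, 2000), 1) for i in range(n)})

    def test_verbatim_host_copy_flagged(self):
        rng = np.random.default_rng(5)
        db = self._host_db(rng)
        read = _read(db.refs["h0"][0][100:700], "hostread")
        host, clean = screen_host([read], db)
        assert [r.read_id for r in host] == ["hostread"] and clean == []

    def test_16s_read_vs_unrelated_host_passes(self, mock_fixture):
        rng = np.random.default_rng(6)
        db = self._host_db(rng)
        refdb, _tax, _tree = mock_fixture
        taxa = sorted(refdb.taxa())
        reads, _ = simulate_reads(refdb, {t: 1 / len(taxa) for t in taxa}, 5, "V3-4", seed=7)
        host, clean = screen_host(reads, db)
        assert host == [] and len(clean) == 5
        # oracle confirms the scores really are below the threshold
        for r in clean:
            best = max(oracles.affine_local_score(r.seq, seq) for seq, _t in db.refs.values())
            assert best < 0.5 * 2 * len(r)

    def test_empty_inputs(self):
        rng = np.random.default_rng(7)
        assert screen_host([], self._host_db(rng)) == ([], [])
        reads = [_read("ACGT" * 100)]
        host, clean = screen_host(reads, None)
        assert host == [] and clean == reads


class TestClassifyRead:
    def _db(self, seqs_taxa):
        return ReferenceDB({f"r{i}": st for i, st in enumerate(seqs_taxa)})

    def test_unique_maximum(self):
        rng = np.random.default_rng(8)
        a = _rand_seq(rng, 300)
        b = _rand_seq(rng, 300)
        db = self._db([(a, 10), (b, 20)])
        out = classify_read(_read(a), db)
        assert out.outcome == "classified" and out.weights == {10: 1.0}
        assert out.best_score == 600

    def test_exact_tie_split_evenly(self):
        rng = np.random.default_rng(9)
        a = _rand_seq(rng, 300)
        db = self._db([(a, 10), (a, 20)])
        out = classify_read(_read(a), db)
        assert out.weights == {10: 0.5, 20: 0.5}

    def test_below_threshold_unclassified(self):
        rng = np.random.default_rng(10)
        db = self._db([(_rand_seq(rng, 300), 10)])
        out = classify_read(_read(_rand_seq(rng, 300)), db)
        assert out.outcome == "unclassified" and out.weights == {}

    def test_duplicate_reference_never_changes_weights(self):
        rng = np.random.default_rng(11)
        a, b = _rand_seq(rng, 300), _rand_seq(rng, 300)
        read = _read(a)
        base = classify_read(read, self._db([(a, 10), (b, 20)]))
        dup = classify_read(read, self._db([(a, 10), (a, 10), (b, 20)]))
        assert base.weights == dup.weights == {10: 1.0}

    def test_raising_threshold_only_shrinks_classified_set(self, small_fixture):
        refdb, tax, _tree = small_fixture
        taxa = sorted(refdb.taxa())
        reads, _ = simulate_reads(
            refdb, {t: 1 / len(taxa) for t in taxa}, 30, "V3-4",
            ErrorModel(p_sub=0.1, p_ins=0.05, p_del=0.1), seed=12,
        )
        classified = {}
        for frac in (0.2, 0.5, 0.8):
            asg = classify_batch(reads, refdb, tax, min_score_frac=frac)
            classified[frac] = {a.read_id for a in asg if a.outcome == "classified"}
        assert classified[0.8] <= classified[0.5] <= classified[0.2]

    def test_weights_sum_to_one_invariant(self):
        with pytest.raises(ValueError):
            ReadAssignment("r", "classified", {1: 0.5, 2: 0.4})


class TestClassifyBatch:
    def test_simulated_reads_recover_source_taxon(self, small_fixture):
        refdb, tax, _tree = small_fixture
        source = sorted(refdb.taxa())[0]
        reads, _truth = simulate_reads(refdb, {source: 1.0}, 300, "V3-4", seed=1)
        asg = classify_batch(reads, refdb, tax)
        total = sum(sum(a.weights.values()) for a in asg if a.outcome == "classified")
        on_source = sum(a.weights.get(source, 0.0) for a in asg)
        assert total > 0 and on_source / total > 0.95

    def test_mode_equivalence_builtin_vs_paf(self, tmp_path, small_fixture):
        refdb, tax, _tree = small_fixture
        taxa = sorted(refdb.taxa())
        reads, _ = simulate_reads(refdb, {t: 1 / len(taxa) for t in taxa}, 40, "V3-4", seed=13)
        builtin = classify_batch(reads, refdb, tax)
        hits = builtin_hits(reads, refdb)
        paf = tmp_path / "hits.paf"
        write_paf(
            hits, paf,
            query_lens={r.read_id: len(r) for r in reads},
            target_lens={rid: len(seq) for rid, (seq, _t) in refdb.refs.items()},
        )
        external = classify_batch(reads, refdb, tax, alignments=read_paf(paf))
        assert external == builtin

    def test_self_alignment_span_is_full_halfopen_interval(self, small_fixture):
        refdb, _tax, _tree = small_fixture
        rid, (seq, _t) = next(iter(refdb.refs.items()))
        read = _read(seq, "self")
        (hit,) = [h for h in builtin_hits([read], refdb) if h.target_id == rid]
        assert hit.query_span == (0, len(seq))
        assert hit.score == 2 * len(seq)

    def test_unknown_read_in_alignments_named(self, small_fixture):
        refdb, _tax, _tree = small_fixture
        rid, (seq, _t) = next(iter(refdb.refs.items()))
        hits = builtin_hits([_read(seq, "ghost")], refdb)
        with pytest.raises(ValueError, match="ghost"):
            classify_batch([], refdb, alignments=hits)

    def test_read_sharing_no_minimizers_unclassified(self, small_fixture):
        refdb, tax, _tree = small_fixture
        read = _read("AT" * 200, "rep")  # repeat sequence shares no random minimizer
        (a,) = classify_batch([read], refdb, tax)
        assert a.outcome == "unclassified"
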