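import io as _io

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import hingecrf as hc
from hingecrf.align import _make_aligner, evalue_from_score

from _oracles import smith_waterman_score

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng, n):
    return "".join(rng.choice(list(AAS), size=n))


def _labels3(n):
    return hc.LabelString(np.zeros(n, dtype=np.int8), arity=3)


def _entry(eid, seq):
    return hc.ReferenceEntry(eid, seq, _labels3(len(seq)))


class TestBuildDB:
    def test_exact_match_exclusion(self):
        rng = np.random.default_rng(0)
        entries = [_entry(f"e{i}", _rand_seq(rng, 30)) for i in range(5)]
        db = hc.build_reference_db(entries, exclude_exact_of={entries[2].sequence})
        assert len(db) == 4 and "e2" not in db
        assert len(hc.build_reference_db(entries, set())) == 5

    def test_duplicate_id_rejected(self):
        rng = np.random.default_rng(1)
        seqs = [_rand_seq(rng, 20) for _ in range(2)]
        with pytest.raises(ValueError, match="duplicate"):
            hc.build_reference_db([_entry("a", seqs[0]), _entry("a", seqs[1])])


class TestLocalSearch:
    def test_score_matches_brute_force_gotoh(self):
        matrix = substitution_matrices.load("BLOSUM62")
        aligner = _make_aligner(hc.SearchParams())
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = _rand_seq(rng, int(rng.integers(4, 13)))
            b = _rand_seq(rng, int(rng.integers(4, 13)))
            assert aligner.score(a, b) == pytest.approx(
                smith_waterman_score(a, b, matrix), abs=1e-9
            )

    def test_self_match_is_top_hit_with_full_coverage(self):
        rng = np.random.default_rng(3)
        target = _rand_seq(rng, 100)
        entries = [_entry("self", target)] + [
            _entry(f"r{i}", _rand_seq(rng, 100)) for i in range(4)
        ]
        hits = hc.local_align_search(target, hc.build_reference_db(entries))
        assert hits and hits[0].subject_id == "self"
        assert hits[0].pairs == tuple((i, i) for i in range(1, 101))

    def test_top_s_truncation_and_ascending_evalues(self):
        rng = np.random.default_rng(4)
        proto = _rand_seq(rng, 80)
        entries = []
        for i in range(15):
            seq = list(proto)
            for j in rng.choice(80, size=i + 1, replace=False):  # 1..15 mutations
                seq[j] = rng.choice(list(AAS))
            entries.append(_entry(f"h{i:02d}", "".join(seq)))
        db = hc.build_reference_db(entries)
        hits = hc.local_align_search(proto, db, hc.SearchParams(top_s=10))
        assert len(hits) == 10
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)

    def test_unrelated_query_below_stringent_ceiling_is_empty(self):
        rng = np.random.default_rng(5)
        entries = [_entry(f"r{i}", _rand_seq(rng, 40)) for i in range(5)]
        db = hc.build_reference_db(entries)
        query = _rand_seq(rng, 40)
        params = hc.SearchParams(e_max=1e-6)
        hits = hc.local_align_search(query, db, params)
        # brute-force confirmation that no score clears the e-value ceiling
        matrix = substitution_matrices.load("BLOSUM62")
        for e in entries:
            raw = smith_waterman_score(query, e.sequence, matrix)
            ev, _ = evalue_from_score(raw, len(query), db.total_residues)
            assert ev > 1e-6
        assert hits == []

    def test_pairs_strictly_increasing(self):
        rng = np.random.default_rng(6)
        proto = _rand_seq(rng, 60)
        noisy = proto[:20] + "W" + proto[20:40] + proto[45:]  # indels
        db = hc.build_reference_db([_entry("s", noisy)])
        hits = hc.local_align_search(proto, db, hc.SearchParams(e_max=10.0))
        assert hits
        for h in hits:
            qs = [p[0] for p in h.pairs]
            ss = [p[1] for p in h.pairs]
            assert all(b > a for a, b in zip(qs, qs[1:]))
            assert all(b > a for a, b in zip(ss, ss[1:]))

    def test_empty_db_and_bad_residues(self):
        assert hc.local_align_search("ACDEF", hc.build_reference_db([])) == []
        rng = np.random.default_rng(7)
        db = hc.build_reference_db([_entry("r", _rand_seq(rng, 10))])
        with pytest.raises(ValueError, match="non-amino-acid"):
            hc.local_align_search("AC1EF", db)


class TestTabularImport:
    def _db(self):
        rng = np.random.default_rng(8)
        return hc.build_reference_db([_entry(f"s{i}", _rand_seq(rng, 50)) for i in range(3)])

    def test_threshold_sort_and_truncation(self):
        db = self._db()
        rows = [
            "q\ts0\t0.5\t20.0\t1-10:1-10",  # above e_max: dropped
            "q\ts1\t0.05\t30.0\t1-10:5-14",
            "q\ts2\t0.001\t40.0\t2-8:3-9",
        ]
        hits = hc.import_tabular_hits(rows, db, hc.SearchParams(e_max=0.1))
        assert [h.subject_id for h in hits] == ["s2", "s1"]
        assert hits[0].pairs[0] == (2, 3)

    def test_unknown_subject_id(self):
        with pytest.raises(KeyError, match="nope"):
            hc.import_tabular_hits(["q\tnope\t0.01\t30\t1-5:1-5"], self._db())

    def test_round_trip_through_writer(self, tmp_path):
        rng = np.random.default_rng(9)
        proto = _rand_seq(rng, 60)
        db = hc.build_reference_db([_entry("s", proto)])
        hits = hc.local_align_search(proto, db)
        path = tmp_path / "hits.tsv"
        from hingecrf import io as hio

        hio.write_hits(path, "q", hits)
        back = hc.import_tabular_hits(open(path), db)
        assert [h.subject_id for h in back] == [h.subject_id for h in hits]
        assert back[0].pairs == hits[0].pairs
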