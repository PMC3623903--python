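"""Labeled reference database and local-alignment hit search.

A query is searched against a database of domain/hinge/boundary-labeled
reference sequences.  The default engine is a single-pass Smith-Waterman
local alignment (Biopython ``PairwiseAligner``) with BLOSUM62 and affine
gaps (open 11, extend 1 in BLAST convention), scored into e-values by
Karlin-Altschul statistics with the total database residue count as the
search-space size.  Hits with e-value <= ``e_max`` are ranked ascending by
e-value (ties: bit score descending, then subject id) and truncated to the
top ``top_s``.  Externally computed hits (e.g. PSI-BLAST tabular output)
can be imported under the same filtering/ranking contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .labels import LabelString

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1,
# as tabulated by NCBI BLAST.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    sequence: str
    labels3: LabelString

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.labels3):
            raise ValueError(f"{self.id}: sequence and label lengths differ")
        if self.labels3.arity != 3:
            raise ValueError(f"{self.id}: reference labels must be three-state")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")


class ReferenceDB:
    """Collection of reference entries with unique ids."""

    def __init__(self, entries: Iterable[ReferenceEntry]):
        self.entries: list[ReferenceEntry] = list(entries)
        self._by_id: dict[str, ReferenceEntry] = {}
        for e in self.entries:
            if e.id in self._by_id:
                raise ValueError(f"duplicate reference id {e.id!r}")
            self._by_id[e.id] = e
        self.total_residues = sum(len(e.sequence) for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def __getitem__(self, entry_id: str) -> ReferenceEntry:
        return self._by_id[entry_id]


@dataclass(frozen=True)
class AlignmentHit:
    """One local match of the query against a reference entry.

    ``pairs`` holds aligned (query_pos, subject_pos) residue pairs, 1-based,
    strictly increasing in both coordinates; gap columns are omitted.
    """

    subject_id: str
    evalue: float
    bit_score: float
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("alignment hit must contain at least one aligned pair")
        if self.evalue <= 0:
            raise ValueError("e-value must be > 0")
        qp = [p[0] for p in self.pairs]
        sp = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(qp, qp[1:])) or any(
            b <= a for a, b in zip(sp, sp[1:])
        ):
            raise ValueError("aligned pairs must be strictly increasing")


@dataclass(frozen=True)
class SearchParams:
    e_max: float = 1e-1
    top_s: int = 10
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be > 0")
        if self.top_s < 1:
            raise ValueError("top_s must be >= 1")


def build_reference_db(
    entries: Sequence[ReferenceEntry],
    exclude_exact_of: set[str] | frozenset[str] | None = None,
) -> ReferenceDB:
    """Assemble a database, dropping entries whose sequence exactly matches
    a member of ``exclude_exact_of`` (fairness filter against a test set)."""
    exclude = exclude_exact_of or set()
    return ReferenceDB(e for e in entries if e.sequence not in exclude)


def _validate_query(query: str) -> None:
    if len(query) < 1:
        raise ValueError("query must be non-empty")
    bad = set(query) - AA_ALPHABET
    if bad:
        raise ValueError(f"query contains non-amino-acid characters {sorted(bad)}")


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # BLAST convention: a gap of length k costs open + k*extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def evalue_from_score(raw_score: float, query_len: int, db_residues: int) -> tuple[float, float]:
    """Karlin-Altschul (e-value, bit score) from a raw alignment score."""
    bits = (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)
    evalue = query_len * db_residues * math.pow(2.0, -bits)
    return max(evalue, 1e-300), bits


def _rank_and_truncate(hits: list[AlignmentHit], params: SearchParams) -> list[AlignmentHit]:
    kept = [h for h in hits if h.evalue <= params.e_max]
    kept.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
    return kept[: params.top_s]


def local_align_search(
    query: str, db: ReferenceDB, params: SearchParams = SearchParams()
) -> list[AlignmentHit]:
    """Smith-Waterman search of a query against every database entry.

    One best-scoring local alignment is kept per subject.  Scoring is done
    first (no traceback); tracebacks are only computed for subjects that
    survive the e-value filter, for speed.
    """
    _validate_query(query)
    if len(db) == 0:
        return []
    aligner = _make_aligner(params)
    scored: list[tuple[float, float, ReferenceEntry, float]] = []
    for entry in db.entries:
        raw = aligner.score(query, entry.sequence)
        if raw <= 0:
            continue
        evalue, bits = evalue_from_score(raw, len(query), db.total_residues)
        if evalue <= params.e_max:
            scored.append((evalue, bits, entry, raw))
    scored.sort(key=lambda t: (t[0], -t[1], t[2].id))
    hits: list[AlignmentHit] = []
    for evalue, bits, entry, _raw in scored[: params.top_s]:
        alignment = aligner.align(query, entry.sequence)[0]
        pairs: list[tuple[int, int]] = []
        qblocks, sblocks = alignment.aligned
        for (qs, qe), (ss, se) in zip(qblocks, sblocks):
            for k in range(qe - qs):
                pairs.append((qs + k + 1, ss + k + 1))
        hits.append(AlignmentHit(entry.id, evalue, bits, tuple(pairs)))
    return hits


def import_tabular_hits(
    stream: TextIO | Iterable[str], db: ReferenceDB, params: SearchParams = SearchParams()
) -> list[AlignmentHit]:
    """Read externally computed hits from tab-separated text.

    Columns: query_id, subject_id, evalue, bit_score, blocks — where blocks
    is a comma-separated list of ungapped runs ``qstart-qend:sstart-send``
    in 1-based inclusive coordinates.  Lines starting with '#' are skipped.
    Filtering, ranking and truncation follow the built-in search contract.
    """
    hits: list[AlignmentHit] = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"expected 5 tab-separated columns, got {len(fields)}")
        _qid, sid, ev, bits, blocks = fields
        if sid not in db:
            raise KeyError(f"subject id {sid!r} not present in the reference database")
        subject_len = len(db[sid].sequence)
        pairs: list[tuple[int, int]] = []
        for block in blocks.split(","):
            qrange, srange = block.split(":")
            qs, qe = (int(x) for x in qrange.split("-"))
            ss, se = (int(x) for x in srange.split("-"))
            if qe - qs != se - ss:
                raise ValueError(f"unequal block lengths in {block!r}")
            if ss < 1 or se > subject_len:
                raise ValueError(f"block {block!r} outside subject {sid!r}")
            pairs.extend((qs + k, ss + k) for k in range(qe - qs + 1))
        hits.append(AlignmentHit(sid, float(ev), float(bits), tuple(pairs)))
    return _rank_and_truncate(hits, params)
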