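"""Host screening and per-read best-hit taxonomic assignment.

Each read is assigned to the reference taxon attaining the highest alignment
score; when several taxa tie exactly for the top score, the read's unit of
weight is allocated evenly across the tied taxa (1/k each).  The per-taxon
score is the maximum over that taxon's references, taken *before* tie
detection, so redundant references for one taxon never absorb tie mass.

Two modes are supported: a built-in aligner (minimizer prescreen followed by
affine-gap Smith-Waterman on candidate references) and an external-mapper
mode consuming precomputed PAF alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .sequence_io import AlignmentHit, ReadRecord, TaxonomyTree

__all__ = [
    "ScoringScheme",
    "ReferenceDB",
    "ReadAssignment",
    "local_align_score",
    "screen_host",
    "classify_read",
    "classify_batch",
    "builtin_hits",
]

logger = logging.getLogger(__name__)

#: Score-equality tolerance for float scores from external tools; built-in
#: integer scores tie iff exactly equal, which this tolerance preserves.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class ScoringScheme:
    """Affine alignment scoring; a gap of length L costs gap_open + L*gap_extend."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


class ReferenceDB:
    """Reference panel: ``ref_id -> (sequence, taxon_id)`` with cached sketches."""

    def __init__(self, refs: dict[str, tuple[str, int]], *, k: int = 15, w: int = 10):
        if any(not seq for seq, _t in refs.values()):
            raise ValueError("reference sequences must be non-empty")
        self.refs = dict(refs)
        self.k = k
        self.w = w
        self._codes = {rid: _align.encode(seq) for rid, (seq, _t) in self.refs.items()}
        self._sketches = {
            rid: _align.minimizer_sketch(codes, k, w) for rid, codes in self._codes.items()
        }

    def __len__(self) -> int:
        return len(self.refs)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.refs

    def taxon_of(self, ref_id: str) -> int:
        return self.refs[ref_id][1]

    def taxa(self) -> set[int]:
        return {t for _s, t in self.refs.values()}

    def validate_against(self, tree: TaxonomyTree) -> None:
        missing = sorted(t for t in self.taxa() if t not in tree)
        if missing:
            raise ValueError(f"reference taxa absent from taxonomy: {missing}")


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome for one read: host, classified (with tie weights), or unclassified."""

    read_id: str
    outcome: str  # {host, classified, unclassified}
    weights: dict[int, float] = field(default_factory=dict)
    best_score: float = 0.0

    def __post_init__(self) -> None:
        if self.outcome == "classified":
            if abs(sum(self.weights.values()) - 1.0) > 1e-12:
                raise ValueError("classified weights must sum to 1")
        elif self.weights:
            raise ValueError(f"outcome {self.outcome!r} must have empty weights")


def local_align_score(query: str, target: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Best local alignment score over both strands of the query.

    N never matches anything (scores as a mismatch).  The score is >= 0 by
    the local-alignment convention (empty alignment scores 0).
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q = _align.encode(query)
    t = _align.encode(target)
    fwd = _align.sw_score(q, t, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    rev = _align.sw_score(
        _align.revcomp_codes(q), t, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    return int(max(fwd, rev))


#: Candidates sharing fewer than this fraction of the best candidate's
#: shared-minimizer count are pruned before alignment.  Exact top-score ties
#: involve (near-)identical reference spans with identical sketches, so tie
#: candidates always survive pruning together.
MIN_SHARE_FRAC = 0.25


def _candidate_refs(
    read_codes: np.ndarray, refdb: ReferenceDB, max_candidates: int
) -> list[tuple[str, str]]:
    """Prescreen: references ranked by shared minimizers; per-candidate strand.

    Returns ``[(ref_id, strand), ...]`` for up to ``max_candidates``
    references by shared-minimizer count over either read strand, pruned at
    ``MIN_SHARE_FRAC`` of the best count.  A '*' strand means the two
    strands tied and both must be aligned.
    """
    fwd = _align.minimizer_sketch(read_codes, refdb.k, refdb.w)
    rev = _align.minimizer_sketch(_align.revcomp_codes(read_codes), refdb.k, refdb.w)
    scored: list[tuple[int, str, str]] = []
    for rid, sketch in refdb._sketches.items():
        nf = len(fwd & sketch)
        nr = len(rev & sketch)
        best = max(nf, nr)
        if best == 0:
            continue
        strand = "+" if nf > nr else ("-" if nr > nf else "*")
        scored.append((best, rid, strand))
    scored.sort(key=lambda x: (-x[0], x[1]))
    if not scored:
        return []
    cutoff = max(1.0, MIN_SHARE_FRAC * scored[0][0])
    return [(rid, strand) for c, rid, strand in scored[:max_candidates] if c >= cutoff]


def _builtin_ref_scores(
    record: ReadRecord,
    refdb: ReferenceDB,
    scheme: ScoringScheme,
    max_candidates: int,
) -> dict[str, int]:
    """Per-reference best alignment scores for the prescreen candidates."""
    codes = _align.encode(record.seq)
    scores: dict[str, int] = {}
    for rid, strand in _candidate_refs(codes, refdb, max_candidates):
        t = refdb._codes[rid]
        args = (scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
        if strand == "+":
            s = _align.sw_score(codes, t, *args)
        elif strand == "-":
            s = _align.sw_score(_align.revcomp_codes(codes), t, *args)
        else:
            s = max(
                _align.sw_score(codes, t, *args),
                _align.sw_score(_align.revcomp_codes(codes), t, *args),
            )
        scores[rid] = int(s)
    return scores


def _assign_from_taxon_scores(
    read_id: str,
    taxon_scores: dict[int, float],
    threshold: float,
) -> ReadAssignment:
    if not taxon_scores:
        return ReadAssignment(read_id, "unclassified")
    top = max(taxon_scores.values())
    if top < threshold:
        return ReadAssignment(read_id, "unclassified", best_score=float(top))
    tied = sorted(t for t, s in taxon_scores.items() if top - s <= TIE_TOL)
    w = 1.0 / len(tied)
    return ReadAssignment(read_id, "classified", {t: w for t in tied}, float(top))


def classify_read(
    record: ReadRecord,
    refdb: ReferenceDB,
    tree: TaxonomyTree | None = None,
    min_score_frac: float = 0.4,
    scheme: ScoringScheme = ScoringScheme(),
) -> ReadAssignment:
    """Best-hit assignment of one read against every reference taxon.

    The read is unclassified when the top per-taxon score falls below
    ``min_score_frac * match * read_length`` (the perfect-match score scaled
    by ``min_score_frac``); otherwise the k taxa tying for the top score each
    receive weight 1/k.
    """
    if len(refdb) == 0:
        raise ValueError("reference database is empty")
    taxon_scores: dict[int, float] = {}
    for rid, (seq, taxon) in refdb.refs.items():
        s = local_align_score(record.seq, seq, scheme)
        if s > taxon_scores.get(taxon, -1):
            taxon_scores[taxon] = s
    threshold = min_score_frac * scheme.match * len(record)
    return _assign_from_taxon_scores(record.read_id, taxon_scores, threshold)


def screen_host(
    records: list[ReadRecord],
    host_refs: ReferenceDB | None,
    min_host_score_frac: float = 0.5,
    scheme: ScoringScheme = ScoringScheme(),
    max_candidates: int = 20,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition reads into (host, non_host), preserving order.

    A read is host when its best alignment score against the host panel
    reaches ``min_host_score_frac * match * read_length``.  An empty or
    missing host panel flags nothing (with a warning).
    """
    if not 0 < min_host_score_frac <= 1:
        raise ValueError("min_host_score_frac must be in (0, 1]")
    if host_refs is None or len(host_refs) == 0:
        logger.warning("host screen: empty host reference panel; no reads flagged")
        return [], list(records)
    host: list[ReadRecord] = []
    non_host: list[ReadRecord] = []
    for rec in records:
        scores = _builtin_ref_scores(rec, host_refs, scheme, max_candidates)
        best = max(scores.values(), default=0)
        if best >= min_host_score_frac * scheme.match * len(rec):
            host.append(rec)
        else:
            non_host.append(rec)
    return host, non_host


def classify_batch(
    records: list[ReadRecord],
    refdb: ReferenceDB,
    tree: TaxonomyTree | None = None,
    min_score_frac: float = 0.4,
    scheme: ScoringScheme = ScoringScheme(),
    *,
    alignments: list[AlignmentHit] | None = None,
    max_candidates: int = 20,
) -> list[ReadAssignment]:
    """Classify a batch of reads, built-in or external-mapper mode.

    With ``alignments`` supplied (external-mapper mode), scores come from the
    alignment hits and no built-in alignment runs.  Otherwise a shared-
    minimizer prescreen picks up to ``max_candidates`` candidate references
    per read and only those are aligned; reads sharing no minimizer with any
    reference are unclassified.
    """
    if tree is not None:
        refdb.validate_against(tree)
    if alignments is not None:
        known = {r.read_id for r in records}
        by_read: dict[str, dict[int, float]] = {}
        for hit in alignments:
            if hit.query_id not in known:
                raise ValueError(f"alignment references unknown read {hit.query_id!r}")
            if hit.target_id not in refdb:
                raise ValueError(f"alignment references unknown reference {hit.target_id!r}")
            taxon = refdb.taxon_of(hit.target_id)
            d = by_read.setdefault(hit.query_id, {})
            if hit.score > d.get(taxon, float("-inf")):
                d[taxon] = hit.score
        out = []
        for rec in records:
            threshold = min_score_frac * scheme.match * len(rec)
            out.append(_assign_from_taxon_scores(rec.read_id, by_read.get(rec.read_id, {}), threshold))
        return out

    out = []
    for rec in records:
        ref_scores = _builtin_ref_scores(rec, refdb, scheme, max_candidates)
        taxon_scores: dict[int, float] = {}
        for rid, s in ref_scores.items():
            taxon = refdb.taxon_of(rid)
            if s > taxon_scores.get(taxon, float("-inf")):
                taxon_scores[taxon] = s
        threshold = min_score_frac * scheme.match * len(rec)
        out.append(_assign_from_taxon_scores(rec.read_id, taxon_scores, threshold))
    return out


def builtin_hits(
    records: list[ReadRecord],
    refdb: ReferenceDB,
    scheme: ScoringScheme = ScoringScheme(),
    max_candidates: int = 20,
) -> list[AlignmentHit]:
    """Export the built-in aligner's per-candidate scores as AlignmentHits.

    Spans are reported as full-sequence spans (the score-only kernel does not
    track the alignment path); scores round-trip exactly through PAF AS tags,
    so external-mapper mode on these hits reproduces built-in assignments.
    """
    hits = []
    for rec in records:
        for rid, s in _builtin_ref_scores(rec, refdb, scheme, max_candidates).items():
            L = len(rec)
            hits.append(
                AlignmentHit(
                    query_id=rec.read_id,
                    target_id=rid,
                    score=s,
                    query_span=(0, L),
                    target_span=(0, len(refdb.refs[rid][0])),
                    strand="+",
                    n_match=L,
                    aln_len=L,
                )
            )
    return hits


def export_assignments(assignments: list[ReadAssignment], path) -> None:
    """TSV export: read_id, outcome, comma-joined taxa and weights, best score."""
    with open(path, "w") as fh:
        fh.write("read_id\toutcome\ttaxon_ids\tweights\tbest_score\n")
        for a in assignments:
            taxa = ",".join(str(t) for t in sorted(a.weights))
            weights = ",".join(f"{a.weights[t]:.6g}" for t in sorted(a.weights))
            fh.write(f"{a.read_id}\t{a.outcome}\t{taxa}\t{weights}\t{a.best_score:g}\n")
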