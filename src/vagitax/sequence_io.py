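"""Readers and writers for the formats the pipeline consumes.

FASTQ (Phred+33, 4-line records), FASTA reference panels, PAF alignments
with optional SAM-style tags, Newick trees, and NCBI-style taxonomy dump
tables (``nodes.dmp`` / ``names.dmp`` dialect).  All coordinates are kept
0-based half-open internally; conversion happens only at format boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import skbio
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "AlignmentHit",
    "TaxonomyTree",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "read_paf",
    "parse_newick",
    "write_newick",
    "load_taxonomy",
]

_PHRED_OFFSET = 33
_MAX_PHRED = 93

VALID_BASES = frozenset("ACGTN")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ input; carries the offending line number."""


class PafParseError(ValueError):
    """Raised for malformed PAF input; carries the offending line number."""


class TaxonomyError(ValueError):
    """Raised for inconsistent taxonomy dump tables."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read: ID, uppercase DNA sequence, per-base Phred scores."""

    read_id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if any(q < 0 or q > _MAX_PHRED for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred scores must be in [0, 93]")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    """A query-to-reference alignment with a comparable score (higher = better).

    Spans are 0-based half-open, as in PAF.  ``n_match`` is the residue-match
    count (PAF column 10); ``score`` is the AS tag when present, else
    ``n_match``.
    """

    query_id: str
    target_id: str
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str
    n_match: int
    aln_len: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.n_match > self.aln_len:
            raise ValueError("n_match cannot exceed alignment block length")


@dataclass
class TaxonomyTree:
    """NCBI-style taxonomy: ``taxon_id -> (parent_id, rank, name)`` plus root.

    The root is self-parented, following the NCBI dump convention.
    """

    nodes: dict[int, tuple[int, str, str]]
    root_id: int

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def parent(self, taxon_id: int) -> int:
        return self.nodes[taxon_id][0]

    def rank(self, taxon_id: int) -> str:
        return self.nodes[taxon_id][1]

    def name(self, taxon_id: int) -> str:
        return self.nodes[taxon_id][2]


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a 4-line-record Phred+33 FASTQ file into ReadRecords.

    The '+' separator line content is ignored.  A truncated record or a
    sequence/quality length mismatch raises :class:`FastqParseError` naming
    the line number where the problem was detected.
    """
    records: list[ReadRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            seq_line = fh.readline()
            plus_line = fh.readline()
            qual_line = fh.readline()
            if not qual_line:
                raise FastqParseError(f"line {lineno}: truncated record starting here")
            lineno += 3
            if not plus_line.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            read_id = header[1:].strip().split()[0]
            if read_id in seen:
                raise FastqParseError(f"line {lineno - 3}: duplicate read ID {read_id!r}")
            seen.add(read_id)
            seq = seq_line.strip().upper()
            quals = tuple(ord(c) - _PHRED_OFFSET for c in qual_line.strip())
            if len(seq) != len(quals):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(quals)} != sequence length {len(seq)}"
                )
            try:
                records.append(ReadRecord(read_id, seq, quals))
            except ValueError as exc:
                raise FastqParseError(f"line {lineno - 3}: {exc}") from exc
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records as 4-line Phred+33 FASTQ, preserving order."""
    with open(path, "w") as fh:
        for rec in records:
            if any(q > _MAX_PHRED for q in rec.quals):
                raise ValueError(f"read {rec.read_id!r}: quality > 93 is not encodable in Phred+33")
            qual = "".join(chr(q + _PHRED_OFFSET) for q in rec.quals)
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-line) FASTA file into ``{id: uppercase seq}``."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path) -> list[AlignmentHit]:
    """Parse a PAF file into AlignmentHits.

    ``score`` is the ``AS:i`` tag when present, else the residue-match count
    (mandatory column 10).  Coordinates stay 0-based half-open as in PAF.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise PafParseError(f"line {lineno}: expected >= 12 columns, got {len(cols)}")
            try:
                q_start, q_end = int(cols[2]), int(cols[3])
                t_start, t_end = int(cols[7]), int(cols[8])
                n_match = int(cols[9])
                aln_len = int(cols[10])
            except ValueError as exc:
                raise PafParseError(f"line {lineno}: non-integer coordinate field") from exc
            strand = cols[4]
            score: float = n_match
            for tag in cols[12:]:
                if tag.startswith("AS:i:"):
                    score = int(tag[5:])
                    break
            try:
                hits.append(
                    AlignmentHit(
                        query_id=cols[0],
                        target_id=cols[5],
                        score=score,
                        query_span=(q_start, q_end),
                        target_span=(t_start, t_end),
                        strand=strand,
                        n_match=n_match,
                        aln_len=aln_len,
                    )
                )
            except ValueError as exc:
                raise PafParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_paf(hits: Iterable[AlignmentHit], path: str | Path, *, query_lens: dict[str, int],
              target_lens: dict[str, int]) -> None:
    """Write AlignmentHits as PAF with an AS:i score tag."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        str(query_lens[h.query_id]),
                        str(h.query_span[0]),
                        str(h.query_span[1]),
                        h.strand,
                        h.target_id,
                        str(target_lens[h.target_id]),
                        str(h.target_span[0]),
                        str(h.target_span[1]),
                        str(h.n_match),
                        str(h.aln_len),
                        "60",
                        f"AS:i:{int(h.score)}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str) -> skbio.TreeNode:
    """Parse a single rooted Newick string into a tree.

    Missing branch lengths default to 0; branch lengths must be non-negative
    and leaf labels unique.
    """
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick string")
    tree = skbio.TreeNode.read(io.StringIO(text))
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length on {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# NCBI-style taxonomy dumps


def _split_dump_line(line: str) -> list[str]:
    # dump rows are pipe-delimited with tab padding: "1\t|\t1\t|\tno rank\t|"
    return [f.strip() for f in line.rstrip("\t|\n").split("|")]


def load_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load pipe-delimited NCBI-style ``nodes``/``names`` tables.

    Only the "scientific name" rows of the names table are used.  The root is
    detected as the self-parented node.  Orphan parents and duplicate taxon
    IDs raise :class:`TaxonomyError`.
    """
    parents: dict[int, tuple[int, str]] = {}
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            taxon_id, parent_id, rank = int(fields[0]), int(fields[1]), fields[2]
            if taxon_id in parents:
                raise TaxonomyError(f"duplicate taxon_id {taxon_id} in nodes table")
            parents[taxon_id] = (parent_id, rank)

    names: dict[int, str] = {}
    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            taxon_id, name = int(fields[0]), fields[1]
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name":
                names[taxon_id] = name

    orphans = sorted(
        {pid for pid, _ in parents.values() if pid not in parents}
    )
    if orphans:
        raise TaxonomyError(f"parent taxon IDs absent from nodes table: {orphans}")

    roots = [tid for tid, (pid, _) in parents.items() if pid == tid]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one self-parented root, found {roots}")
    root_id = roots[0]

    nodes: dict[int, tuple[int, str, str]] = {}
    for tid, (pid, rank) in parents.items():
        name = names.get(tid)
        if name is None:
            raise TaxonomyError(f"taxon {tid} has no scientific name")
        nodes[tid] = (pid, rank, name)

    tree = TaxonomyTree(nodes=nodes, root_id=root_id)
    _check_acyclic(tree)
    return tree


def _check_acyclic(tree: TaxonomyTree) -> None:
    for tid in tree.nodes:
        seen = set()
        cur = tid
        while cur != tree.root_id:
            if cur in seen:
                raise TaxonomyError(f"cycle in taxonomy involving taxon {cur}")
            seen.add(cur)
            cur = tree.parent(cur)


def write_taxonomy(tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path) -> None:
    """Write a TaxonomyTree back out in the dump dialect (round-trip aid)."""
    with open(nodes_path, "w") as fh:
        for tid, (pid, rank, _name) in sorted(tree.nodes.items()):
            fh.write(f"{tid}\t|\t{pid}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for tid, (_pid, _rank, name) in sorted(tree.nodes.items()):
            fh.write(f"{tid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
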