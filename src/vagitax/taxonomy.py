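"""Lineage resolution, lowest common ancestors, and rank roll-up."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from .sequence_io import TaxonomyTree

__all__ = ["lineage", "lca", "rollup", "export_lineages"]

#: Bin label for counts whose lineage has no ancestor at the requested rank.
UNRANKED = "unranked"


def lineage(tree: TaxonomyTree, taxon_id: int) -> list[tuple[int, str]]:
    """Return the root-to-node path as ``[(taxon_id, rank), ...]``."""
    if taxon_id not in tree:
        raise KeyError(f"unknown taxon_id {taxon_id}")
    path = []
    cur = taxon_id
    while True:
        path.append((cur, tree.rank(cur)))
        if cur == tree.root_id:
            break
        cur = tree.parent(cur)
    path.reverse()
    return path


def lca(tree: TaxonomyTree, ids: Iterable[int]) -> int:
    """Deepest node ancestral to (or equal to) every given taxon."""
    ids = list(ids)
    if not ids:
        raise ValueError("lca of an empty set is undefined")
    paths = [[tid for tid, _rank in lineage(tree, i)] for i in ids]
    best = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) != 1:
            break
        best = level.pop()
    return best


def _ancestor_at_rank(tree: TaxonomyTree, taxon_id: int, rank: str) -> int | None:
    cur = taxon_id
    while True:
        if tree.rank(cur) == rank:
            return cur
        if cur == tree.root_id:
            return None
        cur = tree.parent(cur)  # "no rank" nodes are transparent


def rollup(
    counts: Mapping[int, float], tree: TaxonomyTree, rank: str
) -> dict[int | str, float]:
    """Aggregate fractional per-taxon counts up to the requested rank.

    Counts on taxa with no ancestor at that rank accumulate under the
    reserved ``"unranked"`` key.  Fractional counts (from tie-splitting)
    flow through unchanged, so total mass is conserved exactly.
    """
    ranks = {r for _pid, r, _n in tree.nodes.values()}
    if rank not in ranks:
        raise ValueError(f"unknown rank {rank!r}; tree has ranks {sorted(ranks)}")
    out: dict[int | str, float] = {}
    for tid, c in counts.items():
        if tid not in tree:
            raise KeyError(f"unknown taxon_id {tid}")
        anc = _ancestor_at_rank(tree, tid, rank)
        key: int | str = anc if anc is not None else UNRANKED
        out[key] = out.get(key, 0.0) + c
    return out


def export_lineages(tree: TaxonomyTree, path: str | Path) -> None:
    """Write one TSV row per taxon: id, rank, name, semicolon-joined lineage names."""
    with open(path, "w") as fh:
        fh.write("taxon_id\trank\tname\tlineage\n")
        for tid in sorted(tree.nodes):
            chain = ";".join(tree.name(t) for t, _r in lineage(tree, tid))
            fh.write(f"{tid}\t{tree.rank(tid)}\t{tree.name(tid)}\t{chain}\n")
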