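"""Deterministic fixtures: reference panels, taxonomies, trees, and reads.

This module is the desk-scale stand-in for a real reference database and a
real sequencing run.  It builds 16S-like reference panels with controlled
divergence structure (every species embeds realizations of both the V1-9
and V3-4 primer cores at canonical positions, so every species is
amplifiable), a matching NCBI-style taxonomy and phylogeny, and simulates
nanopore-style reads with substitution/insertion/deletion errors and
plausible per-base qualities, recording full ground truth per read.

Everything is reproducible from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import skbio

from .amplicon import PRIMER_SETS, in_silico_pcr, reverse_complement
from .classifier import ReferenceDB
from .sequence_io import ReadRecord, TaxonomyTree, parse_newick

__all__ = [
    "ErrorModel",
    "MockTruth",
    "make_reference_fixture",
    "make_v34_confusable_pair",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))

#: Scaffold geometry (bp): a ~1550-bp 16S-like gene with the V1-9 forward
#: core at the 5' end, the V3-4 cores at the canonical ~341/~805 positions,
#: and the V1-9 reverse core at the 3' end.  The V1-9 amplicon is the whole
#: scaffold (1550 bp, inside the 1300-1950 filter window); the V3-4 amplicon
#: spans 340..805 (465 bp, inside 350-600).
SCAFFOLD_LEN = 1550
_V34_FWD_POS = 340
_V34_REV_END = 805


@dataclass(frozen=True)
class ErrorModel:
    """Per-base nanopore-style error model with quality emission means."""

    p_sub: float = 0.03
    p_ins: float = 0.02
    p_del: float = 0.03
    quality_mean_match: float = 14.0
    quality_mean_error: float = 8.0

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0 <= p < 1:
                raise ValueError("error probabilities must be in [0, 1)")
        if self.p_sub + self.p_ins + self.p_del >= 0.5:
            raise ValueError("total error rate must stay below 0.5")


@dataclass
class MockTruth:
    """Ground truth per simulated read: source taxon and error counts."""

    entries: dict[str, tuple[int, int, int, int]]  # read_id -> (taxon, n_sub, n_ins, n_del)

    def taxon_of(self, read_id: str) -> int:
        return self.entries[read_id][0]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttaxon_id\tn_sub\tn_ins\tn_del\n")
            for rid, (taxon, ns, ni, nd) in self.entries.items():
                fh.write(f"{rid}\t{taxon}\t{ns}\t{ni}\t{nd}\n")


def _realize_core(core: str) -> str:
    """Fix each degenerate position to the lexicographically first allowed base."""
    from .amplicon import IUPAC

    return "".join(min(IUPAC[c]) for c in core)


def _scaffold(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random 16S-like scaffold with primer-core realizations embedded.

    Returns (sequence array of single chars, boolean protected-position mask).
    """
    seq = rng.choice(_BASES, size=SCAFFOLD_LEN)
    protected = np.zeros(SCAFFOLD_LEN, dtype=bool)

    def _embed(s: str, start: int) -> None:
        seq[start : start + len(s)] = list(s)
        protected[start : start + len(s)] = True

    v19, v34 = PRIMER_SETS["V1-9"], PRIMER_SETS["V3-4"]
    _embed(_realize_core(v19.fwd_core), 0)
    _embed(_realize_core(v34.fwd_core), _V34_FWD_POS)
    rc34 = reverse_complement(_realize_core(v34.rev_core))
    _embed(rc34, _V34_REV_END - len(rc34))
    rc19 = reverse_complement(_realize_core(v19.rev_core))
    _embed(rc19, SCAFFOLD_LEN - len(rc19))
    return seq, protected


def _mutate_at(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Return a copy with each listed position changed to a different base."""
    out = seq.copy()
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return out


def _build_taxonomy(genus_names: list[str], species: dict[str, list[str]]) -> TaxonomyTree:
    nodes: dict[int, tuple[int, str, str]] = {1: (1, "no rank", "root")}
    gid = {g: 100 + i for i, g in enumerate(genus_names, start=1)}
    sid_counter = 1000
    for g in genus_names:
        nodes[gid[g]] = (1, "genus", g)
        for s in species[g]:
            sid_counter += 1
            nodes[sid_counter] = (gid[g], "species", s)
    return TaxonomyTree(nodes=nodes, root_id=1)


def _species_ids(tree: TaxonomyTree) -> dict[str, int]:
    return {name: tid for tid, (_p, rank, name) in tree.nodes.items() if rank == "species"}


def _build_tree(
    genus_names: list[str],
    species: dict[str, list[str]],
    inter: float,
    intra: float,
) -> skbio.TreeNode:
    clades = []
    for g in genus_names:
        # labels are quoted so underscores survive newick parsing verbatim
        tips = ",".join(f"'{s}':{intra / 2}" for s in species[g])
        clades.append(f"({tips})'{g}':{inter / 2}")
    return parse_newick(f"({','.join(clades)})root;")


def make_reference_fixture(
    n_genera: int = 10,
    species_per_genus: int = 1,
    seed: int = 0,
    inter_genus_div: float = 0.15,
    intra_genus_div: float = 0.02,
) -> tuple[ReferenceDB, TaxonomyTree, skbio.TreeNode]:
    """Build a reference panel with controlled divergence structure.

    Each genus ancestor is the shared scaffold mutated at its own disjoint
    set of positions (mutations never touch the primer cores), so realized
    pairwise inter-genus divergence equals ``inter_genus_div`` by
    construction; species within a genus diverge analogously at
    ``intra_genus_div``.  The taxonomy is root -> genus -> species and the
    tree's leaf-to-leaf path lengths equal the generating divergences.
    """
    if not (0 < intra_genus_div < inter_genus_div < 0.5):
        raise ValueError("require 0 < intra_genus_div < inter_genus_div < 0.5")
    rng = np.random.default_rng(seed)
    base, protected = _scaffold(rng)
    mutable = np.nonzero(~protected)[0]

    m_genus = round(inter_genus_div / 2 * SCAFFOLD_LEN)
    m_species = round(intra_genus_div / 2 * SCAFFOLD_LEN)
    need = n_genera * (m_genus + species_per_genus * m_species)
    if need > len(mutable):
        raise ValueError(
            f"divergence targets need {need} disjoint mutable positions, "
            f"only {len(mutable)} available; lower the divergences or counts"
        )
    order = rng.permutation(mutable)
    cursor = 0

    genus_names = [f"Genus{i:02d}" for i in range(1, n_genera + 1)]
    species: dict[str, list[str]] = {}
    seqs: dict[str, str] = {}
    for g in genus_names:
        g_positions = order[cursor : cursor + m_genus]
        cursor += m_genus
        ancestor = _mutate_at(base, g_positions, rng)
        species[g] = []
        for s_idx in range(1, species_per_genus + 1):
            s_positions = order[cursor : cursor + m_species]
            cursor += m_species
            name = f"{g}_sp{s_idx}"
            species[g].append(name)
            seqs[name] = "".join(_mutate_at(ancestor, s_positions, rng))

    tax = _build_taxonomy(genus_names, species)
    ids = _species_ids(tax)
    refdb = ReferenceDB({f"ref_{name}": (seq, ids[name]) for name, seq in seqs.items()})
    tree = _build_tree(genus_names, species, inter_genus_div, intra_genus_div)
    return refdb, tax, tree


def make_v34_confusable_pair(seed: int = 0) -> tuple[ReferenceDB, TaxonomyTree, skbio.TreeNode]:
    """Two congeneric species identical over the V3-4 amplicon span but
    >= 5% divergent over the full V1-9 span.

    This reproduces the resolution gap between short and full-length 16S
    amplicons: V3-4 reads from either species tie exactly between the two,
    while V1-9 reads carry enough signal outside V3-4 to pick the true one.
    """
    rng = np.random.default_rng(seed)
    base, protected = _scaffold(rng)
    sp1 = base
    outside_v34 = np.ones(SCAFFOLD_LEN, dtype=bool)
    outside_v34[_V34_FWD_POS:_V34_REV_END] = False
    candidates = np.nonzero(outside_v34 & ~protected)[0]
    n_mut = math.ceil(0.06 * SCAFFOLD_LEN)  # > 5% of the V1-9 span
    positions = rng.choice(candidates, size=n_mut, replace=False)
    sp2 = _mutate_at(sp1, positions, rng)

    genus = ["Genus01"]
    species = {"Genus01": ["Genus01_spA", "Genus01_spB"]}
    tax = _build_taxonomy(genus, species)
    ids = _species_ids(tax)
    refdb = ReferenceDB(
        {
            "ref_Genus01_spA": ("".join(sp1), ids["Genus01_spA"]),
            "ref_Genus01_spB": ("".join(sp2), ids["Genus01_spB"]),
        }
    )
    div = n_mut / SCAFFOLD_LEN
    tree = _build_tree(genus, species, 0.15, div)
    return refdb, tax, tree


def _amplicon_for(refdb: ReferenceDB, taxon: int, region: str) -> str:
    primers = PRIMER_SETS[region]
    for rid, (seq, t) in refdb.refs.items():
        if t == taxon:
            products = in_silico_pcr(seq, primers, template_id=rid)
            if not products:
                raise ValueError(f"no {region} amplicon for taxon {taxon} (reference {rid})")
            return products[0].product_seq
    raise ValueError(f"taxon {taxon} not present in reference database")


def _apply_errors(
    template: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int, int, int]:
    """Apply per-base errors; returns (bases, is_error flags, n_sub, n_ins, n_del)."""
    L = len(template)
    u = rng.random(L)
    sub = u < model.p_sub
    ins = (u >= model.p_sub) & (u < model.p_sub + model.p_ins)
    dele = (u >= model.p_sub + model.p_ins) & (u < model.p_sub + model.p_ins + model.p_del)

    out: list[str] = []
    err: list[bool] = []
    shift = rng.integers(1, 4, size=L)  # substitution offset in base ring
    ins_base = rng.integers(0, 4, size=L)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(L):
        if dele[i]:
            continue
        b = template[i]
        if sub[i]:
            out.append(_BASES[(base_idx[b] + shift[i]) % 4])
            err.append(True)
        else:
            out.append(b)
            err.append(False)
        if ins[i]:
            out.append(_BASES[ins_base[i]])
            err.append(True)
    return (
        np.array(out) if out else np.empty(0, dtype="<U1"),
        np.array(err, dtype=bool),
        int(sub.sum()),
        int(ins.sum()),
        int(dele.sum()),
    )


def simulate_reads(
    refdb: ReferenceDB,
    abundances: dict[int, float],
    n_reads: int,
    region: str = "V1-9",
    model: ErrorModel = ErrorModel(),
    seed: int = 0,
) -> tuple[list[ReadRecord], MockTruth]:
    """Simulate nanopore-style amplicon reads from a reference panel.

    Each read draws its source taxon from ``abundances``, takes that
    species' region amplicon as template (random strand), applies the error
    model base by base, and emits qualities whose means are lower at error
    positions than at match positions.  Ground truth (source taxon and
    error counts) is recorded for every read.
    """
    if abs(sum(abundances.values()) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    region = region.upper()
    taxa = sorted(abundances)
    probs = np.array([abundances[t] for t in taxa])
    templates = {t: np.array(list(_amplicon_for(refdb, t, region))) for t in taxa}

    rng = np.random.default_rng(seed)
    picks = rng.choice(len(taxa), size=n_reads, p=probs)
    flips = rng.random(n_reads) < 0.5

    reads: list[ReadRecord] = []
    entries: dict[str, tuple[int, int, int, int]] = {}
    for i in range(n_reads):
        taxon = taxa[picks[i]]
        bases, err, ns, ni, nd = _apply_errors(templates[taxon], model, rng)
        mu = np.where(err, model.quality_mean_error, model.quality_mean_match)
        quals = np.clip(np.round(rng.normal(mu, 3.0)), 2, 40).astype(int)
        seq = "".join(bases)
        if flips[i]:
            seq = reverse_complement(seq)
            quals = quals[::-1]
        rid = f"read_{i:05d}"
        reads.append(ReadRecord(rid, seq, tuple(int(q) for q in quals)))
        entries[rid] = (taxon, ns, ni, nd)
    return reads, MockTruth(entries)
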