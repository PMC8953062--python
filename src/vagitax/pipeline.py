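"""End-to-end orchestration: filter -> host screen -> subsample -> classify
-> composition, and cohort-level UniFrac/PCoA.

Stage order follows the sequencing workflow: quality/length filtering and
repeat masking first, then human-read elimination, then random subsampling
to the working read depth (subsampling before alignment avoids wasting
alignment work), then best-hit classification and composition reporting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import skbio

from . import sequence_io
from .classifier import ReadAssignment, ReferenceDB, classify_batch, export_assignments, screen_host
from .diversity import DistanceMatrix, PcoaResult, distance_matrix, pcoa
from .profile import (
    OTHERS,
    UNCLASSIFIED,
    UNRANKED,
    SampleProfile,
    apply_minor_grouping,
    composition,
    shannon,
    write_krona,
    write_profile_tsv,
)
from .read_filter import FilterResult, RegionWindow, filter_reads, retention_percent, subsample
from .sequence_io import TaxonomyTree, read_fastq

__all__ = ["RunConfig", "run_sample", "run_cohort", "load_reference_db"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    region: str = "V1-9"
    min_q: float = 7.0
    min_len: int | None = None  # window overrides; None = region default
    max_len: int | None = None
    subsample_n: int = 3000
    seed: int = 0
    mode: str = "builtin"  # {builtin, paf}
    ref_fasta: str | None = None
    ref_map: str | None = None  # TSV: ref_id <TAB> taxon_id
    nodes_path: str | None = None
    names_path: str | None = None
    host_fasta: str | None = None
    paf_path: str | None = None
    min_score_frac: float = 0.4
    min_host_score_frac: float = 0.5
    others_threshold: float = 0.01
    rank: str = "species"
    output_dir: str = "."

    def window(self) -> RegionWindow:
        w = RegionWindow.for_region(self.region)
        if self.min_len is not None or self.max_len is not None:
            w = RegionWindow(w.region, self.min_len or w.min_len, self.max_len or w.max_len)
        return w

    def validate_paths(self) -> None:
        for name in ("ref_fasta", "ref_map", "nodes_path", "names_path", "host_fasta", "paf_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p!r} does not exist")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def load_reference_db(fasta_path: str | Path, map_path: str | Path) -> ReferenceDB:
    """Load a reference panel from FASTA plus a ``ref_id -> taxon_id`` TSV."""
    seqs = sequence_io.read_fasta(fasta_path)
    mapping: dict[str, int] = {}
    with open(map_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            rid, taxon = line.split("\t")[:2]
            mapping[rid.strip()] = int(taxon)
    missing = sorted(set(seqs) - set(mapping))
    if missing:
        raise ValueError(f"references without a taxon mapping: {missing}")
    return ReferenceDB({rid: (seq, mapping[rid]) for rid, seq in seqs.items()})


def _write_stats(
    path: Path,
    sample_id: str,
    config: RunConfig,
    fr: FilterResult,
    n_host: int,
    n_subsampled: int,
    assignments: list[ReadAssignment] | None,
) -> None:
    import numpy as np

    kept_lens = [len(r) for r in fr.kept]
    n_classified = sum(a.outcome == "classified" for a in assignments) if assignments else 0
    n_unclassified = sum(a.outcome == "unclassified" for a in assignments) if assignments else 0
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        fh.write(
            "sample\tregion\tpass_reads\tfiltered_reads\tretention_pct\t"
            "filtered_min_bp\tfiltered_avg_bp\tfiltered_max_bp\t"
            "fail_quality\tfail_length\tfail_masked\t"
            "host_reads\tsubsampled_reads\tclassified\tunclassified\n"
        )
        ret = retention_percent(fr) if fr.n_input else 0.0
        lo = min(kept_lens) if kept_lens else 0
        hi = max(kept_lens) if kept_lens else 0
        avg = float(np.mean(kept_lens)) if kept_lens else 0.0
        fh.write(
            f"{sample_id}\t{config.region}\t{fr.n_input}\t{fr.n_kept}\t{ret}\t"
            f"{lo}\t{avg:.1f}\t{hi}\t"
            f"{fr.n_fail_quality}\t{fr.n_fail_length}\t{fr.n_fail_masked}\t"
            f"{n_host}\t{n_subsampled}\t{n_classified}\t{n_unclassified}\n"
        )


def run_sample(
    config: RunConfig,
    fastq_path: str | Path,
    *,
    sample_id: str | None = None,
    refdb: ReferenceDB | None = None,
    host_db: ReferenceDB | None = None,
    tree: TaxonomyTree | None = None,
) -> tuple[FilterResult, SampleProfile, dict[str, Path]]:
    """Run the full single-sample pipeline and write report files.

    Reference/host panels and the taxonomy may be passed as objects or via
    config paths.  Outputs (stats TSV, profile TSV, Krona text, assignment
    TSV) go under ``config.output_dir``.  Raises on an empty post-filter
    pool after writing the stats sidecar.
    """
    config.validate_paths()
    if refdb is None:
        if config.ref_fasta is None or config.ref_map is None:
            raise ValueError("no reference database: pass refdb or set ref_fasta/ref_map")
        refdb = load_reference_db(config.ref_fasta, config.ref_map)
    if tree is None:
        if config.nodes_path is None or config.names_path is None:
            raise ValueError("no taxonomy: pass tree or set nodes_path/names_path")
        tree = sequence_io.load_taxonomy(config.nodes_path, config.names_path)
    if host_db is None and config.host_fasta is not None:
        host_seqs = sequence_io.read_fasta(config.host_fasta)
        host_db = ReferenceDB({rid: (seq, 1) for rid, seq in host_seqs.items()}) if host_seqs else None

    sample_id = sample_id or Path(fastq_path).stem
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stats": outdir / f"{sample_id}.stats.tsv",
        "profile": outdir / f"{sample_id}.profile.tsv",
        "krona": outdir / f"{sample_id}.krona.txt",
        "assignments": outdir / f"{sample_id}.assignments.tsv",
    }

    records = read_fastq(fastq_path)
    fr = filter_reads(records, config.window(), config.min_q)
    logger.info("%s: %d/%d reads pass filtering", sample_id, fr.n_kept, fr.n_input)
    if fr.n_kept == 0:
        _write_stats(paths["stats"], sample_id, config, fr, 0, 0, None)
        raise RuntimeError(f"{sample_id}: no reads survive filtering; partial stats written")

    host_reads, clean = screen_host(fr.kept, host_db, config.min_host_score_frac)
    logger.info("%s: %d host reads removed, %d remain", sample_id, len(host_reads), len(clean))

    pool = subsample(clean, config.subsample_n, config.seed)
    logger.info("%s: %d reads subsampled for classification", sample_id, len(pool))

    alignments = None
    if config.mode == "paf":
        if config.paf_path is None:
            raise ValueError("mode 'paf' requires paf_path")
        alignments = sequence_io.read_paf(config.paf_path)
    assignments = classify_batch(
        pool, refdb, tree, config.min_score_frac, alignments=alignments
    )

    profile = composition(assignments, tree, config.rank, sample_id=sample_id)
    grouped = apply_minor_grouping(profile, config.others_threshold)

    _write_stats(paths["stats"], sample_id, config, fr, len(host_reads), len(pool), assignments)
    write_profile_tsv(grouped, paths["profile"])
    counts: dict[int, float] = {}
    for a in assignments:
        for t, w in a.weights.items():
            counts[t] = counts.get(t, 0.0) + w
    write_krona(counts, tree, paths["krona"])
    export_assignments(assignments, paths["assignments"])
    logger.info("%s: Shannon H = %.3f (ungrouped, %s rank)", sample_id, shannon(profile), config.rank)
    return fr, grouped, paths


def run_cohort(
    config: RunConfig,
    fastq_paths: dict[str, str | Path],
    phylo_tree: skbio.TreeNode,
    *,
    refdb: ReferenceDB | None = None,
    host_db: ReferenceDB | None = None,
    tree: TaxonomyTree | None = None,
    normalized: bool = True,
) -> tuple[DistanceMatrix, PcoaResult, dict[str, SampleProfile]]:
    """Run every sample, then weighted UniFrac + PCoA across the cohort.

    Profiles are stripped of their unclassified/Others bins and renormalized
    before UniFrac (those bins have no tree placement).  Writes the distance
    matrix and PCoA coordinate TSVs under the output directory.
    """
    if len(fastq_paths) < 2:
        raise ValueError("cohort analysis needs at least 2 samples")
    profiles: dict[str, SampleProfile] = {}
    for sid, fq in fastq_paths.items():
        _fr, prof, _paths = run_sample(
            config, fq, sample_id=sid, refdb=refdb, host_db=host_db, tree=tree
        )
        profiles[sid] = prof

    tree_profiles = []
    for sid, prof in profiles.items():
        clean = {
            t: p
            for t, p in prof.abundances.items()
            if t not in (UNCLASSIFIED, OTHERS, UNRANKED) and p > 0
        }
        total = sum(clean.values())
        if total == 0:
            raise RuntimeError(f"{sid}: no classified taxa for UniFrac")
        tree_profiles.append(
            SampleProfile(sid, {t: p / total for t, p in clean.items()}, prof.n_reads_used)
        )

    dm = distance_matrix(tree_profiles, phylo_tree, normalized)
    result = pcoa(dm, n_axes=2)
    outdir = Path(config.output_dir)
    dm.to_tsv(outdir / "unifrac_distances.tsv")
    result.to_tsv(dm.labels, outdir / "pcoa_coordinates.tsv")
    return dm, result, profiles
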