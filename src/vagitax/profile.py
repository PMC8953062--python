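"""Per-sample composition tables, Shannon diversity, Nugent categorization,
and run-level statistics (retention arithmetic, time-to-N-reads prediction).

A :class:`SampleProfile` is a fractional abundance vector over taxon labels,
including reserved ``"unclassified"`` and ``"Others"`` bins, that always
sums to 1.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import ReadAssignment
from .sequence_io import TaxonomyTree
from .taxonomy import UNRANKED, lineage, rollup

__all__ = [
    "SampleProfile",
    "NugentInput",
    "composition",
    "apply_minor_grouping",
    "shannon",
    "nugent_category",
    "time_to_reads",
    "load_run_stats",
    "write_profile_tsv",
    "write_krona",
    "OTHERS",
    "UNCLASSIFIED",
]

logger = logging.getLogger(__name__)

OTHERS = "Others"
UNCLASSIFIED = "unclassified"


@dataclass
class SampleProfile:
    """Fractional per-taxon abundances for one sample; sums to 1."""

    sample_id: str
    abundances: dict[str, float]
    n_reads_used: int

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if self.abundances and abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile fractions sum to {total}, expected 1")
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("profile fractions must be non-negative")


@dataclass(frozen=True)
class NugentInput:
    """Gram-stain morphotype subscores for Nugent scoring."""

    lactobacillus_score: int
    gardnerella_score: int
    mobiluncus_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.lactobacillus_score <= 4:
            raise ValueError("Lactobacillus subscore must be in 0..4")
        if not 0 <= self.gardnerella_score <= 4:
            raise ValueError("Gardnerella subscore must be in 0..4")
        if not 0 <= self.mobiluncus_score <= 2:
            raise ValueError("Mobiluncus subscore must be in 0..2")

    @property
    def total(self) -> int:
        return self.lactobacillus_score + self.gardnerella_score + self.mobiluncus_score


def composition(
    assignments: Sequence[ReadAssignment],
    tree: TaxonomyTree,
    rank: str = "species",
    *,
    sample_id: str = "sample",
    include_unclassified: bool = True,
) -> SampleProfile:
    """Build a fractional composition profile from read assignments.

    Fractional tie weights are summed per taxon, rolled up to ``rank``, and
    divided by the total classified (+ unclassified, by default) weight.
    Unclassified reads form their own labelled bin; host reads should be
    removed upstream and are ignored here.
    """
    counts: dict[int, float] = {}
    n_unclassified = 0
    n_used = 0
    for a in assignments:
        if a.outcome == "host":
            continue
        n_used += 1
        if a.outcome == "unclassified":
            n_unclassified += 1
            continue
        for taxon, w in a.weights.items():
            counts[taxon] = counts.get(taxon, 0.0) + w

    classified_mass = sum(counts.values())
    if classified_mass == 0:
        logger.warning("composition: zero classified reads in %s", sample_id)
        return SampleProfile(sample_id, {UNCLASSIFIED: 1.0} if n_used else {}, n_used)

    rolled = rollup(counts, tree, rank)
    denom = classified_mass + (n_unclassified if include_unclassified else 0)
    abundances: dict[str, float] = {}
    for key, c in rolled.items():
        label = tree.name(key) if isinstance(key, int) else UNRANKED
        abundances[label] = abundances.get(label, 0.0) + c / denom
    if include_unclassified and n_unclassified:
        abundances[UNCLASSIFIED] = n_unclassified / denom
    return SampleProfile(sample_id, abundances, n_used)


def apply_minor_grouping(profile: SampleProfile, threshold: float = 0.01) -> SampleProfile:
    """Merge taxa below ``threshold`` (strict) into an ``"Others"`` bin.

    The ``"unclassified"`` bin is not a bacterial assignment and is never
    merged.  Total mass is conserved.
    """
    kept: dict[str, float] = {}
    others = 0.0
    for label, p in profile.abundances.items():
        if label != UNCLASSIFIED and p < threshold:
            others += p
        else:
            kept[label] = p
    if others > 0:
        kept[OTHERS] = kept.get(OTHERS, 0.0) + others
    return SampleProfile(profile.sample_id, kept, profile.n_reads_used)


def shannon(profile: SampleProfile) -> float:
    """Shannon diversity H = -sum p_i ln p_i over the profile's bins (natural log).

    All bins with p > 0 are included exactly as listed in the profile handed
    in; pass an un-grouped profile to avoid the distortion minor-grouping
    introduces.
    """
    p = np.array([v for v in profile.abundances.values() if v > 0])
    return float(-(p * np.log(p)).sum())


def nugent_category(score: NugentInput) -> str:
    """Nugent interpretation: total 0-3 healthy, 4-6 intermediate, >= 7 BV."""
    total = score.total
    if total <= 3:
        return "healthy"
    if total <= 6:
        return "intermediate"
    return "BV"


def time_to_reads(
    filtered_counts: Sequence[int], session_minutes: float = 90.0, target_reads: int = 3000
) -> int:
    """Minutes (nearest integer) to accumulate ``target_reads`` filtered reads.

    Uses the median per-session filtered-read count as the rate estimate:
    ``rate = median / session_minutes``, prediction ``target / rate``.
    """
    if not filtered_counts:
        raise ValueError("filtered_counts must be non-empty")
    if session_minutes <= 0:
        raise ValueError("session_minutes must be positive")
    med = float(np.median(np.asarray(filtered_counts, dtype=float)))
    if med == 0:
        raise ValueError("median filtered-read count is zero; rate undefined")
    rate = med / session_minutes
    return int(round(target_reads / rate))


def load_run_stats() -> pd.DataFrame:
    """Bundled per-sample MinION run statistics from a published full-length
    16S vaginal-microbiota feasibility study (18 lavage + 4 swab V1-9 runs
    and 6 V3-4 runs): pass-read counts and lengths, filtered-read counts and
    lengths, and printed retention percentages.
    """
    with importlib.resources.files("vagitax.data").joinpath("minion_run_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_profile_tsv(profile: SampleProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tfraction\tn_reads_used\n")
        for label in sorted(profile.abundances, key=lambda k: -profile.abundances[k]):
            fh.write(f"{label}\t{profile.abundances[label]:.6f}\t{profile.n_reads_used}\n")


def write_krona(counts: dict[int, float], tree: TaxonomyTree, path: str | Path) -> None:
    """Krona two-column text: count TAB tab-separated lineage names."""
    with open(path, "w") as fh:
        for taxon in sorted(counts):
            chain = [tree.name(t) for t, _r in lineage(tree, taxon)]
            fh.write(f"{counts[taxon]:g}\t" + "\t".join(chain) + "\n")
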