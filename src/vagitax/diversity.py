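"""Weighted UniFrac distances and classical PCoA ordination.

Weighted UniFrac weights every branch of a rooted tree by the absolute
difference in the fraction of each community descending from it; the
normalized variant divides by the abundance-weighted root-to-leaf depth sum,
bounding the distance to [0, 1].  PCoA is classical metric scaling: double-
center the squared distance matrix and eigendecompose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import skbio
from scipy.linalg import eigh
from skbio.diversity.beta import weighted_unifrac as _skbio_weighted_unifrac

from .profile import OTHERS, UNCLASSIFIED, SampleProfile

__all__ = ["DistanceMatrix", "PcoaResult", "weighted_unifrac", "distance_matrix", "pcoa"]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]) + "\n")


@dataclass
class PcoaResult:
    """Classical-scaling embedding: coordinates, eigenvalues, explained fractions."""

    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # full spectrum, non-increasing (negatives reported)
    proportion_explained: np.ndarray  # per returned axis

    def to_tsv(self, labels: Sequence[str], path: str | Path) -> None:
        n_axes = self.coordinates.shape[1]
        with open(path, "w") as fh:
            fh.write("# eigenvalues: " + " ".join(f"{e:.6g}" for e in self.eigenvalues) + "\n")
            fh.write(
                "# proportion_explained: "
                + " ".join(f"{p:.6g}" for p in self.proportion_explained)
                + "\n"
            )
            fh.write("sample\t" + "\t".join(f"axis{i + 1}" for i in range(n_axes)) + "\n")
            for lab, row in zip(labels, self.coordinates):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def _profile_vector(profile: SampleProfile, taxa: list[str]) -> np.ndarray:
    return np.array([profile.abundances.get(t, 0.0) for t in taxa])


def weighted_unifrac(
    tree: skbio.TreeNode,
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two profiles over a shared rooted tree.

    Every profile taxon (other than the reserved Others/unclassified bins,
    which have no phylogenetic placement and are rejected) must be a tree
    leaf.  Raw variant: sum over branches of length x |P_A - P_B| of the
    descending fractions; normalized divides by sum_j d_j (p_Aj + p_Bj) with
    d_j the root-to-leaf depth.
    """
    tip_names = {t.name for t in tree.tips()}
    for prof in (profile_a, profile_b):
        missing = sorted(
            t for t, p in prof.abundances.items() if p > 0 and t not in tip_names
        )
        if missing:
            raise ValueError(
                f"profile {prof.sample_id!r} has taxa absent from the tree: {missing} "
                f"(strip {OTHERS!r}/{UNCLASSIFIED!r} bins and renormalize first)"
            )
    taxa = sorted(
        {t for t, p in profile_a.abundances.items() if p > 0}
        | {t for t, p in profile_b.abundances.items() if p > 0}
    )
    # Weighted UniFrac is invariant to scaling a sample's counts, and the
    # backend truncates counts to integers, so fractions are rescaled to
    # large integer counts (relative error <= 5e-10 per taxon).
    u = np.round(_profile_vector(profile_a, taxa) * 1e9)
    v = np.round(_profile_vector(profile_b, taxa) * 1e9)
    # validate=False: taxonomy-derived trees legitimately multifurcate at the
    # root, which skbio's validator rejects; taxon/leaf checks are done above.
    return float(_skbio_weighted_unifrac(u, v, taxa, tree, normalized=normalized, validate=False))


def distance_matrix(
    profiles: Sequence[SampleProfile], tree: skbio.TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over two or more profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for a distance matrix")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = weighted_unifrac(tree, profiles[i], profiles[j], normalized)
    return DistanceMatrix([p.sample_id for p in profiles], d)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    B = -1/2 J D^2 J with J the centering operator; coordinates are
    eigenvectors scaled by sqrt(eigenvalue).  Negative eigenvalues (non-
    Euclidean distortion) are reported in ``eigenvalues`` but treated as
    zero for coordinate scaling and the explained-proportion denominator.
    """
    D = dm.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos = np.clip(evals, 0, None)
    rank = int((pos > 1e-10 * max(pos.max(), 1.0)).sum())
    if n_axes > rank:
        logger.warning("pcoa: requested %d axes but rank is %d; extra axes are zero", n_axes, rank)
    n_axes = min(n_axes, n)
    coords = evecs[:, :n_axes] * np.sqrt(pos[:n_axes])
    total = pos.sum()
    prop = pos[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return PcoaResult(coordinates=coords, eigenvalues=evals, proportion_explained=prop)
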