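"""IUPAC-degenerate primer matching and in-silico PCR.

Ships the two primer sets used for full-length (V1-9, 27F/1492R-style cores
with anchor tails, ~1.6 kb products) and short (V3-4, 341F/805R cores,
~0.4-0.5 kb products) 16S rRNA amplification.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PrimerSet",
    "PcrProduct",
    "PRIMER_SETS",
    "iupac_matches",
    "reverse_complement",
    "in_silico_pcr",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class PrimerSet:
    """Inner primer pair: degenerate cores plus plain-DNA anchor tails."""

    name: str
    fwd_core: str
    rev_core: str
    fwd_anchor: str
    rev_anchor: str

    def __post_init__(self) -> None:
        if not self.fwd_core or not self.rev_core:
            raise ValueError("primer cores must be non-empty")


#: Built-in primer sets. Anchor + core reconstructs the full anchored inner
#: primers; the reverse core is given 5'->3' on the primer (i.e. it binds the
#: template as its reverse complement downstream of the forward site).
PRIMER_SETS = {
    "V1-9": PrimerSet(
        name="V1-9",
        fwd_core="AGRGTTYGATYMTGGCTCAG",
        rev_core="CGGYTACCTTGTTACGACTT",
        fwd_anchor="TTTCTGTTGGTGCTGATATTGC",
        rev_anchor="ACTTGCCTGTCGCTCTATCTTC",
    ),
    "V3-4": PrimerSet(
        name="V3-4",
        fwd_core="CCTACGGGNGGCWGCAG",
        rev_core="GGACTACHVGGGTWTCTAAT",
        fwd_anchor="TTTCTGTTGGTGCTGATATTGC",
        rev_anchor="ACTTGCCTGTCGCTCTATCTTC",
    ),
}


@dataclass(frozen=True)
class PcrProduct:
    """One amplification product; span is 0-based half-open on the template."""

    template_id: str
    product_seq: str
    span: tuple[int, int]
    length: int
    includes_anchors: bool


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(primer_base: str, template_base: str) -> bool:
    """True iff the template base is in the degenerate code's set."""
    try:
        allowed = IUPAC[primer_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {primer_base!r}") from None
    return template_base.upper() in allowed


def _mismatches(primer: str, window: str, limit: int) -> int:
    """Mismatch count of a degenerate primer against a plain window (early exit)."""
    n = 0
    for p, t in zip(primer, window):
        if t not in IUPAC[p]:
            n += 1
            if n > limit:
                return n
    return n


def _find_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    k = len(primer)
    return [
        i
        for i in range(len(template) - k + 1)
        if _mismatches(primer, template[i : i + k], max_mismatch) <= max_mismatch
    ]


def in_silico_pcr(
    template: str,
    primers: PrimerSet,
    max_mismatch: int = 3,
    with_anchors: bool = False,
    *,
    template_id: str = "template",
) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on one template (plus strand).

    The forward core is matched on the plus strand; the reverse core is
    matched as its reverse complement downstream.  Degenerate agreement never
    counts as a mismatch; up to ``max_mismatch`` mismatches are allowed per
    primer.  For each forward site only the minimal-length pairing is
    emitted (PCR favors the shortest product), and products never overlap.
    """
    template = template.upper()
    fwd_sites = _find_sites(template, primers.fwd_core, max_mismatch)
    rev_rc = reverse_complement(primers.rev_core)
    rev_sites = _find_sites(template, rev_rc, max_mismatch)
    products: list[PcrProduct] = []
    cursor = 0
    for f in fwd_sites:
        if f < cursor:
            continue
        fwd_end = f + len(primers.fwd_core)
        ends = [r + len(rev_rc) for r in rev_sites if r >= fwd_end]
        if not ends:
            continue
        end = min(ends)
        seq = template[f:end]
        if with_anchors:
            seq = primers.fwd_anchor + seq + reverse_complement(primers.rev_anchor)
        products.append(
            PcrProduct(
                template_id=template_id,
                product_seq=seq,
                span=(f, end),
                length=len(seq),
                includes_anchors=with_anchors,
            )
        )
        cursor = end
    return products
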