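"""Quality filtering, amplicon-length windows, repeat masking, subsampling.

The filter mirrors the pre-alignment stages of a full-length 16S nanopore
run: pass reads need a mean quality of at least 7 (error-probability
averaging, the basecaller's pass/fail convention), a length inside the
amplicon window (V1-9: 1300-1950 bp; V3-4: 350-600 bp, bounds inclusive),
and must not be mostly low-complexity after tandem-repeat masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import ReadRecord

__all__ = [
    "RegionWindow",
    "FilterResult",
    "mean_read_quality",
    "filter_reads",
    "retention_percent",
    "mask_low_complexity",
    "subsample",
]

logger = logging.getLogger(__name__)

#: Default length windows per amplified region (bp, closed intervals).
REGION_WINDOWS = {
    "V1-9": (1300, 1950),
    "V3-4": (350, 600),
}


@dataclass(frozen=True)
class RegionWindow:
    """Amplicon length window for one 16S region, bounds inclusive."""

    region: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")

    @classmethod
    def for_region(cls, region: str) -> "RegionWindow":
        key = region.upper().replace("V1-V9", "V1-9").replace("V3-V4", "V3-4")
        if key not in REGION_WINDOWS:
            raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGION_WINDOWS)}")
        lo, hi = REGION_WINDOWS[key]
        return cls(key, lo, hi)


@dataclass
class FilterResult:
    """Filtering outcome; the failure counts partition the input count."""

    kept: list[ReadRecord]
    n_input: int
    n_kept: int
    n_fail_quality: int
    n_fail_length: int
    n_fail_masked: int

    def __post_init__(self) -> None:
        total = self.n_kept + self.n_fail_quality + self.n_fail_length + self.n_fail_masked
        if total != self.n_input:
            raise ValueError("failure counts must partition n_input")


def mean_read_quality(record: ReadRecord) -> float:
    """Mean read quality on the Phred scale via error-probability averaging.

    Q_mean = -10 * log10( mean_i 10^(-q_i/10) ).  This is the platform's
    pass-read convention and is always <= the arithmetic mean of the q_i
    (Jensen's inequality).
    """
    if len(record) == 0:
        raise ValueError("mean quality of an empty read is undefined")
    q = np.asarray(record.quals, dtype=float)
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def mask_low_complexity(seq: str, *, max_period: int = 10, mask_min_run: int = 15) -> str:
    """Replace tandem repeats with N.

    A region is masked when it consists of a repeating unit of period 1 to
    ``max_period`` and spans at least ``mask_min_run`` bases.  Output length
    always equals input length and only N is ever introduced.  This is a
    greedy run detector, not a probabilistic repeat model: the pipeline needs
    repeat suppression ahead of alignment, not bit-compatibility with any
    particular masker.
    """
    n = len(seq)
    if n == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(n, dtype=bool)
    for p in range(1, max_period + 1):
        if n <= p:
            break
        eq = arr[p:] == arr[:-p]  # eq[i]: seq[i+p] == seq[i]
        # find maximal runs of consecutive equalities
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            span = (e - s) + p  # repeat region covers seq[s : s+p+(e-s)]
            if span >= mask_min_run:
                mask[s : s + span] = True
    if not mask.any():
        return seq
    out = arr.copy()
    out[mask] = ord("N")
    return out.tobytes().decode()


def filter_reads(
    records: list[ReadRecord],
    window: RegionWindow,
    min_q: float = 7.0,
    *,
    mask_discard_fraction: float = 0.9,
    mask: bool = True,
) -> FilterResult:
    """Apply quality, length, and low-complexity filters in that order.

    Rejection precedence is quality -> length -> mask so that category counts
    are deterministic.  Kept reads carry the masked (N-replaced) sequence,
    since masking precedes alignment downstream; a read that is at least
    ``mask_discard_fraction`` N after masking carries no taxonomic signal and
    is dropped.
    """
    kept: list[ReadRecord] = []
    n_q = n_len = n_mask = 0
    for rec in records:
        if mean_read_quality(rec) < min_q:
            n_q += 1
            continue
        if not (window.min_len <= len(rec) <= window.max_len):
            n_len += 1
            continue
        masked_seq = mask_low_complexity(rec.seq) if mask else rec.seq
        if len(masked_seq) > 0 and masked_seq.count("N") / len(masked_seq) >= mask_discard_fraction:
            n_mask += 1
            continue
        kept.append(ReadRecord(rec.read_id, masked_seq, rec.quals) if masked_seq != rec.seq else rec)
    return FilterResult(
        kept=kept,
        n_input=len(records),
        n_kept=len(kept),
        n_fail_quality=n_q,
        n_fail_length=n_len,
        n_fail_masked=n_mask,
    )


def retention_percent(result: FilterResult | tuple[int, int]) -> float:
    """Percentage of input reads retained, rounded to 1 decimal.

    Accepts either a FilterResult or a ``(n_kept, n_input)`` pair so that
    published pass/filtered read counts can be checked directly.
    """
    if isinstance(result, FilterResult):
        n_kept, n_input = result.n_kept, result.n_input
    else:
        n_kept, n_input = result
    if n_input <= 0:
        raise ValueError("retention undefined for zero input reads")
    return round(100.0 * n_kept / n_input, 1)


def subsample(records: list[ReadRecord], n: int = 3000, seed: int = 0) -> list[ReadRecord]:
    """Draw ``n`` reads uniformly without replacement, in draw order.

    The same seed always yields the same selection.  If the pool is smaller
    than ``n``, all reads are returned and a warning is logged.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if len(records) <= n:
        if len(records) < n:
            logger.warning("subsample: pool of %d < requested %d; returning all reads", len(records), n)
        return list(records)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in idx]
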