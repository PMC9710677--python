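"""Depth-normalized telomere content and tumour/normal ratios.

A raw telomeric read count means little on its own: a deeper-sequenced
sample contains more telomeric reads at the same telomere length.  The
estimate reported here is therefore

    scaled = raw_telomeric_reads * S / total_records

with S = 1e6 by default, i.e. *telomeric reads per million records*.  The
denominator is the total record count from the BAM index statistics
(mapped + unmapped, before any policy filtering), which is available
without a pass over the file.

For paired samples the headline statistic is

    log2_ratio = log2(scaled_tumour / scaled_normal)

which is 0 when tumour and normal have equal telomere content, positive for
telomere gain in the tumour and negative for loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pysam

from .scan import InputFileError, ScanReport

__all__ = [
    "SampleSummary",
    "TelomereEstimate",
    "PairRatio",
    "QuantificationError",
    "total_read_count",
    "scale_counts",
    "telomere_ratio",
    "summarize_sample",
]

DEFAULT_SCALING = 1_000_000.0


class QuantificationError(ValueError):
    """Raised for unscalable inputs (zero totals, zero-content ratios)."""


@dataclass(frozen=True)
class TelomereEstimate:
    """A depth-normalized telomere-content estimate for one sample."""

    raw_count: int
    total_records: int
    scaling: float
    scaled_count: float

    def to_dict(self) -> dict:
        return {
            "raw_count": self.raw_count,
            "total_records": self.total_records,
            "scaling": self.scaling,
            "scaled_count": self.scaled_count,
            "units": "telomeric reads per million records"
            if self.scaling == DEFAULT_SCALING
            else f"telomeric reads per {self.scaling:g} records",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TelomereEstimate":
        return cls(
            raw_count=d["raw_count"],
            total_records=d["total_records"],
            scaling=d["scaling"],
            scaled_count=d["scaled_count"],
        )


@dataclass(frozen=True)
class SampleSummary:
    """One sample's scan outcome plus the normalization denominator."""

    label: str
    total_records: int
    raw_telomeric: int
    report: Optional[ScanReport] = None

    def __post_init__(self):
        if self.raw_telomeric > self.total_records:
            raise QuantificationError(
                f"sample {self.label!r}: telomeric count ({self.raw_telomeric}) "
                f"exceeds total records ({self.total_records})"
            )


@dataclass(frozen=True)
class PairRatio:
    """log2 tumour/normal telomere-content ratio."""

    tumour: TelomereEstimate
    normal: TelomereEstimate
    log2_ratio: float

    def to_dict(self) -> dict:
        return {
            "tumour": self.tumour.to_dict(),
            "normal": self.normal.to_dict(),
            "log2_ratio": self.log2_ratio,
        }


def total_read_count(bam_path: str, strict: bool = False) -> int:
    """Total records (mapped + unmapped) in a BAM.

    Uses index statistics when an index is present — no pass over the file.
    Without an index, falls back to a counting pass (or raises when
    ``strict``).
    """
    try:
        bam = pysam.AlignmentFile(str(bam_path))
    except (OSError, ValueError) as exc:
        raise InputFileError(f"cannot open alignment file {bam_path}: {exc}") from exc
    with bam:
        if bam.has_index():
            # idxstats: per-reference mapped + placed-unmapped, plus the
            # no-coordinate block at the end of the file.
            return bam.mapped + bam.unmapped
        if strict:
            raise InputFileError(
                f"{bam_path} has no index and strict mode forbids a counting pass"
            )
        return sum(1 for _ in bam.fetch(until_eof=True))


def scale_counts(
    raw: int, total: int, scaling: float = DEFAULT_SCALING
) -> TelomereEstimate:
    """Normalize a raw telomeric read count by sequencing depth.

    ``scaled = raw * scaling / total``.  A zero total is an error, never an
    infinity.
    """
    if raw < 0:
        raise QuantificationError("raw count must be >= 0")
    if total <= 0:
        raise QuantificationError(
            "total record count must be > 0 to scale (empty or unindexed BAM?)"
        )
    if scaling <= 0:
        raise QuantificationError("scaling constant must be > 0")
    return TelomereEstimate(
        raw_count=raw,
        total_records=total,
        scaling=scaling,
        scaled_count=raw * scaling / total,
    )


def telomere_ratio(
    tumour: TelomereEstimate,
    normal: TelomereEstimate,
    pseudocount: float = 0.0,
) -> PairRatio:
    """log2 of the tumour/normal scaled-content ratio.

    Antisymmetric under swapping the two samples.  A zero scaled count on
    either side is an error naming the offending sample, unless a positive
    ``pseudocount`` is supplied (added to both scaled counts).
    """
    t = tumour.scaled_count + pseudocount
    n = normal.scaled_count + pseudocount
    if t <= 0 or n <= 0:
        zero = "tumour" if t <= 0 else "normal"
        raise QuantificationError(
            f"{zero} sample has zero telomeric content; "
            "cannot form a log ratio (consider a pseudocount)"
        )
    return PairRatio(tumour=tumour, normal=normal, log2_ratio=math.log2(t / n))


def summarize_sample(
    label: str,
    bam_path: str,
    report: ScanReport,
    scaling: float = DEFAULT_SCALING,
) -> tuple[SampleSummary, TelomereEstimate]:
    """Convenience: index-statistics total + scaled estimate for one scan."""
    total = total_read_count(bam_path)
    raw = report.telomeric_read_count
    summary = SampleSummary(
        label=label, total_records=total, raw_telomeric=raw, report=report
    )
    return summary, scale_counts(raw, total, scaling)
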