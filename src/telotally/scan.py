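"""Region-restricted BAM scanning and tally accumulation.

The scanner streams reads from a coordinate-sorted, indexed BAM in one of
two modes:

* **region mode** (default): only user-defined include regions — typically
  chromosome ends, where telomeric reads pile up — plus every unmapped read.
  This is what makes whole-genome telomere quantification fast: the vast
  majority of the file is never touched.
* **full scan**: every record in the file.  Mapped stage-2-passing reads
  that fall outside all include regions are tallied under a separate
  ``genomic`` category.  Full scan doubles as the validation oracle for
  region mode: restricted to the ``includes`` and ``unmapped`` categories
  the two modes must agree exactly.

Records are de-duplicated globally by identity (query name, flag, reference,
position), so a read overlapping two include regions is counted once,
attributed to the first containing region in (chromosome, start) order.
Placed-but-unmapped mates are handled exclusively by the unmapped stream and
are never double-counted through a region.
"""

from __future__ import annotations

import logging
from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

from .motifs import MotifSpec, build_motif_spec, classify_read

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "ReadFilterPolicy",
    "ReadRecord",
    "CategoryTally",
    "RegionTally",
    "ScanReport",
    "RegionError",
    "InputFileError",
    "load_regions",
    "regions_from_bed",
    "iterate_region_reads",
    "iterate_unmapped",
    "scan",
    "full_scan",
]

logger = logging.getLogger(__name__)


class RegionError(ValueError):
    """Raised for malformed or inconsistent region definitions."""


class InputFileError(RuntimeError):
    """Raised for missing/unreadable BAM input or a missing index."""


@dataclass(frozen=True)
class GenomicRegion:
    """A named 1-based inclusive genomic interval."""

    chromosome: str
    start: int
    end: int
    label: str
    category: str = "include"

    def __post_init__(self):
        if self.start < 1:
            raise RegionError(f"region {self.label!r}: start must be >= 1")
        if self.end < self.start:
            raise RegionError(
                f"region {self.label!r}: end ({self.end}) < start ({self.start})"
            )

    def overlaps(self, chromosome: str, start0: int, end0: int) -> bool:
        """Overlap with a 0-based half-open interval by >= 1 base."""
        return (
            chromosome == self.chromosome
            and start0 < self.end
            and end0 > self.start - 1
        )


class RegionSet:
    """An ordered collection of include regions.

    Regions are kept sorted by (chromosome, start, end); labels must be
    unique.  Overlapping regions are permitted (a read in the overlap is
    attributed to the first region in sorted order) but are logged.
    """

    def __init__(self, regions: Iterable[GenomicRegion]):
        regions = sorted(regions, key=lambda r: (r.chromosome, r.start, r.end))
        labels = [r.label for r in regions]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise RegionError(f"duplicate region labels: {sorted(dupes)}")
        for a, b in zip(regions, regions[1:]):
            if a.chromosome == b.chromosome and b.start <= a.end:
                logger.warning(
                    "regions %s and %s overlap on %s", a.label, b.label, a.chromosome
                )
        self._regions: tuple[GenomicRegion, ...] = tuple(regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __getitem__(self, i):
        return self._regions[i]

    def __eq__(self, other):
        return isinstance(other, RegionSet) and self._regions == other._regions

    def first_containing(
        self, chromosome: str, start0: int, end0: int
    ) -> Optional[GenomicRegion]:
        """First region (in sorted order) overlapping the 0-based half-open
        interval, or None."""
        for region in self._regions:
            if region.overlaps(chromosome, start0, end0):
                return region
        return None


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Which alignment records are excluded from tallies.

    All switches are explicit: duplicate-marked input is required precisely
    so PCR/optical duplicates can be dropped, and secondary/supplementary
    records would count the same template twice.
    """

    exclude_duplicates: bool
    exclude_secondary: bool
    exclude_supplementary: bool
    exclude_qcfail: bool
    min_read_length: int = 0

    @classmethod
    def default(cls) -> "ReadFilterPolicy":
        return cls(
            exclude_duplicates=True,
            exclude_secondary=True,
            exclude_supplementary=True,
            exclude_qcfail=True,
            min_read_length=0,
        )

    def retains(self, read: "ReadRecord") -> bool:
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if len(read.sequence or "") < self.min_read_length:
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "exclude_duplicates": self.exclude_duplicates,
            "exclude_secondary": self.exclude_secondary,
            "exclude_supplementary": self.exclude_supplementary,
            "exclude_qcfail": self.exclude_qcfail,
            "min_read_length": self.min_read_length,
        }


@dataclass(frozen=True)
class ReadRecord:
    """The minimal view of an alignment record the matcher needs."""

    query_name: str
    flag: int
    is_unmapped: bool
    is_duplicate: bool
    is_secondary: bool
    is_supplementary: bool
    is_qcfail: bool
    reference_name: Optional[str]
    position: Optional[int]  # 1-based leftmost, None if no coordinate
    sequence: str

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "ReadRecord":
        pos = rec.reference_start
        return cls(
            query_name=rec.query_name or "",
            flag=rec.flag,
            is_unmapped=rec.is_unmapped,
            is_duplicate=rec.is_duplicate,
            is_secondary=rec.is_secondary,
            is_supplementary=rec.is_supplementary,
            is_qcfail=rec.is_qcfail,
            reference_name=rec.reference_name if rec.reference_id >= 0 else None,
            position=pos + 1 if pos is not None and pos >= 0 else None,
            sequence=rec.query_sequence or "",
        )

    @property
    def identity(self) -> tuple:
        """De-duplication key: one physical record, one identity."""
        return (self.query_name, self.flag, self.reference_name, self.position)


@dataclass
class CategoryTally:
    """Counts for one read category (or one region)."""

    examined: int = 0
    filtered: int = 0
    stage1_passes: int = 0
    stage2_passes: int = 0

    def add(self, other: "CategoryTally") -> None:
        self.examined += other.examined
        self.filtered += other.filtered
        self.stage1_passes += other.stage1_passes
        self.stage2_passes += other.stage2_passes

    def to_dict(self) -> dict:
        return {
            "examined": self.examined,
            "filtered": self.filtered,
            "stage1_passes": self.stage1_passes,
            "stage2_passes": self.stage2_passes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryTally":
        return cls(
            examined=d["examined"],
            filtered=d["filtered"],
            stage1_passes=d["stage1_passes"],
            stage2_passes=d["stage2_passes"],
        )


@dataclass
class RegionTally:
    region: GenomicRegion
    tally: CategoryTally = field(default_factory=CategoryTally)

    def to_dict(self) -> dict:
        return {
            "label": self.region.label,
            "chromosome": self.region.chromosome,
            "start": self.region.start,
            "end": self.region.end,
            **self.tally.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionTally":
        region = GenomicRegion(
            chromosome=d["chromosome"], start=d["start"], end=d["end"], label=d["label"]
        )
        return cls(region=region, tally=CategoryTally.from_dict(d))


@dataclass
class ScanReport:
    """Per-region and per-category tallies from one scan.

    ``categories`` holds ``includes`` and ``unmapped`` always, plus
    ``genomic`` only in full-scan mode (region mode never examines those
    reads, so the key is absent rather than zero).  ``motif_variants``
    counts every repeat-unit variant seen inside stage-2 runs of counted
    reads, e.g. ``{"TTAGGG": 412, "TTGGGG": 9}``.
    """

    mode: str
    motif_spec: MotifSpec
    policy: ReadFilterPolicy
    regions: list[RegionTally]
    categories: dict[str, CategoryTally]
    motif_variants: Counter
    total_examined: int

    @property
    def telomeric_read_count(self) -> int:
        """Stage-2-passing reads summed over every category present."""
        return sum(t.stage2_passes for t in self.categories.values())

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "motif_spec": self.motif_spec.to_dict(),
            "filter_policy": self.policy.to_dict(),
            "regions": [rt.to_dict() for rt in self.regions],
            "categories": {
                name: tally.to_dict() for name, tally in self.categories.items()
            },
            "motif_variants": dict(sorted(self.motif_variants.items())),
            "total_examined": self.total_examined,
            "telomeric_read_count": self.telomeric_read_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanReport":
        ms = d["motif_spec"]
        spec = build_motif_spec(
            canonical_motif=ms["canonical_motif"],
            stage1_repeats=ms["stage1_repeat_count"],
            stage2_min_repeats=ms["stage2_min_repeats"],
            wildcard_prefix=ms["stage2_wildcard_prefix"],
            strands=ms.get("strands", "both"),
        )
        fp = d["filter_policy"]
        policy = ReadFilterPolicy(
            exclude_duplicates=fp["exclude_duplicates"],
            exclude_secondary=fp["exclude_secondary"],
            exclude_supplementary=fp["exclude_supplementary"],
            exclude_qcfail=fp["exclude_qcfail"],
            min_read_length=fp["min_read_length"],
        )
        return cls(
            mode=d["mode"],
            motif_spec=spec,
            policy=policy,
            regions=[RegionTally.from_dict(r) for r in d["regions"]],
            categories={
                name: CategoryTally.from_dict(t)
                for name, t in d["categories"].items()
            },
            motif_variants=Counter(d["motif_variants"]),
            total_examined=d["total_examined"],
        )


# ---------------------------------------------------------------------------
# Region loading
# ---------------------------------------------------------------------------

def load_regions(entries: Iterable[tuple[str, str, int, int]]) -> RegionSet:
    """Build a sorted :class:`RegionSet` from (label, chrom, start, end)
    entries, e.g. as parsed from the INCLUDES section of a config file.

    Raises :class:`RegionError` on duplicate labels or invalid coordinates;
    an empty entry list raises because region mode needs at least one region.
    """
    regions = [
        GenomicRegion(chromosome=chrom, start=start, end=end, label=label)
        for label, chrom, start, end in entries
    ]
    if not regions:
        raise RegionError("no regions defined")
    return RegionSet(regions)


def regions_from_bed(path: str) -> RegionSet:
    """Load include regions from a BED file.

    BED intervals are 0-based half-open; they are converted to the 1-based
    inclusive convention used everywhere else.  The 4th column, when present,
    provides the label; otherwise labels are ``chrom:start-end``.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else f"{chrom}:{start0 + 1}-{end0}"
            regions.append(
                GenomicRegion(
                    chromosome=chrom, start=start0 + 1, end=end0, label=label
                )
            )
    if not regions:
        raise RegionError(f"{path}: no regions found")
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# Read iteration
# ---------------------------------------------------------------------------

def _open_bam(bam_path: str) -> pysam.AlignmentFile:
    try:
        return pysam.AlignmentFile(str(bam_path))
    except (OSError, ValueError) as exc:
        raise InputFileError(f"cannot open alignment file {bam_path}: {exc}") from exc


def _require_index(bam: pysam.AlignmentFile) -> None:
    if not bam.has_index():
        raise InputFileError(
            f"{bam.filename.decode()} has no index; run `samtools index` first"
        )


def _check_chromosome(bam: pysam.AlignmentFile, chromosome: str) -> None:
    if chromosome not in bam.references:
        available = ", ".join(bam.references[:30])
        raise InputFileError(
            f"chromosome {chromosome!r} not in BAM header; available: {available}"
        )


def iterate_region_reads(
    bam: pysam.AlignmentFile,
    region: GenomicRegion,
    policy: ReadFilterPolicy,
    stats: Optional[CategoryTally] = None,
) -> Iterator[ReadRecord]:
    """Yield policy-retained mapped records overlapping ``region`` by >= 1
    base, each exactly once per region.

    Unmapped records stored with a placement coordinate are skipped here —
    they belong to the unmapped stream.  Records failing the policy are
    counted in ``stats.filtered`` (when given) and not yielded.
    """
    _require_index(bam)
    _check_chromosome(bam, region.chromosome)
    for rec in bam.fetch(region.chromosome, region.start - 1, region.end):
        if rec.is_unmapped:
            continue
        read = ReadRecord.from_pysam(rec)
        if policy.retains(read):
            yield read
        elif stats is not None:
            stats.filtered += 1


def iterate_unmapped(
    bam: pysam.AlignmentFile,
    policy: ReadFilterPolicy,
    stats: Optional[CategoryTally] = None,
) -> Iterator[ReadRecord]:
    """Yield every policy-retained record whose own unmapped flag is set.

    This includes unmapped mates stored with their mapped mate's coordinate,
    which an index query can also return — hence unmapped records are
    excluded from the region stream and owned entirely by this one.
    """
    bam.reset()  # a prior indexed fetch leaves the handle mid-file
    for rec in bam.fetch(until_eof=True):
        if not rec.is_unmapped:
            continue
        read = ReadRecord.from_pysam(rec)
        if policy.retains(read):
            yield read
        elif stats is not None:
            stats.filtered += 1


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

# Per-read outcome: (identity, retained, stage1, stage2, unit-variant counts)
_Outcome = tuple[tuple, bool, bool, bool, tuple]


def _read_outcome(read: ReadRecord, spec: MotifSpec, policy: ReadFilterPolicy) -> _Outcome:
    if not policy.retains(read):
        return (read.identity, False, False, False, ())
    result = classify_read(read.sequence, spec)
    units: tuple = ()
    if result.stage2_passed:
        ulen = spec.unit_length
        units = tuple(
            hit.matched_substring[i : i + ulen]
            for hit in result.hits
            for i in range(0, len(hit.matched_substring), ulen)
        )
    return (read.identity, True, result.stage1_passed, result.stage2_passed, units)


def _region_worker(
    bam_path: str, region: GenomicRegion, spec: MotifSpec, policy: ReadFilterPolicy
) -> list[_Outcome]:
    with _open_bam(bam_path) as bam:
        _require_index(bam)
        _check_chromosome(bam, region.chromosome)
        return [
            _read_outcome(ReadRecord.from_pysam(rec), spec, policy)
            for rec in bam.fetch(region.chromosome, region.start - 1, region.end)
            if not rec.is_unmapped
        ]


def _unmapped_worker(
    bam_path: str, spec: MotifSpec, policy: ReadFilterPolicy
) -> list[_Outcome]:
    with _open_bam(bam_path) as bam:
        return [
            _read_outcome(ReadRecord.from_pysam(rec), spec, policy)
            for rec in bam.fetch(until_eof=True)
            if rec.is_unmapped
        ]


def _merge_outcomes(
    outcomes: Iterable[_Outcome],
    tally: CategoryTally,
    variants: Counter,
    seen: set,
) -> None:
    for identity, retained, s1, s2, units in outcomes:
        if identity in seen:
            continue
        seen.add(identity)
        if not retained:
            tally.filtered += 1
            continue
        tally.examined += 1
        if s1:
            tally.stage1_passes += 1
        if s2:
            tally.stage2_passes += 1
            variants.update(units)


def scan(
    bam_path: str,
    regions: RegionSet,
    spec: Optional[MotifSpec] = None,
    policy: Optional[ReadFilterPolicy] = None,
    workers: int = 1,
) -> ScanReport:
    """Region-mode scan: include regions plus all unmapped reads.

    Work is partitioned by region (plus one unmapped partition) across
    ``workers`` threads; partial results are merged in sorted region order
    with global de-duplication, so the report is a pure function of the
    inputs and identical for any worker count.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    spec = spec or build_motif_spec()
    policy = policy or ReadFilterPolicy.default()

    if workers == 1:
        region_results = [
            _region_worker(bam_path, region, spec, policy) for region in regions
        ]
        unmapped_result = _unmapped_worker(bam_path, spec, policy)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = [
                pool.submit(_region_worker, bam_path, region, spec, policy)
                for region in regions
            ]
            unmapped_future = pool.submit(_unmapped_worker, bam_path, spec, policy)
            region_results = [f.result() for f in futures]
            unmapped_result = unmapped_future.result()

    variants: Counter = Counter()
    seen: set = set()
    region_tallies: list[RegionTally] = []
    includes = CategoryTally()
    for region, outcomes in zip(regions, region_results):
        rt = RegionTally(region=region)
        _merge_outcomes(outcomes, rt.tally, variants, seen)
        includes.add(rt.tally)
        region_tallies.append(rt)

    unmapped = CategoryTally()
    _merge_outcomes(unmapped_result, unmapped, variants, seen)

    return ScanReport(
        mode="regions",
        motif_spec=spec,
        policy=policy,
        regions=region_tallies,
        categories={"includes": includes, "unmapped": unmapped},
        motif_variants=variants,
        total_examined=includes.examined + unmapped.examined,
    )


def full_scan(
    bam_path: str,
    regions: RegionSet,
    spec: Optional[MotifSpec] = None,
    policy: Optional[ReadFilterPolicy] = None,
) -> ScanReport:
    """Examine every record in the file.

    Mapped reads inside include regions populate the per-region tallies;
    mapped reads outside all include regions populate the ``genomic``
    category; unmapped reads populate ``unmapped``.  Serves as the
    validation oracle for region mode.
    """
    spec = spec or build_motif_spec()
    policy = policy or ReadFilterPolicy.default()

    region_list = list(regions)
    region_tallies = [RegionTally(region=r) for r in region_list]
    by_region: dict[str, RegionTally] = {rt.region.label: rt for rt in region_tallies}
    unmapped = CategoryTally()
    genomic = CategoryTally()
    variants: Counter = Counter()
    seen: set = set()

    with _open_bam(bam_path) as bam:
        for rec in bam.fetch(until_eof=True):
            read = ReadRecord.from_pysam(rec)
            if read.identity in seen:
                continue
            seen.add(read.identity)
            outcome = _read_outcome(read, spec, policy)
            _, retained, s1, s2, units = outcome
            if rec.is_unmapped:
                target = unmapped
            else:
                start0 = rec.reference_start
                end0 = rec.reference_end if rec.reference_end is not None else start0 + 1
                hit_region = regions.first_containing(
                    rec.reference_name, start0, end0
                )
                target = (
                    by_region[hit_region.label].tally if hit_region else genomic
                )
            if not retained:
                target.filtered += 1
                continue
            target.examined += 1
            if s1:
                target.stage1_passes += 1
            if s2:
                target.stage2_passes += 1
                variants.update(units)

    includes = CategoryTally()
    for rt in region_tallies:
        includes.add(rt.tally)

    return ScanReport(
        mode="full",
        motif_spec=spec,
        policy=policy,
        regions=region_tallies,
        categories={"includes": includes, "unmapped": unmapped, "genomic": genomic},
        motif_variants=variants,
        total_examined=includes.examined + unmapped.examined + genomic.examined,
    )
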