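"""Synthetic BAM fixtures with planted, fully known telomeric content.

Every read class is constructed so that its fate under the default matcher
and default filter policy is known *by construction*, verified at
generation time by an independent brute-force checker (deliberately not the
production matcher):

``forward`` / ``reverse``
    whole-read tilings of the canonical motif (``TTAGGG`` / ``CCCTAA``) —
    pass stage 1 and stage 2.
``degenerate``
    a block of three canonical units (so the stage-1 gate passes) followed
    by units whose first three bases are randomized — pass both stages and
    contribute variant units to the tally.
``near_miss``
    repeats present but never three concurrent canonical units: either
    two-unit blocks separated by spacers (would satisfy stage 2 alone but
    never reach it) or isolated single units — fail the gate, counted as
    examined only.
``background``
    random sequence rejection-sampled to contain no stage-1 string and no
    stage-2 run at all, so expected counts are exact rather than
    probabilistic.
``unmapped`` / ``placed-unmapped``
    telomeric reads with the unmapped flag, without or with a stored
    placement coordinate (emulating the mate-of-mapped-read case).
``duplicate``
    duplicate-flagged telomeric copies at identical coordinates — excluded
    by the default policy.
``genomic``
    telomeric reads mapped outside every include region — visible only to a
    full scan.

Fixtures are written as SAM text first (inspectable), then sorted,
compressed and indexed with samtools via pysam.  The accompanying
:class:`TruthTable` is computed analytically from the class counts, never
by running the matcher under test.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

import pysam

__all__ = [
    "FixtureSpec",
    "TruthTable",
    "FixtureError",
    "make_telomeric_read",
    "generate_fixture",
    "make_ratio_pair",
    "independent_stage1",
    "independent_stage2_runs",
]

_MOTIF = "TTAGGG"
_MOTIF_RC = "CCCTAA"
_BASES = "ACGT"

FLAG_UNMAPPED = 0x4
FLAG_DUPLICATE = 0x400


class FixtureError(ValueError):
    """Raised for impossible fixture specifications."""


# ---------------------------------------------------------------------------
# Independent checker (brute force; no regex, no production code)
# ---------------------------------------------------------------------------

def independent_stage1(seq: str, repeats: int = 3) -> bool:
    """Brute-force check for ``repeats`` concurrent canonical units on
    either strand, by direct substring search."""
    return (_MOTIF * repeats) in seq or (_MOTIF_RC * repeats) in seq


def _forward_unit_ok(seq: str, i: int) -> bool:
    unit = seq[i : i + 6]
    if len(unit) < 6 or any(b not in _BASES for b in unit):
        return False
    return unit[3:] == "GGG"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _greedy_forward_runs(seq: str, min_repeats: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i + 6 * min_repeats <= len(seq):
        if _forward_unit_ok(seq, i):
            k = 0
            while _forward_unit_ok(seq, i + 6 * k):
                k += 1
            if k >= min_repeats:
                runs.append((i, k))
                i += 6 * k
                continue
        i += 1
    return runs


def independent_stage2_runs(seq: str, min_repeats: int = 2) -> list[tuple[int, int, str]]:
    """Brute-force enumeration of maximal greedy stage-2 runs.

    Returns (offset, repeat_count, strand) triples: forward runs from a
    position-by-position scan of the read, reverse runs from the same scan
    of its reverse complement with coordinates mirrored back — the oracle
    counterpart of the production matcher, written without regexes.
    """
    runs = [(i, k, "forward") for i, k in _greedy_forward_runs(seq, min_repeats)]
    rc = _revcomp(seq)
    runs += [
        (len(seq) - (i + 6 * k), k, "reverse")
        for i, k in _greedy_forward_runs(rc, min_repeats)
    ]
    runs.sort(key=lambda r: (r[0], r[2] != "forward"))
    return runs


def _is_clean_background(seq: str) -> bool:
    return not independent_stage1(seq) and not independent_stage2_runs(seq)


# ---------------------------------------------------------------------------
# Read construction
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def make_telomeric_read(
    cls: str, read_length: int, rng: random.Random
) -> str:
    """Construct one read sequence of the requested class.

    Classes: ``forward``, ``reverse``, ``degenerate``, ``near_miss``,
    ``background``.  The returned sequence is verified against the
    independent checker; an impossible class/length combination raises
    :class:`FixtureError`.
    """
    if cls in ("forward", "reverse"):
        if read_length < 18:
            raise FixtureError(f"class {cls!r} needs read length >= 18")
        motif = _MOTIF if cls == "forward" else _MOTIF_RC
        seq = (motif * (read_length // 6 + 1))[:read_length]
        assert independent_stage1(seq)
        return seq

    if cls == "degenerate":
        if read_length < 24:
            raise FixtureError("class 'degenerate' needs read length >= 24")
        units = [_MOTIF] * 3  # stage-1 gate block
        n_units = read_length // 6
        for _ in range(n_units - 3):
            units.append(_random_seq(rng, 3) + "GGG")
        seq = "".join(units)
        seq += _MOTIF[: read_length - len(seq)]
        assert independent_stage1(seq) and independent_stage2_runs(seq)
        return seq

    if cls == "near_miss":
        if read_length < 15:
            raise FixtureError("class 'near_miss' needs read length >= 15")
        for _ in range(1000):
            flavor = rng.choice(("two_concurrent", "isolated_units"))
            block = _MOTIF * 2 if flavor == "two_concurrent" else _MOTIF
            pieces = []
            length = 0
            while length < read_length:
                pieces.append(block)
                spacer = _random_seq(rng, 3)
                pieces.append(spacer)
                length += len(block) + len(spacer)
            seq = "".join(pieces)[:read_length]
            if not independent_stage1(seq):
                return seq
        raise FixtureError("could not construct a near-miss read")

    if cls == "background":
        for _ in range(1000):
            seq = _random_seq(rng, read_length)
            if _is_clean_background(seq):
                return seq
        raise FixtureError("could not construct a clean background read")

    raise FixtureError(f"unknown read class {cls!r}")


# ---------------------------------------------------------------------------
# Fixture specification and truth table
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Declarative description of one synthetic BAM.

    Counts are reads per class; telomeric/near-miss/background reads are
    placed uniformly at random inside the include regions, ``n_genomic_*``
    reads well outside all of them.  A fixed seed makes the fixture
    byte-reproducible.
    """

    seed: int = 0
    read_length: int = 100
    chromosomes: dict = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    include_regions: list = field(
        default_factory=lambda: [
            ("chr1_tel", "chr1", 1, 10_000),
            ("chr2_tel", "chr2", 1, 10_000),
        ]
    )
    n_forward: int = 0
    n_reverse: int = 0
    n_degenerate: int = 0
    n_near_miss: int = 0
    n_background: int = 0
    n_genomic_telomeric: int = 0
    n_genomic_background: int = 0
    n_unmapped_telomeric: int = 0
    n_unmapped_background: int = 0
    n_placed_unmapped_telomeric: int = 0
    n_duplicate_telomeric: int = 0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if name.startswith("n_") and value < 0:
                raise FixtureError(f"{name} must be >= 0")
        if self.read_length < 24:
            raise FixtureError("read_length must be >= 24")
        if not self.include_regions:
            raise FixtureError("at least one include region is required")
        for label, chrom, start, end in self.include_regions:
            if chrom not in self.chromosomes:
                raise FixtureError(f"region {label!r}: unknown chromosome {chrom!r}")
            if end > self.chromosomes[chrom]:
                raise FixtureError(f"region {label!r} extends past {chrom} end")
            if end - start + 1 < self.read_length:
                raise FixtureError(
                    f"region {label!r} is shorter than one read; nothing fits"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        if "include_regions" in d:
            d["include_regions"] = [tuple(r) for r in d["include_regions"]]
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["include_regions"] = [list(r) for r in self.include_regions]
        return d


@dataclass
class TruthTable:
    """Analytically expected tallies under the default matcher and policy.

    Computed from the construction alone: telomeric classes pass both
    stages, near-miss and background pass neither, duplicates are filtered.
    """

    planted: dict
    expected: dict  # category -> {examined, filtered, stage1_passes, stage2_passes}
    total_records: int

    @classmethod
    def from_spec(cls, spec: FixtureSpec) -> "TruthTable":
        planted = {
            k: getattr(spec, k)
            for k in (
                "n_forward",
                "n_reverse",
                "n_degenerate",
                "n_near_miss",
                "n_background",
                "n_genomic_telomeric",
                "n_genomic_background",
                "n_unmapped_telomeric",
                "n_unmapped_background",
                "n_placed_unmapped_telomeric",
                "n_duplicate_telomeric",
            )
        }
        telomeric_in_regions = spec.n_forward + spec.n_reverse + spec.n_degenerate
        includes = {
            "examined": telomeric_in_regions + spec.n_near_miss + spec.n_background,
            "filtered": spec.n_duplicate_telomeric,
            "stage1_passes": telomeric_in_regions,
            "stage2_passes": telomeric_in_regions,
        }
        unmapped_telomeric = (
            spec.n_unmapped_telomeric + spec.n_placed_unmapped_telomeric
        )
        unmapped = {
            "examined": unmapped_telomeric + spec.n_unmapped_background,
            "filtered": 0,
            "stage1_passes": unmapped_telomeric,
            "stage2_passes": unmapped_telomeric,
        }
        genomic = {
            "examined": spec.n_genomic_telomeric + spec.n_genomic_background,
            "filtered": 0,
            "stage1_passes": spec.n_genomic_telomeric,
            "stage2_passes": spec.n_genomic_telomeric,
        }
        total = sum(planted.values())
        return cls(
            planted=planted,
            expected={"includes": includes, "unmapped": unmapped, "genomic": genomic},
            total_records=total,
        )

    def to_dict(self) -> dict:
        return {
            "planted": self.planted,
            "expected": self.expected,
            "total_records": self.total_records,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(
            planted=d["planted"],
            expected=d["expected"],
            total_records=d["total_records"],
        )


# ---------------------------------------------------------------------------
# SAM/BAM emission
# ---------------------------------------------------------------------------

def _header(spec: FixtureSpec) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in spec.chromosomes.items()
            ],
        }
    )


def _mapped_segment(
    header: pysam.AlignmentHeader,
    qname: str,
    seq: str,
    chrom: str,
    pos0: int,
    flag: int = 0,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = pos0
    a.mapping_quality = 60
    a.cigartuples = [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def _unmapped_segment(
    header: pysam.AlignmentHeader,
    qname: str,
    seq: str,
    chrom: Optional[str] = None,
    pos0: Optional[int] = None,
    extra_flag: int = 0,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.query_sequence = seq
    a.flag = FLAG_UNMAPPED | extra_flag
    if chrom is not None and pos0 is not None:
        a.reference_id = header.get_tid(chrom)
        a.reference_start = pos0
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def _region_position(
    rng: random.Random, spec: FixtureSpec, region: tuple
) -> tuple[str, int]:
    _, chrom, start, end = region
    # keep reads fully inside the region so overlap attribution is unambiguous
    pos1 = rng.randint(start, end - spec.read_length + 1)
    return chrom, pos1 - 1


def _genomic_position(rng: random.Random, spec: FixtureSpec) -> tuple[str, int]:
    """A position whose read cannot overlap any include region."""
    for _ in range(1000):
        chrom = rng.choice(sorted(spec.chromosomes))
        length = spec.chromosomes[chrom]
        if length < spec.read_length:
            continue
        pos1 = rng.randint(1, length - spec.read_length + 1)
        lo0, hi0 = pos1 - 1, pos1 - 1 + spec.read_length
        clear = all(
            not (c == chrom and lo0 < end and hi0 > start - 1)
            for _, c, start, end in spec.include_regions
        )
        if clear:
            return chrom, pos1 - 1
    raise FixtureError("no genomic position outside the include regions fits a read")


def generate_fixture(
    spec: FixtureSpec, out_dir: str, name: str = "fixture"
) -> tuple[str, TruthTable]:
    """Write ``<name>.sam`` (text), ``<name>.bam`` (+ .bai) and
    ``<name>.truth.json`` under ``out_dir``; returns (bam path, truth).
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = random.Random(spec.seed)
    header = _header(spec)
    segments: list[pysam.AlignedSegment] = []
    regions = spec.include_regions
    serial = 0

    def next_name(cls: str) -> str:
        nonlocal serial
        serial += 1
        return f"{cls}_{serial:05d}"

    dup_templates: list[tuple[str, int, str]] = []  # (chrom, pos0, seq)

    for cls, count in (
        ("forward", spec.n_forward),
        ("reverse", spec.n_reverse),
        ("degenerate", spec.n_degenerate),
        ("near_miss", spec.n_near_miss),
        ("background", spec.n_background),
    ):
        for i in range(count):
            seq = make_telomeric_read(cls, spec.read_length, rng)
            region = regions[(serial + i) % len(regions)]
            chrom, pos0 = _region_position(rng, spec, region)
            segments.append(
                _mapped_segment(header, next_name(cls), seq, chrom, pos0)
            )
            if cls == "forward":
                dup_templates.append((chrom, pos0, seq))

    for _ in range(spec.n_genomic_telomeric):
        seq = make_telomeric_read("forward", spec.read_length, rng)
        chrom, pos0 = _genomic_position(rng, spec)
        segments.append(_mapped_segment(header, next_name("genomic"), seq, chrom, pos0))

    for _ in range(spec.n_genomic_background):
        seq = make_telomeric_read("background", spec.read_length, rng)
        chrom, pos0 = _genomic_position(rng, spec)
        segments.append(
            _mapped_segment(header, next_name("genomic_bg"), seq, chrom, pos0)
        )

    for _ in range(spec.n_unmapped_telomeric):
        seq = make_telomeric_read("forward", spec.read_length, rng)
        segments.append(_unmapped_segment(header, next_name("unmapped"), seq))

    for _ in range(spec.n_unmapped_background):
        seq = make_telomeric_read("background", spec.read_length, rng)
        segments.append(_unmapped_segment(header, next_name("unmapped_bg"), seq))

    for _ in range(spec.n_placed_unmapped_telomeric):
        seq = make_telomeric_read("forward", spec.read_length, rng)
        region = regions[serial % len(regions)]
        chrom, pos0 = _region_position(rng, spec, region)
        segments.append(
            _unmapped_segment(header, next_name("placed_unmapped"), seq, chrom, pos0)
        )

    if spec.n_duplicate_telomeric and not dup_templates:
        raise FixtureError(
            "duplicate-flagged reads need at least one forward telomeric read "
            "to duplicate (set n_forward >= 1)"
        )
    for k in range(spec.n_duplicate_telomeric):
        chrom, pos0, seq = dup_templates[k % len(dup_templates)]
        segments.append(
            _mapped_segment(
                header, next_name("dup"), seq, chrom, pos0, flag=FLAG_DUPLICATE
            )
        )

    sam_path = os.path.join(out_dir, f"{name}.sam")
    bam_path = os.path.join(out_dir, f"{name}.bam")
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for seg in segments:
            out.write(seg)
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)

    truth = TruthTable.from_spec(spec)
    with open(os.path.join(out_dir, f"{name}.truth.json"), "w") as fh:
        json.dump(
            {"spec": spec.to_dict(), "truth": truth.to_dict()},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return bam_path, truth


def make_ratio_pair(
    out_dir: str,
    telomeric_fraction_tumour: float,
    telomeric_fraction_normal: float,
    n_reads: int,
    seed: int = 0,
    read_length: int = 100,
) -> dict:
    """Generate a tumour/normal fixture pair with planted telomeric
    fractions.

    Each sample has ``n_reads`` records; each record is telomeric with the
    sample's planted probability (binomial draw), telomeric reads placed in
    the include regions and the rest as background mapped elsewhere.  The
    expected log2 content ratio is log2(f_t / f_n); the binomial draw gives
    the sampling noise a real cohort sample would show.
    """
    if not (0 < telomeric_fraction_tumour < 1) or not (
        0 < telomeric_fraction_normal < 1
    ):
        raise FixtureError("telomeric fractions must be in (0, 1)")
    rng = random.Random(seed)
    out = {}
    for label, fraction in (
        ("tumour", telomeric_fraction_tumour),
        ("normal", telomeric_fraction_normal),
    ):
        k = sum(rng.random() < fraction for _ in range(n_reads))
        spec = FixtureSpec(
            seed=rng.randrange(2**31),
            read_length=read_length,
            n_forward=k,
            n_genomic_background=n_reads - k,
        )
        bam_path, truth = generate_fixture(spec, out_dir, name=label)
        out[label] = {
            "bam": bam_path,
            "truth": truth,
            "planted_fraction": fraction,
            "telomeric_drawn": k,
            "n_reads": n_reads,
        }
    return out
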