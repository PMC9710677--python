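"""Shared fixtures and the brute-force stage-2 oracle.

The oracle enumerates repeat-unit windows position by position with plain
string comparisons — no regular expressions — so it is an independent
route to the same answer as the production matcher.
"""

from __future__ import annotations

import random

import pytest

from telotally.motifs import MotifSpec, build_motif_spec, reverse_complement

BASES = "ACGT"


def oracle_unit_ok(seq: str, i: int, strand: str, spec: MotifSpec) -> bool:
    """Does a repeat unit of ``spec``'s scheme start at ``i`` (in read
    coordinates)?"""
    m = spec.unit_length
    w = spec.stage2_wildcard_prefix
    unit = seq[i : i + m]
    if i < 0 or len(unit) < m or any(b not in BASES for b in unit):
        return False
    tail = spec.canonical_motif[w:]
    if strand == "forward":
        return unit[w:] == tail
    return unit[: m - w] == reverse_complement(tail)


def _forward_unit_ok(seq: str, i: int, spec: MotifSpec) -> bool:
    m = spec.unit_length
    w = spec.stage2_wildcard_prefix
    unit = seq[i : i + m]
    if len(unit) < m or any(b not in BASES for b in unit):
        return False
    return unit[w:] == spec.canonical_motif[w:]


def _leftmost_greedy_runs(seq: str, spec: MotifSpec) -> list[tuple[int, int]]:
    m = spec.unit_length
    runs = []
    i = 0
    while i + m * spec.stage2_min_repeats <= len(seq):
        if _forward_unit_ok(seq, i, spec):
            k = 0
            while _forward_unit_ok(seq, i + m * k, spec):
                k += 1
            if k >= spec.stage2_min_repeats:
                runs.append((i, k))
                i += m * k
                continue
        i += 1
    return runs


def oracle_stage2(seq: str, spec: MotifSpec) -> list[tuple[int, int, str]]:
    """Maximal greedy runs as (offset, repeat_count, strand).

    Forward runs by direct scan; reverse runs by scanning the reverse
    complement with the forward unit scheme and mirroring coordinates —
    the same strand convention the matcher commits to.
    """
    seq = seq.upper()
    m = spec.unit_length
    runs = []
    if spec.strands in ("both", "forward"):
        runs += [(i, k, "forward") for i, k in _leftmost_greedy_runs(seq, spec)]
    if spec.strands in ("both", "reverse"):
        rc = reverse_complement(seq)
        runs += [
            (len(seq) - (i + m * k), k, "reverse")
            for i, k in _leftmost_greedy_runs(rc, spec)
        ]
    runs.sort(key=lambda r: (r[0], r[2] != "forward"))
    return runs


def oracle_stage1(seq: str, spec: MotifSpec) -> bool:
    """Naive substring search over every window."""
    seq = seq.upper()
    for s in spec.stage1_strings:
        for i in range(len(seq) - len(s) + 1):
            if seq[i : i + len(s)] == s:
                return True
    return False


def random_dna(rng: random.Random, length: int, alphabet: str = BASES) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def default_spec() -> MotifSpec:
    return build_motif_spec()


def make_bam(
    tmp_dir,
    reads: list[dict],
    chromosomes: dict[str, int] | None = None,
    name: str = "test",
) -> str:
    """Write a sorted, indexed BAM from simple read dicts.

    Each read dict: qname, seq, and optionally chrom, pos1 (1-based),
    flag (SAM flag bits).  Omitting chrom/pos1 makes the read unmapped
    without a coordinate; flag 0x4 with chrom/pos1 makes a placed-unmapped
    record.
    """
    import pysam

    chromosomes = chromosomes or {"chr1": 100_000, "chr2": 100_000}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": l} for n, l in chromosomes.items()],
        }
    )
    sam_path = str(tmp_dir / f"{name}.sam")
    bam_path = str(tmp_dir / f"{name}.bam")
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r["qname"]
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            if "chrom" in r:
                a.reference_id = header.get_tid(r["chrom"])
                a.reference_start = r["pos1"] - 1
                if not a.is_unmapped:
                    a.mapping_quality = 60
                    a.cigartuples = [(0, len(r["seq"]))]
            out.write(a)
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path
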