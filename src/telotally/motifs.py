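"""Two-stage telomeric motif matching.

The matcher classifies a read sequence in two passes:

* **Stage 1** is a fast exact-substring gate: the read must contain a run of
  ``stage1_repeat_count`` concurrent copies of the canonical telomere motif
  (default ``TTAGGG``), on either strand.  Plain ``str`` containment makes
  this cheap enough to apply to every read.
* **Stage 2** is a slower regular-expression confirmation, run only on reads
  that pass stage 1.  It extracts every maximal run of
  ``stage2_min_repeats`` or more concurrent repeat units in which the first
  ``stage2_wildcard_prefix`` bases of each unit may vary (default: any three
  bases followed by ``GGG``, or the reverse-complement scheme ``CCC`` followed
  by any three bases).

Matching is strand-aware: telomeric fragments sequenced from the C-rich
strand appear as ``CCCTAA`` repeats, so both orientations are searched by
default.  ``N`` bases never match, including at wildcard positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MotifSpec",
    "MotifHit",
    "MatchResult",
    "MotifConfigError",
    "build_motif_spec",
    "reverse_complement",
    "stage1_match",
    "stage2_find",
    "classify_read",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGT")


class MotifConfigError(ValueError):
    """Raised for invalid motif parameters (bad alphabet, impossible sizes)."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case-preserving
    for upper-case input)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One maximal run of concurrent repeat units found by stage 2.

    Attributes
    ----------
    start_offset:
        0-based offset of the run within the read sequence.
    matched_substring:
        The matched bases; length is a multiple of the unit length.
    repeat_count:
        Number of concurrent units in the run (matched length / unit length).
    strand_class:
        ``"forward"`` for G-strand runs (``...GGG`` units) or ``"reverse"``
        for C-strand runs (``CCC...`` units).
    """

    start_offset: int
    matched_substring: str
    repeat_count: int
    strand_class: str


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the two-pass classification of one read.

    ``stage2_passed`` implies ``stage1_passed``; stage 2 is evaluated only
    when the stage-1 gate passes, so a read whose sequence would satisfy
    stage 2 in isolation is still rejected if it lacks a stage-1 string.
    """

    stage1_passed: bool
    stage2_passed: bool
    hits: tuple[MotifHit, ...] = ()


@dataclass(frozen=True)
class MotifSpec:
    """Fully resolved parameters of the two-stage matcher.

    Construct with :func:`build_motif_spec`, which derives the stage-1
    strings and compiles the stage-2 patterns.
    """

    canonical_motif: str
    stage1_repeat_count: int
    stage2_min_repeats: int
    stage2_wildcard_prefix: int
    strands: str  # "both" | "forward" | "reverse"
    stage1_strings: frozenset[str]
    forward_unit_pattern: str
    reverse_unit_pattern: str
    _forward_re: re.Pattern = field(repr=False, compare=False)
    _reverse_re: re.Pattern = field(repr=False, compare=False)

    @property
    def unit_length(self) -> int:
        return len(self.canonical_motif)

    @property
    def stage2_patterns(self) -> tuple[str, str]:
        """The (forward, reverse) stage-2 regex sources, for provenance."""
        min_r = self.stage2_min_repeats
        return (
            f"(?:{self.forward_unit_pattern}){{{min_r},}}",
            f"(?:{self.reverse_unit_pattern}){{{min_r},}}",
        )

    def to_dict(self) -> dict:
        fwd, rev = self.stage2_patterns
        return {
            "canonical_motif": self.canonical_motif,
            "stage1_repeat_count": self.stage1_repeat_count,
            "stage2_min_repeats": self.stage2_min_repeats,
            "stage2_wildcard_prefix": self.stage2_wildcard_prefix,
            "strands": self.strands,
            "stage1_strings": sorted(self.stage1_strings),
            "stage2_forward_pattern": fwd,
            "stage2_reverse_pattern": rev,
        }


def build_motif_spec(
    canonical_motif: str = "TTAGGG",
    stage1_repeats: int = 3,
    stage2_min_repeats: int = 2,
    wildcard_prefix: int = 3,
    strands: str = "both",
) -> MotifSpec:
    """Construct a :class:`MotifSpec` from the four tunable parameters.

    Parameters
    ----------
    canonical_motif:
        The repeat unit, over {A,C,G,T}.  Default ``"TTAGGG"``, the human
        telomere hexamer.
    stage1_repeats:
        Number of concurrent units required for the exact stage-1 gate
        (default 3 — an 18-base exact string on either strand).
    stage2_min_repeats:
        Minimum concurrent units for a stage-2 run (default 2, the repeat
        threshold at which read selection best tracks laboratory assays).
    wildcard_prefix:
        How many leading bases of each stage-2 unit may be any base
        (default 3, leaving the ``GGG`` core exact).  Must be strictly
        smaller than the motif length.
    strands:
        ``"both"`` (default — telomeric fragments are sequenced from either
        strand), ``"forward"`` (G-strand only) or ``"reverse"``.

    Raises
    ------
    MotifConfigError
        If the motif contains a non-ACGT character, any count is < 1, or the
        wildcard prefix covers the whole unit.
    """
    if not canonical_motif:
        raise MotifConfigError("canonical motif must be non-empty")
    motif = canonical_motif.upper()
    for ch in motif:
        if ch not in _VALID_BASES:
            raise MotifConfigError(
                f"canonical motif contains invalid character {ch!r}; "
                "allowed bases are A, C, G, T"
            )
    if stage1_repeats < 1:
        raise MotifConfigError("stage1_repeats must be >= 1")
    if stage2_min_repeats < 1:
        raise MotifConfigError("stage2_min_repeats must be >= 1")
    if wildcard_prefix < 0:
        raise MotifConfigError("wildcard_prefix must be >= 0")
    if wildcard_prefix >= len(motif):
        raise MotifConfigError(
            f"wildcard_prefix ({wildcard_prefix}) must be smaller than the "
            f"motif length ({len(motif)})"
        )
    if strands not in ("both", "forward", "reverse"):
        raise MotifConfigError(
            f"strands must be 'both', 'forward' or 'reverse', not {strands!r}"
        )

    stage1_fwd = motif * stage1_repeats
    strings = []
    if strands in ("both", "forward"):
        strings.append(stage1_fwd)
    if strands in ("both", "reverse"):
        strings.append(reverse_complement(stage1_fwd))
    stage1_strings = frozenset(strings)

    # Unit schemes: the first `wildcard_prefix` bases of the unit are free
    # over {A,C,G,T}; the remainder is the exact tail of the motif.  The
    # reverse pattern is the base-wise reverse complement of that scheme, so
    # the wildcard window sits at the unit *end* on the C-rich strand.
    fixed_tail = motif[wildcard_prefix:]
    if wildcard_prefix:
        fwd_unit = f"[ACGT]{{{wildcard_prefix}}}{fixed_tail}"
        rev_unit = f"{reverse_complement(fixed_tail)}[ACGT]{{{wildcard_prefix}}}"
    else:
        fwd_unit = fixed_tail
        rev_unit = reverse_complement(fixed_tail)

    fwd_re = re.compile(f"(?:{fwd_unit}){{{stage2_min_repeats},}}")
    rev_re = re.compile(f"(?:{rev_unit}){{{stage2_min_repeats},}}")

    return MotifSpec(
        canonical_motif=motif,
        stage1_repeat_count=stage1_repeats,
        stage2_min_repeats=stage2_min_repeats,
        stage2_wildcard_prefix=wildcard_prefix,
        strands=strands,
        stage1_strings=stage1_strings,
        forward_unit_pattern=fwd_unit,
        reverse_unit_pattern=rev_unit,
        _forward_re=fwd_re,
        _reverse_re=rev_re,
    )


def stage1_match(sequence: str, spec: MotifSpec) -> bool:
    """True iff any exact stage-1 string occurs in ``sequence``.

    Pure substring containment; an empty sequence returns False.
    """
    seq = sequence.upper()
    return any(s in seq for s in spec.stage1_strings)


def stage2_find(sequence: str, spec: MotifSpec) -> list[MotifHit]:
    """All maximal, greedy, non-overlapping stage-2 runs on both strands.

    Forward (G-strand) runs are leftmost-greedy regex matches of the
    forward pattern.  Reverse (C-strand) runs are found by scanning the
    *reverse complement* of the read with the same forward pattern and
    mapping the match coordinates back — the matched bases in read
    coordinates are ``CCC``-prefixed units, and a read and its reverse
    complement always yield mirror-identical repeat tallies by
    construction.  (In read coordinates this makes reverse runs
    rightmost-greedy; on ambiguous G/C homopolymer phasings the two
    conventions can differ, and only this one treats the strands
    identically.)

    The two strands are scanned independently, so a forward and a reverse
    hit may overlap on pathological inputs (e.g. ``CCCGGG`` runs, which
    satisfy both unit schemes); hits from the same strand never overlap.
    Runs are maximal: no hit can be extended by a whole repeat unit at
    either end without overlapping a neighbouring hit.  Hits are returned
    sorted by offset, forward strand first on ties.
    """
    seq = sequence.upper()
    unit = spec.unit_length
    hits: list[MotifHit] = []
    if spec.strands in ("both", "forward"):
        for m in spec._forward_re.finditer(seq):
            matched = m.group(0)
            hits.append(
                MotifHit(
                    start_offset=m.start(),
                    matched_substring=matched,
                    repeat_count=len(matched) // unit,
                    strand_class="forward",
                )
            )
    if spec.strands in ("both", "reverse"):
        rc = reverse_complement(seq)
        n = len(seq)
        for m in spec._forward_re.finditer(rc):
            length = m.end() - m.start()
            offset = n - m.end()
            hits.append(
                MotifHit(
                    start_offset=offset,
                    matched_substring=seq[offset : offset + length],
                    repeat_count=length // unit,
                    strand_class="reverse",
                )
            )
    hits.sort(key=lambda h: (h.start_offset, h.strand_class != "forward"))
    return hits


def classify_read(sequence: str, spec: MotifSpec) -> MatchResult:
    """Run the two-pass flow on one read sequence.

    Stage 1 is always evaluated; stage 2 only on a stage-1 pass.  With the
    default spec the gate is sound (a stage-1 string is itself a stage-2
    run), so ``stage2_passed`` equals "stage 1 passed and stage 2 found at
    least one run".
    """
    if not stage1_match(sequence, spec):
        return MatchResult(stage1_passed=False, stage2_passed=False)
    hits = tuple(stage2_find(sequence, spec))
    return MatchResult(stage1_passed=True, stage2_passed=bool(hits), hits=hits)
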