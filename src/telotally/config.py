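"""INI-style run configuration.

A run is driven by a single plain-text configuration file in the Windows
INI style.  Three sections are recognized (all keys case-insensitive,
``#``/``;`` comments allowed):

``[PARAMS]``
    motif (default ``TTAGGG``), stage1_repeats (3), stage2_min_repeats (2),
    wildcard_prefix (3), strands (``both``), mode (``regions`` | ``full``),
    workers (1), scaling (1000000).

``[FILTER]``
    exclude_duplicates, exclude_secondary, exclude_supplementary,
    exclude_qcfail (all default ``true``), min_read_length (0).

``[INCLUDES]``
    One region per line, ``label  chrom:start-end`` (whitespace-separated;
    ``label = chrom:start-end`` also accepted), 1-based inclusive
    coordinates.  Required when mode is ``regions``.

After parsing, every tunable is resolved to an explicit value; the resolved
configuration is echoed into the JSON report for provenance.
"""

from __future__ import annotations

import configparser
import logging
import re
from dataclasses import dataclass, field

from .motifs import MotifConfigError, MotifSpec, build_motif_spec
from .scan import ReadFilterPolicy, RegionSet, load_regions

__all__ = ["RunConfig", "ConfigError", "parse_config", "parse_config_file"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration files."""


_REGION_RE = re.compile(r"^(?P<chrom>[^\s:]+):(?P<start>\d+)-(?P<end>\d+)$")

_PARAM_KEYS = {
    "motif",
    "stage1_repeats",
    "stage2_min_repeats",
    "wildcard_prefix",
    "strands",
    "mode",
    "workers",
    "scaling",
}
_FILTER_KEYS = {
    "exclude_duplicates",
    "exclude_secondary",
    "exclude_supplementary",
    "exclude_qcfail",
    "min_read_length",
}


@dataclass
class RunConfig:
    """Fully resolved run parameters — no implicit defaults downstream."""

    motif: str = "TTAGGG"
    stage1_repeats: int = 3
    stage2_min_repeats: int = 2
    wildcard_prefix: int = 3
    strands: str = "both"
    mode: str = "regions"
    workers: int = 1
    scaling: float = 1_000_000.0
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True
    min_read_length: int = 0
    includes: list[tuple[str, str, int, int]] = field(default_factory=list)

    def motif_spec(self) -> MotifSpec:
        try:
            return build_motif_spec(
                canonical_motif=self.motif,
                stage1_repeats=self.stage1_repeats,
                stage2_min_repeats=self.stage2_min_repeats,
                wildcard_prefix=self.wildcard_prefix,
                strands=self.strands,
            )
        except MotifConfigError as exc:
            raise ConfigError(str(exc)) from exc

    def filter_policy(self) -> ReadFilterPolicy:
        return ReadFilterPolicy(
            exclude_duplicates=self.exclude_duplicates,
            exclude_secondary=self.exclude_secondary,
            exclude_supplementary=self.exclude_supplementary,
            exclude_qcfail=self.exclude_qcfail,
            min_read_length=self.min_read_length,
        )

    def region_set(self) -> RegionSet:
        if self.mode == "regions" and not self.includes:
            raise ConfigError("mode=regions but no regions defined in [INCLUDES]")
        if not self.includes:
            return RegionSet([])
        return load_regions(self.includes)

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "stage1_repeats": self.stage1_repeats,
            "stage2_min_repeats": self.stage2_min_repeats,
            "wildcard_prefix": self.wildcard_prefix,
            "strands": self.strands,
            "mode": self.mode,
            "workers": self.workers,
            "scaling": self.scaling,
            "exclude_duplicates": self.exclude_duplicates,
            "exclude_secondary": self.exclude_secondary,
            "exclude_supplementary": self.exclude_supplementary,
            "exclude_qcfail": self.exclude_qcfail,
            "min_read_length": self.min_read_length,
            "includes": [
                {"label": l, "chromosome": c, "start": s, "end": e}
                for l, c, s, e in self.includes
            ],
        }


def _parse_bool(key: str, value: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes", "on"):
        return True
    if v in ("0", "false", "no", "off"):
        return False
    raise ConfigError(f"key {key!r}: expected a boolean, got {value!r}")


def _parse_int(key: str, value: str, minimum: int) -> int:
    try:
        n = int(value)
    except ValueError as exc:
        raise ConfigError(f"key {key!r}: expected an integer, got {value!r}") from exc
    if n < minimum:
        raise ConfigError(f"key {key!r}: must be >= {minimum}, got {n}")
    return n


def _includes_entries(text: str) -> list[tuple[int, str]]:
    """(line number, stripped content) pairs inside the INCLUDES section."""
    entries = []
    in_section = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            in_section = line[1:-1].strip().lower() == "includes"
            continue
        if in_section:
            entries.append((lineno, line))
    return entries


def _parse_include_line(lineno: int, line: str) -> tuple[str, str, int, int]:
    # "label  chrom:start-end" or "label = chrom:start-end"
    parts = [p for p in re.split(r"[=\s]+", line) if p]
    if len(parts) != 2:
        raise ConfigError(
            f"line {lineno}: expected 'label  chrom:start-end', got {line!r}"
        )
    label, region_str = parts
    m = _REGION_RE.match(region_str)
    if not m:
        raise ConfigError(
            f"line {lineno}: malformed region string {region_str!r} "
            "(expected chrom:start-end with 1-based inclusive coordinates)"
        )
    start, end = int(m.group("start")), int(m.group("end"))
    if start < 1 or end < start:
        raise ConfigError(
            f"line {lineno}: invalid coordinates {start}-{end} "
            "(need 1 <= start <= end)"
        )
    return (label, m.group("chrom"), start, end)


def parse_config(text: str, strict: bool = False) -> RunConfig:
    """Parse INI-style configuration text into a :class:`RunConfig`.

    Unknown keys raise in ``strict`` mode and warn otherwise.  The returned
    config has every field explicit (defaults applied).
    """
    if not text.strip():
        raise ConfigError("configuration is empty")

    cp = configparser.ConfigParser(
        delimiters=("=",),
        allow_no_value=True,
        comment_prefixes=("#", ";"),
        inline_comment_prefixes=("#", ";"),
        strict=False,
    )
    cp.optionxform = str  # preserve case; keys matched case-insensitively below
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"malformed INI: {exc}") from exc

    sections = {name.lower(): name for name in cp.sections()}
    known_sections = {"params", "filter", "includes"}
    for name in sections:
        if name not in known_sections:
            msg = f"unknown section [{sections[name]}]"
            if strict:
                raise ConfigError(msg)
            logger.warning(msg)

    cfg = RunConfig()

    def section_items(lower_name: str) -> dict[str, str]:
        if lower_name not in sections:
            return {}
        return {
            key.lower(): (value if value is not None else "")
            for key, value in cp.items(sections[lower_name])
        }

    params = section_items("params")
    for key, value in params.items():
        if key not in _PARAM_KEYS:
            msg = f"unknown key {key!r} in [PARAMS]"
            if strict:
                raise ConfigError(msg)
            logger.warning(msg)
            continue
        if key == "motif":
            cfg.motif = value.strip().upper()
        elif key == "stage1_repeats":
            cfg.stage1_repeats = _parse_int(key, value, 1)
        elif key == "stage2_min_repeats":
            cfg.stage2_min_repeats = _parse_int(key, value, 1)
        elif key == "wildcard_prefix":
            cfg.wildcard_prefix = _parse_int(key, value, 0)
        elif key == "strands":
            v = value.strip().lower()
            if v not in ("both", "forward", "reverse"):
                raise ConfigError(
                    f"strands must be both/forward/reverse, got {value!r}"
                )
            cfg.strands = v
        elif key == "mode":
            v = value.strip().lower()
            if v not in ("regions", "full"):
                raise ConfigError(f"mode must be 'regions' or 'full', got {value!r}")
            cfg.mode = v
        elif key == "workers":
            cfg.workers = _parse_int(key, value, 1)
        elif key == "scaling":
            try:
                cfg.scaling = float(value)
            except ValueError as exc:
                raise ConfigError(f"scaling: expected a number, got {value!r}") from exc
            if cfg.scaling <= 0:
                raise ConfigError("scaling must be > 0")

    filt = section_items("filter")
    for key, value in filt.items():
        if key not in _FILTER_KEYS:
            msg = f"unknown key {key!r} in [FILTER]"
            if strict:
                raise ConfigError(msg)
            logger.warning(msg)
            continue
        if key == "min_read_length":
            cfg.min_read_length = _parse_int(key, value, 0)
        else:
            setattr(cfg, key, _parse_bool(key, value))

    cfg.includes = [
        _parse_include_line(lineno, line)
        for lineno, line in _includes_entries(text)
    ]
    labels = [l for l, *_ in cfg.includes]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ConfigError(f"duplicate region labels in [INCLUDES]: {sorted(dupes)}")

    if cfg.mode == "regions" and not cfg.includes:
        raise ConfigError(
            "mode=regions requires at least one region in [INCLUDES] "
            "(no regions defined)"
        )

    # Validate motif parameters eagerly so errors surface at parse time.
    cfg.motif_spec()
    return cfg


def parse_config_file(path: str, strict: bool = False) -> RunConfig:
    """Read and parse a configuration file."""
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    return parse_config(text, strict=strict)
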