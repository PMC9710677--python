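"""JSON and TSV report writing, with lossless round-trip readers.

The JSON report is the machine-readable record of a run: the fully
resolved configuration, per-region and per-category tallies, repeat-unit
variant counts, the depth-normalized estimate, tool version and an MD5
checksum of the input.  The TSV is a flat tabular view — one row per
include region plus one summary row per category — for spreadsheet and
shell-pipeline use.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from typing import Optional

from . import __version__
from .quantify import SampleSummary, TelomereEstimate
from .scan import CategoryTally, RegionTally, ScanReport

__all__ = [
    "ReportError",
    "write_reports",
    "write_json_report",
    "read_json_report",
    "write_tsv_report",
    "read_tsv_report",
    "preflight_outputs",
    "file_md5",
]

_TSV_COLUMNS = [
    "row_type",
    "label",
    "chromosome",
    "start",
    "end",
    "examined",
    "filtered",
    "stage1_passes",
    "stage2_passes",
]


class ReportError(RuntimeError):
    """Raised for unwritable outputs or unreadable report files."""


def file_md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def preflight_outputs(*paths: Optional[str]) -> None:
    """Fail before any scanning starts if an output path is unwritable."""
    for path in paths:
        if path is None:
            continue
        directory = os.path.dirname(os.path.abspath(path))
        if not os.path.isdir(directory):
            raise ReportError(f"output directory does not exist: {directory}")
        if not os.access(directory, os.W_OK):
            raise ReportError(f"output directory is not writable: {directory}")


def build_json_document(
    report: ScanReport,
    summary: Optional[SampleSummary] = None,
    estimate: Optional[TelomereEstimate] = None,
    config_echo: Optional[dict] = None,
    bam_path: Optional[str] = None,
) -> dict:
    doc: dict = {
        "tool": "telotally",
        "version": __version__,
        "scan": report.to_dict(),
    }
    if config_echo is not None:
        doc["config_echo"] = config_echo
    if bam_path is not None:
        doc["input"] = {"bam": os.path.abspath(bam_path), "md5": file_md5(bam_path)}
    if summary is not None:
        doc["sample"] = {
            "label": summary.label,
            "total_records": summary.total_records,
            "raw_telomeric": summary.raw_telomeric,
        }
    if estimate is not None:
        doc["estimate"] = estimate.to_dict()
    return doc


def write_json_report(doc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str) -> dict:
    """Read a JSON report; ``scan`` / ``estimate`` keys are additionally
    reconstructed into package objects under ``_scan`` / ``_estimate``."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ReportError(f"cannot read JSON report {path}: {exc}") from exc
    if "scan" in doc:
        doc["_scan"] = ScanReport.from_dict(doc["scan"])
    if "estimate" in doc:
        doc["_estimate"] = TelomereEstimate.from_dict(doc["estimate"])
    return doc


def write_tsv_report(report: ScanReport, path: str) -> None:
    """One row per region, then one summary row per category present."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for rt in report.regions:
            writer.writerow(
                [
                    "region",
                    rt.region.label,
                    rt.region.chromosome,
                    rt.region.start,
                    rt.region.end,
                    rt.tally.examined,
                    rt.tally.filtered,
                    rt.tally.stage1_passes,
                    rt.tally.stage2_passes,
                ]
            )
        for name, tally in report.categories.items():
            writer.writerow(
                [
                    "category",
                    name,
                    "",
                    "",
                    "",
                    tally.examined,
                    tally.filtered,
                    tally.stage1_passes,
                    tally.stage2_passes,
                ]
            )


def read_tsv_report(path: str) -> tuple[list[RegionTally], dict[str, CategoryTally]]:
    """Round-trip reader for the TSV report."""
    regions: list[RegionTally] = []
    categories: dict[str, CategoryTally] = {}
    try:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames != _TSV_COLUMNS:
                raise ReportError(f"{path}: unexpected TSV columns {reader.fieldnames}")
            for row in reader:
                tally = CategoryTally(
                    examined=int(row["examined"]),
                    filtered=int(row["filtered"]),
                    stage1_passes=int(row["stage1_passes"]),
                    stage2_passes=int(row["stage2_passes"]),
                )
                if row["row_type"] == "region":
                    regions.append(
                        RegionTally.from_dict(
                            {
                                "label": row["label"],
                                "chromosome": row["chromosome"],
                                "start": int(row["start"]),
                                "end": int(row["end"]),
                                **tally.to_dict(),
                            }
                        )
                    )
                elif row["row_type"] == "category":
                    categories[row["label"]] = tally
                else:
                    raise ReportError(f"{path}: unknown row type {row['row_type']!r}")
    except OSError as exc:
        raise ReportError(f"cannot read TSV report {path}: {exc}") from exc
    return regions, categories


def write_reports(
    report: ScanReport,
    summary: Optional[SampleSummary] = None,
    estimate: Optional[TelomereEstimate] = None,
    json_path: Optional[str] = None,
    tsv_path: Optional[str] = None,
    config_echo: Optional[dict] = None,
    bam_path: Optional[str] = None,
) -> dict:
    """Write whichever of the JSON/TSV outputs were requested; returns the
    JSON document (also when no path was given, for programmatic use)."""
    doc = build_json_document(
        report,
        summary=summary,
        estimate=estimate,
        config_echo=config_echo,
        bam_path=bam_path,
    )
    if json_path:
        write_json_report(doc, json_path)
    if tsv_path:
        write_tsv_report(report, tsv_path)
    return doc
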