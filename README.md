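# telotally

Telomere content estimation from whole-genome sequencing BAM files.

Telomeres are (TTAGGG)n repeat tracts at chromosome ends; their length
changes with ageing and in cancer, where telomere maintenance is a hallmark
of continued proliferation. Laboratory assays (qPCR, Southern blot) measure
telomere length from DNA samples, but whole-genome sequencing data already
contains the information: the number of reads made of concurrent telomeric
repeats, normalized for sequencing depth, is a proxy for relative telomere
length. `telotally` counts those reads quickly and reports per-sample
telomere content and tumour/normal log2 ratios.

## Method

Reads are classified by a two-stage matcher:

* **Stage 1** — a fast exact-substring gate: the read must contain
  `(TTAGGG)₃` or its reverse complement `(CCCTAA)₃` (three concurrent
  copies of the canonical hexamer; reads from the C-rich strand show the
  reverse-complement form). Plain string containment keeps this cheap
  enough for every read.
* **Stage 2** — run only on gate-passing reads: a regex extracts every
  maximal run of ≥ 2 concurrent repeat units in which the first three bases
  of each unit may vary (`NNNGGG` units, or `CCCNNN` on the opposite
  strand, with `N` here meaning any of A/C/G/T — ambiguous `N` base calls
  never match). Reverse-strand runs are found by scanning the reverse
  complement of the read with the forward pattern, so a read and its
  opposite-strand image always tally identically.

A read counts **once** toward telomere content if stage 2 passes,
regardless of how many runs it contains; per-unit variant tallies (e.g.
`TTAGGG: 412, TTGGGG: 9`) are reported separately.

Scanning is region-restricted: telomeric reads map to a small set of
reference locations, so the scanner visits only user-defined include
regions plus all unmapped reads (where poorly-aligning telomeric reads
accumulate). A full scan over every record is available as a validation
mode and additionally tallies telomeric reads mapped elsewhere in the
genome. Duplicate-marked, secondary, supplementary and QC-failed records
are excluded by default.

Per sample, with `raw` stage-2-passing reads and `total` records in the BAM
(from index statistics):

    content = raw × 10⁶ / total        (telomeric reads per million records)
    log2_ratio = log2(content_tumour / content_normal)

## Worked example

Generate a small synthetic BAM with 8 telomeric reads planted in the
include regions, 2 unmapped telomeric reads and 12 background reads, then
scan it:

```sh
cat > fixture.json <<EOF
{"seed": 1, "n_forward": 8, "n_background": 12, "n_unmapped_telomeric": 2}
EOF
cat > run.ini <<EOF
[PARAMS]
mode = regions

[INCLUDES]
chr1_tel  chr1:1-10000
chr2_tel  chr2:1-10000
EOF
telotally make-fixture --spec fixture.json --out demo
telotally scan --bam demo/fixture.bam --config run.ini \
    --json demo/sample.json --tsv demo/sample.tsv --label demo
```

which prints

```
demo	telomeric_reads=10	total_records=22	scaled=454545.4545 (per 1e+06 records)
```

— all 10 planted telomeric reads (8 in regions + 2 unmapped) were
recovered out of 22 records, giving a content of ~454545 telomeric reads
per million records (this fixture is almost half telomeric; real
whole-genome samples are orders of magnitude lower). The JSON report
carries per-region tallies, stage-1/stage-2 pass counts, motif-variant
counts and the resolved configuration; the TSV has one row per region plus
one per category. Two such reports feed the ratio command:

```sh
telotally ratio --tumour-json tumour.json --normal-json normal.json
```

which prints `log2_ratio=...` — 0 for equal content, negative for telomere
loss in the tumour.

## Library use

```python
from telotally import build_motif_spec, load_regions, scan, scale_counts, total_read_count

spec = build_motif_spec()                      # TTAGGG, 3× gate, ≥2 stage-2 units
regions = load_regions([("chr1_tel", "chr1", 1, 10_000)])
report = scan("sample.bam", regions, spec)
est = scale_counts(report.telomeric_read_count, total_read_count("sample.bam"))
print(est.scaled_count)                        # telomeric reads per million
```
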