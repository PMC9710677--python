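# Methods

## Model

`telotally` estimates relative telomere length from short-read whole-genome
sequencing as *telomere content*: the number of reads consisting of
concurrent telomeric repeats, normalized by the total number of records in
the file. The underlying assumptions are that (i) the number of telomeric
fragments sampled by sequencing is proportional to the total amount of
telomeric DNA in the genome, (ii) the total record count is proportional to
sequencing depth, and (iii) systematic biases (GC bias, library chemistry)
are comparable between samples being compared — which is why the headline
statistic is a within-pair ratio (tumour vs matched normal) rather than an
absolute length.

## Two-stage matching

Classification of a read is a two-pass process designed so the expensive
operation runs on almost no reads:

1. **Gate (stage 1).** Exact substring containment of
   `TTAGGG × stage1_repeats` or its reverse complement
   (`CCCTAA × stage1_repeats`). With the default of 3 repeats this is an
   18-base exact string; string containment is a few nanoseconds per read
   versus microseconds for a regex.
2. **Confirmation (stage 2).** A regex over gate-passing reads extracting
   all maximal runs of at least `stage2_min_repeats` (default 2) concurrent
   repeat units, where the first `wildcard_prefix` (default 3) bases of
   each unit are free over {A,C,G,T}: forward units `[ACGT]{3}GGG`,
   reverse units `CCC[ACGT]{3}`. Two concurrent units is the repeat
   threshold at which read selection correlates best with laboratory
   telomere assays; the 3-base wildcard admits the common telomere variant
   repeats (TGAGGG, TCAGGG, …) while keeping the GGG core exact.

The gate is deliberately stricter than the confirmation (3 exact repeats
vs 2 degenerate ones): stage 2 never sees, and therefore never rescues, a
read without a perfect triple repeat. This trades a small amount of
sensitivity for a large constant-factor speedup, and is the behaviour the
tallies reflect: `stage2_passes ≤ stage1_passes` always.

A read contributes **once** to telomere content if stage 2 passes,
however many runs it contains. Separately, every matched run is split into
its hexamer units and tallied per variant, which gives a cheap summary of
variant-repeat composition without attempting telomere-variant-repeat
classification proper.

### Strand convention

Telomeric fragments are sequenced from either strand, so both `TTAGGG` and
`CCCTAA` forms are matched by default (a single-strand mode exists for
asymmetric protocols). Reverse-strand runs are found by scanning the
*reverse complement* of the read with the forward pattern and mapping
coordinates back, rather than by running a mirrored pattern left-to-right
over the read. The two conventions agree on every clean telomeric
sequence; they differ only on ambiguous G/C homopolymer phasings (e.g.
`…CCCCCCCCCC…`, where several unit frames overlap and a left-to-right
greedy scan wastes different bases on each strand). Only the
reverse-complement convention guarantees exactly mirror-identical repeat
tallies for a read and its opposite-strand image, which is the property
read counting relies on. In read coordinates this makes reverse runs
rightmost-greedy; forward runs are standard leftmost-greedy regex matches.

Other matching choices: sequences are uppercased before matching; `N`
never matches any position, including wildcard positions (no-call runs are
not telomeric evidence); hits on the same strand never overlap, and a hit
cannot be extended by a whole unit at either end without overlapping a
neighbouring hit.

## Scanning

The scanner requires a duplicate-marked, coordinate-sorted, indexed BAM.
Two modes:

* **Region mode (default).** Index queries over user-supplied include
  regions (1-based inclusive coordinates, samtools convention; BED import
  converts from 0-based half-open), plus a streaming pass selecting
  unmapped-flagged records. Telomeric reads that align at all pile up at a
  small number of reference locations, so a handful of regions plus the
  unmapped fraction captures nearly all of them at a fraction of the cost
  of a full pass. No default region list ships with the package: the right
  coordinates depend on the reference assembly, and supplying them is the
  user's statement of where telomeric alignments live on their reference.
* **Full scan.** Every record; stage-2-passing mapped reads outside all
  include regions are tallied under a separate `genomic` category. This
  mode doubles as the validation oracle for region mode — restricted to
  the `includes` and `unmapped` categories the two must agree exactly, and
  the test suite enforces this on every fixture.

Records are de-duplicated globally by identity (query name, flag,
reference, position): a read overlapping two include regions is counted
once, attributed to the first containing region in (chromosome, start)
order. Unmapped records stored with a placement coordinate (mates of
mapped reads) are returned by index queries too; they are excluded from
the region stream and owned entirely by the unmapped stream, so they are
never double-counted. Duplicate, secondary, supplementary and QC-fail
records are excluded by default (duplicate marking is required precisely
so PCR/optical duplicates can be dropped); all four switches and a minimum
read length are configurable.

With `workers > 1`, regions are processed in a thread pool (one partition
per region plus one for unmapped reads) and per-read outcomes are merged
in sorted region order with the same global de-duplication, so the report
is a pure function of the inputs and byte-identical for any worker count.
The unmapped stream is a full streaming pass selecting flag-0x4 records;
BAM indices provide no random access to placed-unmapped mates scattered
through the file, so correctness takes precedence over skipping that pass.

## Quantification

* `content = raw × S / total`, with `S = 10⁶` by default — "telomeric
  reads per million records". The label is deliberate: the tool reports
  content and ratios, never absolute length in kilobases, which would
  require laboratory calibration.
* `total` comes from index statistics (mapped + unmapped, before policy
  filtering) — available without a pass over the file. A strict mode
  refuses unindexed input; otherwise a counting pass is the fallback. The
  denominator choice is recorded in the report.
* The pair statistic is `log2(content_t / content_n)`: 0 for equal
  content, antisymmetric under swapping the samples. A zero scaled count
  on either side is an error naming the sample (no silent pseudocount; an
  explicit pseudocount option exists for cohort pipelines that prefer it).
* Ratio computation from saved reports can restrict the counted categories
  (default `includes,unmapped`; `genomic` may be added for full-scan
  reports).

## Synthetic fixtures

The generator plants reads whose fate under the default matcher and policy
is known by construction, so expected tallies are analytic, not
probabilistic:

* pure forward/reverse reads — whole-read motif tilings;
* degenerate reads — a 3-unit canonical block (so the gate passes)
  followed by units with randomized 3-base prefixes;
* near-miss reads — repeat content that never forms three concurrent
  canonical units (two-unit blocks with spacers, or isolated units);
* background reads — rejection-sampled to contain *no* stage-2 run at all;
* unmapped telomeric reads, with and without placement coordinates;
* duplicate-flagged telomeric copies at identical coordinates;
* telomeric reads mapped outside every include region (full-scan only).

Every constructed read is verified by an independent brute-force checker
(window enumeration, no regexes) before being written — never by the
matcher under test. Fixtures are emitted as SAM text first (inspectable in
any editor), then sorted, compressed and indexed. A fixed seed reproduces
the SAM byte-for-byte.

For ratio experiments, tumour/normal pairs are generated with planted
telomeric fractions; the telomeric read count is a binomial draw at the
planted fraction, so recovery tests measure the estimator against genuine
sampling noise rather than an exactly planted count. Default test
conditions: 100 bp reads, two 10 kb include regions on a two-chromosome
toy reference, fixture sizes of tens of reads for tally tests and
3,000–5,000 reads per sample for ratio recovery — large enough that the
3-standard-error binomial band is a meaningful check, small enough that
the whole suite runs in seconds.

What the fixtures do **not** emulate: sequencing errors and base
qualities, insert-size structure, GC bias, interstitial telomeric sequence
abundance genome-wide, or reference-genome alignment artefacts. Passing
tests therefore demonstrate that the counting machinery is exact on known
input, and that ratio recovery behaves as binomial sampling predicts —
not that the default regions or thresholds are optimal for any particular
reference or library chemistry.

## Numerical and degenerate-input choices

* Scaling uses double-precision floats; `raw × S / total` with raw and
  total exact integers is accurate to 1 ulp, and the depth-invariance test
  holds to 1e-9 relative tolerance.
* An empty BAM yields zero tallies without error; scaling it raises
  (`total = 0` is an error, never an infinity or NaN).
* Tie-break for hits at the same offset on both strands: forward first.
* Region sets may overlap (flagged in the log); attribution is
  deterministic as described above.
* Config parsing resolves every tunable to an explicit value and echoes
  the resolved configuration into the JSON report, so two reports are
  comparable key-by-key.

## Known limitations

* No CRAM input; SAM/BAM only.
* No GC or coverage-bias correction, no tumour purity/ploidy adjustment:
  the log2 ratio is a raw content ratio.
* Content is not converted to base-pair length.
* The stage-2 wildcard admits any base in the variable prefix; mismatches
  inside the `GGG` core are never tolerated, so G-core sequencing errors
  in otherwise telomeric units truncate runs.
* Region mode is exactly as good as the supplied region list; reads that
  are telomeric but align outside the regions and are not unmapped are
  only visible to a full scan.
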