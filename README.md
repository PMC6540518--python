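# telomere-profiler

Estimate telomere content and telomere-repeat composition from aligned
short-read sequencing data (BAM/SAM), for single samples or matched
tumor/control pairs.

The pipeline:

1. **Extraction** — reads containing at least `n` telomere repeats
   (t-type `TTAGGG`, c-type `TCAGGG`, g-type `TGAGGG`, j-type `TTGGGG`,
   or their reverse complements) are selected, with
   `n = floor(read_length × 0.06)` (6 repeats for 100-bp reads) unless
   overridden. Non-consecutive (default) or consecutive matching is
   supported, and the pattern set is configurable.
2. **Classification** — extracted reads are sorted by alignment position
   into four fractions using a UCSC cytoBand-style chromosome-band file:
   *subtelomeric* (terminal band, mapping quality ≥ 8), *intrachromosomal*
   (interior band), *junction spanning* (unmapped read whose mate maps to
   a terminal band), and *intratelomeric* (unmapped or low mapping
   quality).
3. **Content** — GC-corrected telomere content in TRPM (intratelomeric
   reads per million reads of 48–52% GC), plus an uncorrected per-million
   value and, for pairs, the tumor/control log2 ratio.
4. **TVR profiling** — intratelomeric reads are scanned for `NNNGGG`
   variant hexamers (arbitrary context, base quality ≥ 20 at all six
   positions), singleton variants `(TTAGGG)₃-NNNGGG-(TTAGGG)₃`, and the
   18-bp sequence contexts around a configurable TVR list; counts are
   normalized (per intratelomeric read / per total read) with per-hexamer
   log2 tumor/control ratios.

A synthetic-fixture generator (`telomere_profiler.simulate`) emits
SAM/BAM files with fully known ground truth — planted categories, TVR
and singleton counts, and closed-form TRPM — so the whole pipeline is
testable without external data.

## CLI

```sh
# paired run
telomere-profiler run --tumor tumor.bam --control control.bam \
    --banding cytoBand.txt --out results/ [--plot]

# single sample
telomere-profiler run --tumor sample.bam --banding cytoBand.txt --out results/

# options: -r/--repeats PATTERN ... , -rt/--repeat-threshold N, --consecutive,
#          -mqt/--mapq-threshold N, --min-base-quality N, --tvr-context HEX ...,
#          --exclude-duplicates, --read-format {bam,sam}, --strict

# synthetic fixture with ground truth
telomere-profiler simulate --spec fixture.json --out sim/ --seed 7
```

Outputs in the run directory: `summary.tsv` (per-sample totals,
GC-matched denominator, per-category counts, TRPM, log2 T/C),
`tvr_counts.tsv`, `singletons.tsv`, `contexts.tsv`, `spectrum.tsv`
(per-chromosome distribution of non-intratelomeric telomeric reads),
`repeats_per_read.tsv`, per-category read files per sample, and optional
PNG diagnostics with `--plot`.

## Library

```python
from telomere_profiler import RunConfig, run_pair

config = RunConfig(band_file="cytoBand.txt", out_dir="results")
result = run_pair("tumor.bam", "control.bam", config)
result.summary               # pandas DataFrame
result.content_log2_tc       # telomere-content log2 T/C
result.profile.hexamer_table # TVR counts with per-hexamer log2 T/C
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and brute-force oracle
cross-checks for every scanning primitive, plus end-to-end ground-truth
recovery on synthetic fixtures (`tests/test_acceptance.py`).

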