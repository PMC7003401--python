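# sasnv

Reference-free, mapping-free somatic SNV calling from paired tumour–control
short-read data using generalised suffix arrays, plus a paired-read
simulator and an evaluation toolkit for benchmarking.

## Method overview

The caller never uses read mapping coordinates to *detect* variants.
Instead it organises the raw reads by genomic locus through direct
sequence comparison:

1. **Preprocessing** — an optional exact-match prefilter (`emfilter`,
   on by default in the CLI) discards tumour reads that match the
   reference exactly on either strand; reads are split at `N` characters
   and N-free fragments of ≥ 30 bp are kept.
2. **Suffix-array SNV detection** — a *primary* generalised suffix array
   is built over the tumour + control read corpus and partitioned into
   *sections*: maximal intervals of suffixes sharing a ≥ 30-character
   prefix. Sections whose suffixes are (up to a contamination tolerance
   `e_cont`, default 0) exclusively tumour-derived and contain at least
   `pMSS` (default 2) tumour suffixes mark candidate variant loci. The
   tumour reads they contain are extracted into an *auxiliary* suffix
   array that also includes reverse complements, so that variant
   evidence split across sequencing strands is pooled; auxiliary
   sections of size ≥ `aMSS` (default 4) become *variant blocks* —
   gapless multi-read alignments derived from suffix offsets.
3. **Consensus pairs** — each deduplicated block yields a phred-filtered
   tumour consensus `T` (bases with phred < 35 do not vote); control
   reads sharing a 30-mer with `T` (either strand) are recruited through
   the primary array and give the control consensus `C`.
4. **Filtering** — pairs whose optimal `T`/`C` alignment needs an indel
   are discarded; columns where the control matrix shows two alleles
   above ratio `e` (default 0.1) are masked (`T_j := C_j`, suppressing
   germline SNPs); pairs generating ≥ 5 masking events across their
   matrices are discarded as repeat-locus chimeras.
5. **Calling** — `C` is mapped to the reference (built-in gapless
   seed-and-extend aligner; pluggable), and every remaining `T`≠`C`
   mismatch with ≥ 4 high-quality supporting tumour reads is reported at
   coordinate `μ = m + i`, where `m` is `C`'s mapping position and `i`
   the mismatch index in `C`. Calls are merged and written as VCF 4.2.

Because detection only ever inspects the leading 30 characters of each
suffix, the large-corpus suffix-array backend sorts packed 30-mer keys
with a single stable radix-style pass; a naive full-lexicographic
backend is used for small inputs and as the reference implementation in
the test suite.

## Command-line usage

Simulate a paired dataset with implanted SNVs and a truth VCF:

```sh
sasnv simulate --out-dir sim --ref-length 200000 --coverage 100 \
    --n-snvs 40 --allele-frequencies 0.05 --seed 1
```

Call somatic SNVs:

```sh
sasnv call --tumour sim/tumour.fastq --control sim/control.fastq \
    --reference sim/reference.fasta --output calls.vcf --report report.json
```

Key flags: `--pmss/--amss` (suffix-count thresholds), `--e-cont`
(tumour-in-normal tolerance), `--phred-threshold` (consensus filter,
default 35), `--mask-e` / `--mask-discard` (masking and multi-locus
filters), `--emfilter/--no-emfilter`, `--min-alt-support`.

Score calls against a truth VCF (precision/recall plus cluster-size
stratified *k*-recall / *k*-precision for clustered SNVs):

```sh
sasnv evaluate --calls calls.vcf --truth sim/truth.vcf --out metrics.json
```

## Library layout

| module              | contents                                                |
|---------------------|---------------------------------------------------------|
| `sasnv.gsa`         | segment corpus, generalised suffix array, sections, enrichment, variant blocks |
| `sasnv.preprocess`  | N-splitting, exact-match tumour read filter             |
| `sasnv.consensus`   | block dedupe, frequency matrices, consensus strings, control recruitment |
| `sasnv.filters`     | indel / masking / multi-locus filters                   |
| `sasnv.caller`      | control-consensus mapping, `μ = m + i` calling, VCF IO  |
| `sasnv.reference`   | reference k-mer index (exact containment + gapless mapping) |
| `sasnv.simulate`    | reference/variant/read simulation, truth VCF, evaluation metrics |
| `sasnv.pipeline`    | stage orchestration and run reports                     |
| `sasnv.experiments` | the two benchmark experiment recipes                    |
| `sasnv.cli`         | `sasnv simulate | call | evaluate`                      |

## Tests

```sh
python -m pytest -q tests/
```

The suite contains per-module unit tests, property tests against
brute-force oracles (suffix order, LCP, sections, frequency matrices,
recruitment), and `tests/test_acceptance.py`, which re-runs desk-scale
versions of the two benchmark simulations (rare-SNV allele-frequency
series and clustered-SNV detection). The full suite takes roughly
15–20 minutes on one CPU; everything outside `test_acceptance.py`
finishes in well under a minute.

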