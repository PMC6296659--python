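# exocnv

Copy-number variant (CNV) and aneuploidy detection from whole-exome
sequencing (WES) read depth, with a seeded synthetic cohort generator and
concordance evaluation against array-based gold-standard call sets.

WES is usually analysed only for SNVs and indels, but its read-depth
signal also carries copy-number information: the number of reads covering
a captured region is roughly proportional to the number of genomic copies
present. `exocnv` turns that signal into clinical-style CNV screening for
people building or validating exome pipelines:

- **Focal CNV calling** (`CnvCaller`): for each test sample a reference
  set of samples with similar read-count profiles is selected and
  aggregated; the test count *y*<sub>w</sub> in window *w* is modelled as
  beta-binomial given the window total *n*<sub>w</sub> = *y*<sub>w</sub> +
  *r*<sub>w</sub> with expected diploid fraction φ and overdispersion θ.
  A 3-state hidden Markov model over copy numbers *c* ∈ {1, 2, 3}, with
  emission mean fraction (c/2)φ / ((c/2)φ + 1 − φ), is decoded by
  Viterbi; each non-diploid segment becomes a call scored with a Bayes
  factor, BF = Σ<sub>w</sub> log₁₀ [BB(y; n, f<sub>c</sub>, θ) /
  BB(y; n, f₂, θ)]. Deep losses are relabelled homozygous (CN 0).
- **Aneuploidy and mosaicism** (`AneuploidyDetector`): capture-restricted
  chromosomal read counts are normalised so every sample has the same
  total, and each sample's per-chromosome ratio ρ to the cross-sample
  mean is screened with the two-sided Grubbs outlier test
  (sex-stratified for chrX/chrY). The mosaic cell fraction follows from
  the dosage arithmetic f = 2|ρ − 1| on a disomic baseline, or
  f = 1 − ρ for male chrY loss.
- **Annotation and prioritisation** (`CallAnnotator`): basepair Jaccard
  similarity against ISCA-like and DGV-like interval databases, exon
  content, cohort recurrence, heterozygous-SNP allele-fraction
  consistency (deletions → fractions near 0/1, duplications → 1/3 and
  2/3), and a high/medium/low tier built from Bayes-factor cutoffs (20,
  100), a 100 kb size criterion and a recurrence cap.
- **Concordance** (`exocnv.concordance`): array gold-standard calls are
  stratified by detectability (overlapping capture, non-repeated,
  adequately covered), matched to same-direction WES calls, and
  summarised as stratified sensitivity percentages.
- **Synthetic cohorts** (`exocnv.datasets`): seeded generation of capture
  designs, overdispersed window counts scaled by copy number (including
  mosaic and polymorphic events and sex-dependent chrX/chrY baselines),
  SNP allele counts, and breakpoint-jittered "array" call sets, so the
  whole pipeline is testable end to end without external data.

All estimators follow scikit-learn conventions (`fit`/`predict`/
`transform`, `get_params`/`set_params`, fitted attributes with trailing
underscores) and operate on plain containers (`ReadCountMatrix`, pandas
DataFrames).

## Worked example

An eight-sample validation-style cohort: five carriers (a ~1.0 Mb and a
~5.6 Mb deletion, two ~1.4 Mb duplications, one whole-chromosome
trisomy) plus three event-free negatives, simulated at 62× mean window
depth.

```python
from exocnv import AneuploidyDetector, CallAnnotator, CnvCaller, make_pilot_cohort

cohort = make_pilot_cohort(seed=1)
calls = CnvCaller().fit(cohort.counts).predict()
annotated = CallAnnotator(design=cohort.design).fit(calls).transform(calls)
print(annotated[annotated["tier"] == "high"].to_string(index=False))

det = AneuploidyDetector().fit(cohort.counts)
print("\n".join(det.summary_lines()))
```

prints

```
sample chrom   start     end  cn  bayes_factor  size_bp  n_exons tier
  S001  chr1 1348490 2349026   1    170.294186  1000536       73 high
  S002  chr2 1966387 3365600   3    189.307226  1399213      126 high
  S003  chr3  161487 5780318   1    658.205915  5618831      454 high
  S004  chr4 3636016 5034274   3    174.969118  1398258      102 high
  S005  chr5   18713 6162736   3    260.857517  6144023      497 high
S003: chr3x1 (ratio=0.600, f=0.80)
S005: chr5x3 (ratio=1.264, f=0.53)
```

Reading the output: each of the five carriers gets exactly one high-tier
call matching its injected event — `cn` is the called copy number (1 =
heterozygous deletion, 3 = duplication), `bayes_factor` the log₁₀
likelihood ratio of the called state over diploid summed along the
segment, and the negatives S006–S008 get nothing. The ploidy screen
independently flags the trisomic sample (`chr5x3`, coverage ratio 1.26)
and the near-chromosome-scale deletion; `f` is the estimated fraction of
cells carrying the event (1.0 would be fully constitutional; the values
here are damped by the small scaled-down genome, see
`docs/methods.md`).

The same pipeline is available from a shell:

```sh
exocnv simulate --preset pilot --seed 1 --out-dir sim/
exocnv call --counts sim/counts.tsv --out sim/calls.tsv
exocnv aneuploidy --counts sim/counts.tsv --sexes sim/sexes.tsv --out sim/ploidy.tsv
exocnv annotate --calls sim/calls.tsv --design sim/design.bed --out sim/annotated.tsv
exocnv report --annotated sim/annotated.tsv --aneuploidy sim/ploidy.tsv
```

`exocnv compare` matches a WES call set against an array gold standard
and prints the stratified sensitivity table; `exocnv config-show` lists
every tunable with its default.

## Layout

```
src/exocnv/
  core.py         intervals, capture designs, count matrices, truth events
  datasets.py     synthetic cohort generation
  depth.py        reference selection, beta-binomial HMM caller, Bayes factors
  aneuploidy.py   chromosome ratios, Grubbs screen, mosaic fractions
  annotate.py     database/exon/recurrence/VAF annotation and tiers
  concordance.py  gold-standard matching and stratified sensitivity
  io.py           BED/TSV readers and writers (coordinate conventions)
  config.py       PipelineConfig (validated, hashable)
  cli.py          the exocnv command
docs/methods.md   model details, defaults, and known limitations
```
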