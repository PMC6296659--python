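# Methods

This note documents the models implemented in `exocnv`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical corner cases. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Read-depth CNV model

### Windowing

Capture regions are tiled left-to-right into 100 bp windows
(`window_bp`, configurable). A terminal remainder at least half a window
long becomes its own window; a shorter remainder is merged into the
preceding window; a region shorter than half a window stands alone.
Windows therefore tile the capture exactly, and calls never extend
beyond captured sequence.

### Reference selection

For a test sample, candidate references are ranked by Pearson
correlation between log-CPM window profiles (log1p of counts per million
of the sample total). Members are added greedily in rank order while the
predicted sampling variance of the test fraction — mean over windows of
φ(1−φ)(1+(n<sub>w</sub>−1)θ̂)/n<sub>w</sub>, with θ̂ refitted for each
candidate set — keeps decreasing, capped at `max_members` (default 10).
Ties in correlation break by sample-id order, making selection
deterministic. Member counts are **summed**, not averaged: the
beta-binomial likelihood needs genuine trials, and summation preserves
the count nature of the data.

On designs containing chrX/chrY the candidate pool is restricted to
samples of the test sample's sex (taken from the count matrix or
inferred from the chrY count share). An opposite-sex background makes
the entirety of chrX/chrY look copy-altered and produces whole-arm
artifact calls; sex-matching is standard read-depth practice and is
exposed as `sex_match_reference` (default on).

### Emission model

With aggregated reference counts r<sub>w</sub> and test counts
y<sub>w</sub>, the diploid expectation of the test fraction is constant
under the global-ratio fit: φ = t/(1+t) with t = Σy/Σr. Overdispersion θ
is estimated by method of moments from the pooled excess of
(y−nφ)² over the binomial value nφ(1−φ) across autosomal windows
(sex-chromosome windows are excluded because sex composition, not
technical noise, dominates them), floored at `theta_floor` (default 0).
The beta-binomial is parameterised by mean fraction f and
overdispersion θ through α = f(1−θ)/θ, β = (1−f)(1−θ)/θ; θ = 0
degenerates exactly to the binomial. Copy number c shifts the emission
mean through the odds: f<sub>c</sub> = (c/2)φ / ((c/2)φ + 1 − φ).

### Segmentation and scoring

A 3-state HMM over c ∈ {1, 2, 3} is decoded per chromosome by Viterbi.
The diploid state is sticky with exit probability `q` = 10⁻⁴ per window
(split evenly between loss and gain); CNV states persist with
probability 1 − 1/L, L = `cnv_mean_windows` = 50, and return to diploid
(no direct loss↔gain transitions). CNVs are rare and multi-window; both
parameters are exposed in the configuration because no canonical values
exist for them. Windows with n<sub>w</sub> = 0 carry no evidence and
contribute log-ratio 0 to every state — an uncovered region can neither
support nor reject a call.

Each maximal non-diploid run becomes a call spanning exactly its
windows. Its Bayes factor is the summed per-window log₁₀ emission ratio
of the called state to diploid along the decoded path (not the full
forward-probability ratio): this matches the "likelihood ratio of CNV to
normal copy number" reading and is exactly testable against a
brute-force path enumeration oracle. Calls whose summed ratio is not
positive are discarded (they can arise only from near-tie decodings), so
every emitted call is better explained by its state than by diploidy.

Homozygous deletions are handled post hoc rather than as a fourth HMM
state: the c = 0 emission mean collapses toward zero and destabilises
decoding, so calls whose observed/expected-diploid ratio falls below
`min_ratio_cn0` = 0.15 are relabelled CN 0. The observed ratio uses the
odds-form diploid expectation (φ/(1−φ))·r<sub>w</sub>, which is
independent of the test count itself; the equivalent form φ·n<sub>w</sub>
would shrink with the very signal being measured. The integer CN label
is round(2 × ratio) clipped to [0, 4].

## Aneuploidy and mosaicism

Per-sample chromosome counts (capture windows only) are scaled by
k<sub>s</sub> = mean(total)/total<sub>s</sub> so all samples share the
same total, then divided by the per-chromosome cross-sample mean to give
ratios ρ. For chrX/chrY the mean is taken within the sample's sex group
(`sex_stratify`, default on); sex is inferred as male when the chrY
share exceeds 0.4× the male-typical (maximum) share. The 0.4 factor —
rather than exactly half — keeps a 50%-mosaic loss-of-Y male, whose
share sits precisely at half of typical, robustly inside the male group.

Outliers are flagged with the two-sided Grubbs test at α = 0.05 per
chromosome: G = max|x−x̄|/s against
G<sub>crit</sub> = ((N−1)/√N)·√(t²/(N−2+t²)), t the upper α/(2N)
Student-t quantile on N−2 df. The test is re-applied after removing a
flagged sample (capped at 10% of the cohort, at least one) so that two
aneuploid samples cannot mask each other. Zero-variance vectors yield no
outlier by definition.

The mosaic cell fraction is f = clip(2|ρ−1|, 0, 1) on a disomic
baseline (f = 1 at a constitutional trisomy or monosomy) and
f = clip(|1−ρ|, 0, 1) on the single-copy male chrY baseline. An
aneuploidy is **reported** only when a sample is a Grubbs outlier *and*
f ≥ `min_mosaic_fraction` (default 0.2): with per-chromosome testing at
α = 0.05, a pure statistical outlier at ρ ≈ 1.02 is expected by chance
in any clean cohort and is not a biological aneuploidy. The floor sits
well below the smallest mosaic fraction the depth signal can usefully
quantify at ~60× and well above the null spread of the ratios.

Two normalisation choices deserve note. First, the per-sample total
renormalisation slightly damps the very signal it preserves: a trisomic
chromosome inflates its carrier's total, so k<sub>s</sub> scales the
ratio down by a factor 1 + g/2 where g is the chromosome's share of the
capture. For a real small chromosome (g ≈ 2–4%) this is a 1–2% effect
and is accepted as part of the stated procedure. On deliberately tiny
synthetic genomes (2–4 equal chromosomes, g ≈ 25–50%) the damping is
large; validation cohorts therefore use a 26-chromosome design whose
per-chromosome share approximates real exomes. Second, the cross-sample
mean includes the sample under test by default
(`include_self_in_mean`); at cohort sizes of a few hundred this is
immaterial, but at the n ≈ 20 used in scaled-down validation the
aneuploid sample drags its own baseline, so the leave-one-out option is
used wherever a ratio is compared against an absolute expectation (for
example the 50%-coverage mosaic-LOY check).

## Annotation and tiers

Jaccard similarity is basepairs in the intersection over basepairs in
the union; on-disk 1-based inclusive coordinates and internal half-open
coordinates give identical values because the conversion is
length-preserving. Database similarity is computed only against
same-direction records (a deletion against loss records, a duplication
against gain records) — cross-direction overlap is clinically
meaningless even when the intervals coincide. The DGV-like annotation
reports the maximum population frequency of any overlapping record.

VAF consistency checks heterozygous-SNP alternate fractions against the
band implied by the called copy number: [0, w] ∪ [1−w, 1] for CN ≤ 1,
|f − 1/2| ≤ w for CN 2, within w of 1/3 or 2/3 for gains, with
w = `band_half_width` = 0.1 at site depth ≥ 30 and 2·√(0.25/depth)
below that (binomial sampling noise). Calls overlapping no SNPs report
an absent value, not zero.

Tiers operationalise the usual sign-out filters: **high** requires
BF > 100, ≥ 3 exons, recurrence in ≤ 2 other samples (≥ 50% reciprocal
overlap, same direction), and either size > 100 kb or Jaccard ≥ 0.5
against a pathogenic database record; **medium** requires BF > 20 and
the recurrence cap; everything else is **low**. The ISCA-similarity
threshold (0.5) and recurrence cap (2) are package choices — published
filter tables bin these quantities without printing operative cutoffs —
and every cutoff is configurable.

## Concordance

Gold-standard calls are stratified as *potentially detectable* (≥ 1 bp
overlap with a capture window), *non-repeated* (no same-direction call
in another sample at ≥ 50% reciprocal overlap), and *adequately covered*
(overlapping at least one exon of a characterised gene — symbols not
matching the configurable `LOC*`/`LINC*` patterns — with cohort-median
window depth ≥ 10). The depth rule is a proxy: whether the original
"adequately covered" filter was numeric or manual review is not
documented, so the threshold is exposed in the configuration. Matching
requires a same-sample, same-chromosome, same-direction WES call with
≥ `min_overlap_bp` (default 1) basepairs of overlap; the best match
maximises Jaccard, and one WES call may match several gold calls.
Sensitivity percentages are rounded half-up to one decimal; this
rounding convention can differ by one final digit from tables rounded
half-even, and the discrepancy is documented rather than special-cased.
Zero-total strata report an absent percentage, never 0.

## Synthetic data

The generator draws, per cohort: a shared per-window capture-efficiency
factor μ<sub>w</sub> (log-normal, σ = `capture_sigma` = 0.5, unit mean)
reproducing the strong window-to-window variation of exome capture;
per-sample depth factors (log-normal with CV `sample_depth_cv` = 0.1);
and counts with mean d<sub>s</sub>·μ<sub>w</sub>·depth·CN/2 (CN/1 for
male chrY, where one copy defines full coverage) and variance
mean·(1 + dispersion·mean), i.e. negative binomial with
`dispersion` = 0.01 (Poisson at 0). The default `mean_depth` = 62 reads
per window mirrors a ~62× exome. Mosaic events scale the effective copy
number as base + f·(CN − base); polymorphic events are assigned
independently to a random fraction (default 30%) of samples, producing
the copy-number-divergent regions that degrade reference-based calling.
Sex is a per-sample attribute: chrX baseline is 2/1 (F/M), chrY 0/1.
Heterozygous SNP sites are placed over autosomal capture regions and
sampled binomially at Poisson depth with allele fractions set by dosage
(1/2 diploid; 1/3 or 2/3 in duplications by random phase; hemizygous
fractions bounded by a 0.5% error rate in deletions; dosage-shifted for
mosaics). Array-style gold sets emit each focal event ≥ 10 kb once with
endpoints jittered uniformly up to ±2 kb — a free parameter, since array
breakpoint precision is not quantified in the sources this emulates.

All randomness flows from a single integer seed through a splittable
`numpy.random.SeedSequence`; identical seeds reproduce bit-identical
cohorts and no global state is touched.

What the generator does **not** emulate: GC-content bias and mappability
structure, batch effects between capture kits, raw reads (FASTQ/BAM),
segmental duplications, and tumor subclonality. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not performance on real exomes, where reference
quality and capture artifacts dominate.

### Problem sizes used in validation

The pilot-style cohort uses 7 chromosomes × 500 targets (~200 bp,
~12 kb gaps; chromosome span ≈ 6 Mb), 8 samples, and five events (two
deletions of ~1.0 and ~5.6 Mb, two ~1.4 Mb duplications, one trisomy);
the ~5.6 Mb deletion necessarily covers most of its scaled-down
chromosome. Ratio-accuracy checks use 26 chromosomes × 20 targets so
each chromosome is ~4% of the capture. The
deletion-versus-duplication asymmetry check injects 1,000 six-window
events of each direction in equal numbers across 40 samples. These sizes
are the package's own validation choices.

## Known limitations

- φ is constant across windows (global-ratio fit); per-window GC or
  batch corrections are out of scope.
- The caller's states stop at single-copy gain; higher amplifications
  are only reflected in the observed-ratio CN label (clipped at 4).
- Breakpoints are window-resolution; no sub-window refinement.
- The Grubbs screen assumes approximately normal ratio distributions
  and flags at most ~10% of a cohort per chromosome; pervasive
  aneuploidy (e.g. cell-line artifacts) violates both assumptions.
- Specificity against arrays (false-discovery estimation) is not
  implemented; only sensitivity-style concordance is reported.
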