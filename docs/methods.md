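# Methods

This note records the statistical model behind `serialclones`, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions used throughout.

## 1. Variant model and somatic filtering

A variant call carries tumor depth `d_t`, tumor alt count `a_t`, and matched
normal depth/alt counts. Tumor VAF is `a_t / d_t`. The somatic competence
filter keeps a call when, per sample:

- `d_t ≥ min_depth` (default 20) — below this, a 20% VAF cannot be
  distinguished from noise with useful power;
- VAF `≥ min_vaf` (default 0.20, inclusive) — targets clonal heterozygous
  variants in reasonably pure samples;
- normal VAF `≤ max_normal_vaf` (default 0, i.e. zero supporting reads in
  blood) — any blood evidence marks a germline or artifactual call. A call
  with zero normal depth cannot be evaluated against this rule and is
  excluded and counted separately (`n_normal_unevaluable`) rather than
  silently passed.

Cross-sample harmonization then builds a variants × samples VAF matrix and
keeps a variant only if its locus has depth ≥ `min_depth_all` (default 20) in
*every* sample. This is the competence requirement that lets a VAF of 0 be
read as a confident absence. Missing loci remain NaN, which is deliberately
distinct from 0.

## 2. Clone partitioning and replacement

Presence per sample is `VAF > presence_vaf` (default 0.10, strict). The
presence threshold (0.10) is intentionally looser than the per-sample somatic
filter (0.20): once a variant has passed the stringent filter in at least one
sample, a 10% signal in another competent sample is strong evidence of the
clone's presence there, while 20% would misread partially diluted clones as
absent. Both thresholds are exposed as parameters.

Variants with identical binary presence profiles form a group. The profile
positive in every sample is labeled `shared` (truncal) unless it is the only
group. Groups of size ≥ `min_clone_size` (default 2) become clones labeled
A, B, … in order of first-positive sample (ties broken by size); smaller
groups are absorbed into a core clone when within Hamming distance
`merge_hamming` (default 1) of its profile, which tolerates one
noise-flipped sample, and otherwise remain `unassigned`.

Each clone's *characteristic samples* are those where only that clone (among
non-shared clones) is present. The exclusivity index is
`1 − violations / assigned`, where a violation is an assigned variant
observed present in another clone's characteristic sample. An index of 1
means perfect separation.

A replacement event between consecutive samples `i → i+1` requires, on the
clones' presence fractions `f`:

- outgoing clone: `f_out(i+1) < 0.5 · f_out(i)` and `f_out(i+1) < 0.5`;
- incoming clone: `f_in(i+1) ≥ 0.5` and `f_in(i+1) ≥ f_in(i) − 0.1`
  (the 0.1 slack tolerates sampling noise in an already-dominant clone).

This calls a hard switch at the interval where it happens, calls nothing for
a single persistent clone, and on a gradual decline (e.g. 0.9 → 0.5 → 0.1)
fires exactly once, at the interval where the outgoing clone actually
collapses.

## 3. Copy number

Per-bin tumor and normal read counts are each divided by their library total
(sum over bins), the per-bin ratio is taken, smoothed with a centered rolling
median of `smooth_window` bins (default 5), and log2-transformed. Bins with
zero normal count are masked (NaN) before and after smoothing so they can
neither produce infinities nor be filled from neighbors. Adjacent bins are
merged into a segment while each new bin's log2 stays within
`merge_tolerance` (default 0.3) of the running segment mean.

Focal amplifications are segments with log2 ≥ `min_log2` (default 0.5);
adjacent qualifying segments (gap ≤ 1 bp) are first merged with an
`n_bins`-weighted mean log2, and the span rule (≤ `max_span_bp`, default
10 Mb) is applied after merging, so one biological event split by
segmentation noise is not dropped or double-counted. Broad arm-level gains
fail the span rule by design.

Absolute copies at a locus, given tumor purity `p` and a diploid normal:

```
copies = round_half_away( (2 · 2^log2 − (1 − p) · 2) / p )
```

With `p = 1` this reduces to `2^(log2+1)`, so log2 1.4 → 4.95 → 5 copies and
log2 0.5 → 2.83 → 3 copies. Purity is a per-sample parameter; the default of
1.0 makes the no-information behavior explicit rather than guessing.

Fusion breakpoint concordance: events across samples for the same gene pair
are concordant when all 5′ and all 3′ breakpoints agree within
`tolerance_bp` (default 0, exact). Concordance implies a common founder
clone; the copy number at the 3′ breakpoint, purity-corrected, is reported
per sample.

## 4. Mutation-catalog statistics

Catalog records pass the support filter when depth ≥ 20 (or
variant-supporting reads ≥ 20 when `support_metric="alt"`; the metric is a
parameter because catalogs differ in what they record), alt ratio ≥ 0.2, and
the variant class is coding (missense, nonsense, insertion, deletion,
silent). Records lacking support fields are excluded and counted, not
guessed.

The per-gene silent fraction is `silent / total` over filtered records, with
a display form like `24% (599)` (integer percent, half-away rounding, total
in parentheses) and `NA (0)` for an absent gene — undefined is not 0%.
Classification: driver-like when silent fraction ≤ 0.05 and total ≥ 30;
passenger-like when ≥ 0.15; otherwise indeterminate. The ≥ 30 floor prevents
driver calls from small counts; the 15% bound sits below the ~25% neutral
expectation for random coding changes so moderately depleted genes remain
indeterminate rather than being forced into a class.

## 5. Expression ranking

`RPKM = count / ((length_bp / 1000) · (total_mapped / 10⁶))`. When a table
covers only a gene subset, the library size must come from its
`total_mapped` column (or an explicit argument); summing subset counts would
inflate every value. Fold change is case RPKM (median over case samples if
several) divided by the *median* RPKM of the reference cohort — median, not
mean, so one aberrant reference sample cannot mask a candidate. The display
form rounds half away from zero (`×98`); a zero reference median with
nonzero case signal is flagged infinite rather than given a number.

A gene is a candidate when its region (1-based inclusive; BED input is
converted) overlaps a called amplification and its rounded fold is
≥ `min_fold` (default 5). Candidates are ranked by raw fold descending,
alphabetical on ties. The ≥ 5 default deliberately trades sensitivity for
specificity: a gene at 2× inside an amplified region (e.g. a fold consistent
with copy number alone) is reported as `non-candidate` rather than hidden,
so the threshold's effect is auditable. Genes in amplified regions with no
expression measurement appear as `unquantified`.

## 6. Synthetic cohort generator

The generator emulates a four-sample serial cohort with clonal replacement:

- Clone A (default fraction 0.80 in sample 1, 0.02 after) carries 37 private
  variants and 5 fusion copies; clone B (0.02 in sample 1, 0.80 after)
  carries 21 private variants, 3 fusion copies, and three focal chr1
  amplifications; 3 variants are truncal. Purity per sample is the sum of
  clone fractions (0.82), so the minor clone is genuinely present at trace
  level rather than absent.
- Expected VAF of a variant on `m` mutated copies at clone fraction `f` with
  tumor copy number `c_t` is `f·m / (f·c_t + (1−f)·2)`, the standard mixture
  of tumor and diploid normal alleles; it reduces to `f/2` for heterozygous
  diploid variants.
- Reads are simulated as depth ~ Poisson(100) truncated at ≥ 1 and alt count
  ~ Binomial(depth, expected VAF). Copy-number bins (100 kb over a chr1
  window and around the fusion breakpoints) get Poisson counts scaled by the
  purity-mixed copy ratio. Expression counts follow the RPKM identity with a
  fixed library size; the reference cohort is gamma-distributed around each
  gene's reference level.
- Truth (clone membership per variant, expected VAFs, purity, expected
  fusion log2) is recorded exactly and round-trips through JSON.

Not emulated: sequencing error and strand artifacts, germline contamination
of the tumor sample, mappability and GC bias in bin counts, subclonal copy
number within a clone, more than two competing clones, and tumor-in-normal
contamination. The generator is a correctness instrument for the analysis
code, not a sequencing simulator.

## 7. Numerical conventions

- All rounding of displayed or discrete quantities (copies, fold display,
  percent display) is *half away from zero*, implemented once in
  `round_half_away`, because banker's rounding (Python's default) would turn
  e.g. 2.5 copies into 2.
- Thresholds are inclusive where the rule says "at least" (depth ≥ 20,
  VAF ≥ 0.20, log2 ≥ 0.5, fold ≥ 5) and strict where the rule says "more
  than" (presence VAF > 0.10, normal VAF > 0 disqualifies).
- Chromosome names are normalized (`chr17` ≡ `17`) at the variant-key level
  so catalogs and call sets with different conventions join correctly.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipelines rerun bit-identically apart from the
  provenance hash, which covers the output directory path.

## 8. Known limitations

- Presence calling is a hard threshold on VAF, not a posterior over clone
  fractions; very low-purity samples would need the threshold lowered and
  would then admit more noise.
- The replacement rule is interval-local; a clone that oscillates around 0.5
  across many samples could trigger more than one event.
- The exclusivity index is undefined (reported as 1) when no clone has a
  characteristic sample, e.g. two clones always co-present.
- Absolute copy estimation assumes a diploid normal and one dominant clone
  per sample; mixtures of clones with different copy numbers at the same
  locus yield an averaged, possibly non-integer-looking log2 that still gets
  rounded to one copy number.
- Catalog classification uses fixed fraction bands rather than a binomial
  test against the neutral silent rate; genes with totals near 30 can sit on
  the driver-like boundary by chance.
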