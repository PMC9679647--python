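# Methods

## The problem

Targeted-panel TMB is defined here as the count of nonsynonymous somatic
mutations and indels inside the panel footprint, divided by the footprint in
megabases. With a matched normal, germline variants are removed by the
caller's tumor/normal comparison and TMB is a filtered count. Without one,
every call is a mixture of somatic mutations, the patient's germline SNPs,
and artifacts; the pipeline must separate them from tumor-side evidence
alone: observed allele fractions, local copy number, and a population
background library. Misclassification is consequential in both directions —
leaked germline inflates TMB (each leaked nonsynonymous SNP adds
1/footprint mut/Mb), while lost somatic calls deflate it.

## Filter engine

Four exclusion predicates are applied in order; a record is removed if any
fires. They are hard-coded transcriptions of bcftools-style expressions over
VarDict/VarScan-type tags:

* **basic** — `len(REF) > 50 or len(ALT) > 50`, or the caller's STATUS does
  not contain "Somatic";
* **hotspot** (only when the HOTSPOT tag is set) — SOR in (0, 3), VD < 5,
  AF < 0.007, or SSF > 0.05;
* **fpdb** (only when HOTSPOT is unset) — FPDB or GERMLINE database tag set
  (neither "0" nor ".");
* **normal** (only when HOTSPOT is unset) — a fifteen-clause disjunction of
  artifact signatures (read-position, mapping/base quality, microsatellite
  context, mismatch load, depth, strand bias, and combinations with low AF).

Semantics decided here, since an expression engine on missing data can go
either way:

* **Missing tags never fire a clause.** A clause referencing an absent tag
  cannot establish the artifact signature it encodes, so it evaluates false.
  This is the conservative choice (it never discards a call for lack of
  annotation) and matches NaN-comparison semantics; the test suite's
  independent oracle encodes missing numerics as NaN for exactly this
  reason.
* **Tumor-only mode** skips the sub-conditions indexing the matched normal
  (`DP[1] < 30`, `NM[1] > 3`) rather than letting them auto-fail.
* **SOR = 0 means "not computed"**, not "maximally biased": every SOR clause
  is guarded by `SOR != 0`.
* **BIAS encoding.** The strand-bias category string is read as two
  `;`-separated codes "forward;reverse"; the clause fires on forward "2"
  with reverse "1" (variant reads on one strand only while reference reads
  cover both). This interpretation of the two-code indexing is documented
  rather than asserted — upstream callers differ in how they serialize the
  field.

The engine is validated clause-for-clause against an independently written
naive transcription of the printed expressions on 10⁴ randomized records
per mode.

## SGZ model and fit

Expected coverage log-ratio of a segment at total copy number C in a tumor
of purity P and ploidy Ψ:

    lr(C) = log2( (P·C + 2(1−P)) / (P·Ψ + 2(1−P)) )

With D = P·C + 2(1−P), expected allele fractions are

    germline het  (P·m + (1−P)) / D     m ∈ {M, C−M}  (minor/major copies)
    germline hom  (P·C + 2(1−P)) / D  = 1
    somatic       k·P / D               k ∈ {1..C}    (clonal, k copies)

P ∈ (0,1]; P = 1 with C = 0 yields lr = −∞ (documented sentinel).

**Segmentation.** Greedy least-squares binary changepoint search per
chromosome. The split with the largest residual-sum-of-squares gain is
accepted while the gain exceeds 3·σ̂²·log n, with σ̂ estimated from the
median absolute first difference (robust to true level shifts). Simple and
adequate at panel scale (~10²–10³ bins); the interface takes any
(chrom, start, end, logratio) table, so a different segmenter can be
substituted.

**Grid fit.** P ∈ {0.05, …, 1.00 step 0.01} × Ψ ∈ {1.0, …, 6.0 step 0.05}.
For each candidate, every segment picks the integer pair (C ≤ 8,
M ≤ C/2) minimizing

    (lr(C) − lr_obs)² + w_af · mean_j min(|af_j − e₁|, |af_j − e₂|)²

over that segment's candidate heterozygous-germline allele fractions
(w_af = 1). The AF term is what identifies purity: on a balanced diploid
segment every het sits at 0.5 regardless of purity, but on C ≠ 2 or
M ≠ C/2 segments the het branches split by an amount controlled by P.
When a background library is available, only library-recurrent sites are
used as het probes (recurrent germline SNPs are the cleanest ones);
otherwise all calls with AF in [0.1, 0.9].

Three deliberate regularizations, each needed because the likelihood alone
is degenerate:

* **Ploidy-doubling aliasing.** (P′, 2Ψ, 2C) reproduces the same log-ratios
  and allele fractions as (P, Ψ, C) almost exactly, and on a quantized grid
  the doubled solution can even score better. Among grid points within
  quantization noise of the optimum (objective ≤ 3× minimum), the
  lowest-ploidy cluster is selected, then its best point — the parsimony
  convention of allele-specific copy-number callers.
* **Homozygous-deletion alias.** On noiseless data a halved-purity solution
  can fit by assigning C = 0 to whole segments. Whole-segment homozygous
  deletion at 10⁵ bp scale is implausible, so C = 0 carries a small
  objective penalty (10⁻³); a genuine deep deletion still wins when the
  log-ratio demands it. Exact residual ties then prefer the higher purity.
* **Flat genomes are honestly unidentifiable.** If no segment's |log-ratio|
  exceeds 0.1 and no segment's het AFs deviate from 0.5 by more than 0.05
  on average, the fit returns the configured default purity (0.5) with
  `identifiable=False` instead of an arbitrary argmin.

Recovery on simulated genomes (50 genomes, purity 0.2–0.9, copy numbers
1–3): median purity error ≈ 0.003 (required ≤ 0.05), median ploidy error
≈ 0.007 (required ≤ 0.1) — the grid resolution, not the model, is the
limiting factor.

## Classification

Each filtered variant is assigned to its segment; its **error log ratio**
is |variant log-ratio − segment log-ratio|, where the variant-level
log-ratio is log₂(variant depth / baseline depth) and the baseline is the
median of depth/2^(segment log-ratio) over all variants (the
diploid-equivalent depth, i.e. the same normalization as the coverage
bins — the estimator is not pinned down by the model, so the simplest
consistent one is used). Decision rule:

1. error log ratio > τ_lr (0.5) → **ambiguous** (the copy-number model does
   not describe this locus; don't trust either expectation family);
2. observed AF > 0.9 → **germline** (homozygous);
3. otherwise compare the distance to the nearest germline expectation (d_g)
   and nearest somatic expectation (d_s): if min > τ_af (0.1) →
   **ambiguous**; else the nearer family wins, ties to germline.

Two refinements, both motivated by failure modes that a plain
nearest-expectation rule provably has:

* **Multi-copy somatic margin.** Near P ≈ 0.5 on a diploid segment the
  k = 2 somatic expectation (AF = P) sits next to the het germline 0.5, and
  binomial noise would leak a quarter of germline hets into "somatic".
  A somatic expectation with k ≥ 2 (mutation followed by amplification — an
  a-priori rare event) must beat germline by `germline_margin_z` (default 2)
  binomial standard deviations of the observed AF. The default clonal k = 1
  case competes head-on, so somatic sensitivity at ordinary purities is
  unaffected.
* **Collision arbitration by library presence.** At specific parameter
  configurations the families coincide exactly — e.g. on a C = 1 (LOH)
  segment at P = 0.5, clonal somatic P/(2−P) equals lost-copy het germline
  (1−P)/(2−P) — and the allele fraction carries no information at all.
  When the two nearest expectations are within one binomial SD of each
  other, the call is arbitrated by whether the variant key appears anywhere
  in the background library: somatic mutations are private to a tumor, so
  presence in any population normal tips germline, verified absence tips
  somatic. Without a library the tie falls to germline.

All thresholds live in `SGZConfig`; no numeric thresholds for this decision
are published for the optimized pipeline, so the defaults here are
engineering choices validated by the simulation recovery properties
(somatic recall and germline leakage at purity ≥ 0.4), not reproductions of
anyone's production values.

## Background library

The library maps normalized variant keys (multiallelics split, shared
allele context trimmed) to the number of contributing normal samples
(deduplicated per sample). The filter removes a call when its key occurs in
**more than five** samples, an absolute count regardless of library size.
The published rule that calls with "frequency higher than 0.9 were
retained" is ambiguous; both defensible readings are implemented:

* `literal` (default): observed tumor AF > 0.9 exempts the call from
  background removal. Retained homozygous germline calls are then labeled
  germline by the classifier's high-AF rule, so they still never reach the
  TMB count.
* `high_vaf_germline`: AF > 0.9 is itself treated as evidence of homozygous
  germline and removed along with the recurrent calls.

On simulated cohorts with a 100-normal library, the `high_vaf_germline`
policy removes > 95 % of germline calls at population-AF ≥ 0.05 sites and
never removes a private somatic call (somatic sites cannot enter the
library).

## TMB

Qualifying mutations are nonsynonymous SNVs (missense, nonsense,
start/stop, splice site) plus coding indels (frameshift and in-frame),
inside the panel, after all filters; synonymous and non-coding calls never
count. Hotspot drivers are counted by default (`count_hotspots=False`
excludes them — some commercial assays do). The footprint always comes from
the supplied BED; nothing is hard-coded.

## Cutoff analysis

DCB (durable clinical benefit) = CR/PR, or SD sustained ≥ 24 weeks; SD
< 24 weeks and PD are NDB. The cutoff search sweeps integer candidates
1–20 mut/Mb, computes sensitivity/specificity of `TMB ≥ cutoff` against
DCB, and picks the Youden-J maximum (ties toward the smaller cutoff); the
log-rank statistic on overall survival is reported across the whole grid
as corroboration, with an optional `criterion="logrank"` mode that instead
minimizes p (flagged in the docstring as multiplicity-prone, since the scan
is uncorrected). AUC is the Mann–Whitney probability (midrank ties), which
the tests pin to brute-force pair counting. Kaplan–Meier, log-rank and Cox
(Efron ties) go through lifelines; Welch's t and Fisher's exact through
scipy. Overall survival is the default log-rank endpoint, PFS available by
argument. Significance is reported at α = 0.05 with no multiple-testing
correction, matching common practice in this setting; the scan's
multiplicity caveat is the user's to handle.

## Simulator

What it emulates: a 1.4 Mb panel (14 × 100 kb regions); a shared catalogue
of germline SNP sites at population AFs {0.5, 0.25, 0.1, 0.05, 0.01} with
site counts {800, 900, 1200, 2000, 5000}, giving ~1500 germline variants
per sample under Hardy–Weinberg genotypes — enough rare variants that the
background library is decisive rather than decorative; per-region
copy-number states drawn from {(2,1)×0.5, (1,0)×0.2, (3,1)×0.2, (2,0)×0.1}
(balanced diploid, LOH, gain, copy-neutral LOH); tumor purity uniform on
0.4–0.9; private clonal somatic mutations at a per-sample rate uniform on
1–30 mut/Mb with a realistic effect-class mix (60 % missense, 20 %
synonymous, 10 % indel, plus nonsense/splice); depths Poisson around
1027× (tumor) and 455× (normal) scaled by the local copy ratio; alt reads
binomial at the model-expected AF; coverage bins at the expected log-ratio
plus N(0, 0.05) noise. The paired and tumor-only views of a tumor share
the same tumor reads, so arm-to-arm comparisons measure classification,
not sampling. The clinical layer draws DCB from a logistic model in true
TMB (center 7 mut/Mb, slope 1.0 per mut/Mb), overall survival from
exponentials with hazard ratio 2.5 between TMB groups (median ~12 months
in the favorable group), and independent exponential censoring.

What it does **not** emulate — and therefore what passing tests do not
show: sequencing-error substitution artifacts and FFPE damage (filter-tag
values are "comfortably passing" unless an artifact record is injected
deliberately, so the filter clauses are exercised by construction rather
than by a chemistry model); subclonal somatic populations (all somatic is
clonal k = 1 by default); mapping artifacts and alignment context; indel
realignment ambiguity beyond simple allele-context trimming; panel capture
bias. Real-data performance therefore depends on upstream calling quality
in ways these simulations cannot certify.

`inject_artifacts` appends, per named filter clause, one record that trips
that clause and only it (within the gating rules — a germline database tag
necessarily fires both the fpdb and the normal filters' germline clauses),
for bookkeeping tests of the exclusion cascade.

All randomness descends from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs
end to end.

## Problem sizes and numerics

The shipped concordance study uses 62 tumors and a 100-normal library
(~1500 calls per sample), the purity-recovery study 50 genomes, the filter
oracle 10⁴ records, and the permutation oracle 10⁴ permutations — sizes at
which every reported quantity is stable to the third digit across seeds
while a full run stays in the tens of seconds on one CPU. Floats written
to VCF round-trip at float32 precision (htslib storage); tests compare
accordingly. Interval arithmetic is half-open 0-based on disk (BED),
1-based inclusive in memory; segment assignment is inclusive on both ends.

## Known limitations

* Purity is only identifiable from copy-number-aberrant segments; a truly
  flat diploid genome returns the default purity, flagged, and
  classification then leans entirely on AF families computed at that
  default.
* The collision arbitration needs a background library; tumor-only runs
  without one lose somatic calls on LOH segments near purity 0.5.
* The grid fit assumes one dominant clone; subclonal copy number biases
  the fitted purity toward the major clone.
* `M` (minor allele count) informs both the fit and the germline AF family;
  whether production SGZ implementations use it in classification is not
  public, so both uses are implemented and the family definition is
  configurable in code.
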