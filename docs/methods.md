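# Methods

`chclone` implements a desk-scale analysis pipeline for clonal
hematopoiesis (CH) detected by error-corrected panel sequencing in a
cohort stratified by cumulative radioiodine (RAIT) dose. Because the
clinical dataset it is modeled on is not reproducible from public data
(raw reads only, no covariates), every stage is paired with a synthetic
generator that emulates the study conditions, and all validation is
against generated truth. This note records the models, the defaults and
why, and what the synthetic results do and do not show.

## Variant filtering

Raw per-sample calls pass six rule families; removals are attributed to
the *first* failing rule in a fixed order (bias → germline → region mask
→ confidence → recurrence → detection floor), but each rule is an
independent predicate, so the retained set does not depend on the order.
All comparative thresholds are strict inequalities.

* **Sequence bias.** Orientation bias: two-sided exact binomial test of
  alt-supporting F1R2 vs F2R1 read pairs against 0.5, alpha 0.05. Strand
  bias: Fisher exact test of (ref fwd, ref rev) × (alt fwd, alt rev),
  alpha 0.01. A bias call additionally requires at least
  `min_bias_count = 20` informative alt reads and at least
  `min_bias_imbalance = 90%` of alt reads on the dominant side. The
  guards exist because a pure significance rule misbehaves at both ends
  of the depth range: at ~1900× consensus depth a 60:40 orientation split
  among 1,000 alt reads is highly significant but biologically
  meaningless, while at 10–16 alt reads the exact test flags ~1% of
  genuinely balanced clones. Practical bias annotators threshold a bias
  score with a support minimum; this filter does the equivalent with
  explicit, configurable parameters. With the defaults, balanced calls
  are false-flagged at ~10⁻⁴ while fully oriented calls with ≥20 alt
  reads are always caught. Variants without usable counts are flagged
  untestable and pass.
* **Germline.** Population allele frequency > 1% in either reference
  database (exome or genome); VAF > 35%; VAF > 20% with the variant key
  in a user-supplied review list. The review list replaces interactive
  dbSNP inspection so that runs are reproducible; no interactive mode
  exists.
* **Region mask.** BED intervals (0-based half-open) are flanked by 5 bp
  per side, merged, and converted once to the internal 1-based
  convention. A variant is removed iff any base of its reference span
  intersects the mask; indels are therefore masked conservatively.
* **Confidence.** Depth > 400× and alt reads > 2 (SNV/MNV) or > 5
  (indel).
* **Recurrence.** A variant key present in > 10% of distinct samples is
  removed everywhere. The sample count is always taken on the
  post-germline set, so the rule is insensitive to the order of the
  per-variant filters; whether to count before or after germline
  filtering is genuinely open, and post-germline was chosen because
  common germline polymorphisms would otherwise saturate the counter.
* **Detection floor.** VAF > 0.5%, applied last so the audit separates
  detection-floor losses from artifact losses.

Synonymous variants are excluded from the association stream but kept in
a parallel stream, since dN/dS needs them.

## ARCH-PD driver classification

A deterministic rule engine evaluates criteria C1–C6 and C8 in order and
reports the first match: truncating change in one of 17
loss-of-function myeloid genes (C1); truncating CALR exon-9 (C2); JAK2
V617F (C3); FLT3 ITD, read as an in-frame insertion ≥ 3 nt in FLT3 from
annotation (C4); curated hotspot residue (C5); COSMIC count ≥ 10 with
VAF < 42% and population AF < 0.003 (C6); COSMIC count > 100 with
population AF < 0.003 at any VAF (C8). The criterion about clustering
near validated loci is omitted: it needs curation that cannot be made
objective. COSMIC counts and population frequencies are annotation
inputs; missing values count as zero, and population AF is the maximum
of the exome and genome values (conservative, mirroring the germline
filter's either-database logic). The bundled hotspot table carries only
seed entries (CBL, DNMT3A R882, FLT3 D835/I836) and is explicitly
incomplete; faithful use requires the user's own table, as does the CALR
exon-9 interval.

## dN/dS selection inference

The neutral mutation model uses 96 strand-collapsed substitution classes
(pyrimidine-centred trinucleotide × alternate base). For each gene all
3L possible single-base substitutions are enumerated and classified by
codon translation; the per-gene totals are exactly 3L, which is
property-tested against an independent brute-force enumerator.
Conventions: truncating = nonsense + stop-loss (+ splice where
annotated); stop-retaining changes in the stop codon are synonymous;
frameshift indels are outside the substitution model and excluded from
dN/dS (they remain in association analyses). Trinucleotide context at
the CDS edges comes from stored flanking bases.

Per-class neutral rates are Poisson-ML estimates from pooled synonymous
counts (count / opportunities, empty classes shrunk to the global mean
rate). Per gene and impact class, ω = observed / expected with a 1-df
likelihood-ratio test against ω = 1 and Benjamini–Hochberg adjustment
per impact class across genes; q < 0.10 is called significant. Genes
with zero expectation but nonzero observation are flagged infinite and
excluded from FDR. The group-level dN/dS is Σ observed / Σ expected over
nonsynonymous classes. This is deliberately a reduced model — no
per-gene covariates, no indel channel, no per-gene overdispersion — so
gene lists from richer implementations are not expected to reproduce
exactly; calibration (global dN/dS ≈ 1 under neutrality) and directional
power (truncating selection detected in the truncating class only) are
the validated properties.

## Firth penalized logistic regression

Gene-level and high-cutoff CH outcomes are sparse (zero-event cells,
quasi-separation), so presence models use Firth's penalized likelihood
ℓ*(β) = ℓ(β) + ½ log det I(β), maximized by Newton iteration on the
modified score with step-halving and a per-iteration step cap of 5 on
the log-odds scale. P-values are penalized likelihood-ratio tests;
confidence intervals default to profile penalized likelihood (endpoints
found by bracketed root finding on the profile deviance; Wald intervals
available by flag). Convergence requires both the score norm and the
step below `tol = 1e-8` within 100 iterations, and the flag is honest —
the last iterate is returned unconverged otherwise. Oracles: in the
saturated 2×2 design the estimate must equal the add-½ closed form, and
both the estimate and the profile CI are checked against dense-grid
maximization of the penalized likelihood.

## Association analyses

Subjects are assigned to control (0 GBq), low (< 7.4 GBq) and high
(≥ 7.4 GBq) dose groups. Per subject, the maximum VAF over surviving
mutations defines CH presence at each cutoff of the 0.5/1/2/5% ladder
(strictly greater; ties in the maximum are broken by lowest genomic
position so the witness is deterministic). Clone-size models are OLS on
ln(max VAF in percent) — the 0.5% floor makes a pseudocount
unnecessary; subjects without clones are excluded and counted — with age
per 10 years and dose per 1.11 GBq, optionally with an age × dose
interaction. Dose-cutoff optimization scans a candidate grid,
dichotomizes dose at each candidate and ranks candidates by the
penalized LRT statistic of the indicator from a Firth fit (Youden's J
available); the criterion behind the original analysis is not public,
so the method is recorded in the output. Gene co-occurrence uses
two-sided Fisher exact tests on subject-level 2×2 tables with BH
adjustment across pairs. Pathogenicity-score association assigns
rank-based score tertiles and reports per-tertile VAF quartiles plus an
OLS slope of ln(VAF%) on the score. No multiplicity correction is
applied across the per-gene association models, matching the reporting
convention the pipeline mirrors.

## Longitudinal dynamics

Pre/post samples are joined per patient on exact variant identity
(chrom, pos, ref, alt); no clone tracking across distinct mutations is
attempted. Each mutation is vanished/decreased (absent after, or VAF
lower), emerged/increased (new after, or VAF higher) or unchanged
(equal within a configurable epsilon, default 0 — the tie category keeps
the rule total and deterministic; swapping timepoints exactly swaps the
two directional categories). Summaries are per-patient counts and cohort
means.

## Synthetic-data generator

The generator defines the study conditions:

* **Cohort** (`CohortSimParams`): 110/115/133 subjects in
  control/low/high groups; ages normal with means (SD) 60.0 (14.5),
  52.4 (14.0), 56.4 (13.9) years truncated at 20; female fractions
  0.855/0.861/0.692; doses 0, uniform (1.11, 7.4) GBq, and
  7.4 + Exponential(16.5) GBq (mean 23.9); elapsed months normal
  75.9 (74.8) / 116.4 (76.3) truncated at 12; age at first treatment
  derived as age minus elapsed time. Ever-smoker fractions default to
  0.027/0.052/0.075 — the cohort table this emulates reports the
  complementary never-smoker counts.
* **Clone acquisition** (`EffectConfig`): per gene × consequence class,
  counts are Poisson with rate background × P(class|gene) ×
  age_hazard^((age−50)/10) × dose_hazard^(dose/1.11). Defaults:
  background 0.25 per gene per subject over a 10-gene panel (≈ 3.5
  clones/subject), age hazard 1.7/decade for DNMT3A and TET2 and
  1.4 for PPM1D, dose hazard 1.10 per 1.11 GBq for truncating PPM1D and
  1.05 for missense TP53. The hazards are testing placeholders, not
  estimates — no quantitative per-gene effect sizes are public.
  Multiplicative dose hazards compound over ~70 dose units, so values
  much above ~1.2 explode; tests that exercise stronger hazards restrict
  the dose range.
* **Clone sizes**: ln(VAF%) ~ N(−1.6, 0.9²) truncated below at the 0.5%
  floor, with a positive coupling from the CADD-like score (+0.03 per
  point). These defaults were calibrated to the emulated cohort's
  prevalence anchors at the 0.5% and 2% cutoffs (observed ≈ 93% and 15%
  of subjects vs. 96.9% and 11.2% reported) and give a mean maximum VAF
  of ≈ 1.45%. A single log-normal cannot simultaneously match the 1% and
  5% rungs of the reported ladder (the real tail is heavier); analyses
  sensitive to the extreme tail should not rely on these defaults.
* **Rendering**: depth ~ N(1926, 300²) clipped to [1200, 3200]
  (median panel depth ≈ 1926×); alt count = ceil(VAF × depth), which
  guarantees every true call clears the detection floor and the
  confidence cutoffs by construction; strand and orientation counts are
  Binomial(·, 0.5).
* **Artifacts**: six classes injected per sample at configurable Poisson
  rates, each violating exactly one rule — all alt reads on one
  orientation (≥ 20 reads), all on one strand, popAF 2–30% with VAF
  ≈ 50%, positions inside mask intervals, depth 120–400×, and three
  fixed recurrent keys each hitting 25% of samples. Every other field of
  an artifact is construction-clean (perfectly balanced counts, popAF
  ≈ 0, confident depth, unmasked position), so first-failure attribution
  is exact by construction.
* **Paired samples**: 24 patients by default; post VAF = pre VAF ×
  exp(N(0, 0.35²)), clones dropped at 10% (or below the floor),
  new clones Poisson(2). With zero drift and zero add/drop the post
  sample is an exact copy, which anchors the dynamics tests.

Randomness is a master seed plus CRC-derived per-operation substreams,
so each stage is independently reproducible.

What passing the synthetic suite shows: the rules implement their
definitions exactly (boundaries, precedence, audit conservation), the
estimators are calibrated (CI coverage, neutral dN/dS, uniform null
p-values) and powered against planted effects. What it does not show:
performance on real error-corrected sequencing data, where artifact
classes overlap, annotations disagree between tools, and clone-size
distributions are heavier-tailed than the generator's log-normal.

## Validation problem sizes

The validation suite uses: a 100-sample, ~2,700-raw-call cohort for
filter truth recovery (≥ 99% true-call retention, 100% artifact removal
with intended reasons); 500 replicates at n = 360 and true OR 2.5 for
95% profile-CI coverage (band 0.93–0.97); a 20-gene, 300-codon panel
with ~20,000 mutations for dN/dS calibration (global dN/dS in
[0.9, 1.1]) and 200 replicates with truncating ω = 5 in 3 genes for
power (≥ 80% at q < 0.10, null discoveries ≤ 10%); 200 replicates of a
log-OR 1.8 step at 8.0 GBq on a 358-subject cohort for dose-cutoff
recovery (within one 1-GBq grid step in ≥ 80%); and a 24-pair cohort for
the dynamics properties. The same quantities are recomputed from scratch
by `scripts/acceptance.py`.

## Known limitations

* The dN/dS model is SNV-only and covariate-free; it measures selection
  on a panel, not exome-wide, and its gene lists are not comparable to
  covariate-adjusted implementations.
* Hotspot (C5) and CALR exon-9 (C2) resources ship as incomplete seeds.
* FLT3-ITD detection trusts upstream annotation; no read-level ITD
  calling.
* The recurrence filter assumes samples are unrelated; cohorts with
  technical replicates need the fraction raised.
* The generator plants at most one variant per (sample, site) and does
  not model UMI-family errors, contamination, or sequencing batch
  effects.
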