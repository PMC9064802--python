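# Methods

## Design

The package implements a trio-based case–control burden analysis. Inputs
are a multi-sample VCF 4.2 with per-sample GT/DP/AD/GQ, a 6-column PED
pedigree (phenotype column: 2 = post-neonatal epilepsy, 1 = none),
a per-variant annotation TSV (gene, consequence class, distance to the
nearest splice site, allele frequencies from two population panels,
CADD Phred, optional Polyphen-2 HumDiv/HumVar, optional curated ACMG
label), plain-text gene-panel files, and a gene→KEGG-orthology mapping
TSV. Alignment, genotype calling and annotation computation are
upstream of this package; ACMG classification is consumed as a curated
label because it rests on expert review, not on anything recomputable
from the inputs.

## Filtering

A variant enters the analysis when

* consequence ∈ {missense, nonsense, frameshift}, or the site lies
  within `splice_window_bp` (default 3 bp) of a splice site;
* max(AF panel 1, AF panel 2) < `max_pop_freq` (default 0.001) — the
  stricter "common in either database excludes" reading;
* CADD Phred > `min_cadd` (default 20, strict);
* the proband carries the alternate allele with GQ > `min_gq_proband`
  (default 50, strict).

Inequality directions are deliberate and asymmetric: carrier-side
quality and allelic-balance rules are strict (>), while depth,
alternate-read and homozygous-reference-parent GQ minima are inclusive
(≥, "a minimum of"). In-frame indels do not qualify (only
out-of-frame indels are consequence-qualifying). A missing annotation
row excludes the variant with an explicit `ANNOTATION_MISSING` reason;
an absent frequency field is treated as 0 (absent from the panel means
unobserved, i.e. rare), whereas an absent CADD value excludes, since
the CADD rule cannot be evaluated. Every decision is logged with
reason codes; exceptions are never used for filter outcomes.

## Trio classification

For each surviving proband-carrier variant in each trio, exactly one
call is made:

* a carrier parent ⇒ transmitted (maternal / paternal / biparental
  when both carry it); an X-hemizygous son of a heterozygous mother is
  maternal;
* both parents homozygous reference ⇒ de novo when proband DP ≥ 10,
  alternate reads ≥ 3, allelic balance > mode floor, and both parents
  have GQ ≥ 50 with zero alternate reads for that allele (checked on
  the decomposed AD after multi-allelic splitting); otherwise
  unresolved with the failing reasons — never silently discarded and
  never counted as de novo;
* Y-chromosome and mitochondrial records are not classified (no
  defensible trio rule exists for them here).

Two analysis modes differ only in the allelic-balance floor: 0.25
exome-wide, 0.1 in targeted gene panels. Consequently the exome-wide
de novo call set is always a subset of the targeted-mode set, which
the tests exploit (sites planted with AB in (0.1, 0.25] flip wholesale
between modes).

Non-transmitted detection is an independent scan: one call per carrier
parent (GQ > 50) of a site-filter-passing panel variant whose proband
is homozygous reference. No allelic-balance floor is applied to
inherited or non-transmitted variants; the floors are de novo evidence
rules.

Variant identity is (chrom, pos, ref, alt) after multi-allelic
splitting and reference-free normalization (shared-suffix then
shared-prefix trimming, one base always retained). Full indel
left-alignment would require the reference FASTA, which the pipeline
deliberately does not consume; the reference-free step is the portion
that is well defined without it. Allelic balance is alt_depth /
total_depth from the decomposed AD, flagged undefined at zero depth.

## Burden statistics

Exposure is proband-level: "carries ≥ 1 qualifying variant", where
qualifying = curated class pathogenic or likely pathogenic on a
filter-passing de novo or transmitted panel variant. The
non-transmitted control is family-level ("≥ 1 parent carries a
qualifying non-transmitted panel variant"). Each proband contributes
exactly once.

The point estimate is the sample cross-product OR = ad/bc (flagged
infinite or undefined on zero products rather than raised). The
confidence interval is the exact conditional (Cornfield) interval:
with both margins fixed, the exposed-case count X follows Fisher's
noncentral hypergeometric law

P(X = k | ψ) ∝ C(m₁, k) · C(m₂, n₁ − k) · ψᵏ,

and the bounds solve P(X ≥ a | ψ_lo) = α/2 and P(X ≤ a | ψ_hi) = α/2.
Both tails are monotone in ψ, so the bounds are found by bisection on
log ψ over [log 1e−12, log 1e12] (100 iterations, i.e. resolution far
below the 1e−8 plug-back tolerance the tests assert); the pmf is
evaluated in log space and renormalized for numerical stability.
Support-edge cells yield 0 / +∞ bounds. The method was chosen by
computation, not by convention: for the demonstration tables
(5, 5, 1, 9) and (1, 9, 1, 9) the Cornfield bounds are
(0.639, 471.7) and (0.0115, 87.11), matching the reported intervals
0.6–472 and 0.01–87 after rounding, while the mid-p variant gives
(0.83, 235.5) and (0.023, 43.1) and the Woolf logit interval is far
narrower still — so Cornfield is the default, with `mid_p=True` and
`woolf_or_ci` available and labeled. The conditional MLE (the ψ with
E[X | ψ] = a) is reported in the method notes alongside the
cross-product estimate; the two differ and the cross-product is the
headline number.

Pearson chi-square is computed without continuity correction — the
closed form n(ad − bc)² / (r₁r₂c₁c₂) on 2×2 tables, the
observed-vs-expected sum with k − 1 df on 2×k covariate tables. The
no-correction choice is verifiable from the demonstration covariate
tables: (6,4,3,7) → p 0.178, (6,4,8,2) → p 0.329, (2,8,0,10) → p 0.136,
which round to the reported 0.18 / 0.33 / 0.14 (Yates-corrected values
do not). Fisher's two-sided p sums hypergeometric probabilities no
larger than the observed table's. Continuous covariates use the
pooled-variance two-sample t test. No multiplicity correction is
applied anywhere (none belongs to this design).

## KEGG orthology

Genes of exome-wide de novo pathogenic / likely-pathogenic / VUS
variants are mapped through a user-supplied (or simulated) KO snapshot
TSV — never a live database query, keeping runs hermetic and
version-stable. Excluded from categorization: code 09160 (human
disease) with its descendants, and 09150 (organismal systems) with its
descendants apart from 09156 (nervous system) and its descendants.
Counting is per gene within each group (a gene recurring in two
variants counts once; a gene in several categories counts in each, as
KO is a multi-membership hierarchy), with within-group proportions over
categorized genes. Unmapped genes and genes whose every category is
excluded are reported in side buckets, never dropped silently. The
output is descriptive counts/proportions only; at these sample sizes an
enrichment test would be theater.

## Synthetic cohorts

`simulate_cohort` emits VCF + PED + annotation TSV + panel files + KO
mapping + a truth table with one row per emitted variant. Defaults
mirror the study conditions: 10 + 10 trios, a 200-gene epilepsy panel
and a disjoint 89-gene CAD panel, exposure probabilities 0.5 (cases)
vs 0.1 (controls) for carrying a pathogenic panel variant — an
expected population odds ratio of (0.5/0.5)/(0.1/0.9) = 9.0 — depth
Poisson around 60×, heterozygous allelic balance binomial around 0.5,
GQ passing with probability 0.98, and annotation spectra that straddle
every filter boundary (CADD mixture across 20, allele-frequency tail
across 0.1%) so threshold behavior is actually exercised. Planted
classes: group-dependent pathogenic panel variants, de novo and
non-transmitted events at configurable Poisson rates, and a Mendelian
inherited background. All randomness flows from one seeded generator;
a fixed config is byte-deterministic, and the seed is echoed into the
VCF header. A `noise_free` switch pins all planted evidence above the
thresholds for recall/precision checks, and `denovo_ab_range` places
planted de novo allelic balance in a chosen interval (the mode-flip
experiments use (0.1, 0.25]).

Two curated cohorts (`triowes.curated`) fix the variant content
instead of sampling it, reproducing the demonstration tables: 29
proband panel variants (6 P/LP in 6 probands — 5 with epilepsy, 1
without — 6 VUS, 17 B/LB; 4 de novo variants in 3 genes, 25 inherited
in 23 genes) with CAD and non-transmitted controls, and 17 exome-wide
de novo P/LP/VUS variants split 7-in-6 vs 10-in-6 probands. Evidence
fields are synthetic and comfortably above thresholds; the highlighted
gene symbols are real, panel filler symbols are synthetic.

What the simulator does **not** model: read-level errors, mapping
artifacts, batch effects, relatedness beyond the trio, mosaicism,
regional mutation-rate variation, or realistic site-frequency spectra.
Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under its stated evidence model, not robustness to
real sequencing noise.

## Problem sizes in the test suite

The oracle-agreement property checks 1,000 random single-trio cohorts
against an independent raw-text classifier; odds-ratio coverage uses
200 replicates of 500 + 500 trios drawn directly from the two exposure
Bernoulli rates (the genotype layer is marginalized out there, since
only exposure enters the table — the full VCF-level generator is
exercised at 10 + 10-trio scale for recall/precision); the exact-CI
coverage property uses 1,000 binomially sampled 10 + 10 tables at
ψ = 9. These sizes give Monte-Carlo error well inside the asserted
margins while keeping the default test run fast.

## Known limitations

* Exposure is carrier-status, not variant counts or dosage; a proband
  with three qualifying variants counts once.
* The curated ACMG label is trusted as-is; the pipeline adds only the
  quantitative filters on top of it.
* Parent-of-origin is resolved only through parental carrier status;
  biparental-het transmissions stay phase-unresolved.
* Hemizygosity is taken from VCF ploidy, not inferred from pedigree
  sex; a diploid X call in a male sample is handled as written.
* The exact CI is conservative by construction (coverage ≥ nominal);
  the mid-p option trades guaranteed coverage for shorter intervals.
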