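# Methods

## Problem and scope

Non-obstructive azoospermia with a Sertoli cell-only (SCO) histology — a
complete absence of germ cells from the seminiferous tubules — is genetically
heterogeneous, and most cases lack a molecular diagnosis. This package
implements a candidate-gene discovery workflow for exome cohorts of men with
severe spermatogenic failure: a five-stage loss-of-function (LoF) filtering
cascade with a per-stage audit trail, an allele-level LoF burden test against
a reference population, an inheritance-aware screen of known infertility
genes, and calculators for the two cell-based assays commonly used to follow
up candidate genes (CRISPR growth-competition sequencing and dye-dilution
proliferation). A seeded synthetic-data module generates cohorts with planted
ground truth so that every stage is testable offline; real patient exomes of
this kind are access-restricted and are not bundled.

## The prioritization cascade

All filters act on annotated per-allele variant records (multi-allelic VCF
rows are split; AD is taken per allele). LoF means one of
{stop gained, frameshift, splice acceptor, splice donor}; a shipped synonym
table accepts common annotation spellings, and unknown terms fall into
`other`. Stages run in a fixed order, and gene counts are recorded after
each stage even where the filter acts per variant or per call:

1. **Effect and rarity.** Keep LoF variants with population MAF <= 0.01.
   A variant absent from the frequency table is treated as novel (MAF 0);
   this matches how public databases report unseen alleles.
2. **Call quality.** A call survives with read depth >= 10, alt-allele depth
   >= 4 and variant allele fraction AD/DP >= 40% (all inclusive). The VAF
   gate is applied to every genotype, not only heterozygotes. A variant
   survives through any quality-passing carrier call.
3. **Genotype-aware rarity.** Homozygous autosomal calls require MAF <= 0.01;
   heterozygous or X-linked calls (including homozygous X) require
   MAF <= 0.001.
4. **Testis expression.** Keep genes whose testis expression is strictly
   above 50% of their maximum across all tissues in the supplied table
   ("above" is read literally, so a fraction of exactly 0.5 fails). The
   tissue denominator is whatever columns the input table provides. Genes
   missing from the table are removed with an explicit reason rather than
   silently passed — conservative and auditable.
5. **Control exclusion.** Remove genes in which any control individual with
   intact spermatogenesis carries a LoF call. Control evidence must itself
   pass the stage-2 quality gate (so genes are not discarded on sequencing
   noise) but no MAF gate is applied: any LoF allele in a fertile man
   disqualifies the gene regardless of its population frequency.

Candidates are genes surviving all stages with at least one qualifying case
variant; recurrence bins them by the number of distinct patients. The audit
object enforces the chain invariants (counts non-increasing, each stage's
input equals the previous stage's output) and serializes to both a text table
and JSON.

Known ambiguity: published tabulations of this workflow describe variants
with MAF up to 0.0047 as "rare (MAF <= 0.001)". The cascade and the panel
screen use the stated cutoffs (0.01 homozygous / 0.001 heterozygous)
verbatim; the discrepancy is surfaced here rather than resolved.

## Burden statistics

LoF burden is compared at the allele level: an autosomal gene contributes two
alleles per individual, so a cohort of N with h heterozygous and H homozygous
carriers has (h + 2H) affected and (2N − h − 2H) unaffected alleles. The
reference allele number is configurable because population databases can
report fewer called alleles than 2N at a site.

The two-sided Fisher test is the exact conditional test: with margins fixed,
p is the sum of hypergeometric point probabilities over all tables whose
point probability is at most that of the observed table. Point probabilities
are computed from a cached log-factorial table, and the "at most" comparison
uses a 1e-7 relative tolerance so that exact ties are not dropped to
floating-point rounding. Degenerate margins (an empty row or column) return
p = 1 by convention. The test suite checks this implementation against an
independent exact integer-arithmetic enumerator for every 2x2 table with
total count <= 60, and against `scipy.stats.fisher_exact` on spot tables.

The odds-ratio interval is the Woolf logit interval:
OR = ad/bc, SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d),
CI = exp(log OR ± z·SE). When any cell is zero the Haldane–Anscombe
correction adds 0.5 to every cell first (and the result is flagged); this is
the standard companion to the Woolf method. No multiple-testing correction is
applied — a single pre-specified gene is tested.

## Panel screen

Known infertility genes are screened with: LoF variants, or missense variants
with CADD >= 20 (missense without a CADD annotation never qualifies and is
logged), subject to the genotype-aware rarity cutoffs above. For recessive
genes a hit requires a homozygous qualifying variant or a likely
compound-heterozygous state, implemented as two distinct qualifying variants
in the same gene in the same patient — phase is unknown and deliberately not
guessed. Hits carry their rationale (lof / missense_cadd / homozygous /
compound_het); interpretation and variant classification (ACMG/AMP) are out
of scope.

## Competition and dye-dilution assays

Amplicon reads are classified by the net signed indel length inside a
half-open quantification window, by default ±10 bp around the cut site: no
overlapping indel → wild type; net length ≡ 0 (mod 3) with at least one
indel → in-frame; otherwise frameshift. Substitution-only reads leave the
reading frame intact and count as wild type — the three-class scheme leaves
them otherwise unplaced. Insertions overlap the window through their
insertion point; deletions through their deleted reference interval. A naive
global aligner (match 2, mismatch −1, gap open −6, gap extend −1, via
Bio.Align) converts raw fixture reads into indel calls; note that tandem
duplications are placement-ambiguous and left-align within the repeat, so
windows should cover the duplicated segment. Production input is expected to
be pre-called indel tables from a dedicated editing-outcome pipeline, whose
quality trimming and alignment scoring are not reproduced here.

Frequency fold changes are reported as f_start/f_end with a nearest-integer
fold; a zero final frequency is flagged as infinite rather than divided.

Dye dilution assumes the median fluorescence intensity (MFI) of a stained
population halves with each division:

    divisions = log2((MFI_day0 − MFI_unstained) / (MFI_final − MFI_unstained))
    mean cycle duration = elapsed hours / divisions

Both quantities are invariant under a uniform instrument-gain rescaling of
all three MFIs. A final MFI at or below background is an error, as is a
cycle-duration request at zero divisions. Published cycle-prolongation
figures of the form "x% reduction in proliferation" do not follow from these
inputs by any stated formula and are therefore not produced as outputs.

## Synthetic data: what it emulates and what it does not

The cohort generator defaults to the study design this workflow was built
for: 247 case exomes and 89 intact-spermatogenesis controls. The gene
universe defaults to 120 genes — a deliberate scale stand-in for the ~20k-gene
exome chosen to keep seeded multi-cohort test runs fast; cohort recovery
does not depend on the universe size because every background gene enters
stage 1 and leaves it. Per gene the generator plants exactly one case
variant:

* **planted causal genes** (default 5): a novel LoF variant (absent from the
  frequency table), heterozygous in 1–4 distinct patients (cycling), depth
  20–60x with ~50% VAF, testis fraction in (0.6, 1.0), absent from controls;
* **decoy genes**, one per filter class by default: common MAF (0.02), low
  call quality (DP < 10), heterozygous MAF above the het cutoff (0.0047),
  testis fraction 0.4, or a quality-passing control LoF carrier — each decoy
  satisfies every other filter, so its removal stage identifies the filter
  that caught it (the common-MAF decoy necessarily also violates the stage-3
  MAF rule, but is removed at stage 1 where rarity is first tested);
* **background genes**: one rare missense case variant each, with MAFs drawn
  from a Beta(0.5, 200) spectrum and uniform CADD — they populate stage 1's
  input and leave at the effect filter.

Chromosomes cycle through 1–22 and X so X-linked logic is exercised; VCFs
are minimal valid 4.2 with GT:DP:AD. All floats are emitted with fixed
formatting, so identical configs produce byte-identical files (the
determinism contract is tested). The generator does not emulate real exome
error profiles, batch effects, capture bias, multi-variant genes, or linkage
— so passing recovery tests demonstrates correctness of the filter logic and
bookkeeping, not robustness to real-data noise.

The competition generator grows the three allele classes exponentially,
n_x(t) = p_x(0)·2^(t/T_x), and draws read counts multinomially from the
abundance shares; defaults are a 1:1 wild-type:mutant mix sampled at days
0/3/7/14/21 at 50,000 reads, a 38 h wild-type cycle (a typical doubling time
for the assayed embryonal carcinoma line) and mutant classes ~2 and ~3.94 h
slower. The dye generator decays the background-subtracted signal by
2^(−t/T) with optional multiplicative lognormal noise; noiseless output
inverts exactly through the calculators, and at 5% noise the median of 200
replicates recovers T within 5%.

## Numerical and design choices

* Thresholds live in one `FilterConfig`; no command duplicates a constant.
  All depth/VAF/MAF gates are inclusive (`>=`/`<=`); only the expression gate
  is strict (`>`), following "above".
* Missing per-call DP/AD fails quality rather than erroring; missing MAF is
  zero; missing CADD disqualifies a missense panel variant. Each policy is
  logged where applied.
* Multi-transcript consequence collapse takes the most severe class
  (lof > missense > other); transcript selection is configurable input, not
  inference.
* Output ordering (candidates, qualifying variants, audit reasons) is sorted,
  making every pipeline product independent of input order.
* The Fisher tie tolerance (1e-7 relative) is part of the test's definition
  here, mirrored exactly — in integer arithmetic — by the test-suite oracle.
* Random engine: `numpy.random.default_rng` seeded per generator config; the
  cascade acceptance run derives its 20 cohort seeds from one root seed and
  keeps them below 2^31.

## Limitations

* The cascade audits gene counts, not variant counts; two different variant
  sets can produce the same audit line.
* Compound-heterozygous calls are phase-unaware and can be in cis.
* The naive aligner is for fixtures only; indel placement near repeats
  follows alignment convention, not biological truth.
* The expression filter inherits whatever tissue panel the input table
  carries; results are only comparable across runs using the same panel.
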