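# Methods

This note records the models, rules, thresholds and design decisions
behind the package, in the order the pipeline runs.

## Cohort eligibility

Probands must have a breast or ovarian cancer diagnosis. Family-history
**level 1** requires (1) two or more first-degree relatives with breast
or ovarian cancer, or (2) one first-degree relative whose breast/ovarian
cancer was diagnosed before age 40, was bilateral primary breast cancer,
or was part of a multiple-primary cancer. **Level 2** requires at least
one affected first- or second-degree relative; level 1 takes precedence.
Two readings were open and are fixed here: the age/bilaterality/
multiple-primary qualifiers attach to the *relative's* cancer (the
grammatical subject of the criterion), and both synchronous and
asynchronous bilateral disease qualify, with no time-window parameter.
The classifier is monotone: adding an affected relative never lowers the
level (property-tested).

A second tumor is an **independent primary** (not a recurrence) iff the
first tumor's surgical margin was negative *and* the second differs in at
least one of occurrence side, histology, hormonal status, or HER2
expression. Unknown margin status raises an explicit indeterminate
signal rather than silently returning false. Laterality categories
(Unilateral n=1 / Unilateral n≥2 / Bilateral n≥2) count independent
primary breast tumors; placeholder records without any tumor data are
ignored, which also resolves the one packaged case whose extra tumor row
carries no data.

## Variant filtering

Germline calls are genuine only if emitted by every configured caller
(identity = chrom/pos/ref/alt; exon-level CNVs by gene + exon span);
somatic calls need at least 2 of the 3 configured callers. The
significance cascade then keeps a variant iff, in order: (1) it is a
coding SNV/inframe/frameshift indel or a splice-site variant within ±2 bp
of an exon–intron boundary (genomic offset parsed from the HGVS c.
string); (2) depth ≥ 20; (3) alt reads/depth ≥ 0.2; (4) max allele
frequency over the configured MAF databases (ExAC-non-TCGA global,
ESP6500, 1000 Genomes by default) < 0.01, where absence from a database
counts as 0 *for this rule only*. Rejections carry the first failing
rule in that fixed order so audit output is reproducible; using the
maximum AF across databases makes the MAF rule conservative and
order-independent. The filter is idempotent and monotone in its
thresholds (property-tested).

The variant-type classifier maps HGVS strings deterministically:
trailing `fs` → frameshift indel; trailing `*` (including `delins*`) →
stop-gain; intronic offset within ±2 → splice site; exon-span deletion →
CNV. Unparseable descriptions fall through to `other` with a warning.

## Pathogenicity rule engine

Eighteen of the 27 ACMG-AMP evidence codes are enabled. The nine
disabled codes (PS2, PM3, PM6, PP1, PP4, BS2, BS4, BP2, BP5) require
de-novo status, phasing, segregation, or syndrome-specific phenotype
data that a family-ascertained, frequency-prefiltered, non-monogenic
cohort analysis cannot use consistently; BP7 is likewise not modeled.
Code semantics and defaults:

| code | fires when | default |
|------|------------|---------|
| PVS1 | null variant (stop-gain, frameshift, ±2 splice, multi-exon deletion) in an LoF-mechanism gene | 28-gene panel |
| PS1/PM5 | same/novel change at an established pathogenic residue (input flags) | off |
| PS3/BS3 | functional assay damaging / benign | input |
| PS4 | prevalence evidence | input flag (computed prevalence would be circular with the enrichment module) |
| PM1 | in a functional domain (annotation) | input |
| PM2 | absent from every configured population DB | east-Asian panel (HGVD, TMM, ExAC east-Asian) |
| PM4 | protein-length change (inframe indel) | — |
| PP2/BP1 | missense in a constrained / truncating-mechanism gene | empty config lists |
| PP3/BP4 | in-silico deleterious fraction ≥ 0.8 / ≤ 0.2 | 0.8 / 0.2 |
| PP5/BP6 | ClinVar P/LP assertion or HGMD entry / ClinVar B/LB | — |
| BA1/BS1 | any AF ≥ 0.05 / ≥ 0.01 | 0.05 / 0.01 |

The PM2 panel choice matters: population-registration columns in the
packaged carrier table distinguish east-Asian databases from the
other-ethnicity ExAC slice, and absence is judged against the east-Asian
trio (config-overridable), matching the control construction used for
enrichment. A missing annotation silently skips the code and is
recorded in the result's audit list. Missing AF means "absent from that
database" and is represented by key absence, never 0.0.

Combining rules are the standard ones (pathogenic: PVS1 + {≥1 PS | ≥2 PM
| PM+PP | ≥2 PP}, ≥2 PS, or PS + {≥3 PM | 2 PM + ≥2 PP | PM + ≥4 PP};
likely pathogenic: PVS1 + PM, PS + 1–2 PM, PS + ≥2 PP, ≥3 PM, 2 PM + ≥2
PP, PM + ≥4 PP; benign: BA1 or ≥2 BS; likely benign: BS + BP or ≥2 BP);
any simultaneous pathogenic-side and benign-side match is a conflict and
returns VUS. The implementation is count-based and is tested against an
independent clause-table oracle over every subset of the 18 enabled codes
with ≤ 5 members.

**Manual review.** Raw calls are flagged when discordant with the
ClinVar assertion, when LP/P, or when truncating. Human review cannot be
packaged, but its documented outcome for this cohort — every truncating
call ended P or LP — is reproduced by a deterministic resolution rule: a
raw-VUS null variant in an LoF-mechanism gene with max AF below 0.01 in
*every* database and no benign evidence is upgraded to LP. This is
needed because a truncation registered at trace frequency in an
east-Asian database fires PVS1 without PM2, and {PVS1} alone (or with
one PP) is not LP under the combining rules. The raw tier is preserved
alongside the resolved tier; the upgrade is config-disableable
(`review_upgrade=False`). PVS1 in a final exon is still fired; the
truncating-review flag covers potential NMD escape.

The 5-tier call collapses to 3 tiers (P/LP → pathogenic, B/LB → benign)
for burden and second-hit analyses. The default 28-gene panel contains
the 12 genes mutated in the packaged cohort, the four syndromic
high-penetrance genes, and twelve conventional panel members; the exact
published panel membership is not printed, so the set is configurable and
only the 12 observed genes matter for fixture analyses.

## Exact Fisher engine

Gene-level burden sums one allele per P/LP variant observation per case;
CNV deletions are excluded by default because population databases carry
no CNV allele counts (`include_cnv=True` restores them). Case columns
are (count, 2·n_cases − count); control columns sum per-gene alt counts
across the supplied databases, with totals summed from each database's
maximal high-quality per-gene allele count. Two preset control
constructions mirror the study design: east-Asian metadata (HGVD 1,208 +
TMM 3,554 + east-Asian ExAC 3,933 subjects = 8,695) and female non-TCGA
ExAC (22,937 subjects). Genes with zero case alleles are kept as OR ≤ 1
rows rather than dropped.

The test conditions on both margins: with ψ the noncentral
hypergeometric odds-ratio parameter, the estimate is the conditional MLE
(solving E_ψ[a] = a in log ψ by bracketed root-finding, exactly 0/∞ when
a sits at the support boundary — which is why near-boundary tables can
still report large finite ORs), the two-sided p-value is the
minimum-likelihood sum Σ{f₁(x) : f₁(x) ≤ f₁(a)·(1+10⁻⁷)}, and the CI
inverts the one-sided exact tests at α/2 per side. Degenerate margins
(single admissible table) return p = 1 with an undefined OR. Numerics:
log-space weights with max-subtraction, a crude cross-product log-OR as
the root-search start, outward bracket doubling capped at |log ψ| ≤ 80,
Brent's method at ~1e-11 tolerance. The engine agrees with R 4.3.3
`fisher.test` to ≥ 4 significant figures on reference tables (frozen in
the tests) and with a direct-enumeration oracle on every 2×2 table with
total ≤ 40; transposing the mutant/other columns maps OR ↦ 1/OR and
preserves p.

## Second-hit analysis

For a heterozygous germline SNV/indel (germline VAF within the closed
window [0.2, 0.6]), somatic loss of the wildtype allele is called when
the tumor VAF is strictly greater than 0.6; the window endpoints are read
literally from the rule's statement (inclusive germline bounds, strict
tumor bound) and are property-tested on a VAF grid. Germline VAFs
outside the window are not evaluable (reported ND with a note rather than
a spurious NA, which is reserved for missing assays).

For germline exon-level deletion carriers, per-exon log2(tumor/germline)
mean-read-count ratios are normalized by a LOWESS trend of ratio versus
overall exon abundance (A = ½·log2(tumor·germline)); the trend is
estimated from the exons *outside* the deleted span (fraction 0.3) so the
deletion signal cannot be absorbed, and it also removes the constant
offset between germline- and tumor-panel coverage. Additional copy loss
is called when the mean normalized ratio over the affected span is ≤ −0.5
with at least 3 informative exons (zero-count exons are dropped with a
warning). The −0.5 cutoff is a design default chosen to detect a
one-copy loss at ≥ 50% tumor purity (the expected ratio is log2(1 − p),
i.e. −1 at p = 0.5); the source rule states only "a decrease", so the
cutoff, the LOWESS fraction and the minimum exon count are exposed in
config.

An **AST** is a consensus-filtered somatic truncating variant in the
same gene at a different site from the germline variant. A tumor with
both LOH and AST evidence is reported once, as AST — the specific second
truncation identifies the mechanism — so summary rows stay mutually
exclusive. Per-gene summaries count analyzed = LOH + AST + ND (NA
excluded) and ratio = (LOH + AST)/analyzed.

## Clinical association

Genotype–phenotype tests compare carrier tumors of one gene against the
tumors of the other carriers for a binary feature (solid-tubular
histology, nuclear grade 3, triple-negative subtype), excluding records
with missing feature values; the association unit defaults to the tumor
(one row per distinct tumor), with a per-patient option. A case carrying
pathogenic variants in two genes contributes its tumors to both carrier
groups and is flagged in the result note; because the published analysis
does not state its handling of that case (nor its exact contingency
construction), the packaged fixture's ORs are checked for direction and
significance, not for equality with printed values. Raw p-values are
reported; a Benjamini–Hochberg column is optional downstream.

The onset-age comparison is a Mann–Whitney U test: with combined n ≤ 12
the two-sided p is exact, from full enumeration of the permutation
distribution of U (valid under ties; p = P(|U − n₁n₂/2| ≥ |U_obs −
n₁n₂/2|)); larger samples use the tie-corrected normal approximation
(scipy). The exact mode is tested against an independent
label-permutation oracle for all combined n ≤ 10.

Family segregation is concordant iff every genotyped member is either an
affected carrier or an unaffected non-carrier; members without phenotype
data are excluded with a warning and at least two informative members are
required.

## Synthetic cohorts

The generators emulate the study conditions: 568 cases by default, each
with relatives sampled to produce history level 1 or 2 (half each);
per-gene carrier rates default to 2·AF·RR with control allele
frequencies and relative risks on the scale of the significantly
enriched genes (e.g. PALB2 AF 4×10⁻⁴, RR 10.7); read depth is negative
binomial with mean 120 (the reported median exome coverage is 123-fold)
and dispersion 5; heterozygous VAF is Beta-centered on 0.5 with binomial
read sampling. Planted pathogenic variants are truncations absent from
every population database; planted benign variants are common (AF
0.02–0.2) missense changes the frequency filter must remove. Control
records mimic the HGVD/TMM/east-Asian trio plus a female panel with
binomial alt counts. Tumor data plant LOH (tumor VAF expectation
1/(2 − purity), purity 0.7 by default; CNV carriers get Poisson exon
counts at germline-panel depth 366 and tumor-panel depth 790 with the
deleted span at half coverage and a further (1 − purity) drop under LOH)
and AST events (a second somatic truncation surviving the 2-of-3 caller
consensus, alongside caller-private artifacts that must not), at
fractions 8/22 and 4/22 of carrier tumors, the observed second-hit
rates. Truth tables are returned as first-class outputs so recovery
tests never re-derive ground truth.

What the generator does *not* emulate: mosaicism, sequencing artifacts
correlated across sites, population stratification within a database,
subclonal tumor heterogeneity, or purity estimation error. Passing
recovery tests therefore demonstrate the correctness of the pipeline's
logic under its stated model, not robustness to real-data artifacts.

## Problem sizes and numerical checks

The test suite runs the full enumeration equivalence of the Fisher
engine over all 135,750 non-empty 2×2 tables with total ≤ 40 (~1.5 min),
100 seeded replicates of the end-to-end relative-risk recovery at n =
568 with RR 8 and AF 2×10⁻³, a 500-carrier tumor cohort for LOH/AST
sensitivity/specificity, and 100-replicate checks of the 40%-purity CNV
detection example. Hypothesis-based property tests run derandomized.

## Known limitations

* The exact published 18-attribute decision thresholds are in an unseen
  supplementary figure; PP3/BP4 and BA1/BS1 cutoffs are reconstructed
  from the cited guidelines and exposed in config.
* The packaged fixture transcribes its source verbatim, including
  internal inconsistencies (one allele-count denominator of 600 where
  sibling rows use 858; a gene listed with 2 alleles in the published
  enrichment table where the carrier table holds 3; a tumor row with no
  data that makes the tumor count 48 where the text says 47). The
  fixtures do not reconcile these; analyses document which reading they
  use.
* Real per-gene control allele counts are not distributed; enrichment
  against real databases requires user-supplied control tables, and the
  published enrichment ORs are therefore not reproduced exactly.
* No purity/ploidy deconvolution, allele-specific copy number, or
  methylation-based silencing analysis.
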