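# Methods

## The screen

The pipeline estimates, from population allele frequencies, how common
carriers of recessive DSD/CHG pathogenic alleles are. Its stages and the
assumptions behind them:

**Variant ingestion.** Input is a sites-only or genotyped VCF. Multiallelic
records are split into biallelic variants: each alternate allele keeps its
own AC while AN is unchanged, so allele counts are conserved. The stored
frequency is the alternate-allele frequency `aaf = AC/AN` — reference-panel
"MAF" columns can exceed 0.5 and every threshold in the pipeline is applied
to `aaf`, matching how such panels report frequency. Only records whose
FILTER is the literal `PASS` survive (any recalibration-tranche token is
removed and logged); no VQSR model is re-run. Variants are then intersected
with the panel's gene intervals extended by a 1 kb flank (promoter-proximal
context); a variant inside two genes' flanked intervals is duplicated, once
per gene, because every downstream statistic is per-gene. Indel
left-normalization is assumed, not performed; a shared leading base with
both alleles longer than one triggers a warning only. For the X-linked gene
the released AN/AC are used as-is, with no sex-aware recomputation.

**Platform-bias QC.** Aggregated panels mix sequencing platforms; a variant
whose alt/ref counts are heterogeneous across platforms is treated as a
batch artifact. One 2 × k exact conditional test (classic Fisher at k = 2,
Freeman–Halton for k > 2) is run per variant over all platforms with data,
rather than pairwise tests — a single test is the direct reading of "do the
platform frequencies agree". Two-sidedness uses the probability-ordering
definition, with tables compared to the observed probability at relative
tolerance 1e−7. The null space is enumerated exactly when the margin-bounded
table count is ≤ 200,000 (counted by dynamic programming before
enumerating); beyond that, p is estimated from 100,000 multivariate
hypergeometric draws with an add-one correction `(b+1)/(B+1)` and a reported
standard error. Variants with p < 0.001 (strict) are excluded, not
re-estimated. Degenerate tables (an all-zero row or column) give p = 1.
Allele counts, not any transformed frequency, are tested — the only quantity
an exact conditional test accepts.

**Tier classification.** Decision order per variant: ACMG P/LP → Set 1 when
ClinVar also asserts P/LP, else Set 2; ACMG VUS with `aaf < 0.03` → Set 3
when ClinVar P/LP, else Set 4 when HGMD DM; everything else none. ClinVar
"conflicting interpretations" does not count as P/LP, and only HGMD's
literal `DM` class rescues. ACMG P/LP variants are *not* gated on the
frequency threshold (a violation is logged): the threshold exists to keep
common VUS out of the rescue path, and P/LP calls in practice all pass it.
Sets are nested; the classifier records a variant's first (strictest) set
and cumulative collections are materialized separately.

**Isoform-aware demotion.** A stop-gain/frameshift/splice call asserted only
on a transcript with minor RNA-seq support, while the most-expressed
transcript is merely intronic/intergenic/other, is weak evidence of loss of
function. Such variants lose PVS1, are flagged ambiguous, and — because no
full ACMG recombination engine is run here — an ACMG P/LP class owed to
PVS1 falls back to VUS unless the annotation supplies an explicit PVS1-free
class. Ties in expression weight make all tied transcripts major and block
demotion (the conservative choice: no silent demotion on equivocal
expression evidence). Ambiguous variants stay in count reports, flagged, but
are excluded from all frequency totals.

**Carrier statistics.** Per gene and cumulative tier, `Q` is the sum of
`aaf` over non-ambiguous tiered variants. Under HWE the heterozygous carrier
frequency is `2(1−Q)Q` and biallelic inactivation (BI) `Q²` for autosomal
genes; for the X-linked gene the convention reported here is `Q/3`, the
share of X chromosomes in males under a 1:2 accounting, with the plain male
hemizygote rate `Q` available via `x_linked_mode="Q"`. Category totals sum
per-gene `Q²` (not the square of a pooled category Q), and the X-linked row
is reported separately, excluded from the autosomal total. Cohort-wide
carrier fractions are emitted in two conventions — pooled `2(1−Q_tot)Q_tot`
and per-gene product `1 − Π(1 − 2Q_g(1−Q_g))` — which agree for one gene and
diverge at second order; neither is privileged because the exact convention
behind published single-number carrier figures is generally unrecoverable.
Display denominators use `floor(1/f)` ("1 in 40"), optionally floored to
whole thousands ("1 in 29 thousand"); a rounding convention would not
reproduce the standard printed conversions. The genotype census counts
homozygotes (dosage 2 at a tiered variant), unphased compound heterozygotes
(≥ 2 distinct tiered variants of one gene with dosage ≥ 1, trans assumed, as
manual inspection would), and multi-gene carriers.

**Haploinsufficiency comparison.** Published gene-level scores are grouped
by category: pLI on a log₁₀ scale (pLI = 0 is excluded from the log vector
rather than pseudo-counted — transparent and reported), Episcore as-is.
Pairwise contrasts use the pooled-variance Student's t test, two-sided
(Welch behind a flag); no multiple-testing correction across the three
contrasts, and raw p values are labelled as such. Box summaries are
min/Q1/median/Q3/max with linear-interpolation quartiles.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with known truth. Genotypes are
drawn under HWE: each chromosome of an individual carries one of a record's
alleles with its site frequency, independently across records; simulated
males (1:1 sex ratio) are haploid at the X-linked gene. Defaults are the
study conditions at reduced scale: 32 genes × 30 variants × 2000 individuals
(the real panel held 8380; 2000 keeps a full run in seconds on one CPU while
leaving binomial standard errors small enough for the recovery checks),
label mixture following the reported five-class proportions (13/29/43856/
445/5279 of 49,622), allele frequencies 90% log-uniform on 1e−4..0.01 with a
10% common tail to 0.5, 5% multiallelic sites, 2% quality-tranche failures
(using the two tranche tokens the QC stage must recognize), and exactly
three minor-isoform LOF traps — the number of ambiguous variants the
reference screen flagged. True tiers are computed by a literal transcription
of the set definitions kept separate from the production classifier, so
recovery tests compare two independent implementations. Platform tables
place 10% of variants with a 5-fold frequency distortion on one of three
platforms, 2000 alleles each; haploinsufficiency tables draw Beta scores
whose category medians are ordered GD > CHG ≳ HSA on both scales.

Not modelled: linkage disequilibrium, population structure, genotype
uncertainty, pseudogene read-misalignment (the known *CYP21A2*/*CYP21A1P*
problem), annotation errors correlated between databases, and sex-phenotype
discordance. Passing recovery tests therefore show the pipeline's logic is
correct under idealized sampling, not that real-panel artifacts are handled;
in particular the *CYP21A2* region would need orthogonal assays in practice.

## Numerical and design choices

* Coordinates are 1-based inclusive throughout (VCF convention); BED export
  converts to 0-based half-open.
* The packaged panel fixture carries placeholder intervals on each gene's
  real chromosome: no analysis step depends on absolute positions, only on
  gene membership, and a user panel TSV overrides the fixture.
* Tier truth-table behaviour is threshold-parametric: the classifier is
  exercised against the independent decision table at several thresholds,
  not only the default 0.03.
* Exact-test p values never exceed 1; when the observed table is modal the
  enumeration short-circuits to exactly 1.0 to avoid float-sum noise.
* `Q > 1` can arise in synthetic stress settings (many common pathogenic
  alleles); the pooled carrier form is then reported as NaN rather than a
  clamped number.
* Annotation joins are exact on (chrom, pos, ref, alt); a variant with no
  ACMG class after the join is a hard error listing keys, because the
  classifier cannot proceed without one.
* Errors early in the pipeline abort with the stage name and offending keys;
  reruns with identical inputs and config are byte-identical.

## Known limitations

* The published carrier denominators for pooled tiers ("1 in 157/73/16")
  cannot all be reproduced exactly from the printed per-tier Q totals under
  any single rounding convention; the package reports both carrier-fraction
  conventions and pins its checks to the conversions that are exactly
  recoverable (e.g. "1 in 40", "1 in 2293", "1 in 29 thousand").
* The `Q/3` X-linked convention sits uneasily beside a per-male-birth
  denominator (the male hemizygote frequency under HWE is `Q`); both
  conventions are implemented and the choice is a config switch.
* Isoform demotion encodes the specific minor-isoform pattern observed in
  curated examples; it is a rule distilled from instances, not a general
  ACMG re-evaluation engine.
* BI frequency is not disease incidence: phenotypes of these genes are
  sex-dependent and penetrance is not modelled.
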