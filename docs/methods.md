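# Methods

## Scope and data model

The pipeline starts downstream of alignment: its inputs are per-site allele
read-count tables ("pileup-like": sample, chrom, pos, ref, allele, count,
mean base quality) and per-gene read-base coverage tables for matched
tumor/normal pairs, together with a panel design (BED + gene models), a
dbSNP membership list and per-marker MSI instability calls. Read counts are
taken to be counts of uniquely mapped reads; mapping-quality modeling,
realignment and FFPE artifacts are out of scope. BED files on disk are
0-based half-open; all in-memory coordinates are 1-based inclusive, with the
conversion confined to the readers/writers. Variant alleles are always
reported on the forward genomic strand; consequence annotation
reverse-complements for minus-strand genes.

## Variant detection and somatic filtering

Detection applies three inclusive thresholds per non-reference allele:
supporting reads ≥ 2, mean base quality of the supporting reads ≥ 20, and
allele fraction ≥ 20%. "Two or more reads" is interpreted as variant-
supporting reads rather than total depth (total-depth ≥ 2 would be vacuous
at panel coverage). Indels use the same thresholds, with the quality of
their flanking bases standing in for base quality. Zero-depth sites are
skipped with a logged warning.

The somatic filter evaluates four conditions in a fixed order —
nonsynonymous consequence, zero variant reads in the normal, ≥ 10 wild-type
(reference-allele) reads in the normal, absence from dbSNP — and records a
pass/fail audit for all four on every candidate, so
`candidates = accepted + rejected-with-reason` holds exactly. A candidate
position missing from the normal table is treated as zero normal coverage
and fails the wild-type-depth condition. dbSNP matching is by exact
(chrom, pos, ref, alt); position-only matching was rejected as too
aggressive since it would also suppress novel somatic alleles at
polymorphic positions.

Consequence is determined by applying the edit to the gene's coding
sequence and translating: SNVs become synonymous/missense/nonsense by codon
comparison; indels are frameshift when their length is not a multiple of 3,
otherwise in-frame. Nonsense-mediated decay (NMD) is predicted when the
first stop codon of the mutated CDS ends more than 50 nt upstream of the
last exon–exon junction, both measured in mutated coordinates; because the
natural terminator always lies downstream of that junction, the rule never
fires on a transcript whose stop is unchanged. Indels spanning an exon
boundary are refused by the coordinate machinery (splice effects are not
modeled).

## Purity

Somatic SNVs are assumed to come from a single major clone, heterozygous,
in copy-neutral territory: the tumor-cell fraction then satisfies
`purity = 2·v/n` per site. Per-site estimates are aggregated by the median
(default) because the median resists inflation by SNVs that actually sit in
copy-gained genes; `mean` and `pooled` (`2Σv/Σn`) aggregations are provided
as options. Estimates are clipped to ≤ 1. Samples with no somatic SNV fall
back to the cohort median of the SNV-based estimates (even counts average
the two central values), with the provenance recorded on the estimate. SNVs
used for purity are deliberately not filtered for copy-neutrality — truth
is unknown in real use — which is a documented bias source.

## Copy number

Per-gene fold ratios are computed on read-base *proportions* (gene bases
divided by the library's total read bases), so library-size differences
cancel. The purity adjustment inverts the two-component mixture
`r = p·C/2 + (1−p)`, i.e. `adj = max(0, (r − (1−p))/p)`, the unique linear
model consistent with the purity definition above; at purity 1 it is the
identity, and it maps the gain/loss thresholds 2.0/0.5 exactly onto integer
copy states 4 and 1. The inversion is refused below a purity floor of 0.1,
where it amplifies coverage noise more than ten-fold. Thresholds are
applied to the adjusted ratio (an unadjusted mode exists for comparison);
genes with zero normal coverage are excluded with a logged reason. No
segmentation, GC correction or allele-specific copy number is attempted.

## MSI typing

Classification counts unstable markers among the five reference
microsatellites: 0 → MSS, 1 → MSI-L, ≥ 2 → MSI-H. The rule presumes all
five markers were assayed, so incomplete vectors are an error rather than
being renormalized. Marker instability determination itself
(electrophoresis) is upstream wet lab and out of scope.

## Cohort statistics

Mutation and copy-number events are combined into a patient × gene matrix
of alteration-type sets with union semantics; a patient counts as altered
in a gene once, however many events hit it. Frequency percentages are
rounded half-up to integers, matching how such tables are printed.
Association of per-gene alteration with MSI-H status (MSI-H vs MSS+MSI-L)
uses the two-sided Fisher exact test under the minimum-likelihood rule —
the sum over fixed-margin tables whose hypergeometric probability does not
exceed the observed table's (relative tolerance 1e-7); this choice
reproduces all five published worked-example p-values (0.002, 0.046, 0.024,
0.008, 0.005) from their reconstructed 6-vs-54 tables, which is why it was
selected over chi-square or mid-p variants. The odds ratio reported is the
sample odds ratio ad/bc, infinite when bc = 0. Burden comparisons use
Welch's unequal-variance t-test (pooled variant available); two constant,
equal groups are reported as t = 0, p = 1 rather than NaN. Pathway flags
and actionability reports are simple monotone rule matches over the matrix;
the defaults encode a gain-of-function RAS/RAF set (KRAS/NRAS/BRAF
mutation, HRAS or RAF1 gain) and treatment rules for ERBB2, EGFR,
PIK3CA/PTEN and BRCA1/2. No multiple-testing correction is applied across
genes, and no external enrichment service is consulted.

## Synthetic cohorts

The generator emulates a ~183-gene (~1 Mb) capture cohort of paired
tumor/normal colorectal samples. Defaults are the study conditions: 60
patients, mean coverage 175×, tumor purity uniform on 0.42–1.0, ~6 somatic
SNVs/indels per tumor (7% indels), 10% MSI-H and 10% MSI-L patients, 4% of
genes copy-altered per tumor with integer states {0, 1, 3, 4, 5, 6}.

* **Depth** is negative-binomial per site (mean 175, dispersion 8) —
  capture data are overdispersed relative to Poisson; the choice of noise
  family is ours, as no coverage noise model is prescribed by the design.
* **Variant reads** are binomial given depth. A clonal het variant on one
  of `C` copies at purity `p` has allele fraction `p/(p·C + 2(1−p))`
  (`p/2` when copy-neutral); expected tumor coverage of a gene scales by
  `p·C/2 + (1−p)`. Somatic variants are never planted on fully deleted
  genes.
* **Germline SNPs** come from a panel-wide polymorphism catalogue (all of
  it dbSNP-listed); each patient carries each catalogue site with
  probability 1/5, het:hom 2:1, giving ~2×10⁻⁴ het SNPs/bp per patient — a
  desk-scale rate chosen so cohorts stay small while every filter branch is
  exercised. Somatic variants are planted only at positions absent from the
  catalogue, so truth and dbSNP are disjoint by construction.
* **Errors**: each non-reference base receives substitution errors at
  rate 10⁻⁴/3. This represents the residual miscall rate of
  quality-screened counts of uniquely mapped reads (raw instrument error is
  higher, but the count tables model post-filter pileups). Thirty
  error-only sites per sample keep the detector honest at negative
  positions.
* **Base qualities**: the reported per-allele mean quality is drawn as the
  mean of per-read qualities — Normal(32, 4) for real alleles, Normal(18, 6)
  for error alleles, truncated to [2, 40] — so single-read errors often fall
  below Q20 while well-supported alleles essentially never do.
* **Coverage tables** use gamma multiplicative noise with CV 5% per gene
  and a fixed 75% on-target rate (off-target bases inflate both library
  totals equally, which the proportion normalization cancels).
* Counts are generated only at informative sites (planted variants, SNPs,
  error sites), not across the full megabase: downstream operations consume
  sites, and gap positions carry no information.

One seeded generator drives every draw in a fixed patient order, so a fixed
config yields byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: alignment and mapping artifacts, strand
bias, FFPE damage, GC-dependent coverage, subclonal architecture beyond one
major clone, germline indels, and multi-nucleotide variants. Recovery rates
measured on these cohorts are upper bounds for real specimens.

## Problem sizes and numerical choices

Validation uses desk-scale problem sizes chosen to keep the full suite
fast while leaving the statistics well-powered: 200 replicates for purity
and copy-number recovery, 1,000 randomized candidates for the somatic
filter oracle, exhaustive Fisher enumeration up to table total 40, and a
60-patient default cohort (about 18 s per end-to-end run) for determinism.
Cohort-scale headline counts of the original 60-patient study (hundreds of
somatic variations across 113 genes) depend on its real panel and patient
genomes and are not reproduction targets here; the cohort-level machinery
is instead validated against the published worked examples and planted
truth. Ties at thresholds are resolved inclusively everywhere (≥/≤), the
Fisher comparison uses the 1e-7 relative tolerance above, and percentages
round half-up.

## Known limitations

Purity estimates are biased downward when many somatic SNVs sit in gained
regions (median aggregation only mitigates this); the copy-number caller
reports gene-level states only and inherits any purity error through the
mixture inversion; the NMD rule is the standard 50-nt heuristic, not a
transcript-level model; and the association tests are unadjusted for
multiplicity by design.
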