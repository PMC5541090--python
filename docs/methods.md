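# Methods and implementation notes

This note documents the statistical procedures, the defaults and why they
were chosen, the numerical choices, and what the synthetic-data tests do
and do not establish about real data.

## QC cascade

Filters run in a fixed order — pseudogenic, refseq_error, low_complexity,
uncertain, low_depth, hwe_violation — applied after multiallelic records
are removed at ingestion. Each variant is binned by the *first* filter it
fails; bins are therefore disjoint and the ledger identity
`input = survivors + Σ exclusions` is exact. The order itself is a
convention (any order yields a valid audit trail, but ledgers are only
comparable across runs if the order is fixed); it is recorded in the
ledger output.

*Uncertain* is operationalized as the per-sample PASS-filter criterion
(failed in more than `max_fail_fraction` = 0.10 of samples); *low_depth*
as depth below `min_depth` = 10× in more than 0.10 of samples.

**Low complexity.** The DUST-style score of a window is
`Σ_t c_t(c_t−1)/2 / (T−1)` over its overlapping triplets, with triplets
containing N unscored and the denominator floored at 1. A variant is
low-complexity when either 15-base reference flank scores above the
masking threshold 2.0. The threshold and window are conventions of
symmetric-DUST-style masking, exposed as configuration; windows truncated
at contig ends are scored when at least 3 bases remain. A 15-base
homopolymer scores 6.5, a period-4 repeat 1.25, an all-distinct window 0.

**Hardy-Weinberg.** The exact conditional test: given the observed allele
counts, the probability of every possible heterozygote count is computed
(log-space, via `gammaln`), and the p-value sums the probabilities of all
tables no more probable than the observed one (probability ordering). An
independent exact-rational enumeration oracle in the test suite agrees to
1e-12 for all tables up to 50 individuals. The default alpha is 1e-6, the
conventional stringency for QC-grade HWE filtering.

A discreteness floor worth knowing: with 21 diploid controls the most
extreme heterozygote-*excess* table (all 21 heterozygous) has exact
p ≈ 3.9e-6. An alpha below that can therefore only ever flag
heterozygote-deficit patterns at this cohort size; analyses that want the
excess direction flagged (the typical pseudogene signature) should raise
`hwe_alpha` to 1e-5–1e-4. The planted-signal tests use 1e-4 for exactly
this reason. Hemizygous genotypes (male X/Y) are excluded from the test
rather than modelled.

## Rarity thresholds

Dominant: MAF bound = incidence (1/5000 → 2e-4). Recessive: from
incidence = p², the carrier bound is expressed as `1/ceil(sqrt(1/I))` —
the denominator rounds *up* so the bound errs conservative (√5000 ≈ 70.71
→ 1/71). A 1e-9 tolerance inside the ceiling keeps exact integer squares
exact under floating point. Any single database frequency at or above the
model threshold vetoes rarity (most conservative reading), as does
carriage by more than `max_control_carriers` = 2 in-study control
*samples* (carriers, not alleles). Variants absent from every database
and from controls form the separate "unknown-rare" stratum; they are
treated as rare by the screens.

## Region burden and the occupancy null

Sub-gene regions per transcript: one strand-aware upstream window
(default 1 kb), contiguous 5'/3' UTR pieces, per-exon coding segments,
and two intron-flanking splice windows of `flank` = 8 bp per intron
(clipped at the intron midpoint). The 8 bp default matches the span of
splice-region annotation; both knobs are configuration. Regions of
different classes may overlap, and a variant is credited to every region
containing it.

Burden counting distinguishes samples from variants: a sample counts once
per region however many of its rare variants fall there, while
`variant_count` counts distinct variants. Candidates require
`case_sample_count ≥ k` and `control_sample_count = 0`, ranked by
descending case count with (chrom, start) tie-breaks.

The null model drops V variants uniformly at random over the *count* of
regions, not length-weighted — this is the assumption expressed by a
random-distribution null over a region list, and it is the variant that
reproduces the ≈ 1% calibration at V = 14,393, R = 594,910, k = 4.
Implementation: each replicate's draws are sorted and scanned for a run
of k equal indices (equivalent to a max-bin test without allocating the
occupancy vector); 10,000 replicates at full scale take ~2 s. The
Poissonized closed form `1 − exp(−R·P[Poisson(V/R) ≥ k])` is reported
alongside and agrees within Monte Carlo error in the sparse regime
(λ = V/R ≤ 0.1). An exact small-instance oracle (exponential generating
functions over rationals) pins the estimator in the test suite.

## Inheritance screens

Impact classes follow the SnpEff putative-impact convention; combined
consequence strings ("stop-gain & splice region") take the
maximum-severity term, and unrecognized terms fall back to MODIFIER. The
screens use the worse of the annotated impact and the class implied by
the consequence string.

Transcript-level exclusions: models without a verified ORF (no start
codon, multiple stops, incomplete) are dropped; so are transcripts
carrying any HIGH-impact variant whose public MAF (or in-study control
carrier frequency, carriers/2n) exceeds the model threshold — a gene with
a common protein-truncating allele cannot act by loss of function at the
assumed incidence.

Compound heterozygosity requires ≥ 2 rare HIGH/MODERATE heterozygotes in
one transcript in one case sample, with at least one pair surviving phase
exclusion; all pairs are tested and every variant participating in a
surviving pair is reported. Phase exclusion is deliberately asymmetric:
within one read length (default 100 bp) a same-phase-set, same-haplotype
pair is provably cis and rejected; beyond read range no phase information
exists and the pair is *retained* — the screen keeps candidates it cannot
disprove. Each contributing variant must individually be absent from
controls (stricter than requiring joint absence). The multi-sample
dominant screen defaults to `min_samples` = 2, matching the reported
per-gene counts for this design. A hemizygous call in a female sample is
a data error and aborts the run.

## Auxiliary scans

Coverage normalization rescales each sample column by
`median(total mapped reads) / sample total`, preserving zeros and
within-column rank order. The rank-sum scan uses the exact null
distribution whenever the pooled row is tie-free and both groups have
≤ 25 samples, otherwise the normal approximation with tie correction —
necessary because Bonferroni-corrected per-test alphas (1.74e-7 at
286,754 regions) sit far in the tail where the normal approximation alone
is unreliable. Constant rows get p = 1 by convention and are logged.
Bonferroni division is done in exact rational arithmetic before rounding
for display.

Power uses Noether's approximation for the Wilcoxon–Mann–Whitney test:
`n_total = (z₁₋α/₂ + z₁₋β)² / (12(p′ − ½)²)` with
`p′ = Φ(effect/(sd√2))`. The method is recorded in the output metadata
because rank-test power calculations are method-dependent: for the CNV
configuration (alpha 1.74e-7, power 0.95, 50% shift, SD 0.17) Noether
gives a smaller per-group n than other published conventions, so the
number should be compared across studies only together with its method.

The viral filter is a pure threshold filter (> 90 bp, > 95% identity;
strict inequalities) followed by a distinct-sample count per virus per
cohort; it is idempotent and input-order independent.

## Synthetic cohorts

The generator emulates the study conditions: 23 cases (15 male) and 21
controls (14 male); ~5,000 sub-gene regions from generated transcript
models and 3,000 biallelic SNVs by default (a reduced scale that keeps a
full pipeline run under a minute; the full-scale occupancy calibration
does not need a cohort and runs at true scale); 2.63% multiallelic
records; control genotypes drawn binomially under HWE; common-variant
MAFs from Beta(0.5, 5); ~5% rare variants, of which 89.7% carry a known
public MAF — all matching the reference design's observed proportions.
The in-study controls play the role of the population-control carrier
count, so the MAF table is internally consistent with the genotypes.
Planted signals (one per screen: dominant-HI, recessive hom/hemi,
cis/trans compound het, region burden, HWE violation, CNV shift, STR
expansion, viral hits, plus low-complexity flanks and PASS/depth
failures) are placed on transcripts kept free of background variants and
recorded in a truth manifest. All randomness flows from one seeded
generator; identical configurations produce byte-identical bundles.

What passing these tests shows: the screens implement their stated rules
exactly, recover every planted signal, and leak no cis-planted pair. What
they do not show: robustness to annotation dialects beyond SnpEff-style
ANN fields, indel normalization, linkage structure beyond the planted
cis/trans pairs, batch effects in coverage, or caller-specific artifacts
— real-data behaviour on those axes is untested by construction.

## Worked-example tables

Four small candidate tables from a published 23/21 whole-exome screen are
packaged (`rarescreen.datasets`) and used to exercise the ranking and
reporting paths: 21 burden candidate regions (top region at 7 case
samples), 61 dominant high-impact variants (one shared by two samples),
42 multi-sample genes (two at 4 samples), and 20 hemizygous X-linked
rows over 19 genes. Printed run-together indel alleles in the source
table are ambiguous to split into REF/ALT; the packaged split preserves
the annotated consequence class, and coordinates, genes and sample IDs
are as printed.

## Known limitations

- Multiallelic records are excluded, not decomposed (an explicit design
  choice to keep the ledger faithful to the audited design; decomposition
  would require re-annotation).
- The burden null is not length- or mutability-weighted; regions with
  unusual length or mutation rate will be mis-calibrated relative to the
  uniform null.
- HWE filtering is blind to heterozygote excess below the discreteness
  floor described above.
- The recessive screen trusts the VCF's phase sets; switch errors in
  upstream phasing propagate directly.
- Coverage refinement trims regions by per-base mean control depth with
  no smoothing window; ragged depth profiles produce fragmented regions.
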