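# rarescreen

Rare-variant prioritization for small case-control whole-exome cohorts.

`rarescreen` implements the full downstream analysis of a two-cohort exome
study (the reference design is 23 cases and 21 controls): an audited
biallelic QC cascade, incidence-derived rarity thresholds, a region-level
rare-variant accumulation scan calibrated by a Monte Carlo occupancy null,
dominant and recessive loss-of-function screens with compound-heterozygote
phase logic, and secondary genome-wide scans (coverage/CNV, STR lengths,
off-target viral hits). A synthetic-cohort generator produces complete,
seeded input bundles with planted signals and a machine-readable truth
manifest, so every stage is testable end to end without any sequence data.

## The model

**QC ledger.** Starting from the raw call set, variants are excluded in a
fixed order — multiallelic, pseudogenic, RefSeq-error, low-complexity
(DUST score of the 15-base flanks > 2), uncertain (per-sample PASS filter
failed in > 10% of samples), low-depth (< 10× in > 10% of samples), and
Hardy-Weinberg violation in controls (exact conditional test) — with each
variant counted in the bin of the first filter it fails, so

    input = survivors + Σ exclusions

holds exactly and the ledger is an audit trail.

**Rarity.** For disease incidence *I*, a dominant-acting allele must have
MAF < *I* (the default *I* = 1/5000 gives 2×10⁻⁴); a recessive-acting
allele satisfies *p*² = *I*, bounded conservatively as
1/⌈√(1/*I*)⌉ (= 1/71 for *I* = 1/5000). A variant is *common* if any
public database (dbSNP/EVS/ExAC-style) reports MAF at or above the model
threshold or more than two in-study control samples carry it.

**Region burden.** Genes are split into sub-gene regions (upstream, 5'UTR,
exon, intron-flanking splice windows, 3'UTR). A region is a candidate when
≥ *k* distinct case samples carry rare variants there and no control does.
The rule is calibrated by the occupancy null: dropping *V* rare variants
uniformly into *R* regions,

    P(max bin ≥ k) ≈ 1 − exp(−R · P[Poisson(V/R) ≥ k]),

estimated by simulation and reported with the closed form. At the
reference scale (*V* = 14,393, *R* = 594,910, *k* = 4) the chance is about
1%, which is what justifies *k* = 4.

**Inheritance screens.** Dominant: rare HIGH-impact heterozygotes carried
only by cases; and genes where ≥ 2 distinct cases carry rare HIGH/MODERATE
variants in one transcript. Recessive: homozygous, hemizygous (males,
X/Y), or compound-heterozygous HIGH/MODERATE variants under the 1/71
bound; pairs within one read length (100 bp) whose phase sets place both
alternate alleles on the same haplotype are rejected as cis.

**Auxiliary scans.** Region × sample coverage matrices are normalized by
total mapped reads and compared cohort-wise with the Wilcoxon–Mann–Whitney
test under Bonferroni correction (0.05/286,754 regions = 1.74×10⁻⁷ at
genome scale; the exact null distribution is used wherever group sizes
allow). Sample-size requirements use Noether's approximation. STR repeat
counts get the same scan; viral alignment hits are filtered at > 90 bp and
> 95% identity and summarized per virus per cohort.

## Worked example

Simulate a cohort with one planted signal of every kind, then run the full
pipeline:

```sh
rarescreen simulate --seed 7 --outdir bundle
rarescreen run-all --bundle bundle --outdir results --seed 7
rarescreen report --outdir results
```

which prints (abridged):

```
n_samples            44
n_vcf_records        3089
n_qc_survivors       2869
n_rare_case_variants 91
n_regions            5011
n_burden_candidates  1
n_dominant_hi        6
n_recessive          4
cnv_n_significant    1
str_n_significant    1
viral_n_hits_kept    6
```

The one burden candidate is the planted 5-case-sample 3'UTR region; the
recessive calls include the planted homozygote, the X-linked hemizygote
and the trans compound heterozygote (the cis-planted pair is correctly
rejected); the CNV and STR scans each flag exactly the planted row; the
kept viral hits are the planted HHV6B reads in two case samples.
`bundle/truth.tsv` lists every planted signal for comparison.

The same stages are available as a library
(`rarescreen.qc_filters.apply_qc_cascade`,
`rarescreen.region_burden.mc_null_max_burden`,
`rarescreen.inheritance_screens.recessive_screen`, ...) and as individual
subcommands (`qc`, `burden`, `screen-dominant`, `screen-recessive`, `cnv`,
`str`, `viral`).

## Layout

- `src/rarescreen/cohort_io.py` — cohort model, VCF/BED/TSV readers and writers
- `src/rarescreen/qc_filters.py` — DUST, exact HWE test, QC cascade
- `src/rarescreen/rarity.py` — thresholds and common/rare classification
- `src/rarescreen/region_burden.py` — sub-gene regions, burden counts, occupancy null
- `src/rarescreen/inheritance_screens.py` — dominant/recessive screens, phase logic
- `src/rarescreen/aux_signals.py` — CNV/STR scans, power analysis, viral filter
- `src/rarescreen/synthetic_cohort.py` — seeded bundle generator with planted truth
- `src/rarescreen/pipeline.py`, `cli.py` — orchestration and the `rarescreen` CLI
- `src/rarescreen/datasets.py` — packaged worked-example candidate tables
- `docs/methods.md` — modelling and implementation notes
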