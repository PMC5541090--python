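"""Loss-of-function screens: dominant and recessive candidate selection.

Three deterministic screens over QC-surviving, rarity-classified variants:

* dominant high-impact — heterozygous (or hemizygous) protein-disrupting
  variants below the dominant MAF bound, carried only by case samples;
* dominant multi-sample — genes where at least ``min_samples`` distinct
  case samples each carry a rare high- or moderate-impact variant in the
  same transcript, none in controls;
* recessive — homozygous, hemizygous (males, X/Y) or compound-heterozygous
  high/moderate-impact variants below the recessive MAF bound, with phase
  information used to reject same-haplotype (cis) pairs within read range.

Compound heterozygosity means both copies of a gene are hit at different
sites: two heterozygous variants in one transcript on opposite haplotypes.
Pairs closer than one read length with phase annotations placing both
alternate alleles on the same haplotype are excluded; pairs at or beyond
read range carry no phase information and are retained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .cohort_io import (
    CandidateCall,
    Cohort,
    CohortVariant,
    Genotype,
    Impact,
    MafTable,
    Sample,
    Sex,
    Transcript,
)
from .rarity import RarityConfig, is_rare

__all__ = [
    "classify_consequence",
    "exclude_bogus_transcripts",
    "exclude_common_hi_transcripts",
    "dominant_hi_screen",
    "dominant_multi_sample_screen",
    "phase_exclude_pair",
    "recessive_screen",
]

# SnpEff-style consequence term -> putative impact; combined terms
# ("stop-gain & splice region") take the maximum-severity class.
_IMPACT_BY_TERM: dict[str, Impact] = {
    "frameshift": Impact.HIGH,
    "frameshift_variant": Impact.HIGH,
    "stop_gained": Impact.HIGH,
    "stop_gain": Impact.HIGH,
    "stop_lost": Impact.HIGH,
    "stop_loss": Impact.HIGH,
    "start_lost": Impact.HIGH,
    "start_loss": Impact.HIGH,
    "splice_acceptor": Impact.HIGH,
    "splice_acceptor_variant": Impact.HIGH,
    "splice_donor": Impact.HIGH,
    "splice_donor_variant": Impact.HIGH,
    "transcript_ablation": Impact.HIGH,
    "missense": Impact.MODERATE,
    "missense_variant": Impact.MODERATE,
    "inframe_insertion": Impact.MODERATE,
    "inframe_deletion": Impact.MODERATE,
    "splice_region": Impact.LOW,
    "splice_region_variant": Impact.LOW,
    "synonymous": Impact.LOW,
    "synonymous_variant": Impact.LOW,
    "stop_retained_variant": Impact.LOW,
    "intron": Impact.MODIFIER,
    "intron_variant": Impact.MODIFIER,
    "intergenic": Impact.MODIFIER,
    "upstream_gene_variant": Impact.MODIFIER,
    "downstream_gene_variant": Impact.MODIFIER,
    "5_prime_utr_variant": Impact.MODIFIER,
    "3_prime_utr_variant": Impact.MODIFIER,
    "non_coding_transcript_exon": Impact.MODIFIER,
    "non_coding_transcript_exon_variant": Impact.MODIFIER,
}


def _normalize_term(term: str) -> str:
    term = term.strip().lower()
    term = re.sub(r"[\s\-]+", "_", term)
    return term


def classify_consequence(consequence: str) -> Impact:
    """Putative impact of a consequence string, worst class wins.

    Accepts both underscore terms (``stop_gained``) and the spaced/combined
    dialect used in report tables (``stop-gain & splice region``).
    Unrecognized terms contribute MODIFIER.
    """
    worst = Impact.MODIFIER
    for raw in consequence.split("&"):
        term = _normalize_term(raw)
        impact = _IMPACT_BY_TERM.get(term)
        if impact is None:
            impact = _IMPACT_BY_TERM.get(term.removesuffix("_variant"), Impact.MODIFIER)
        worst = max(worst, impact)
    return worst


def variant_impact(v: CohortVariant) -> Impact:
    """Impact for screening: the annotated class or, if absent/weaker, the
    class implied by the consequence terms."""
    return max(v.impact, classify_consequence(v.consequence))


def exclude_bogus_transcripts(
    transcripts: Sequence[Transcript],
) -> tuple[list[Transcript], list[Transcript]]:
    """Drop transcript models unusable for coding interpretation
    (no start codon, multiple stops, incomplete)."""
    kept = [t for t in transcripts if not t.is_bogus]
    excluded = [t for t in transcripts if t.is_bogus]
    return kept, excluded


def exclude_common_hi_transcripts(
    transcripts: Sequence[Transcript],
    variants: Sequence[CohortVariant],
    mafs: MafTable,
    threshold: float,
    n_hu_controls: int = 21,
) -> list[Transcript]:
    """Drop transcripts carrying any common high-impact variant.

    A transcript where some protein-disrupting variant segregates at MAF
    above the model threshold cannot act through a loss-of-function
    mechanism at the assumed incidence.  Commonness is judged from the
    public databases or from the Hungarian-control carrier count converted
    to an allele-frequency estimate (carriers / 2n).
    """
    dropped: set[str] = set()
    for v in variants:
        if variant_impact(v) is not Impact.HIGH:
            continue
        rec = mafs.lookup(v)
        if rec is None:
            continue
        hu_af = rec.hu_control_carriers / (2 * n_hu_controls) if n_hu_controls else 0.0
        max_af = max(rec.known_afs(), default=0.0)
        if max(max_af, hu_af) > threshold:
            dropped.add(v.transcript_id)
    return [t for t in transcripts if t.transcript_id not in dropped]


def _cohort_indices(samples: Sequence[Sample]) -> tuple[dict[int, str], dict[int, str]]:
    case = {i: s.sample_id for i, s in enumerate(samples) if s.cohort == Cohort.CASE}
    control = {i: s.sample_id for i, s in enumerate(samples) if s.cohort == Cohort.CONTROL}
    return case, control


def _case_only_carriers(
    v: CohortVariant, case: dict[int, str], control: dict[int, str]
) -> list[str] | None:
    """Case carrier IDs if the variant is absent from every control, else None."""
    carriers = v.carrier_indices()
    if any(i in control for i in carriers):
        return None
    ids = sorted(case[i] for i in carriers if i in case)
    return ids or None


def dominant_hi_screen(
    variants: Sequence[CohortVariant],
    samples: Sequence[Sample],
    mafs: MafTable,
    cfg: RarityConfig,
    kept_transcripts: set[str] | None = None,
) -> list[CandidateCall]:
    """Rare high-impact variants carried exclusively by case samples.

    One call per qualifying variant, listing every case carrier.
    """
    case, control = _cohort_indices(samples)
    calls: list[CandidateCall] = []
    for v in variants:
        if kept_transcripts is not None and v.transcript_id not in kept_transcripts:
            continue
        if variant_impact(v) is not Impact.HIGH:
            continue
        if not is_rare(v, mafs, cfg, "dominant"):
            continue
        ids = _case_only_carriers(v, case, control)
        if ids is None:
            continue
        calls.append(
            CandidateCall(
                gene=v.gene,
                transcript_id=v.transcript_id,
                model="dominant_HI",
                variants=[v],
                sample_ids=ids,
                consequence_summary=v.consequence,
            )
        )
    calls.sort(key=lambda c: (c.variants[0].chrom, c.variants[0].pos))
    return calls


def dominant_multi_sample_screen(
    variants: Sequence[CohortVariant],
    samples: Sequence[Sample],
    mafs: MafTable,
    cfg: RarityConfig,
    min_samples: int = 2,
    kept_transcripts: set[str] | None = None,
) -> list[CandidateCall]:
    """Genes with rare damaging variants in >= min_samples distinct cases.

    High- and moderate-impact variants are eligible; all contributing
    variants must share one transcript and be absent from controls.
    Returns one call per qualifying gene (its best transcript), sorted by
    descending case sample count.
    """
    case, control = _cohort_indices(samples)
    by_transcript: dict[str, tuple[set[str], list[CohortVariant], str]] = {}
    for v in variants:
        if kept_transcripts is not None and v.transcript_id not in kept_transcripts:
            continue
        if variant_impact(v) < Impact.MODERATE:
            continue
        if not is_rare(v, mafs, cfg, "dominant"):
            continue
        ids = _case_only_carriers(v, case, control)
        if ids is None:
            continue
        entry = by_transcript.setdefault(v.transcript_id, (set(), [], v.gene))
        entry[0].update(ids)
        entry[1].append(v)

    best_by_gene: dict[str, CandidateCall] = {}
    for tx, (ids, vs, gene) in by_transcript.items():
        if len(ids) < min_samples:
            continue
        call = CandidateCall(
            gene=gene,
            transcript_id=tx,
            model="dominant_multi",
            variants=sorted(vs, key=lambda v: v.pos),
            sample_ids=sorted(ids),
            consequence_summary=";".join(sorted({v.consequence for v in vs})),
        )
        prev = best_by_gene.get(gene)
        if prev is None or len(call.sample_ids) > len(prev.sample_ids):
            best_by_gene[gene] = call
    return sorted(best_by_gene.values(), key=lambda c: (-len(c.sample_ids), c.gene))


def phase_exclude_pair(
    v1: CohortVariant,
    v2: CohortVariant,
    sample_index: int,
    read_length: int = 100,
) -> bool:
    """True when phasing proves the pair sits on ONE haplotype (cis).

    Phase information only exists within read range: pairs separated by at
    least ``read_length`` bases are unphased by construction and never
    excluded.  Within range, both variants must carry a phase-set
    annotation for the sample, share the phase set, and place the
    alternate allele on the same haplotype.
    """
    if abs(v1.pos - v2.pos) >= read_length:
        return False
    p1 = v1.phase.get(sample_index)
    p2 = v2.phase.get(sample_index)
    if p1 is None or p2 is None:
        return False
    ps1, hap1 = p1
    ps2, hap2 = p2
    return ps1 == ps2 and hap1 == hap2


def recessive_screen(
    variants: Sequence[CohortVariant],
    samples: Sequence[Sample],
    mafs: MafTable,
    cfg: RarityConfig,
    kept_transcripts: set[str] | None = None,
    read_length: int = 100,
) -> list[CandidateCall]:
    """Homozygous / hemizygous / compound-heterozygous candidates.

    Per transcript and case sample: a homozygous-alternate rare damaging
    variant yields a ``recessive_hom`` call; a hemizygous alternate in a
    male on X or Y yields ``recessive_hemi`` (a hemizygous call in a
    female is a data error); two or more rare damaging heterozygotes
    yield a ``compound_het`` call when at least one pair survives phase
    exclusion.  Every contributing variant must be absent from controls.
    """
    case, control = _cohort_indices(samples)
    eligible: dict[str, list[CohortVariant]] = {}
    for v in variants:
        if kept_transcripts is not None and v.transcript_id not in kept_transcripts:
            continue
        if variant_impact(v) < Impact.MODERATE:
            continue
        if not is_rare(v, mafs, cfg, "recessive"):
            continue
        if _case_only_carriers(v, case, control) is None:
            continue
        eligible.setdefault(v.transcript_id, []).append(v)

    calls: list[CandidateCall] = []
    for tx, vs in sorted(eligible.items()):
        vs = sorted(vs, key=lambda v: v.pos)
        gene = vs[0].gene
        for idx, sample in enumerate(samples):
            if sample.cohort is not Cohort.CASE:
                # hemizygous sanity applies cohort-wide
                for v in vs:
                    _check_hemi_sanity(v, idx, sample)
                continue
            homs = [v for v in vs if v.genotypes[idx] == Genotype.HOM_ALT]
            hemis = []
            for v in vs:
                if v.genotypes[idx] == Genotype.HEMI_ALT:
                    _check_hemi_sanity(v, idx, sample)
                    hemis.append(v)
            hets = [v for v in vs if v.genotypes[idx] == Genotype.HET]

            for v in homs:
                calls.append(
                    CandidateCall(gene, tx, "recessive_hom", [v], [sample.sample_id], v.consequence)
                )
            for v in hemis:
                calls.append(
                    CandidateCall(gene, tx, "recessive_hemi", [v], [sample.sample_id], v.consequence)
                )
            if len(hets) >= 2:
                in_trans: set[tuple] = set()
                for a, b in combinations(hets, 2):
                    if not phase_exclude_pair(a, b, idx, read_length):
                        in_trans.add(a.key)
                        in_trans.add(b.key)
                pair_vs = [v for v in hets if v.key in in_trans]
                if len(pair_vs) >= 2:
                    calls.append(
                        CandidateCall(
                            gene,
                            tx,
                            "compound_het",
                            pair_vs,
                            [sample.sample_id],
                            ";".join(sorted({v.consequence for v in pair_vs})),
                        )
                    )
    return calls


def _check_hemi_sanity(v: CohortVariant, idx: int, sample: Sample) -> None:
    if v.genotypes[idx] == Genotype.HEMI_ALT:
        if sample.sex is not Sex.MALE or v.chrom.removeprefix("chr") not in ("X", "Y"):
            raise ValueError(
                f"hemizygous genotype for {sample.sample_id} at {v.chrom}:{v.pos} "
                "is inconsistent with sample sex/chromosome"
            )
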