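"""Biallelic variant QC cascade.

Filters, applied in a fixed order with first-failing-filter binning so that
exclusion bins are disjoint and the ledger conserves counts:

1. ``pseudogenic``    — transcript flagged as a pseudogene artifact
2. ``refseq_error``   — transcript flagged as a RefSeq model error
3. ``low_complexity`` — DUST score of either 15-base flank above threshold
4. ``uncertain``      — per-sample PASS filter failed in > 10% of samples
5. ``low_depth``      — depth < 10x in > 10% of samples
6. ``hwe_violation``  — exact Hardy-Weinberg test in controls below alpha

The Hardy-Weinberg exact test is the conditional test on the observed
allele counts with probability ordering (tables whose conditional
probability does not exceed the observed one contribute to the p-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy.special import gammaln

from .cohort_io import CohortVariant, FilterLedger, Genotype, Sample, Cohort

__all__ = [
    "QcConfig",
    "dust_score",
    "is_low_complexity",
    "hwe_exact_test",
    "apply_qc_cascade",
    "FILTER_ORDER",
]

FILTER_ORDER = (
    "pseudogenic",
    "refseq_error",
    "low_complexity",
    "uncertain",
    "low_depth",
    "hwe_violation",
)


@dataclass
class QcConfig:
    """Thresholds for the QC cascade.

    ``max_fail_fraction``/``min_depth_fail_fraction`` are the tolerated
    fractions of samples failing the per-sample PASS / depth checks;
    ``dust_window_flank`` is the number of reference bases scored on each
    side of a variant; ``hwe_alpha`` is the exact-test significance level
    below which a control-cohort genotype table is treated as a technical
    or pseudogenic artifact.
    """

    max_fail_fraction: float = 0.10
    min_depth: int = 10
    min_depth_fail_fraction: float = 0.10
    dust_window_flank: int = 15
    dust_threshold: float = 2.0
    hwe_alpha: float = 1e-6

    def __post_init__(self) -> None:
        for frac in (self.max_fail_fraction, self.min_depth_fail_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fail fractions must lie in [0, 1]")
        if self.dust_window_flank < 3:
            raise ValueError("dust window must cover at least one triplet")

    @classmethod
    def disabled(cls) -> "QcConfig":
        """A configuration under which no variant is ever excluded."""
        return cls(
            max_fail_fraction=1.0,
            min_depth=0,
            min_depth_fail_fraction=1.0,
            dust_threshold=math.inf,
            hwe_alpha=0.0,
        )


class SequenceAccessor(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class DictReference:
    """Reference accessor backed by a plain chrom -> sequence mapping."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = dict(sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"contig {chrom!r} absent from reference")
        seq = self._seqs[chrom]
        return seq[max(start, 0):min(end, len(seq))]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs


class FastaReference:
    """Reference accessor over a pyfaidx FASTA file."""

    def __init__(self, path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} absent from reference")
        return str(self._fasta[chrom][max(start, 0):end])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta


def dust_score(seq: str) -> float:
    """Triplet-repetition (DUST-style) score of a nucleotide window.

    score = [sum over distinct triplets t of c_t (c_t - 1) / 2] / (T - 1)
    where c_t counts overlapping occurrences of triplet t and T is the
    number of scored triplets; triplets containing N are not scored and the
    denominator is floored at 1.  A window of all-distinct triplets scores
    0; a homopolymer maximizes the score for its length.
    """
    if len(seq) < 3:
        raise ValueError("dust_score needs a window of at least 3 bases")
    seq = seq.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - 2):
        t = seq[i : i + 3]
        if "N" in t:
            continue
        counts[t] = counts.get(t, 0) + 1
    n_triplets = sum(counts.values())
    if n_triplets == 0:
        return 0.0
    num = sum(c * (c - 1) // 2 for c in counts.values())
    return num / max(n_triplets - 1, 1)


def is_low_complexity(
    variant: CohortVariant, reference: SequenceAccessor, cfg: QcConfig
) -> bool:
    """Whether either reference flank of the variant is low-complexity.

    Scores ``cfg.dust_window_flank`` bases 5' and 3' of the variant site;
    windows truncated at contig ends are scored when at least 3 bases
    remain, otherwise that side is skipped.
    """
    w = cfg.dust_window_flank
    pos0 = variant.pos - 1
    flank5 = reference.fetch(variant.chrom, pos0 - w, pos0)
    flank3 = reference.fetch(variant.chrom, pos0 + len(variant.ref), pos0 + len(variant.ref) + w)
    for flank in (flank5, flank3):
        if len(flank) >= 3 and dust_score(flank) > cfg.dust_threshold:
            return True
    return False


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability is at most that
    of the observed table (probability ordering).  Returns a p-value in
    (0, 1]; a monomorphic site returns 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0

    # log P(het = h | allele counts) over the support (h same parity as n_rare)
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hs) // 2
    hom_common = n - hs - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hs + 1)
        - gammaln(hom_common + 1)
        + hs * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def control_genotype_counts(
    variant: CohortVariant, control_idx: np.ndarray
) -> tuple[int, int, int]:
    """Diploid genotype counts among controls (hemizygous/missing skipped)."""
    g = variant.genotypes[control_idx]
    return (
        int(np.sum(g == Genotype.HOM_REF)),
        int(np.sum(g == Genotype.HET)),
        int(np.sum(g == Genotype.HOM_ALT)),
    )


@dataclass
class QcResult:
    survivors: list[CohortVariant]
    ledger: FilterLedger
    bins: dict[str, list[CohortVariant]] = field(default_factory=dict)


def apply_qc_cascade(
    variants: Sequence[CohortVariant],
    samples: Sequence[Sample],
    cfg: QcConfig,
    flags: Mapping[str, frozenset[str] | set[str]] | None = None,
    reference: SequenceAccessor | None = None,
) -> tuple[list[CohortVariant], FilterLedger]:
    """Run the ordered QC cascade over ingested biallelic variants.

    ``flags`` maps transcript (or gene) identifiers to annotation flags
    containing ``"pseudogene"`` and/or ``"refseq_error"``.  When
    ``reference`` is None the low-complexity filter is skipped (counted as
    zero).  Each variant lands in the bin of the FIRST filter it fails, so
    bins are disjoint and the ledger conserves the input count.
    """
    flags = flags or {}
    control_idx = np.array(
        [i for i, s in enumerate(samples) if s.cohort == Cohort.CONTROL], dtype=int
    )
    bins: dict[str, list[CohortVariant]] = {name: [] for name in FILTER_ORDER}
    survivors: list[CohortVariant] = []

    for v in variants:
        v_flags = set(flags.get(v.transcript_id, ())) | set(flags.get(v.gene, ()))
        failed = None
        if "pseudogene" in v_flags:
            failed = "pseudogenic"
        elif "refseq_error" in v_flags:
            failed = "refseq_error"
        elif reference is not None and is_low_complexity(v, reference, cfg):
            failed = "low_complexity"
        elif np.mean(~v.pass_flags) > cfg.max_fail_fraction:
            failed = "uncertain"
        elif np.mean(v.depths < cfg.min_depth) > cfg.min_depth_fail_fraction:
            failed = "low_depth"
        elif cfg.hwe_alpha > 0 and control_idx.size > 0:
            aa, ab, bb = control_genotype_counts(v, control_idx)
            if aa + ab + bb > 0 and hwe_exact_test(aa, ab, bb) < cfg.hwe_alpha:
                failed = "hwe_violation"
        if failed is None:
            survivors.append(v)
        else:
            bins[failed].append(v)

    ledger = FilterLedger(input_count=len(variants))
    for name in FILTER_ORDER:
        ledger.add(name, len(bins[name]))
    ledger.validate()
    assert ledger.surviving_count == len(survivors)
    return survivors, ledger
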