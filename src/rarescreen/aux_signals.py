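"""Secondary genome-wide scans: coverage (CNV), STR lengths, power, viruses.

The CNV scan compares read-depth between cohorts region by region with the
Wilcoxon–Mann–Whitney rank-sum test under Bonferroni correction; because
the corrected per-test alpha sits far in the tail (0.05 / 286,754 regions
= 1.74e-7 at genome scale), the exact null distribution is used whenever
group sizes allow, falling back to the normal approximation with tie
correction otherwise.  Sample-size requirements are computed with
Noether's approximation for the rank-sum test.  The viral screen is a pure
filter over off-target alignment hits (length and identity thresholds)
with a per-cohort, per-virus sample summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort, GenomicRegion, Sample

log = logging.getLogger(__name__)

__all__ = [
    "CoverageMatrix",
    "PowerSpec",
    "ViralHit",
    "ScanResult",
    "bonferroni_alpha",
    "refine_high_coverage_regions",
    "normalize_coverage",
    "groupwise_wilcoxon_scan",
    "wmw_power_n",
    "str_compare",
    "filter_viral_hits",
]


@dataclass
class CoverageMatrix:
    """Region x sample coverage values (raw or normalized)."""

    regions: list[GenomicRegion]
    samples: list[Sample]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError("coverage matrix shape must be (n_regions, n_samples)")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def cohort_columns(self, cohort: Cohort) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.cohort == cohort], dtype=int)


@dataclass
class PowerSpec:
    """Inputs/outputs of a rank-sum sample-size calculation.

    ``effect`` is the between-group location shift in the measurement's
    units (e.g. 0.5 for a 50% change of a mean-1 normalized coverage, or 2
    for two repeat units); ``sd`` the within-group standard deviation.
    """

    alpha: float
    power: float
    effect: float
    sd: float
    n_per_group: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < self.power < 1.0:
            raise ValueError("need 0 < alpha < power < 1")
        if self.effect <= 0 or self.sd <= 0:
            raise ValueError("effect and sd must be positive")


@dataclass(frozen=True)
class ViralHit:
    read_id: str
    sample_id: str
    virus_accession: str
    align_length: int
    identity: float

    def __post_init__(self) -> None:
        if self.align_length < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity is a percentage in [0, 100]")


@dataclass
class ScanResult:
    pvalues: np.ndarray
    per_test_alpha: float
    significant: np.ndarray  # indices
    n_tests: int
    skipped: list[int] = field(default_factory=list)
    constant: list[int] = field(default_factory=list)


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test alpha under Bonferroni, computed in exact rational
    arithmetic and converted to float only at the end."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(Fraction(family_alpha).limit_denominator(10**9) / n_tests)


def refine_high_coverage_regions(
    depth_profiles: Sequence[tuple[GenomicRegion, np.ndarray]],
    min_avg_coverage: float = 20.0,
) -> list[GenomicRegion]:
    """Trim target regions to their empirically well-covered spans.

    Each profile is the per-base mean control-cohort depth over one
    region.  Contiguous runs of bases above the threshold become output
    regions; fully shallow regions are dropped.
    """
    out: list[GenomicRegion] = []
    for region, depth in depth_profiles:
        depth = np.asarray(depth, dtype=float)
        if len(depth) != region.length:
            raise ValueError(
                f"depth profile length {len(depth)} != region length {region.length}"
            )
        mask = depth > min_avg_coverage
        if not mask.any():
            continue
        # contiguous True runs -> sub-intervals
        padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            out.append(
                GenomicRegion(
                    region.chrom,
                    region.start + int(s),
                    region.start + int(e),
                    region.region_class,
                    region.gene,
                    region.transcript_id,
                )
            )
    return out


def normalize_coverage(m: CoverageMatrix, total_mapped_reads: Sequence[float]) -> CoverageMatrix:
    """Rescale each sample's coverage column by median_total / sample_total."""
    totals = np.asarray(total_mapped_reads, dtype=float)
    if totals.shape != (len(m.samples),):
        raise ValueError("one read total per sample required")
    if (totals <= 0).any():
        raise ValueError("read totals must be positive")
    scale = np.median(totals) / totals
    return CoverageMatrix(m.regions, m.samples, m.values * scale[None, :], normalized=True)


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided rank-sum p-value; exact when tie-free and groups small."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (not has_ties and max(len(x), len(y)) <= exact_max_n) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def groupwise_wilcoxon_scan(
    m: CoverageMatrix | np.ndarray,
    samples: Sequence[Sample] | None = None,
    family_alpha: float = 0.05,
) -> ScanResult:
    """Region-by-region rank-sum scan with Bonferroni-corrected calls.

    Constant rows cannot be ranked and are assigned p = 1 by convention
    (and recorded).  The significant set is {i : p_i < family_alpha / R}.
    """
    if isinstance(m, CoverageMatrix):
        values = m.values
        samples = m.samples
    else:
        values = np.asarray(m, dtype=float)
        if samples is None:
            raise ValueError("samples required when passing a bare matrix")
    case_idx = np.array([i for i, s in enumerate(samples) if s.cohort == Cohort.CASE], dtype=int)
    ctrl_idx = np.array([i for i, s in enumerate(samples) if s.cohort == Cohort.CONTROL], dtype=int)
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValueError("need at least two samples per group")

    n_tests = values.shape[0]
    alpha = bonferroni_alpha(family_alpha, n_tests)
    pvalues = np.ones(n_tests)
    constant: list[int] = []
    for i in range(n_tests):
        row = values[i]
        if np.ptp(row) == 0:
            constant.append(i)
            continue
        pvalues[i] = _rank_sum_p(row[case_idx], row[ctrl_idx])
    if constant:
        log.info("%d constant rows assigned p = 1", len(constant))
    significant = np.flatnonzero(pvalues < alpha)
    return ScanResult(pvalues, alpha, significant, n_tests, constant=constant)


def wmw_power_n(spec: PowerSpec) -> PowerSpec:
    """Per-group sample size for the rank-sum test, Noether's formula.

    n_total = (z_{1-a/2} + z_{1-b})^2 / (12 (p' - 1/2)^2) with
    p' = Phi(effect / (sd * sqrt(2))), the probability that a case
    observation exceeds a control observation under normal shift.
    """
    p_prime = float(stats.norm.cdf(spec.effect / (spec.sd * math.sqrt(2.0))))
    capped = False
    if p_prime >= 1.0 - 1e-12:
        p_prime = 1.0 - 1e-12
        capped = True
        log.warning("exceedance probability capped at 1 - 1e-12")
    z_alpha = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    z_beta = float(stats.norm.ppf(spec.power))
    n_total = (z_alpha + z_beta) ** 2 / (12.0 * (p_prime - 0.5) ** 2)
    return PowerSpec(
        alpha=spec.alpha,
        power=spec.power,
        effect=spec.effect,
        sd=spec.sd,
        n_per_group=math.ceil(n_total / 2.0),
        metadata={
            "method": "noether",
            "p_prime": p_prime,
            "n_total": n_total,
            "capped": capped,
        },
    )


def str_compare(
    str_table: pd.DataFrame,
    samples: Sequence[Sample],
    family_alpha: float = 0.05,
) -> tuple[ScanResult, pd.DataFrame]:
    """Rank-sum scan over STR repeat counts (loci x samples, NaN = missing).

    Loci genotyped in fewer than two samples of either group are skipped
    (p = NaN, recorded) and do not count as tests.
    """
    ids = [s.sample_id for s in samples]
    missing_cols = [c for c in ids if c not in str_table.columns]
    if missing_cols:
        raise ValueError(f"STR table lacks sample columns: {missing_cols}")
    values = str_table[ids].to_numpy(dtype=float)
    case_idx = np.array([i for i, s in enumerate(samples) if s.cohort == Cohort.CASE], dtype=int)
    ctrl_idx = np.array([i for i, s in enumerate(samples) if s.cohort == Cohort.CONTROL], dtype=int)

    testable: list[int] = []
    skipped: list[int] = []
    for i in range(values.shape[0]):
        x = values[i, case_idx]
        y = values[i, ctrl_idx]
        if np.sum(~np.isnan(x)) >= 2 and np.sum(~np.isnan(y)) >= 2:
            testable.append(i)
        else:
            skipped.append(i)
    if skipped:
        log.info("%d STR loci skipped (insufficient genotypes)", len(skipped))
    n_tests = max(len(testable), 1)
    alpha = bonferroni_alpha(family_alpha, n_tests)
    pvalues = np.full(values.shape[0], np.nan)
    constant: list[int] = []
    for i in testable:
        x = values[i, case_idx]
        y = values[i, ctrl_idx]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            pvalues[i] = 1.0
            constant.append(i)
            continue
        pvalues[i] = _rank_sum_p(x, y)
    significant = np.flatnonzero(pvalues < alpha)
    result = ScanResult(pvalues, alpha, significant, len(testable), skipped=skipped, constant=constant)
    frame = str_table.copy()
    frame["pvalue"] = pvalues
    frame["significant"] = False
    frame.loc[frame.index[significant], "significant"] = True
    return result, frame


def filter_viral_hits(
    hits: Iterable[ViralHit],
    samples: Sequence[Sample],
    min_len: int = 90,
    min_ident: float = 95.0,
) -> tuple[list[ViralHit], pd.DataFrame]:
    """Keep alignment hits longer than ``min_len`` bp and above
    ``min_ident`` percent identity; summarize distinct samples per virus
    per cohort.  Order-independent and idempotent.
    """
    cohort_of = {s.sample_id: s.cohort.value for s in samples}
    kept = sorted(
        (h for h in hits if h.align_length > min_len and h.identity > min_ident),
        key=lambda h: (h.virus_accession, h.sample_id, h.read_id),
    )
    tally: dict[tuple[str, str], set[str]] = {}
    for h in kept:
        cohort = cohort_of.get(h.sample_id, "unknown")
        tally.setdefault((h.virus_accession, cohort), set()).add(h.sample_id)
    rows = [
        (virus, cohort, len(sample_set), ",".join(sorted(sample_set)))
        for (virus, cohort), sample_set in sorted(tally.items())
    ]
    summary = pd.DataFrame(rows, columns=["virus", "cohort", "n_samples", "sample_ids"])
    return kept, summary


def read_viral_hits(path) -> list[ViralHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        ViralHit(
            read_id=str(r.read_id),
            sample_id=str(r.sample_id),
            virus_accession=str(r.virus_accession),
            align_length=int(r.align_length),
            identity=float(r.identity),
        )
        for r in df.itertuples(index=False)
    ]
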