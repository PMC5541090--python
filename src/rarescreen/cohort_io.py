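"""Core cohort data model and readers/writers for the standard file formats.

Everything downstream of variant calling works on the in-memory types
defined here: :class:`Sample`, :class:`CohortVariant`, :class:`FilterLedger`,
:class:`GenomicRegion`, :class:`Transcript`, :class:`MafTable` and
:class:`CandidateCall`.

Coordinate conventions: internal intervals are 0-based half-open (BED
native); single positions on variants and in report output are 1-based
(VCF / GRCh37 table native).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "Sex",
    "Impact",
    "Genotype",
    "RegionClass",
    "Sample",
    "CohortVariant",
    "FilterLedger",
    "GenomicRegion",
    "Transcript",
    "MafRecord",
    "MafTable",
    "CandidateCall",
    "read_cohort_vcf",
    "read_bed_regions",
    "read_transcript_table",
    "write_candidate_table",
    "read_candidate_table",
    "candidate_calls_from_table",
]


class Cohort(str, Enum):
    CASE = "case"
    CONTROL = "control"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Impact(IntEnum):
    """SnpEff-style putative impact, ordered by severity."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


class Genotype(IntEnum):
    """Per-sample genotype codes stored in :attr:`CohortVariant.genotypes`."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    HEMI_ALT = 3


class RegionClass(str, Enum):
    """Sub-gene region classes used by the burden analysis."""

    UPSTREAM = "UPSTREAM"
    FIVE_UTR = "5'UTR"
    SPLICE = "SPLICE"
    EXONIC = "EXONIC"
    INTRON = "INTRON"
    THREE_UTR = "3'UTR"


#: accepted spellings for region classes in BED column 4 / report tables
_REGION_ALIASES: dict[str, RegionClass] = {
    "upstream": RegionClass.UPSTREAM,
    "5utr": RegionClass.FIVE_UTR,
    "5'utr": RegionClass.FIVE_UTR,
    "5' utr": RegionClass.FIVE_UTR,
    "five_utr": RegionClass.FIVE_UTR,
    "five_prime_utr": RegionClass.FIVE_UTR,
    "splice": RegionClass.SPLICE,
    "flanking_intron": RegionClass.SPLICE,
    "exon": RegionClass.EXONIC,
    "exonic": RegionClass.EXONIC,
    "intron": RegionClass.INTRON,
    "intronic": RegionClass.INTRON,
    "3utr": RegionClass.THREE_UTR,
    "3'utr": RegionClass.THREE_UTR,
    "3' utr": RegionClass.THREE_UTR,
    "three_utr": RegionClass.THREE_UTR,
    "three_prime_utr": RegionClass.THREE_UTR,
}


def parse_region_class(token: str) -> RegionClass:
    key = token.strip().lower()
    try:
        return _REGION_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown region class: {token!r}") from None


@dataclass(frozen=True)
class Sample:
    sample_id: str
    cohort: Cohort
    sex: Sex


@dataclass
class CohortVariant:
    """One biallelic variant with per-sample genotype/depth/filter state.

    ``genotypes``, ``depths`` and ``pass_flags`` are aligned with the sample
    list the variant was read with.  ``phase`` maps a sample index to a
    ``(phase_set_id, alt_haplotype)`` pair for phased heterozygous
    genotypes; ``alt_haplotype`` is 0 or 1, the haplotype carrying the
    alternate allele.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    transcript_id: str
    consequence: str
    impact: Impact
    genotypes: np.ndarray  # int8, Genotype codes
    depths: np.ndarray  # int32
    pass_flags: np.ndarray  # bool
    phase: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        n = len(self.genotypes)
        if len(self.depths) != n or len(self.pass_flags) != n:
            raise ValueError("per-sample arrays must share one length")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carrier_indices(self) -> np.ndarray:
        """Indices of samples carrying at least one alternate allele."""
        return np.flatnonzero(np.isin(self.genotypes, (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)))


@dataclass
class FilterLedger:
    """Ordered, conserved accounting of variants removed by named filters.

    Invariant: ``input_count == surviving_count + sum of exclusion counts``.
    """

    input_count: int
    exclusions: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative exclusion count for {name!r}")
        self.exclusions.append((name, count))

    @property
    def excluded_total(self) -> int:
        return sum(c for _, c in self.exclusions)

    @property
    def surviving_count(self) -> int:
        return self.input_count - self.excluded_total

    def validate(self) -> None:
        if self.input_count < 0 or any(c < 0 for _, c in self.exclusions):
            raise ValueError("ledger counts must be non-negative")
        if self.surviving_count < 0:
            raise ValueError("exclusions exceed input count")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(name, c) for name, c in self.exclusions]
        rows.append(("surviving", self.surviving_count))
        return pd.DataFrame(rows, columns=["filter", "count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GenomicRegion:
    """A sub-gene interval, 0-based half-open, tied to one transcript."""

    chrom: str
    start: int
    end: int
    region_class: RegionClass
    gene: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos1: int) -> bool:
        """Whether a 1-based position falls inside the region."""
        return self.start < pos1 <= self.end

    @property
    def name(self) -> str:
        return f"{self.region_class.value}|{self.gene}|{self.transcript_id}"


@dataclass
class Transcript:
    transcript_id: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # 0-based half-open, sorted
    cds_start: int | None = None
    cds_end: int | None = None
    flags: frozenset[str] = frozenset()

    #: flags marking a transcript model as unusable for coding interpretation
    BOGUS_FLAGS = frozenset({"no_start_codon", "multiple_stop", "incomplete"})

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty exon in {self.transcript_id}")
        self.exons = exons
        # a transcript without a CDS cannot have a verified ORF
        if self.cds_start is None or self.cds_end is None:
            self.flags = frozenset(self.flags) | {"incomplete"}
        else:
            self.flags = frozenset(self.flags)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_bogus(self) -> bool:
        return bool(self.flags & self.BOGUS_FLAGS)


@dataclass(frozen=True)
class MafRecord:
    af_dbsnp: float | None = None
    af_evs: float | None = None
    af_exac: float | None = None
    hu_control_carriers: int = 0

    def known_afs(self) -> list[float]:
        return [a for a in (self.af_dbsnp, self.af_evs, self.af_exac) if a is not None]

    @property
    def max_known_af(self) -> float | None:
        afs = self.known_afs()
        return max(afs) if afs else None


class MafTable:
    """Lookup of public allele frequencies keyed by (chrom, pos, ref, alt)."""

    COLUMNS = ["chrom", "pos", "ref", "alt", "af_dbsnp", "af_evs", "af_exac", "hu_control_carriers"]

    def __init__(self, records: Mapping[tuple[str, int, str, str], MafRecord] | None = None):
        self._records: dict[tuple[str, int, str, str], MafRecord] = dict(records or {})
        for key, rec in self._records.items():
            for af in rec.known_afs():
                if not 0.0 <= af <= 1.0:
                    raise ValueError(f"allele frequency out of [0,1] at {key}")
            if rec.hu_control_carriers < 0:
                raise ValueError(f"negative control carrier count at {key}")

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._records

    def get(self, key: tuple[str, int, str, str]) -> MafRecord | None:
        return self._records.get(key)

    def lookup(self, v: CohortVariant) -> MafRecord | None:
        return self._records.get(v.key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MafTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        records = {}
        for row in df.itertuples(index=False):
            records[(row.chrom, int(row.pos), row.ref, row.alt)] = MafRecord(
                af_dbsnp=None if pd.isna(row.af_dbsnp) else float(row.af_dbsnp),
                af_evs=None if pd.isna(row.af_evs) else float(row.af_evs),
                af_exac=None if pd.isna(row.af_exac) else float(row.af_exac),
                hu_control_carriers=int(row.hu_control_carriers),
            )
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (chrom, pos, ref, alt), rec in sorted(self._records.items()):
            rows.append((chrom, pos, ref, alt, rec.af_dbsnp, rec.af_evs, rec.af_exac, rec.hu_control_carriers))
        pd.DataFrame(rows, columns=self.COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class CandidateCall:
    """A prioritized gene/variant with its inheritance-model tag."""

    gene: str
    transcript_id: str
    model: str  # dominant_HI | dominant_multi | recessive_hom | recessive_hemi | compound_het | region_burden
    variants: list[CohortVariant]
    sample_ids: list[str]
    consequence_summary: str = ""

    MODELS = ("dominant_HI", "dominant_multi", "recessive_hom", "recessive_hemi", "compound_het", "region_burden")

    def __post_init__(self) -> None:
        if self.model not in self.MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "compound_het" and len(self.variants) < 2:
            raise ValueError("compound_het call needs >= 2 variants")


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def _parse_ann(ann: str) -> tuple[str, str, str, Impact]:
    """First entry of a SnpEff ANN field -> (gene, transcript, consequence, impact)."""
    first = ann.split(",")[0]
    fields = first.split("|")
    if len(fields) < 7:
        raise ValueError(f"malformed ANN entry: {first!r}")
    consequence = fields[1]
    impact_str = fields[2].upper()
    gene = fields[3]
    transcript = fields[6]
    try:
        impact = Impact[impact_str]
    except KeyError:
        log.warning("unknown impact %r; mapping to MODIFIER", impact_str)
        impact = Impact.MODIFIER
    return gene, transcript, consequence, impact


def _genotype_code(alleles: Sequence[int]) -> int:
    """Allele indices (``-1`` for missing) -> a :class:`Genotype` code."""
    if len(alleles) == 1:  # haploid
        if alleles[0] < 0:
            return Genotype.MISSING
        return Genotype.HEMI_ALT if alleles[0] == 1 else Genotype.HOM_REF
    a, b = alleles[0], alleles[1]
    if a < 0 or b < 0:
        return Genotype.MISSING
    n_alt = (a > 0) + (b > 0)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]


def read_cohort_vcf(path: str | Path, samples: list[Sample]) -> tuple[list[CohortVariant], FilterLedger]:
    """Read an annotated cohort VCF into :class:`CohortVariant` records.

    Only the multiallelic exclusion is applied here (records with more than
    one ALT allele are dropped and counted); every other QC filter belongs
    to the downstream cascade.  Raises on a missing ANN annotation or on a
    sample-column mismatch.
    """
    vcf = VCF(str(path))
    expected = [s.sample_id for s in samples]
    if list(vcf.samples) != expected:
        raise ValueError(
            f"VCF sample columns {list(vcf.samples)} do not match the declared cohort {expected}"
        )
    n = len(expected)
    variants: list[CohortVariant] = []
    total = 0
    n_multi = 0
    for rec in vcf:
        total += 1
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ann = rec.INFO.get("ANN")
        if ann is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks an ANN annotation field")
        gene, transcript, consequence, impact = _parse_ann(ann)

        gts = np.full(n, Genotype.MISSING, dtype=np.int8)
        phase: dict[int, tuple[str, int]] = {}
        ps_field = rec.format("PS")
        ft_field = rec.format("FT")
        dp_field = rec.format("DP")
        genotypes = rec.genotypes  # [a1, a2, phased] or [a1, phased]
        for i in range(n):
            g = genotypes[i]
            alleles = g[:-1]
            phased = bool(g[-1])
            gts[i] = _genotype_code(alleles)
            if gts[i] == Genotype.HET and phased and len(alleles) == 2 and ps_field is not None:
                ps = _format_str(ps_field[i])
                # "." and negative sentinels both mean a missing phase set
                if ps and ps != "." and not ps.startswith("-"):
                    phase[i] = (ps, 0 if alleles[0] == 1 else 1)

        depths = np.zeros(n, dtype=np.int32)
        if dp_field is not None:
            dp = np.asarray(dp_field).reshape(n, -1)[:, 0]
            depths = np.where(dp < 0, 0, dp).astype(np.int32)
        pass_flags = np.ones(n, dtype=bool)
        if ft_field is not None:
            for i in range(n):
                ft = _format_str(ft_field[i])
                pass_flags[i] = ft in (None, "", ".", "PASS")

        variants.append(
            CohortVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                gene=gene,
                transcript_id=transcript,
                consequence=consequence,
                impact=impact,
                genotypes=gts,
                depths=depths,
                pass_flags=pass_flags,
                phase=phase,
            )
        )
    ledger = FilterLedger(input_count=total)
    ledger.add("multiallelic", n_multi)
    ledger.validate()
    return variants, ledger


def _format_str(value) -> str | None:
    """Normalize a cyvcf2 per-sample String FORMAT value."""
    if value is None:
        return None
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.ndarray):
        value = value.item() if value.size == 1 else value.tolist()[0]
        return _format_str(value)
    return str(value)


# ---------------------------------------------------------------------------
# BED / transcript tables
# ---------------------------------------------------------------------------

def read_bed_regions(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3+ file whose 4th column is ``class|gene|transcript``."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{line_no}: need BED3+ with a class|gene|transcript column")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{line_no}: start >= end")
            parts = fields[3].split("|")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: 4th column must be class|gene|transcript")
            cls = parse_region_class(parts[0])
            regions.append(GenomicRegion(chrom, start, end, cls, parts[1], parts[2]))
    return regions


def write_bed_regions(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


TRANSCRIPT_COLUMNS = ["transcript_id", "gene", "chrom", "strand", "exon_starts", "exon_ends", "cds_start", "cds_end", "flags"]


def read_transcript_table(path: str | Path) -> list[Transcript]:
    """Read a refFlat-like TSV of transcript models (0-based half-open exons)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "flags": str})
    out = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"{row.transcript_id}: exon start/end count mismatch")
        flags = frozenset() if pd.isna(row.flags) or row.flags in (".", "") else frozenset(str(row.flags).split(","))
        out.append(
            Transcript(
                transcript_id=row.transcript_id,
                gene=row.gene,
                chrom=row.chrom,
                strand=row.strand,
                exons=list(zip(starts, ends)),
                cds_start=None if pd.isna(row.cds_start) else int(row.cds_start),
                cds_end=None if pd.isna(row.cds_end) else int(row.cds_end),
                flags=flags,
            )
        )
    return out


def write_transcript_table(transcripts: Iterable[Transcript], path: str | Path) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            (
                t.transcript_id,
                t.gene,
                t.chrom,
                t.strand,
                ",".join(str(s) for s, _ in t.exons),
                ",".join(str(e) for _, e in t.exons),
                t.cds_start,
                t.cds_end,
                ",".join(sorted(t.flags)) or ".",
            )
        )
    pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = ["gene", "chrom", "pos", "ref", "alt", "consequence", "model", "sample_ids"]


def write_candidate_table(candidates: Iterable[CandidateCall], path: str | Path) -> None:
    """Serialize candidate calls to TSV, one row per contributing variant.

    Column order is stable and round-trips through
    :func:`read_candidate_table`.
    """
    rows = []
    for call in candidates:
        ids = ",".join(call.sample_ids)
        for v in call.variants:
            rows.append((call.gene, v.chrom, v.pos, v.ref, v.alt, v.consequence, call.model, ids))
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_ids": str})
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    return df


def candidate_calls_from_table(df: pd.DataFrame, model: str | None = None) -> list[CandidateCall]:
    """Rebuild :class:`CandidateCall` objects from a candidate table.

    Rows sharing (gene, model, sample_ids) collapse back into one call; this
    is the reporting path used to replay externally curated candidate
    tables through the same counting logic as live screen output.
    """
    grouped: dict[tuple[str, str, str], list] = {}
    for row in df.itertuples(index=False):
        row_model = model or row.model
        key = (row.gene, row_model, str(row.sample_ids))
        grouped.setdefault(key, []).append(row)
    calls = []
    for (gene, row_model, sample_str), rows in grouped.items():
        sample_ids = [s for s in sample_str.split(",") if s]
        n = max(len(sample_ids), 1)
        variants = [
            CohortVariant(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                gene=gene,
                transcript_id="",
                consequence=r.consequence,
                impact=Impact.MODIFIER,
                genotypes=np.ones(n, dtype=np.int8),
                depths=np.zeros(n, dtype=np.int32),
                pass_flags=np.ones(n, dtype=bool),
            )
            for r in rows
        ]
        calls.append(
            CandidateCall(
                gene=gene,
                transcript_id="",
                model=row_model,
                variants=variants,
                sample_ids=sample_ids,
                consequence_summary=rows[0].consequence,
            )
        )
    return calls
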