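"""Synthetic two-cohort exome bundles with planted, manifest-tracked signals.

Generates every input the pipeline consumes — annotated VCF, sub-gene
region BED, transcript models, public-MAF table, QC flag table, reference
FASTA, coverage/STR/viral tables — for a 23-case / 21-control design, with
non-planted control genotypes drawn under Hardy-Weinberg equilibrium and a
machine-readable truth manifest recording every planted signal.

The generator emulates the statistical structure the analysis assumes
(biallelic SNVs, SnpEff-style annotations, per-sample GT/DP/FT/PS fields,
rarity structure split between known and unknown public MAFs); it does not
attempt read-level realism, linkage disequilibrium beyond the cis/trans
pairs needed for compound-heterozygote logic, or indel mutation models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    Cohort,
    GenomicRegion,
    Genotype,
    Impact,
    MafRecord,
    MafTable,
    RegionClass,
    Sample,
    Sex,
    Transcript,
    write_bed_regions,
    write_transcript_table,
)
from .region_burden import build_subgene_regions

__all__ = [
    "SimConfig",
    "PlantSpec",
    "SimulatedBundle",
    "default_plants",
    "simulate_cohort",
    "simulate_null_burden",
]

PLANT_KINDS = (
    "dominant_HI",
    "recessive_hom",
    "recessive_hemi",
    "compound_het_trans",
    "compound_het_cis",
    "region_burden",
    "cnv_shift",
    "str_expansion",
    "viral_hits",
    "hwe_violation",
)

#: chromosomes genes are placed on (X included so hemizygous logic is exercised)
CHROM_CYCLE = [str(i) for i in range(1, 11)] + ["X"]
BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantSpec:
    """One planted signal; ``gene`` and ``carriers`` may be left for the
    generator to resolve (carriers are then drawn from the correct cohort
    and sex for the kind)."""

    kind: str
    gene: str | None = None
    carriers: tuple[str, ...] = ()
    magnitude: float = 1.5  # cnv fold-change / STR repeat delta
    n_samples: int = 5  # region_burden carriers

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")


def default_plants() -> tuple[PlantSpec, ...]:
    """One plant of every kind, carriers auto-resolved."""
    return tuple(
        PlantSpec(kind=k, magnitude=(3.0 if k == "str_expansion" else 1.5))
        for k in PLANT_KINDS
    )


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Cohort sizes and sex ratios follow the 23-case (15 male) / 21-control
    (14 male) design; the rarity structure follows the observed survivor
    statistics: about 5% of QC-surviving variants are rare, 89.7% of
    variants have a known public MAF, and 2.63% of raw VCF records are
    multiallelic.  ``n_regions``/``n_variants`` default to a reduced scale
    that keeps a full pipeline run under a minute.
    """

    seed: int
    n_case: int = 23
    n_control: int = 21
    case_male_fraction: float = 15 / 23
    control_male_fraction: float = 14 / 21
    n_regions: int = 5000
    n_variants: int = 3000
    maf_beta: tuple[float, float] = (0.5, 5.0)
    rare_fraction: float = 0.05
    known_maf_fraction: float = 0.897
    multiallelic_fraction: float = 0.0263
    uncertain_fraction: float = 0.01
    low_depth_fraction: float = 0.01
    low_complexity_fraction: float = 0.005
    flagged_transcript_fraction: float = 0.02
    flank: int = 8
    upstream_len: int = 1000
    n_cov_regions: int = 200
    n_str_loci: int = 50
    planted: tuple[PlantSpec, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_regions, self.n_variants) < 1:
            raise ValueError("cohort sizes, region and variant counts must be >= 1")


@dataclass
class SimulatedBundle:
    directory: Path
    paths: dict[str, Path]
    samples: list[Sample]
    truth: pd.DataFrame
    n_regions: int
    n_vcf_records: int


@dataclass
class _SimVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    transcript_id: str
    consequence: str
    impact: Impact
    gts: np.ndarray
    depths: np.ndarray
    fts: list[str]
    phase: dict[int, tuple[str, int]] = field(default_factory=dict)
    maf: MafRecord | None = None
    in_maf_table: bool = False
    multiallelic: bool = False


def _make_samples(cfg: SimConfig) -> list[Sample]:
    samples = []
    n_case_male = round(cfg.n_case * cfg.case_male_fraction)
    for i in range(cfg.n_case):
        sex = Sex.MALE if i < n_case_male else Sex.FEMALE
        samples.append(Sample(f"CASE{i + 1:02d}", Cohort.CASE, sex))
    n_ctrl_male = round(cfg.n_control * cfg.control_male_fraction)
    for i in range(cfg.n_control):
        sex = Sex.MALE if i < n_ctrl_male else Sex.FEMALE
        samples.append(Sample(f"CTRL{i + 1:02d}", Cohort.CONTROL, sex))
    return samples


def _make_transcripts(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[Transcript], list[GenomicRegion], dict[str, int]]:
    """Generate transcript models until the sub-gene region count reaches
    the configured target; returns (transcripts, regions, chrom lengths)."""
    cursors = {c: 1000 for c in CHROM_CYCLE}
    transcripts: list[Transcript] = []
    regions: list[GenomicRegion] = []
    gene_idx = 0
    while len(regions) < cfg.n_regions:
        chrom = CHROM_CYCLE[gene_idx % len(CHROM_CYCLE)]
        gene_idx += 1
        start = cursors[chrom] + cfg.upstream_len + 100
        n_exons = int(rng.integers(2, 7))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(150, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(300, 900))
        strand = "+" if rng.random() < 0.5 else "-"
        cds_start = exons[0][0] + int(rng.integers(60, 140))
        cds_end = exons[-1][1] - int(rng.integers(60, 140))
        t = Transcript(
            transcript_id=f"TX{gene_idx:05d}",
            gene=f"GENE{gene_idx:05d}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        transcripts.append(t)
        regions.extend(build_subgene_regions([t], cfg.flank, cfg.upstream_len))
        cursors[chrom] = t.end + int(rng.integers(500, 1500))
    chrom_lengths = {c: cursors[c] + 2000 for c in CHROM_CYCLE}
    return transcripts, regions, chrom_lengths


_CONSEQUENCES = {
    RegionClass.EXONIC: (
        ("missense_variant", Impact.MODERATE, 0.55),
        ("synonymous_variant", Impact.LOW, 0.35),
        ("stop_gained", Impact.HIGH, 0.10),
    ),
    RegionClass.SPLICE: (
        ("splice_region_variant&intron_variant", Impact.LOW, 0.7),
        ("splice_acceptor_variant&intron_variant", Impact.HIGH, 0.15),
        ("splice_donor_variant&intron_variant", Impact.HIGH, 0.15),
    ),
    RegionClass.FIVE_UTR: (("5_prime_UTR_variant", Impact.MODIFIER, 1.0),),
    RegionClass.THREE_UTR: (("3_prime_UTR_variant", Impact.MODIFIER, 1.0),),
    RegionClass.UPSTREAM: (("upstream_gene_variant", Impact.MODIFIER, 1.0),),
    RegionClass.INTRON: (("intron_variant", Impact.MODIFIER, 1.0),),
}


def _draw_consequence(cls: RegionClass, rng: np.random.Generator) -> tuple[str, Impact]:
    options = _CONSEQUENCES[cls]
    r = rng.random()
    acc = 0.0
    for term, impact, w in options:
        acc += w
        if r < acc:
            return term, impact
    return options[-1][0], options[-1][1]


def _is_male_x(chrom: str, sample: Sample) -> bool:
    return chrom in ("X", "Y") and sample.sex is Sex.MALE


def _hwe_genotypes(
    chrom: str, f: float, samples: Sequence[Sample], rng: np.random.Generator
) -> np.ndarray:
    """Genotypes under HWE at allele frequency f; males haploid on X/Y."""
    gts = np.empty(len(samples), dtype=np.int8)
    for i, s in enumerate(samples):
        if _is_male_x(chrom, s):
            gts[i] = Genotype.HEMI_ALT if rng.random() < f else Genotype.HOM_REF
        else:
            n_alt = int(rng.binomial(2, f))
            gts[i] = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]
    return gts


def _carrier_genotypes(
    chrom: str, carrier_idx: Sequence[int], samples: Sequence[Sample]
) -> np.ndarray:
    gts = np.full(len(samples), Genotype.HOM_REF, dtype=np.int8)
    for i in carrier_idx:
        gts[i] = Genotype.HEMI_ALT if _is_male_x(chrom, samples[i]) else Genotype.HET
    return gts


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> SimulatedBundle:
    """Write a complete synthetic input bundle into ``outdir``.

    All randomness flows from ``cfg.seed`` through one generator, so the
    same configuration produces byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = _make_samples(cfg)
    n = len(samples)
    case_idx = [i for i, s in enumerate(samples) if s.cohort == Cohort.CASE]
    ctrl_idx = [i for i, s in enumerate(samples) if s.cohort == Cohort.CONTROL]
    id_of = {s.sample_id: i for i, s in enumerate(samples)}

    transcripts, regions, chrom_lengths = _make_transcripts(cfg, rng)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    region_by_tx: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        region_by_tx.setdefault(r.transcript_id, []).append(r)

    # reference sequences (mutable byte arrays; poly-A flanks planted later)
    seqs = {
        c: rng.integers(0, 4, size=length).astype(np.uint8)
        for c, length in chrom_lengths.items()
    }

    used: set[tuple[str, int]] = set()

    def try_position(region: GenomicRegion, margin: int = 0) -> int | None:
        """A 1-based position inside the region not used by another variant."""
        for _ in range(50):
            pos0 = int(rng.integers(region.start + margin, region.end - margin))
            if (region.chrom, pos0) not in used:
                used.add((region.chrom, pos0))
                return pos0 + 1
        return None

    def fresh_position(region: GenomicRegion, margin: int = 0) -> int:
        pos = try_position(region, margin)
        if pos is None:
            raise RuntimeError("could not place a variant; region too crowded")
        return pos

    def default_fields() -> tuple[np.ndarray, list[str]]:
        depths = rng.integers(40, 90, size=n).astype(np.int32)
        fts = ["PASS"] * n
        return depths, fts

    variants: list[_SimVariant] = []
    truth_rows: list[dict] = []

    # ---------------- planted signals (placed first so background noise
    # cannot contaminate planted transcripts) ----------------
    plant_txs: set[str] = set()

    def pick_transcript(
        plant: PlantSpec, chrom_x: bool, need_cls: RegionClass, min_len: int = 60
    ) -> Transcript:
        if plant.gene is not None:
            cands = [t for t in transcripts if t.gene == plant.gene]
            if not cands:
                raise ValueError(f"plant targets nonexistent gene {plant.gene!r}")
        else:
            cands = [
                t
                for t in transcripts
                if (t.chrom == "X") == chrom_x
                and t.transcript_id not in plant_txs
                and any(
                    r.region_class == need_cls and r.length >= min_len
                    for r in region_by_tx[t.transcript_id]
                )
            ]
            if not cands:
                raise ValueError(f"no transcript available for plant {plant.kind}")
        t = cands[int(rng.integers(len(cands)))]
        plant_txs.add(t.transcript_id)
        return t

    def pick_region(t: Transcript, cls: RegionClass, min_len: int = 60) -> GenomicRegion:
        cands = [r for r in region_by_tx[t.transcript_id] if r.region_class == cls and r.length >= min_len]
        return cands[int(rng.integers(len(cands)))]

    def resolve_carriers(plant: PlantSpec, k: int, male_only: bool = False) -> list[int]:
        if plant.carriers:
            idx = [id_of[c] for c in plant.carriers]
            for i in idx:
                if samples[i].cohort is not Cohort.CASE:
                    raise ValueError(f"plant {plant.kind} carrier {samples[i].sample_id} is not a case")
                if male_only and samples[i].sex is not Sex.MALE:
                    raise ValueError(f"plant {plant.kind} needs male carriers")
            return idx
        pool = [i for i in case_idx if not male_only or samples[i].sex is Sex.MALE]
        return [int(i) for i in rng.choice(pool, size=k, replace=False)]

    def add_planted_variant(
        t: Transcript,
        region: GenomicRegion,
        consequence: str,
        impact: Impact,
        gts: np.ndarray,
        phase: dict[int, tuple[str, int]] | None = None,
        pos: int | None = None,
    ) -> _SimVariant:
        depths, fts = default_fields()
        v = _SimVariant(
            chrom=region.chrom,
            pos=pos if pos is not None else fresh_position(region),
            ref="",
            alt="",
            gene=t.gene,
            transcript_id=t.transcript_id,
            consequence=consequence,
            impact=impact,
            gts=gts,
            depths=depths,
            fts=fts,
            phase=phase or {},
            maf=None,
            in_maf_table=False,
        )
        variants.append(v)
        return v

    def record_truth(plant: PlantSpec, gene: str, tx: str, chrom: str, positions: list[int], ids: list[str], note: str = "") -> None:
        truth_rows.append(
            {
                "kind": plant.kind,
                "gene": gene,
                "transcript_id": tx,
                "chrom": chrom,
                "positions": ",".join(str(p) for p in positions),
                "sample_ids": ",".join(ids),
                "note": note,
            }
        )

    cnv_plants: list[tuple[PlantSpec, list[int]]] = []
    str_plants: list[tuple[PlantSpec, list[int]]] = []
    viral_plants: list[tuple[PlantSpec, list[int]]] = []

    for plant in cfg.planted:
        if plant.kind == "dominant_HI":
            t = pick_transcript(plant, False, RegionClass.EXONIC)
            region = pick_region(t, RegionClass.EXONIC)
            carriers = resolve_carriers(plant, 1)
            v = add_planted_variant(
                t, region, "stop_gained", Impact.HIGH, _carrier_genotypes(region.chrom, carriers, samples)
            )
            record_truth(plant, t.gene, t.transcript_id, v.chrom, [v.pos], [samples[i].sample_id for i in carriers])
        elif plant.kind == "recessive_hom":
            t = pick_transcript(plant, False, RegionClass.EXONIC)
            region = pick_region(t, RegionClass.EXONIC)
            carriers = resolve_carriers(plant, 1)
            gts = np.full(n, Genotype.HOM_REF, dtype=np.int8)
            gts[carriers[0]] = Genotype.HOM_ALT
            v = add_planted_variant(t, region, "missense_variant", Impact.MODERATE, gts)
            record_truth(plant, t.gene, t.transcript_id, v.chrom, [v.pos], [samples[carriers[0]].sample_id])
        elif plant.kind == "recessive_hemi":
            t = pick_transcript(plant, True, RegionClass.EXONIC)
            region = pick_region(t, RegionClass.EXONIC)
            carriers = resolve_carriers(plant, 1, male_only=True)
            gts = np.full(n, Genotype.HOM_REF, dtype=np.int8)
            gts[carriers[0]] = Genotype.HEMI_ALT
            v = add_planted_variant(t, region, "missense_variant", Impact.MODERATE, gts)
            record_truth(plant, t.gene, t.transcript_id, v.chrom, [v.pos], [samples[carriers[0]].sample_id])
        elif plant.kind in ("compound_het_trans", "compound_het_cis"):
            t = pick_transcript(plant, False, RegionClass.EXONIC, min_len=140)
            region = pick_region(t, RegionClass.EXONIC, min_len=140)
            carriers = resolve_carriers(plant, 1)
            ci = carriers[0]
            base0 = int(rng.integers(region.start + 10, region.end - 60))
            pos1, pos2 = base0 + 1, base0 + 41
            for p in (pos1 - 1, pos2 - 1):
                if (region.chrom, p) in used:
                    raise RuntimeError("compound-het plant collided with an existing variant")
                used.add((region.chrom, p))
            ps = str(pos1)
            hap2 = 1 if plant.kind == "compound_het_trans" else 0
            gts = _carrier_genotypes(region.chrom, [ci], samples)
            v1 = add_planted_variant(
                t, region, "missense_variant", Impact.MODERATE, gts.copy(), phase={ci: (ps, 0)}, pos=pos1
            )
            v2 = add_planted_variant(
                t, region, "missense_variant", Impact.MODERATE, gts.copy(), phase={ci: (ps, hap2)}, pos=pos2
            )
            record_truth(
                plant, t.gene, t.transcript_id, v1.chrom, [v1.pos, v2.pos], [samples[ci].sample_id],
                note="trans" if hap2 == 1 else "cis",
            )
        elif plant.kind == "region_burden":
            t = pick_transcript(plant, False, RegionClass.THREE_UTR)
            region = pick_region(t, RegionClass.THREE_UTR, min_len=60)
            carriers = resolve_carriers(plant, plant.n_samples)
            positions = []
            for ci in carriers:
                v = add_planted_variant(
                    t, region, "3_prime_UTR_variant", Impact.MODIFIER,
                    _carrier_genotypes(region.chrom, [ci], samples),
                )
                positions.append(v.pos)
            record_truth(
                plant, t.gene, t.transcript_id, region.chrom, positions,
                [samples[i].sample_id for i in carriers],
                note=f"{region.chrom}:{region.start}-{region.end}|{region.region_class.value}",
            )
        elif plant.kind == "hwe_violation":
            t = pick_transcript(plant, False, RegionClass.EXONIC)
            region = pick_region(t, RegionClass.EXONIC)
            gts = _hwe_genotypes(region.chrom, 0.5, samples, rng)
            gts[ctrl_idx] = Genotype.HET  # heterozygote excess in every control
            depths, fts = default_fields()
            f = 0.5
            v = _SimVariant(
                chrom=region.chrom,
                pos=fresh_position(region),
                ref="",
                alt="",
                gene=t.gene,
                transcript_id=t.transcript_id,
                consequence="synonymous_variant",
                impact=Impact.LOW,
                gts=gts,
                depths=depths,
                fts=fts,
                maf=MafRecord(af_dbsnp=f, af_evs=f, af_exac=f, hu_control_carriers=len(ctrl_idx)),
                in_maf_table=True,
            )
            variants.append(v)
            record_truth(plant, t.gene, t.transcript_id, v.chrom, [v.pos], [], note="all controls heterozygous")
        elif plant.kind == "cnv_shift":
            row = int(rng.integers(cfg.n_cov_regions))
            cnv_plants.append((plant, [row]))
            record_truth(plant, "", "", "", [row], [], note=f"fold={plant.magnitude}")
        elif plant.kind == "str_expansion":
            locus = int(rng.integers(cfg.n_str_loci))
            str_plants.append((plant, [locus]))
            record_truth(plant, "", "", "", [locus], [], note=f"delta_repeats={plant.magnitude}")
        elif plant.kind == "viral_hits":
            carriers = resolve_carriers(plant, 2)
            viral_plants.append((plant, carriers))
            record_truth(
                plant, "", "", "", [], [samples[i].sample_id for i in carriers], note="HHV6B"
            )

    # ---------------- background variants ----------------
    lc_planned: list[int] = []  # indices of variants whose 5' flank becomes poly-A
    for _ in range(cfg.n_variants):
        pos = None
        while pos is None:
            region = regions[int(rng.integers(len(regions)))]
            if region.transcript_id in plant_txs:
                continue
            pos = try_position(region)
        consequence, impact = _draw_consequence(region.region_class, rng)
        depths, fts = default_fields()
        r = rng.random()
        if r < cfg.uncertain_fraction:
            fail = rng.choice(n, size=max(int(0.2 * n), 1), replace=False)
            for i in fail:
                fts[i] = "q10"
        elif r < cfg.uncertain_fraction + cfg.low_depth_fraction:
            fail = rng.choice(n, size=max(int(0.2 * n), 1), replace=False)
            depths[fail] = 5
        elif r < cfg.uncertain_fraction + cfg.low_depth_fraction + cfg.low_complexity_fraction:
            lc_planned.append(len(variants))

        rare = rng.random() < cfg.rare_fraction
        if rare:
            n_carriers = 1 + int(rng.random() < 0.2)
            carrier_idx = rng.choice(n, size=n_carriers, replace=False)
            gts = _carrier_genotypes(region.chrom, carrier_idx, samples)
            known = rng.random() < cfg.known_maf_fraction
            af = float(rng.uniform(1e-6, 1e-4)) if known else None
        else:
            f = float(np.clip(rng.beta(*cfg.maf_beta), 5e-4, 0.5))
            gts = _hwe_genotypes(region.chrom, f, samples, rng)
            known = True
            af = f
        hu = int(
            np.isin(gts[ctrl_idx], (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)).sum()
        )
        maf = MafRecord(af_dbsnp=af, af_evs=af, af_exac=af, hu_control_carriers=hu)
        variants.append(
            _SimVariant(
                chrom=region.chrom,
                pos=pos,
                ref="",
                alt="",
                gene=region.gene,
                transcript_id=region.transcript_id,
                consequence=consequence,
                impact=impact,
                gts=gts,
                depths=depths,
                fts=fts,
                maf=maf,
                in_maf_table=known or hu > 0,
            )
        )

    # ---------------- transcript QC flags ----------------
    flag_rows = []
    unflagged = [t for t in transcripts if t.transcript_id not in plant_txs]
    n_flagged = int(len(unflagged) * cfg.flagged_transcript_fraction)
    flagged = rng.choice(len(unflagged), size=n_flagged, replace=False) if n_flagged else []
    for j, ti in enumerate(sorted(int(x) for x in flagged)):
        flag = "pseudogene" if j % 2 == 0 else "refseq_error"
        flag_rows.append((unflagged[ti].transcript_id, flag))
    flags_df = pd.DataFrame(flag_rows, columns=["transcript_id", "flags"])

    # ---------------- reference flanks + alleles ----------------
    for vi in lc_planned:
        v = variants[vi]
        seq = seqs[v.chrom]
        seq[max(v.pos - 16, 0) : v.pos - 1] = 0  # poly-A 5' flank
        truth_rows.append(
            {
                "kind": "low_complexity",
                "gene": v.gene,
                "transcript_id": v.transcript_id,
                "chrom": v.chrom,
                "positions": str(v.pos),
                "sample_ids": "",
                "note": "poly-A 5' flank",
            }
        )
    base_order = "ACGT"
    for v in variants:
        ref_code = int(seqs[v.chrom][v.pos - 1])
        v.ref = base_order[ref_code]
        v.alt = base_order[(ref_code + 1 + int(rng.integers(3))) % 4]

    # ---------------- multiallelic records ----------------
    n_multi = int(rng.binomial(cfg.n_variants, cfg.multiallelic_fraction / (1 - cfg.multiallelic_fraction)))
    multi_records: list[_SimVariant] = []
    for _ in range(n_multi):
        pos = None
        while pos is None:
            region = regions[int(rng.integers(len(regions)))]
            pos = try_position(region)
        ref_code = int(seqs[region.chrom][pos - 1])
        ref = base_order[ref_code]
        alts = [base_order[(ref_code + 1) % 4], base_order[(ref_code + 2) % 4]]
        depths, fts = default_fields()
        multi_records.append(
            _SimVariant(
                chrom=region.chrom,
                pos=pos,
                ref=ref,
                alt=",".join(alts),
                gene=region.gene,
                transcript_id=region.transcript_id,
                consequence="missense_variant",
                impact=Impact.MODERATE,
                gts=np.full(n, Genotype.HOM_REF, dtype=np.int8),
                depths=depths,
                fts=fts,
                multiallelic=True,
            )
        )

    # ---------------- write the bundle ----------------
    paths = {
        "vcf": outdir / "cohort.vcf",
        "bed": outdir / "regions.bed",
        "transcripts": outdir / "transcripts.tsv",
        "flags": outdir / "transcript_flags.tsv",
        "maf": outdir / "maf_table.tsv",
        "reference": outdir / "reference.fa",
        "coverage": outdir / "coverage.tsv",
        "read_totals": outdir / "read_totals.tsv",
        "str_table": outdir / "str_table.tsv",
        "viral": outdir / "viral_hits.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }

    pd.DataFrame(
        [(s.sample_id, s.cohort.value, s.sex.value) for s in samples],
        columns=["sample_id", "cohort", "sex"],
    ).to_csv(paths["samples"], sep="\t", index=False)

    write_bed_regions(regions, paths["bed"])
    write_transcript_table(transcripts, paths["transcripts"])
    flags_df.to_csv(paths["flags"], sep="\t", index=False)

    maf_records = {
        (v.chrom, v.pos, v.ref, v.alt): v.maf
        for v in variants
        if v.in_maf_table and v.maf is not None
    }
    MafTable(maf_records).to_tsv(paths["maf"])

    _write_fasta(seqs, paths["reference"])
    all_records = sorted(
        variants + multi_records, key=lambda v: (_chrom_rank(v.chrom), v.pos)
    )
    _write_vcf(all_records, samples, chrom_lengths, paths["vcf"])

    _write_coverage(cfg, samples, rng, cnv_plants, case_idx, regions, paths)
    _write_str(cfg, samples, rng, str_plants, case_idx, paths)
    _write_viral(cfg, samples, rng, viral_plants, paths)

    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "gene", "transcript_id", "chrom", "positions", "sample_ids", "note"],
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)

    return SimulatedBundle(
        directory=outdir,
        paths=paths,
        samples=samples,
        truth=truth,
        n_regions=len(regions),
        n_vcf_records=len(all_records),
    )


def _chrom_rank(chrom: str) -> int:
    order = [str(i) for i in range(1, 23)] + ["X", "Y"]
    return order.index(chrom) if chrom in order else len(order)


def _write_fasta(seqs: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs, key=_chrom_rank):
            fh.write(f">{chrom}\n")
            text = BASES[seqs[chrom]].tobytes().decode()
            for i in range(0, len(text), 60):
                fh.write(text[i : i + 60] + "\n")


def _gt_string(v: _SimVariant, i: int, sample: Sample) -> str:
    code = int(v.gts[i])
    haploid = _is_male_x(v.chrom, sample)
    if code == Genotype.MISSING:
        return "." if haploid else "./."
    if haploid:
        return "1" if code == Genotype.HEMI_ALT else "0"
    if code == Genotype.HOM_REF:
        return "0/0"
    if code == Genotype.HOM_ALT:
        return "1/1"
    phase = v.phase.get(i)
    if phase is not None:
        _, hap = phase
        return "1|0" if hap == 0 else "0|1"
    return "0/1"


def _write_vcf(
    records: Sequence[_SimVariant],
    samples: Sequence[Sample],
    chrom_lengths: dict[str, int],
    path: Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(chrom_lengths, key=_chrom_rank):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | "
            "Feature_ID | Transcript_BioType | Rank'\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample filter">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s.sample_id for s in samples)
            + "\n"
        )
        for v in records:
            first_alt = v.alt.split(",")[0]
            ann = f"{first_alt}|{v.consequence}|{v.impact.name}|{v.gene}|{v.gene}|transcript|{v.transcript_id}|protein_coding|1"
            cols = [
                v.chrom,
                str(v.pos),
                ".",
                v.ref,
                v.alt,
                "100",
                "PASS",
                f"ANN={ann}",
                "GT:DP:FT:PS",
            ]
            for i, s in enumerate(samples):
                ps = v.phase.get(i)
                cols.append(
                    f"{_gt_string(v, i, s)}:{int(v.depths[i])}:{v.fts[i]}:{ps[0] if ps else '.'}"
                )
            fh.write("\t".join(cols) + "\n")


def _write_coverage(cfg, samples, rng, cnv_plants, case_idx, regions, paths) -> None:
    n = len(samples)
    n_rows = min(cfg.n_cov_regions, len(regions))
    region_means = rng.uniform(30.0, 80.0, size=n_rows)
    totals = rng.uniform(0.8, 1.2, size=n) * 1e8
    noise = np.abs(rng.normal(1.0, 0.17, size=(n_rows, n)))
    raw = region_means[:, None] * (totals[None, :] / np.median(totals)) * noise
    for plant, rows in cnv_plants:
        for row in rows:
            raw[row, case_idx] *= plant.magnitude
    cov = pd.DataFrame(raw, columns=[s.sample_id for s in samples])
    cov.insert(0, "region", [f"{r.chrom}:{r.start}-{r.end}" for r in regions[:n_rows]])
    cov.to_csv(paths["coverage"], sep="\t", index=False, float_format="%.4f")
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples], "total_mapped_reads": totals.astype(np.int64)}
    ).to_csv(paths["read_totals"], sep="\t", index=False)


def _write_str(cfg, samples, rng, str_plants, case_idx, paths) -> None:
    n = len(samples)
    base = rng.integers(5, 30, size=cfg.n_str_loci)
    counts = base[:, None] + np.round(rng.normal(0.0, 1.07, size=(cfg.n_str_loci, n)))
    counts = np.clip(counts, 1, None)
    missing = rng.random(size=counts.shape) < 0.05
    for plant, loci in str_plants:
        for locus in loci:
            counts[locus, case_idx] += plant.magnitude
            missing[locus, :] = False
    counts[missing] = np.nan
    df = pd.DataFrame(counts, columns=[s.sample_id for s in samples])
    df.insert(0, "unit", [["AC", "AG", "AT", "CAG"][int(i % 4)] for i in range(cfg.n_str_loci)])
    df.insert(0, "locus", [f"STR{i:03d}" for i in range(cfg.n_str_loci)])
    df.to_csv(paths["str_table"], sep="\t", index=False)


def _write_viral(cfg, samples, rng, viral_plants, paths) -> None:
    rows = []
    read_no = 0
    # sub-threshold background alignments spread over the whole cohort
    for s in samples:
        for _ in range(int(rng.integers(0, 3))):
            read_no += 1
            short = rng.random() < 0.5
            rows.append(
                (
                    f"read{read_no:05d}",
                    s.sample_id,
                    "NC_001664.4",  # HHV6A
                    int(rng.integers(40, 90)) if short else int(rng.integers(95, 150)),
                    float(rng.uniform(96, 99)) if short else float(rng.uniform(80, 94)),
                )
            )
    for plant, carriers in viral_plants:
        for ci in carriers:
            for _ in range(3):
                read_no += 1
                rows.append(
                    (
                        f"read{read_no:05d}",
                        samples[ci].sample_id,
                        "NC_000898.1",  # HHV6B
                        int(rng.integers(100, 150)),
                        float(rng.uniform(96.5, 99.5)),
                    )
                )
    pd.DataFrame(
        rows, columns=["read_id", "sample_id", "virus_accession", "align_length", "identity"]
    ).to_csv(paths["viral"], sep="\t", index=False, float_format="%.2f")


def simulate_null_burden(
    n_variants: int, n_regions: int, seed: int = 0
) -> np.ndarray:
    """Uniform multinomial variant-to-region assignment (no clustering).

    Returns the per-region occupancy counts; the generative counterpart of
    the Monte Carlo occupancy null.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    if n_variants == 0:
        return np.zeros(n_regions, dtype=np.int64)
    draws = rng.integers(0, n_regions, size=n_variants)
    return np.bincount(draws, minlength=n_regions)
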