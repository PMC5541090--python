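"""Pipeline orchestration: qc -> rarity -> burden -> screens -> aux scans.

A :class:`PipelineConfig` points at a bundle directory (the layout written
by :func:`rarescreen.synthetic_cohort.simulate_cohort`, or real data laid
out the same way) and an output directory.  Every stage is a pure function
of (inputs, config, seed); every output table carries the configuration
hash in a leading comment line, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import aux_signals, inheritance_screens, region_burden
from .cohort_io import (
    Cohort,
    FilterLedger,
    MafTable,
    Sample,
    Sex,
    read_bed_regions,
    read_cohort_vcf,
    read_transcript_table,
    write_candidate_table,
)
from .qc_filters import FastaReference, QcConfig, apply_qc_cascade
from .rarity import RarityConfig, is_rare

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_samples_table"]


@dataclass
class BurdenConfig:
    k: int = 4
    reps: int = 2000
    flank: int = 8
    upstream_len: int = 1000


@dataclass
class ScreenConfig:
    min_samples: int = 2
    read_length: int = 100


@dataclass
class AuxConfig:
    family_alpha: float = 0.05
    min_avg_coverage: float = 20.0
    viral_min_len: int = 90
    viral_min_ident: float = 95.0
    power: float = 0.95
    cnv_effect: float = 0.5
    cnv_sd: float = 0.17


@dataclass
class PipelineConfig:
    bundle_dir: Path
    outdir: Path
    seed: int = 0
    qc: QcConfig = field(default_factory=QcConfig)
    rarity: RarityConfig = field(default_factory=RarityConfig)
    burden: BurdenConfig = field(default_factory=BurdenConfig)
    screens: ScreenConfig = field(default_factory=ScreenConfig)
    aux: AuxConfig = field(default_factory=AuxConfig)
    log_level: str = "INFO"

    REQUIRED_INPUTS = (
        "cohort.vcf",
        "regions.bed",
        "transcripts.tsv",
        "maf_table.tsv",
        "samples.tsv",
    )

    def __post_init__(self) -> None:
        self.bundle_dir = Path(self.bundle_dir)
        self.outdir = Path(self.outdir)

    def validate(self) -> None:
        missing = [
            name
            for name in self.REQUIRED_INPUTS
            if not (self.bundle_dir / name).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"bundle {self.bundle_dir} is missing required inputs: {missing}"
            )

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "qc": asdict(self.qc),
            "rarity": asdict(self.rarity),
            "burden": asdict(self.burden),
            "screens": asdict(self.screens),
            "aux": asdict(self.aux),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)

        def section(name: str) -> dict:
            return dict(parser[name]) if parser.has_section(name) else {}

        def build(factory, values: dict):
            fields = factory().__dataclass_fields__
            kwargs = {}
            for key, raw in values.items():
                if key not in fields:
                    raise KeyError(f"unknown option {key!r} for [{factory.__name__}]")
                typ = type(getattr(factory(), key))
                kwargs[key] = typ(raw) if typ is not bool else raw.lower() in ("1", "true", "yes")
            return factory(**kwargs)

        paths = section("paths")
        return cls(
            bundle_dir=Path(paths["bundle_dir"]),
            outdir=Path(paths["outdir"]),
            seed=int(paths.get("seed", 0)),
            qc=build(QcConfig, section("qc")),
            rarity=build(RarityConfig, section("rarity")),
            burden=build(BurdenConfig, section("burden")),
            screens=build(ScreenConfig, section("screens")),
            aux=build(AuxConfig, section("aux")),
        )


def read_samples_table(path: str | Path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t")
    return [
        Sample(str(r.sample_id), Cohort(r.cohort), Sex(r.sex))
        for r in df.itertuples(index=False)
    ]


def _write_with_hash(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages over a bundle; returns the output paths.

    Stage failures abort with the stage name in the exception message.
    """
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    b = cfg.bundle_dir
    out: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage: %s", name)

    try:
        stage("load")
        samples = read_samples_table(b / "samples.tsv")
        transcripts = read_transcript_table(b / "transcripts.tsv")
        regions = read_bed_regions(b / "regions.bed")
        mafs = MafTable.from_tsv(b / "maf_table.tsv")
        flags: dict[str, set[str]] = {}
        flags_path = b / "transcript_flags.tsv"
        if flags_path.exists():
            fdf = pd.read_csv(flags_path, sep="\t")
            for r in fdf.itertuples(index=False):
                flags.setdefault(str(r.transcript_id), set()).update(str(r.flags).split(","))
        reference = None
        if (b / "reference.fa").exists():
            reference = FastaReference(b / "reference.fa")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load' failed: {exc}") from exc

    try:
        stage("qc")
        variants, ledger = read_cohort_vcf(b / "cohort.vcf", samples)
        survivors, qc_ledger = apply_qc_cascade(variants, samples, cfg.qc, flags, reference)
        full = FilterLedger(input_count=ledger.input_count, exclusions=list(ledger.exclusions) + list(qc_ledger.exclusions))
        full.validate()
        out["ledger"] = cfg.outdir / "ledger.tsv"
        _write_with_hash(full.to_frame(), out["ledger"], cfg_hash, cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'qc' failed: {exc}") from exc

    try:
        stage("burden")
        case_idx = {i for i, s in enumerate(samples) if s.cohort == Cohort.CASE}
        rare_case, rare_control = [], []
        for v in survivors:
            if not is_rare(v, mafs, cfg.rarity, "dominant"):
                continue
            carriers = set(v.carrier_indices().tolist())
            if not carriers:
                continue
            if carriers <= case_idx:
                rare_case.append(v)
            else:
                rare_control.append(v)
        records = region_burden.count_region_burden(rare_case, rare_control, regions, samples)
        ranked = region_burden.rank_candidate_regions(records, cfg.burden.k)
        out["burden"] = cfg.outdir / "burden_candidates.tsv"
        _write_with_hash(region_burden.burden_table(ranked), out["burden"], cfg_hash, cfg.seed)

        calib = region_burden.mc_null_max_burden(
            n_variants=max(len(rare_case), 1),
            n_regions=len(regions),
            k=cfg.burden.k,
            reps=cfg.burden.reps,
            seed=cfg.seed,
        )
        out["calibration"] = cfg.outdir / "calibration.json"
        with open(out["calibration"], "w") as fh:
            json.dump(
                {"config_hash": cfg_hash, **asdict(calib)}, fh, indent=2, sort_keys=True
            )
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'burden' failed: {exc}") from exc

    try:
        stage("screens")
        kept, _ = inheritance_screens.exclude_bogus_transcripts(transcripts)
        n_controls = sum(1 for s in samples if s.cohort == Cohort.CONTROL)
        kept_dom = inheritance_screens.exclude_common_hi_transcripts(
            kept, survivors, mafs, cfg.rarity.dominant_maf_max, n_controls
        )
        kept_rec = inheritance_screens.exclude_common_hi_transcripts(
            kept, survivors, mafs, cfg.rarity.recessive_maf_max, n_controls
        )
        dom_ids = {t.transcript_id for t in kept_dom}
        rec_ids = {t.transcript_id for t in kept_rec}

        dom = inheritance_screens.dominant_hi_screen(survivors, samples, mafs, cfg.rarity, dom_ids)
        multi = inheritance_screens.dominant_multi_sample_screen(
            survivors, samples, mafs, cfg.rarity, cfg.screens.min_samples, dom_ids
        )
        rec = inheritance_screens.recessive_screen(
            survivors, samples, mafs, cfg.rarity, rec_ids, cfg.screens.read_length
        )
        for name, calls in (("dominant_hi", dom), ("dominant_multi", multi), ("recessive", rec)):
            out[name] = cfg.outdir / f"candidates_{name}.tsv"
            write_candidate_table(calls, out[name])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'screens' failed: {exc}") from exc

    try:
        stage("aux")
        aux_summary = {}
        cov_path = b / "coverage.tsv"
        if cov_path.exists():
            cov = pd.read_csv(cov_path, sep="\t")
            totals = pd.read_csv(b / "read_totals.tsv", sep="\t")
            values = cov[[s.sample_id for s in samples]].to_numpy(float)
            scale = totals.set_index("sample_id").loc[[s.sample_id for s in samples], "total_mapped_reads"].to_numpy(float)
            import numpy as np

            norm = values * (np.median(scale) / scale)[None, :]
            scan = aux_signals.groupwise_wilcoxon_scan(norm, samples, cfg.aux.family_alpha)
            cnv_df = pd.DataFrame(
                {"region": cov["region"], "pvalue": scan.pvalues, "significant": False}
            )
            cnv_df.loc[cnv_df.index[scan.significant], "significant"] = True
            out["cnv"] = cfg.outdir / "cnv_scan.tsv"
            _write_with_hash(cnv_df, out["cnv"], cfg_hash, cfg.seed)
            power = aux_signals.wmw_power_n(
                aux_signals.PowerSpec(
                    alpha=scan.per_test_alpha,
                    power=cfg.aux.power,
                    effect=cfg.aux.cnv_effect,
                    sd=cfg.aux.cnv_sd,
                )
            )
            aux_summary["cnv"] = {
                "n_regions": int(scan.n_tests),
                "per_test_alpha": scan.per_test_alpha,
                "n_significant": int(len(scan.significant)),
                "power_n_per_group": power.n_per_group,
                "power_method": power.metadata["method"],
            }
        str_path = b / "str_table.tsv"
        if str_path.exists():
            str_df = pd.read_csv(str_path, sep="\t")
            str_scan, str_frame = aux_signals.str_compare(str_df, samples, cfg.aux.family_alpha)
            out["str"] = cfg.outdir / "str_scan.tsv"
            _write_with_hash(str_frame, out["str"], cfg_hash, cfg.seed)
            aux_summary["str"] = {
                "n_loci_tested": int(str_scan.n_tests),
                "n_skipped": len(str_scan.skipped),
                "n_significant": int(len(str_scan.significant)),
            }
        viral_path = b / "viral_hits.tsv"
        if viral_path.exists():
            hits = aux_signals.read_viral_hits(viral_path)
            kept_hits, viral_summary = aux_signals.filter_viral_hits(
                hits, samples, cfg.aux.viral_min_len, cfg.aux.viral_min_ident
            )
            out["viral"] = cfg.outdir / "viral_summary.tsv"
            _write_with_hash(viral_summary, out["viral"], cfg_hash, cfg.seed)
            aux_summary["viral"] = {
                "n_hits_kept": len(kept_hits),
                "n_viruses": int(viral_summary["virus"].nunique()) if len(viral_summary) else 0,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'aux' failed: {exc}") from exc

    try:
        stage("report")
        summary_lines = [
            f"config_hash\t{cfg_hash}",
            f"seed\t{cfg.seed}",
            f"n_samples\t{len(samples)}",
            f"n_vcf_records\t{full.input_count}",
            f"n_qc_survivors\t{full.surviving_count}",
            f"n_rare_case_variants\t{len(rare_case)}",
            f"n_regions\t{len(regions)}",
            f"n_burden_candidates\t{len(ranked)}",
            f"mc_null_p_hat\t{calib.p_hat:.6f}",
            f"mc_null_analytic_p\t{calib.analytic_p:.6f}",
            f"n_dominant_hi\t{len(dom)}",
            f"n_dominant_multi\t{len(multi)}",
            f"n_recessive\t{len(rec)}",
        ]
        for key, stats_ in aux_summary.items():
            for stat, val in stats_.items():
                summary_lines.append(f"{key}_{stat}\t{val}")
        out["summary"] = cfg.outdir / "summary.txt"
        out["summary"].write_text("\n".join(summary_lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'report' failed: {exc}") from exc

    return out
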