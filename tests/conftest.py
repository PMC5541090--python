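"""Shared fixtures: a session-scoped synthetic bundle and small builders."""

from __future__ import annotations

import numpy as np
import pytest

from rarescreen.cohort_io import Cohort, CohortVariant, Impact, Sample, Sex
from rarescreen.pipeline import read_samples_table
from rarescreen.cohort_io import read_cohort_vcf
from rarescreen.synthetic_cohort import SimConfig, default_plants, simulate_cohort

DEFAULT_SEED = 20170802


def make_samples(n_case: int = 3, n_control: int = 2, male_cases: int = 2, male_controls: int = 1):
    samples = []
    for i in range(n_case):
        sex = Sex.MALE if i < male_cases else Sex.FEMALE
        samples.append(Sample(f"CASE{i + 1:02d}", Cohort.CASE, sex))
    for i in range(n_control):
        sex = Sex.MALE if i < male_controls else Sex.FEMALE
        samples.append(Sample(f"CTRL{i + 1:02d}", Cohort.CONTROL, sex))
    return samples


def make_variant(
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    gene="GENE1",
    transcript="TX1",
    consequence="missense_variant",
    impact=Impact.MODERATE,
    genotypes=(0, 0, 0, 0, 0),
    depths=None,
    pass_flags=None,
    phase=None,
):
    gts = np.asarray(genotypes, dtype=np.int8)
    n = len(gts)
    return CohortVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        transcript_id=transcript,
        consequence=consequence,
        impact=impact,
        genotypes=gts,
        depths=np.asarray(depths if depths is not None else [60] * n, dtype=np.int32),
        pass_flags=np.asarray(pass_flags if pass_flags is not None else [True] * n, dtype=bool),
        phase=dict(phase or {}),
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default-scale synthetic cohort with one plant of every kind."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=DEFAULT_SEED, planted=default_plants())
    return simulate_cohort(cfg, outdir)


@pytest.fixture(scope="session")
def bundle_samples(bundle):
    return read_samples_table(bundle.paths["samples"])


@pytest.fixture(scope="session")
def bundle_variants(bundle, bundle_samples):
    variants, ledger = read_cohort_vcf(bundle.paths["vcf"], bundle_samples)
    return variants, ledger


@pytest.fixture(scope="session")
def screens(bundle, bundle_samples, bundle_variants):
    """QC + dominant/recessive screen results over the session bundle.

    The HWE alpha is set to 1e-4: with 21 diploid controls the most extreme
    heterozygote-excess table has exact p ~ 3.9e-6, so a stricter alpha can
    never flag excess at this cohort size.
    """
    import pandas as pd

    from rarescreen.cohort_io import MafTable
    from rarescreen.inheritance_screens import dominant_hi_screen, recessive_screen
    from rarescreen.qc_filters import FastaReference, QcConfig, apply_qc_cascade
    from rarescreen.rarity import RarityConfig

    variants, _ = bundle_variants
    mafs = MafTable.from_tsv(bundle.paths["maf"])
    flags = {}
    fdf = pd.read_csv(bundle.paths["flags"], sep="\t")
    for r in fdf.itertuples(index=False):
        flags.setdefault(str(r.transcript_id), set()).update(str(r.flags).split(","))
    reference = FastaReference(bundle.paths["reference"])
    survivors, ledger = apply_qc_cascade(
        variants, bundle_samples, QcConfig(hwe_alpha=1e-4), flags, reference
    )
    cfg = RarityConfig()
    dom = dominant_hi_screen(survivors, bundle_samples, mafs, cfg)
    rec = recessive_screen(survivors, bundle_samples, mafs, cfg)
    return dict(survivors=survivors, ledger=ledger, dom=dom, rec=rec, mafs=mafs)
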