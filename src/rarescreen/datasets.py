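"""Packaged worked-example candidate tables.

Small curated tables from a published 23-case / 21-control whole-exome
screen, used in documentation and tests to exercise the reporting and
ranking paths on realistic output shapes:

* ``load_burden_regions`` — sub-gene regions where at least four case
  samples accumulated rare variants (region-burden candidates);
* ``load_dominant_hi`` — heterozygous high-impact candidate variants found
  exclusively in case samples;
* ``load_dominant_multi`` — genes with rare damaging variants in two or
  more case samples, with per-gene case counts;
* ``load_hemizygous`` — X-linked hemizygous moderate-impact candidate
  variants in male case samples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort_io import GenomicRegion, parse_region_class
from .region_burden import BurdenRecord

__all__ = [
    "load_burden_regions",
    "load_dominant_hi",
    "load_dominant_multi",
    "load_hemizygous",
    "burden_records_from_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("rarescreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_burden_regions() -> pd.DataFrame:
    return _read("burden_regions.tsv")


def load_dominant_hi() -> pd.DataFrame:
    return _read("dominant_hi.tsv")


def load_dominant_multi() -> pd.DataFrame:
    return _read("dominant_multi.tsv")


def load_hemizygous() -> pd.DataFrame:
    return _read("hemizygous.tsv")


def burden_records_from_table(df: pd.DataFrame) -> list[BurdenRecord]:
    """Rebuild :class:`BurdenRecord` objects from a burden-region table.

    Coordinates in the table are 1-based inclusive (report convention) and
    are converted to the internal 0-based half-open form.  Control sample
    counts are zero by construction: the table lists case-exclusive
    candidates.
    """
    records = []
    for row in df.itertuples(index=False):
        ids = frozenset(str(row.sample_ids).split(","))
        records.append(
            BurdenRecord(
                region=GenomicRegion(
                    chrom=str(row.chrom),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    region_class=parse_region_class(str(row.region)),
                    gene=str(row.gene),
                    transcript_id=str(row.gene),
                ),
                case_sample_count=int(row.sample_count),
                control_sample_count=0,
                variant_count=int(row.n_variants),
                case_sample_ids=ids,
            )
        )
    return records
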