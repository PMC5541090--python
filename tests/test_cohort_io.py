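"""Readers/writers and the core cohort data model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarescreen import datasets
from rarescreen.cohort_io import (
    CandidateCall,
    FilterLedger,
    GenomicRegion,
    Genotype,
    Impact,
    MafRecord,
    MafTable,
    RegionClass,
    Transcript,
    candidate_calls_from_table,
    read_bed_regions,
    read_candidate_table,
    read_cohort_vcf,
    read_transcript_table,
    write_candidate_table,
    write_transcript_table,
)
from conftest import make_samples, make_variant

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=FT,Number=1,Type=String,Description="Filter">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}
"""


def write_vcf(path, rows, samples):
    names = "\t".join(s.sample_id for s in samples)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(names=names))
        for row in rows:
            fh.write(row + "\n")


def vcf_row(pos, alt="T", ann="T|missense_variant|MODERATE|G1|G1|transcript|TX1|protein_coding|1", gts=("0/0", "0/1", "0/0", "0/0", "0/0")):
    cols = ["1", str(pos), ".", "A", alt, "99", "PASS", f"ANN={ann}", "GT:DP:FT:PS"]
    cols += [f"{g}:50:PASS:." for g in gts]
    return "\t".join(cols)


class TestReadCohortVcf:
    def test_multiallelic_records_are_excluded_and_counted(self, tmp_path):
        samples = make_samples(3, 2)
        rows = [vcf_row(100 + i) for i in range(8)]
        rows.insert(3, vcf_row(550, alt="T,G"))
        rows.append(vcf_row(990, alt="C,G"))
        path = tmp_path / "c.vcf"
        write_vcf(path, rows, samples)
        variants, ledger = read_cohort_vcf(path, samples)
        assert len(variants) == 8
        assert ledger.input_count == 10
        assert ledger.exclusions == [("multiallelic", 2)]
        assert ledger.surviving_count == 8
        assert variants[0].pos == 100  # 1-based preserved

    def test_empty_vcf(self, tmp_path):
        samples = make_samples(3, 2)
        path = tmp_path / "e.vcf"
        write_vcf(path, [], samples)
        variants, ledger = read_cohort_vcf(path, samples)
        assert variants == []
        assert (ledger.input_count, ledger.surviving_count) == (0, 0)

    def test_missing_annotation_is_hard_error(self, tmp_path):
        samples = make_samples(3, 2)
        path = tmp_path / "m.vcf"
        row = "1\t100\t.\tA\tT\t99\tPASS\t.\tGT:DP:FT:PS" + "\t0/0:50:PASS:." * 5
        write_vcf(path, [row], samples)
        with pytest.raises(ValueError, match="1:100"):
            read_cohort_vcf(path, samples)

    def test_sample_mismatch_is_hard_error(self, tmp_path):
        samples = make_samples(3, 2)
        path = tmp_path / "s.vcf"
        write_vcf(path, [vcf_row(100)], samples)
        with pytest.raises(ValueError, match="sample columns"):
            read_cohort_vcf(path, make_samples(2, 2))

    def test_genotype_codes_and_phase(self, tmp_path):
        samples = make_samples(3, 2)
        row = vcf_row(200, gts=("0/0", "1|0", "1/1", "./.", "0|1"))
        row = row.replace("1|0:50:PASS:.", "1|0:50:PASS:200").replace("0|1:50:PASS:.", "0|1:50:PASS:200")
        path = tmp_path / "g.vcf"
        write_vcf(path, [row], samples)
        (v,), _ = read_cohort_vcf(path, samples)
        assert list(v.genotypes) == [
            Genotype.HOM_REF,
            Genotype.HET,
            Genotype.HOM_ALT,
            Genotype.MISSING,
            Genotype.HET,
        ]
        assert v.phase[1] == ("200", 0)  # alt on haplotype 0
        assert v.phase[4] == ("200", 1)


class TestBedRegions:
    def test_single_region(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t200\texon|GENE1|TX1\n")
        (region,) = read_bed_regions(p)
        assert region.length == 100
        assert region.region_class is RegionClass.EXONIC
        assert (region.gene, region.transcript_id) == ("GENE1", "TX1")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert read_bed_regions(p) == []

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\t200\t100\texon|G|T", "start >= end"),
            ("chr1\t100\t200\tweird|G|T", "unknown region class"),
            ("chr1\t100\t200", "BED3"),
        ],
    )
    def test_malformed_lines(self, tmp_path, line, match):
        p = tmp_path / "b.bed"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=match):
            read_bed_regions(p)

    def test_worked_example_region_classes(self):
        df = datasets.load_burden_regions()
        assert len(df) == 21
        classes = set(df["region"])
        assert classes == {"UPSTREAM", "SPLICE", "3' UTR", "INTRON", "EXONIC"}


class TestCandidateTable:
    def test_empty_list_gives_header_only(self, tmp_path):
        p = tmp_path / "c.tsv"
        write_candidate_table([], p)
        assert p.read_text().strip() == "gene\tchrom\tpos\tref\talt\tconsequence\tmodel\tsample_ids"

    def test_single_candidate_two_lines(self, tmp_path):
        v = make_variant(genotypes=(1, 0, 0, 0, 0))
        call = CandidateCall("GENE1", "TX1", "dominant_HI", [v], ["CASE01"], "missense_variant")
        p = tmp_path / "c.tsv"
        write_candidate_table([call], p)
        assert len(p.read_text().strip().splitlines()) == 2

    def test_round_trip_reproduces_calls(self, tmp_path):
        v1 = make_variant(pos=100, genotypes=(1, 0, 0, 0, 0))
        v2 = make_variant(pos=140, genotypes=(1, 0, 0, 0, 0))
        calls = [
            CandidateCall("GENE1", "TX1", "compound_het", [v1, v2], ["CASE01"], "missense_variant"),
            CandidateCall("GENE2", "TX2", "dominant_HI", [make_variant(gene="GENE2", pos=999, genotypes=(1, 1, 0, 0, 0))], ["CASE01", "CASE02"], "stop_gained"),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_candidate_table(calls, p1)
        rebuilt = candidate_calls_from_table(read_candidate_table(p1))
        assert {(c.gene, c.model, tuple(c.sample_ids), len(c.variants)) for c in rebuilt} == {
            ("GENE1", "compound_het", ("CASE01",), 2),
            ("GENE2", "dominant_HI", ("CASE01", "CASE02"), 1),
        }
        write_candidate_table(rebuilt, p2)
        assert sorted(p1.read_text().splitlines()) == sorted(p2.read_text().splitlines())

    def test_worked_example_table_reserializes(self, tmp_path):
        df = datasets.load_dominant_hi()
        calls = candidate_calls_from_table(df, model="dominant_HI")
        p = tmp_path / "t2.tsv"
        write_candidate_table(calls, p)
        assert len(read_candidate_table(p)) == 61


class TestLedger:
    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=0, max_size=8),
        st.integers(min_value=0, max_value=5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_invariant(self, counts, extra_survivors):
        ledger = FilterLedger(input_count=sum(counts) + extra_survivors)
        for i, c in enumerate(counts):
            ledger.add(f"f{i}", c)
        ledger.validate()
        assert ledger.input_count == ledger.surviving_count + ledger.excluded_total

    def test_over_exclusion_rejected(self):
        ledger = FilterLedger(input_count=5)
        ledger.add("a", 6)
        with pytest.raises(ValueError):
            ledger.validate()


class TestTranscripts:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            Transcript("TX", "G", "1", "+", [(0, 100), (50, 150)])

    def test_missing_cds_marks_incomplete(self):
        t = Transcript("TX", "G", "1", "+", [(0, 100)])
        assert "incomplete" in t.flags and t.is_bogus

    def test_table_round_trip(self, tmp_path):
        t = Transcript("TX1", "G1", "2", "-", [(100, 300), (500, 800)], 150, 700, frozenset({"no_start_codon"}))
        p = tmp_path / "t.tsv"
        write_transcript_table([t], p)
        (back,) = read_transcript_table(p)
        assert back == t


class TestMafTable:
    def test_round_trip_and_lookup(self, tmp_path):
        rec = MafRecord(af_dbsnp=0.01, af_exac=None, af_evs=0.002, hu_control_carriers=3)
        table = MafTable({("1", 100, "A", "T"): rec})
        p = tmp_path / "maf.tsv"
        table.to_tsv(p)
        back = MafTable.from_tsv(p)
        got = back.get(("1", 100, "A", "T"))
        assert got == rec
        assert got.max_known_af == 0.01

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError):
            MafTable({("1", 1, "A", "T"): MafRecord(af_dbsnp=1.5)})


def test_variant_validation():
    with pytest.raises(ValueError, match="ref == alt"):
        make_variant(ref="A", alt="A")
    v = make_variant(genotypes=(1, 2, 3, 0, -1))
    assert list(v.carrier_indices()) == [0, 1, 2]


def test_region_validation():
    with pytest.raises(ValueError):
        GenomicRegion("1", 100, 100, RegionClass.EXONIC, "G", "T")
    r = GenomicRegion("1", 100, 200, RegionClass.EXONIC, "G", "T")
    assert r.contains(101) and r.contains(200) and not r.contains(100)
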