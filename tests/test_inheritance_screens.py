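"""Dominant/recessive loss-of-function screens and phase logic."""

from __future__ import annotations

import pytest

from rarescreen import datasets
from rarescreen.cohort_io import Impact, MafRecord, MafTable, Transcript
from rarescreen.inheritance_screens import (
    classify_consequence,
    dominant_hi_screen,
    dominant_multi_sample_screen,
    exclude_bogus_transcripts,
    exclude_common_hi_transcripts,
    phase_exclude_pair,
    recessive_screen,
)
from rarescreen.rarity import RarityConfig
from conftest import make_samples, make_variant


class TestConsequenceClassification:
    @pytest.mark.parametrize(
        "term, impact",
        [
            ("stop_gained", Impact.HIGH),
            ("stop-loss", Impact.HIGH),
            ("stop gain", Impact.HIGH),
            ("start-loss", Impact.HIGH),
            ("frameshift", Impact.HIGH),
            ("splice donor & intron", Impact.HIGH),
            ("splice acceptor & splice region & intron & non-coding transcript exon", Impact.HIGH),
            ("frameshift & splice region", Impact.HIGH),
            ("missense variant", Impact.MODERATE),
            ("missense variant & splice region variant", Impact.MODERATE),
            ("synonymous_variant", Impact.LOW),
            ("intron_variant", Impact.MODIFIER),
            ("totally_new_term", Impact.MODIFIER),
        ],
    )
    def test_term_mapping_takes_worst_class(self, term, impact):
        assert classify_consequence(term) is impact

    def test_worked_example_tables_are_all_damaging(self):
        hi = datasets.load_dominant_hi()
        assert all(classify_consequence(c) is Impact.HIGH for c in hi["consequence"])
        hemi = datasets.load_hemizygous()
        assert all(classify_consequence(c) is Impact.MODERATE for c in hemi["consequence"])

    def test_printed_consequence_census(self):
        hi = datasets.load_dominant_hi()

        def bucket(term: str) -> str:
            t = term.replace("-", " ").replace("_", " ")
            if "frameshift" in t:
                return "frameshift"
            if "splice donor" in t or "splice acceptor" in t:
                return "splice"
            if "start loss" in t:
                return "start_loss"
            if "stop loss" in t:
                return "stop_loss"
            return "stop_gain"

        census = hi["consequence"].map(bucket).value_counts().to_dict()
        assert census == {
            "splice": 21,
            "frameshift": 19,
            "stop_gain": 13,
            "stop_loss": 5,
            "start_loss": 3,
        }


class TestTranscriptExclusions:
    def test_bogus_partition(self):
        clean = Transcript("TX1", "G", "1", "+", [(0, 100), (200, 300)], 10, 290)
        no_cds = Transcript("TX2", "G", "1", "+", [(0, 100)])
        flagged = Transcript("TX3", "G", "1", "+", [(0, 100)], 10, 90, frozenset({"multiple_stop"}))
        kept, excluded = exclude_bogus_transcripts([clean, no_cds, flagged])
        assert kept == [clean]
        assert len(excluded) == 2

    def test_common_hi_variant_drops_transcript_model_dependently(self):
        t = Transcript("TX1", "G", "1", "+", [(0, 2000)], 10, 1900)
        v = make_variant(pos=500, consequence="stop_gained", impact=Impact.HIGH)
        mafs = MafTable({v.key: MafRecord(af_exac=0.01)})
        cfg = RarityConfig()
        # 0.01 > 1/5000 -> dropped under the dominant bound
        assert exclude_common_hi_transcripts([t], [v], mafs, cfg.dominant_maf_max) == []
        # 0.01 < 1/71 -> kept under the recessive bound
        assert exclude_common_hi_transcripts([t], [v], mafs, cfg.recessive_maf_max) == [t]

    def test_no_public_hi_variants_keeps_transcript(self):
        t = Transcript("TX1", "G", "1", "+", [(0, 2000)], 10, 1900)
        v = make_variant(pos=500, consequence="missense_variant", impact=Impact.MODERATE)
        mafs = MafTable({v.key: MafRecord(af_exac=0.2)})
        assert exclude_common_hi_transcripts([t], [v], mafs, 1 / 5000) == [t]


class TestPhaseExclusion:
    def _pair(self, d, phase1, phase2):
        v1 = make_variant(pos=1000, genotypes=(1, 0, 0, 0, 0), phase={0: phase1} if phase1 else {})
        v2 = make_variant(pos=1000 + d, alt="G", genotypes=(1, 0, 0, 0, 0), phase={0: phase2} if phase2 else {})
        return v1, v2

    def test_cis_pair_within_read_range_is_excluded(self):
        v1, v2 = self._pair(40, ("ps1", 0), ("ps1", 0))
        assert phase_exclude_pair(v1, v2, 0) is True

    def test_trans_pair_is_kept(self):
        v1, v2 = self._pair(40, ("ps1", 0), ("ps1", 1))
        assert phase_exclude_pair(v1, v2, 0) is False

    def test_beyond_read_length_is_never_excluded(self):
        v1, v2 = self._pair(400, ("ps1", 0), ("ps1", 0))
        assert phase_exclude_pair(v1, v2, 0) is False

    def test_unphased_or_different_phase_sets_are_kept(self):
        v1, v2 = self._pair(40, ("ps1", 0), None)
        assert phase_exclude_pair(v1, v2, 0) is False
        v1, v2 = self._pair(40, ("ps1", 0), ("ps2", 0))
        assert phase_exclude_pair(v1, v2, 0) is False


class TestDominantScreens:
    def _setup(self):
        samples = make_samples(3, 2)
        cfg = RarityConfig()
        return samples, cfg

    def test_control_carrier_excludes_variant(self):
        samples, cfg = self._setup()
        case_only = make_variant(pos=100, consequence="stop_gained", impact=Impact.HIGH, genotypes=(1, 0, 0, 0, 0))
        shared = make_variant(pos=200, consequence="stop_gained", impact=Impact.HIGH, genotypes=(1, 0, 0, 1, 0))
        calls = dominant_hi_screen([case_only, shared], samples, MafTable(), cfg)
        assert [c.variants[0].pos for c in calls] == [100]
        assert calls[0].sample_ids == ["CASE01"]

    def test_moderate_impact_is_not_a_hi_call(self):
        samples, cfg = self._setup()
        v = make_variant(consequence="missense_variant", impact=Impact.MODERATE, genotypes=(1, 0, 0, 0, 0))
        assert dominant_hi_screen([v], samples, MafTable(), cfg) == []

    def test_multi_sample_requires_distinct_samples(self):
        samples, cfg = self._setup()
        same_sample = [
            make_variant(pos=100, genotypes=(1, 0, 0, 0, 0)),
            make_variant(pos=150, genotypes=(1, 0, 0, 0, 0)),
        ]
        assert dominant_multi_sample_screen(same_sample, samples, MafTable(), cfg, 2) == []
        two_samples = [
            make_variant(pos=100, genotypes=(1, 0, 0, 0, 0)),
            make_variant(pos=150, genotypes=(0, 1, 0, 0, 0)),
        ]
        (call,) = dominant_multi_sample_screen(two_samples, samples, MafTable(), cfg, 2)
        assert call.sample_ids == ["CASE01", "CASE02"]
        assert len(call.variants) == 2

    def test_worked_example_dominant_hi_counts(self):
        df = datasets.load_dominant_hi()
        assert len(df) == 61
        shared = df[df["sample_ids"].str.contains(",")]
        assert len(shared) == 1
        assert shared.iloc[0]["gene"] == "MRPL45"
        assert set(shared.iloc[0]["sample_ids"].split(",")) == {"BrA206", "Y426"}

    def test_worked_example_multi_sample_counts(self):
        df = datasets.load_dominant_multi()
        assert len(df) == 42
        top = set(df[df["sample_count"] == 4]["gene"])
        assert top == {"DOT1L", "TTC28"}
        assert (df["sample_count"] >= 5).sum() == 0  # min_samples=5 selects nothing
        assert (df["sample_count"] == 3).sum() == 5


class TestRecessiveScreen:
    def _samples(self):
        # CASE01/CASE02 male, CASE03 female, CTRL01 male, CTRL02 female
        return make_samples(3, 2)

    def test_trans_compound_het_is_called_cis_is_not(self):
        samples = self._samples()
        cfg = RarityConfig()

        def pair(hap2):
            v1 = make_variant(pos=1000, genotypes=(1, 0, 0, 0, 0), phase={0: ("ps", 0)})
            v2 = make_variant(pos=1040, alt="G", genotypes=(1, 0, 0, 0, 0), phase={0: ("ps", hap2)})
            return [v1, v2]

        trans_calls = recessive_screen(pair(1), samples, MafTable(), cfg)
        assert [c.model for c in trans_calls] == ["compound_het"]
        assert len(trans_calls[0].variants) == 2
        assert recessive_screen(pair(0), samples, MafTable(), cfg) == []

    def test_homozygous_and_hemizygous_calls(self):
        samples = self._samples()
        cfg = RarityConfig()
        hom = make_variant(pos=100, genotypes=(2, 0, 0, 0, 0))
        hemi = make_variant(chrom="X", pos=200, genotypes=(0, 3, 0, 0, 0))
        calls = recessive_screen([hom, hemi], samples, MafTable(), cfg)
        models = {c.model: c for c in calls}
        assert models["recessive_hom"].sample_ids == ["CASE01"]
        assert models["recessive_hemi"].sample_ids == ["CASE02"]

    def test_hemizygous_female_is_a_data_error(self):
        samples = self._samples()
        bad = make_variant(chrom="X", pos=100, genotypes=(0, 0, 3, 0, 0))  # CASE03 female
        with pytest.raises(ValueError, match="inconsistent"):
            recessive_screen([bad], samples, MafTable(), RarityConfig())

    def test_control_carried_variant_never_contributes(self):
        samples = self._samples()
        hom_shared = make_variant(pos=100, genotypes=(2, 0, 0, 1, 0))
        assert recessive_screen([hom_shared], samples, MafTable(), RarityConfig()) == []

    def test_worked_example_hemizygous_genes(self):
        df = datasets.load_hemizygous()
        assert len(df) == 20
        assert df["gene"].nunique() == 19
        rp2 = df[df["gene"] == "RP2"]
        assert set(rp2["sample_ids"]) == {"Y558", "Y591"}
        assert set(df["chrom"]) == {"X"}


def test_screens_are_idempotent_on_their_own_output(tmp_path, bundle, bundle_samples, bundle_variants):
    """Re-serializing screen output reproduces the table byte-for-byte."""
    from rarescreen.cohort_io import MafTable as MT, write_candidate_table, read_candidate_table, candidate_calls_from_table

    variants, _ = bundle_variants
    mafs = MT.from_tsv(bundle.paths["maf"])
    calls = dominant_hi_screen(variants, bundle_samples, mafs, RarityConfig())
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_candidate_table(calls, p1)
    write_candidate_table(candidate_calls_from_table(read_candidate_table(p1)), p2)
    assert sorted(p1.read_bytes().splitlines()) == sorted(p2.read_bytes().splitlines())
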