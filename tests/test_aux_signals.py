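"""Coverage/STR rank-sum scans, power analysis, and the viral-hit filter."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rarescreen.aux_signals import (
    CoverageMatrix,
    PowerSpec,
    ViralHit,
    bonferroni_alpha,
    filter_viral_hits,
    groupwise_wilcoxon_scan,
    normalize_coverage,
    refine_high_coverage_regions,
    str_compare,
    wmw_power_n,
)
from rarescreen.cohort_io import GenomicRegion, RegionClass
from conftest import make_samples


def region(start=0, end=100, chrom="1"):
    return GenomicRegion(chrom, start, end, RegionClass.EXONIC, "G", "T")


class TestBonferroni:
    def test_genome_scale_per_test_alpha(self):
        alpha = bonferroni_alpha(0.05, 286_754)
        assert f"{alpha:.2e}" == "1.74e-07"

    def test_exact_rational_division(self):
        assert bonferroni_alpha(0.05, 5) == 0.01
        assert bonferroni_alpha(1.0, 4) == 0.25

    def test_invalid_test_count(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestRefineHighCoverage:
    def test_flat_deep_region_kept_whole(self):
        out = refine_high_coverage_regions([(region(), np.full(100, 30.0))])
        assert [(r.start, r.end) for r in out] == [(0, 100)]

    def test_flat_shallow_region_dropped(self):
        assert refine_high_coverage_regions([(region(), np.full(100, 10.0))]) == []

    def test_mixed_region_trimmed_to_deep_half(self):
        depth = np.concatenate([np.full(50, 40.0), np.full(50, 5.0)])
        out = refine_high_coverage_regions([(region(), depth)])
        assert [(r.start, r.end) for r in out] == [(0, 50)]

    def test_profile_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            refine_high_coverage_regions([(region(), np.full(99, 30.0))])


class TestNormalizeCoverage:
    def _matrix(self, values):
        samples = make_samples(2, 2)
        regions = [region(i * 100, (i + 1) * 100) for i in range(values.shape[0])]
        return CoverageMatrix(regions, samples, values)

    def test_equal_totals_are_identity(self):
        m = self._matrix(np.arange(8, dtype=float).reshape(2, 4))
        out = normalize_coverage(m, [1e6] * 4)
        assert np.allclose(out.values, m.values)
        assert out.normalized

    def test_double_reads_halves_the_column(self):
        m = self._matrix(np.ones((3, 4)))
        out = normalize_coverage(m, [1e6, 1e6, 1e6, 2e6])
        assert np.allclose(out.values[:, :3], 1.0)
        assert np.allclose(out.values[:, 3], 0.5)

    def test_joint_rescale_invariance(self):
        # scaling one sample's raw coverage and read total together leaves
        # its normalized column unchanged (scale the largest total so the
        # median reference itself does not move)
        rng = np.random.default_rng(0)
        values = rng.uniform(10, 50, size=(5, 4))
        totals = rng.uniform(0.5e8, 1.5e8, size=4)
        j = int(np.argmax(totals))
        base = normalize_coverage(self._matrix(values), totals)
        values2 = values.copy()
        values2[:, j] *= 3.0
        totals2 = totals.copy()
        totals2[j] *= 3.0
        rescaled = normalize_coverage(self._matrix(values2), totals2)
        assert np.allclose(base.values[:, j], rescaled.values[:, j])

    def test_rank_order_within_columns_preserved(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 100, size=(20, 4))
        out = normalize_coverage(self._matrix(values), rng.uniform(1e7, 1e8, size=4))
        for j in range(4):
            assert np.array_equal(np.argsort(values[:, j]), np.argsort(out.values[:, j]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_coverage(self._matrix(np.ones((2, 4))), [1e6, 0.0, 1e6, 1e6])


class TestWilcoxonScan:
    def test_planted_shift_is_detected_at_genome_scale_alpha(self):
        # 50% coverage change, SD 0.17, 19 vs 19: detectable below 1.74e-7
        rng = np.random.default_rng(3)
        samples = make_samples(19, 19, male_cases=10, male_controls=10)
        n_regions = 300
        values = rng.normal(1.0, 0.17, size=(n_regions, 38))
        values[0, :19] += 0.5
        scan = groupwise_wilcoxon_scan(values, samples, family_alpha=0.05)
        assert scan.per_test_alpha == pytest.approx(0.05 / n_regions)
        assert 0 in scan.significant
        # planted per-test alpha at true genome scale is reachable by the exact test
        assert scan.pvalues[0] < 1.74e-7

    def test_constant_rows_get_p_one(self):
        samples = make_samples(3, 3)
        values = np.vstack([np.ones(6), np.arange(6, dtype=float)])
        scan = groupwise_wilcoxon_scan(values, samples)
        assert scan.pvalues[0] == 1.0
        assert scan.constant == [0]

    def test_type_one_family_error_controlled_on_null_data(self):
        rng = np.random.default_rng(11)
        samples = make_samples(10, 10, male_cases=5, male_controls=5)
        n_datasets, n_regions = 120, 40
        any_hit = 0
        for _ in range(n_datasets):
            values = rng.normal(1.0, 0.2, size=(n_regions, 20))
            scan = groupwise_wilcoxon_scan(values, samples, family_alpha=0.05)
            any_hit += len(scan.significant) > 0
        se = math.sqrt(0.05 * 0.95 / n_datasets)
        assert any_hit / n_datasets <= 0.05 + 3 * se

    def test_too_few_samples_rejected(self):
        samples = make_samples(1, 3)
        with pytest.raises(ValueError):
            groupwise_wilcoxon_scan(np.ones((2, 4)), samples)


class TestPower:
    def test_smaller_effect_needs_more_samples(self):
        base = dict(alpha=1e-4, power=0.95, sd=1.0)
        ns = [wmw_power_n(PowerSpec(effect=e, **base)).n_per_group for e in (2.0, 1.0, 0.5, 0.25)]
        assert ns == sorted(ns)
        assert ns[-1] > 10 * ns[0]  # diverges as the effect vanishes

    def test_stricter_alpha_never_decreases_n(self):
        ns = [
            wmw_power_n(PowerSpec(alpha=a, power=0.95, effect=0.5, sd=0.17)).n_per_group
            for a in (1e-2, 1e-4, 1.74e-7)
        ]
        assert ns == sorted(ns)

    def test_str_configuration_is_feasible(self):
        # two-repeat difference, SD 1.07, per-test alpha 1.472e-4
        spec = wmw_power_n(PowerSpec(alpha=1.472e-4, power=0.95, effect=2.0, sd=1.07))
        assert spec.metadata["method"] == "noether"
        assert 2 <= spec.n_per_group <= 25

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=0.5, power=0.2, effect=1.0, sd=1.0)


class TestStrCompare:
    def _table(self, values, samples):
        df = pd.DataFrame(values, columns=[s.sample_id for s in samples])
        df.insert(0, "unit", "AC")
        df.insert(0, "locus", [f"L{i}" for i in range(len(df))])
        return df

    def test_identical_distributions_find_nothing(self):
        rng = np.random.default_rng(5)
        samples = make_samples(8, 8, male_cases=4, male_controls=4)
        values = rng.integers(5, 30, size=(30, 16)).astype(float)
        scan, frame = str_compare(self._table(values, samples), samples)
        assert len(scan.significant) == 0
        assert not frame["significant"].any()

    def test_planted_expansion_detected(self):
        rng = np.random.default_rng(6)
        samples = make_samples(12, 12, male_cases=6, male_controls=6)
        values = np.round(rng.normal(20, 1.07, size=(20, 24)))
        values[0, :12] += 3  # all cases carry a +3 repeat expansion
        scan, _ = str_compare(self._table(values, samples), samples)
        assert list(scan.significant) == [0]

    def test_sparse_locus_skipped(self):
        samples = make_samples(3, 3)
        values = np.full((2, 6), 10.0)
        values[0, :] = np.nan
        values[0, 0] = 12.0
        scan, _ = str_compare(self._table(values, samples), samples)
        assert scan.skipped == [0]
        assert scan.n_tests == 1


class TestViralFilter:
    def _hits(self):
        return [
            ViralHit("r1", "CASE01", "HHV6B", 100, 96.0),
            ViralHit("r2", "CASE01", "HHV6B", 100, 94.0),
            ViralHit("r3", "CASE02", "HHV6B", 85, 99.0),
            ViralHit("r4", "CTRL01", "HHV7", 200, 98.0),
        ]

    def test_threshold_boundary_walk(self):
        samples = make_samples(2, 1)
        kept, _ = filter_viral_hits(self._hits(), samples)
        assert {h.read_id for h in kept} == {"r1", "r4"}

    def test_empty_input(self):
        kept, summary = filter_viral_hits([], make_samples(1, 1))
        assert kept == [] and summary.empty

    def test_pure_filter_is_idempotent_and_order_free(self):
        samples = make_samples(2, 1)
        kept1, _ = filter_viral_hits(self._hits(), samples)
        kept2, _ = filter_viral_hits(reversed(self._hits()), samples)
        kept3, _ = filter_viral_hits(kept1, samples)
        assert kept1 == kept2 == kept3

    def test_cohort_summary_counts_distinct_samples(self):
        samples = make_samples(3, 1)
        hits = [
            ViralHit("a", "CASE01", "HHV6B", 120, 98.0),
            ViralHit("b", "CASE01", "HHV6B", 130, 97.0),
            ViralHit("c", "CASE02", "HHV6B", 120, 98.0),
        ]
        _, summary = filter_viral_hits(hits, samples)
        row = summary.set_index(["virus", "cohort"]).loc[("HHV6B", "case")]
        assert row["n_samples"] == 2

    def test_invalid_hit_rejected(self):
        with pytest.raises(ValueError):
            ViralHit("r", "s", "v", 0, 99.0)
        with pytest.raises(ValueError):
            ViralHit("r", "s", "v", 100, 101.0)
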