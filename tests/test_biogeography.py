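"""Grubbs screening and abundance algebra."""
import numpy as np
import pandas as pd
import pytest

from sagtools.biogeography import (
    correct_abundance,
    grubbs_critical_value,
    grubbs_outliers,
    merge_outliers,
    normalize_by_max,
    raw_abundance,
    regional_means,
    station_median_identity,
    station_outlier_scan,
)
from sagtools.recruitment import compute_rpkm
from sagtools.types import ReadAlignment, RecruitmentMatrix


from oracles import oracle_grubbs


class TestGrubbs:
    def test_textbook_example(self):
        # G = 1.786 exceeds the n=5 critical value 1.715
        assert grubbs_outliers([8, 9, 10, 11, 50]) == [4]
        assert grubbs_critical_value(5, 0.05) == pytest.approx(1.715, abs=1e-3)

    def test_constant_vector_has_no_outliers(self):
        assert grubbs_outliers([5, 5, 5, 5]) == []

    def test_short_vector_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert grubbs_outliers([1.0, 2.0]) == []

    def test_single_shifted_value_flagged(self, rng):
        x = rng.normal(size=50)
        x[17] += 10.0
        assert grubbs_outliers(x) == [17]

    def test_matches_independent_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            x = rng.normal(size=n)
            if rng.random() < 0.5:
                x[rng.integers(n)] += rng.uniform(3, 12)
            assert grubbs_outliers(x) == oracle_grubbs(x)

    def test_one_sided_ignores_low_extremes(self):
        x = [10.0, 10.5, 9.5, 10.2, 9.8, -30.0]
        assert grubbs_outliers(x, two_sided=True) == [5]
        assert grubbs_outliers(x, two_sided=False) == []


def _matrix(counts, lengths=None, detected=None):
    counts = pd.DataFrame(counts)
    lengths = lengths if lengths is not None else pd.Series(1000.0, index=counts.index)
    m = RecruitmentMatrix(
        counts=counts, gene_lengths=lengths,
        sample_sequenced_totals=pd.Series(10**6, index=counts.columns),
        detected=detected,
    )
    return compute_rpkm(m)


class TestStationScan:
    def test_eligibility_boundary_is_inclusive_twenty_percent(self, rng):
        n_genes = 100
        counts = pd.DataFrame({
            "skip": [0] * 81 + [10] * 19,   # 19% detected
            "test": [0] * 80 + [10] * 20,   # 20% detected
        }, index=[f"g{i}" for i in range(n_genes)])
        m = _matrix(counts)
        tested, _ = station_outlier_scan(m)
        assert tested == {"skip": False, "test": True}

    def test_inflated_gene_flagged_in_eligible_sample(self, rng):
        vals = rng.poisson(40, size=60)
        vals[7] = 40 * 50
        m = _matrix(pd.DataFrame({"s": vals}, index=[f"g{i}" for i in range(60)]))
        tested, per_sample = station_outlier_scan(m)
        assert tested["s"] is True
        assert "g7" in per_sample["s"]

    def test_undetected_genes_excluded_from_scan_vector(self):
        counts = pd.DataFrame({"s": [100] * 30 + [0] * 10},
                              index=[f"g{i}" for i in range(40)])
        m = _matrix(counts)
        _, per_sample = station_outlier_scan(m)
        # the zero genes are undetected, so the detected vector is constant
        assert per_sample["s"] == set()


class TestMergeAndDiscard:
    def test_union_and_scaffold_discard(self):
        per_sample = {"a": {"g1"}, "b": {"g2"}}
        gene_scaffold = {"g1": "s1", "g2": "s1", "g3": "s2"}
        rep = merge_outliers({"a": True, "b": True}, per_sample,
                             ["g1", "g2", "g3"], gene_scaffold)
        assert rep.merged == {"g1", "g2"}
        assert rep.inliers == {"g3"}
        assert rep.discarded_scaffolds == {"s1"}

    def test_scaffold_with_one_inlier_kept(self):
        rep = merge_outliers({"a": True}, {"a": {"g1"}}, ["g1", "g2"],
                             {"g1": "s1", "g2": "s1"})
        assert rep.discarded_scaffolds == set()

    def test_empty_scan_discards_nothing(self):
        rep = merge_outliers({}, {}, ["g1"], {"g1": "s1"})
        assert rep.merged == set() and rep.inliers == {"g1"}
        assert rep.discarded_scaffolds == set()

    def test_flag_counts_per_gene(self):
        rep = merge_outliers({"a": True, "b": True},
                             {"a": {"g1"}, "b": {"g1", "g2"}}, ["g1", "g2"], None)
        counts = rep.flag_counts()
        assert counts["g1"] == 2 and counts["g2"] == 1


class TestAbundanceAlgebra:
    @staticmethod
    def _bundle(total=30_000_000, gene_space=15_000_000, completion=0.5):
        # duck-typed stand-in carrying only the size bookkeeping the
        # correction formula reads
        from types import SimpleNamespace
        return SimpleNamespace(assembly_size_bp=total,
                               mapped_gene_space_bp=gene_space,
                               completion=completion)

    def test_raw_abundance_sums_inlier_counts(self):
        m = _matrix(pd.DataFrame({"s": [10, 20, 99]}, index=["g1", "g2", "g3"]))
        raw = raw_abundance(m, inliers={"g1", "g2"})
        assert raw["s"] == pytest.approx(3e-5)

    def test_all_counts_on_outliers_gives_zero(self):
        m = _matrix(pd.DataFrame({"s": [50]}, index=["g1"]))
        assert raw_abundance(m, inliers=set())["s"] == 0.0

    def test_corrected_equals_raw_for_complete_fully_mapped_genome(self):
        bundle = self._bundle(total=10**6, gene_space=10**6, completion=1.0)
        raw = pd.Series({"s": 1e-4})
        assert correct_abundance(raw, bundle)["s"] == pytest.approx(1e-4)

    def test_corrected_worked_example(self):
        bundle = self._bundle(total=30_000_000, gene_space=15_000_000, completion=0.5)
        corrected = correct_abundance(pd.Series({"s": 1e-4}), bundle)
        assert corrected["s"] == pytest.approx(4e-4)

    def test_normalization_and_zero_row(self):
        df = pd.DataFrame({"a": [2.0, 0.0], "b": [4.0, 0.0], "c": [1.0, 0.0]},
                          index=["o1", "o2"])
        norm = normalize_by_max(df)
        assert norm.loc["o1"].max() == 1.0
        assert norm.loc["o1", "a"] == pytest.approx(0.5)
        assert (norm.loc["o2"] == 0).all()

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (10, 6)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(6)])
        bundle = self._bundle()
        for scale in (1, 10):
            m = RecruitmentMatrix(
                counts=counts * scale,
                gene_lengths=pd.Series(1000.0, index=counts.index),
                sample_sequenced_totals=pd.Series(10**6 * scale, index=counts.columns),
            )
            raw = raw_abundance(m, set(counts.index))
            if scale == 1:
                base = correct_abundance(raw, bundle)
            else:
                scaled = correct_abundance(raw, bundle)
                pd.testing.assert_series_equal(base, scaled)

    def test_regional_means_include_zeros(self):
        df = pd.DataFrame({"s1": [0.0], "s2": [2e-5], "s3": [4e-5]}, index=["o"])
        regions = {"s1": "Atlantic", "s2": "Atlantic", "s3": "Indian"}
        means = regional_means(df, regions)
        assert means.loc["o", "Atlantic"] == pytest.approx(1e-5)
        assert means.loc["o", "Indian"] == pytest.approx(4e-5)


class TestMedianIdentity:
    def _aln(self, gene, identity):
        return ReadAlignment("r", "ST1", "SRF", gene, 101, 101, identity)

    def test_median_over_inlier_alignments(self):
        alns = [self._aln("g1", 94), self._aln("g1", 95), self._aln("g1", 96),
                self._aln("gX", 50)]
        med = station_median_identity(alns, inliers={"g1"})
        assert med["ST1:SRF"] == 95

    def test_even_count_midpoint(self):
        alns = [self._aln("g1", 95), self._aln("g1", 97)]
        assert station_median_identity(alns, {"g1"})["ST1:SRF"] == 96

    def test_no_alignments_absent(self):
        assert station_median_identity([], {"g1"}).empty
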