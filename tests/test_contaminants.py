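import numpy as np
import pandas as pd
import pytest

from lowbiom import (
    AnalysisError,
    ContaminantModel,
    FilterConfig,
    OtuTable,
    SampleMetadata,
    ValidationError,
    apply_filter,
    feature1,
    feature2,
    relative_abundance,
)
from conftest import ladder_table
from _oracles import spearman_oracle


class TestRelativeAbundance:
    def test_columns_sum_to_one(self, tiny_table):
        rel = relative_abundance(tiny_table)
        assert rel.sum(axis=0).tolist() == pytest.approx([1.0, 1.0], abs=1e-12)
        assert rel["S1"].tolist() == pytest.approx([10 / 15, 5 / 15, 0.0])

    def test_simple_fractions(self):
        t = OtuTable(pd.DataFrame({"S1": [10, 30]}, index=["a", "b"]))
        assert relative_abundance(t)["S1"].tolist() == [0.25, 0.75]

    def test_zero_depth_sample_warns_and_stays_zero(self):
        t = OtuTable(pd.DataFrame({"S1": [1], "S2": [0]}, index=["a"]))
        with pytest.warns(UserWarning, match="zero total reads"):
            rel = relative_abundance(t)
        assert rel["S2"].tolist() == [0.0]

    def test_random_table_normalisation(self, rng):
        counts = rng.integers(1, 1000, size=(50, 20))
        t = OtuTable(pd.DataFrame(counts))
        sums = relative_abundance(t).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestFeature1:
    def test_perfect_monotone_not_flagged(self):
        table, meta = ladder_table({"up": [1, 2, 3, 4, 5, 6, 7, 8],
                                    "rest": [9, 9, 9, 9, 9, 9, 9, 9]})
        calls = feature1(relative_abundance(table), meta)
        assert calls.loc["up", "rho"] == pytest.approx(1.0)
        assert not calls.loc["up", "feature1"]

    def test_perfect_antitone_flagged(self):
        table, meta = ladder_table({"down": [80, 70, 60, 50, 40, 30, 20, 10],
                                    "rest": [10, 20, 30, 40, 50, 60, 70, 80]})
        calls = feature1(relative_abundance(table), meta)
        assert calls.loc["down", "rho"] == pytest.approx(-1.0)
        assert calls.loc["down", "p_value"] <= 0.05
        assert bool(calls.loc["down", "feature1"])

    def test_matches_bruteforce_oracle(self, rng):
        n = 10
        densities = 10.0 ** rng.uniform(3, 9, size=n)
        counts = rng.integers(0, 500, size=(25, n))
        counts[0] += 1  # keep depths positive
        table = OtuTable(pd.DataFrame(counts, columns=[f"S{i}" for i in range(n)]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "density": densities,
            "replicate_group": [f"G{i}" for i in range(n)],
        }))
        rel = relative_abundance(table)
        calls = feature1(rel, meta)
        for otu in table.otu_ids:
            rho, p = spearman_oracle(rel.loc[otu].to_numpy(), densities)
            if np.isnan(rho):
                assert np.isnan(calls.loc[otu, "rho"])
            else:
                assert calls.loc[otu, "rho"] == pytest.approx(rho, abs=1e-12)
                assert calls.loc[otu, "p_value"] == pytest.approx(p, abs=1e-9)

    def test_zero_variance_otu_undefined_and_unflagged(self):
        table, meta = ladder_table({"flat": [5, 5, 5, 5, 5, 5, 5, 5],
                                    "also": [15, 15, 15, 15, 15, 15, 15, 15]})
        rel = relative_abundance(table)
        calls = feature1(rel, meta)
        assert np.isnan(calls.loc["flat", "rho"])
        assert np.isnan(calls.loc["flat", "p_value"])
        assert not calls.loc["flat", "feature1"]

    def test_log_density_invariance(self, rng):
        """Monotone transforms of density leave Spearman calls unchanged."""
        table, meta = ladder_table({
            "a": list(rng.integers(1, 100, 8)),
            "b": list(rng.integers(1, 100, 8)),
        })
        rel = relative_abundance(table)
        raw = feature1(rel, meta)
        log_frame = meta.frame.reset_index().assign(
            density=lambda f: np.log10(f["density"])
        )
        logged = feature1(rel, SampleMetadata(log_frame))
        pd.testing.assert_frame_equal(raw, logged)

    def test_min_prevalence_gates_flagging(self):
        table, meta = ladder_table({"down": [30, 20, 10, 0, 0, 0, 0, 0],
                                    "rest": [2, 10, 10, 10, 10, 10, 10, 10]})
        rel = relative_abundance(table)
        loose = feature1(rel, meta, FilterConfig(min_prevalence=0.0))
        strict = feature1(rel, meta, FilterConfig(min_prevalence=0.5))
        assert bool(loose.loc["down", "feature1"])
        assert not strict.loc["down", "feature1"]

    def test_too_few_samples_is_analysis_error(self):
        table = OtuTable(pd.DataFrame({"S1": [1], "S2": [1]}, index=["a"]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["S1", "S2"], "density": [1e5, 1e6],
            "replicate_group": ["G1", "G2"],
        }))
        with pytest.raises(AnalysisError, match="3"):
            feature1(relative_abundance(table), meta)

    def test_benjamini_hochberg_is_more_conservative(self, rng):
        counts = rng.integers(0, 50, size=(40, 12))
        counts[0] += 1
        table = OtuTable(pd.DataFrame(counts, columns=[f"S{i}" for i in range(12)]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(12)],
            "density": 10.0 ** rng.uniform(3, 9, 12),
            "replicate_group": [f"G{i}" for i in range(12)],
        }))
        rel = relative_abundance(table)
        raw = feature1(rel, meta)
        bh = feature1(rel, meta, FilterConfig(multiple_testing="benjamini_hochberg"))
        assert (bh["p_adjusted"] >= raw["p_value"] - 1e-15).all()
        assert bh["feature1"].sum() <= raw["feature1"].sum()


class TestFeature2:
    def pair(self, counts_a, counts_b):
        otus = [f"O{i}" for i in range(len(counts_a))]
        table = OtuTable(pd.DataFrame({"S1": counts_a, "S2": counts_b}, index=otus))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["S1", "S2"], "density": [8e5, 8e5],
            "replicate_group": ["R1", "R1"],
        }))
        return table, meta

    def test_singleton_detected(self):
        table, meta = self.pair([5, 5], [0, 3])
        groups = feature2(table, meta)
        assert groups["O0"] == frozenset({"R1"})
        assert groups["O1"] == frozenset()

    def test_relative_abundance_threshold(self):
        # 1 read at depth 1e4 is 1e-4 < 1e-3 -> "absent" in both replicates
        counts = {"S1": [1, 9_999], "S2": [0, 10_000]}
        table = OtuTable(pd.DataFrame(counts, index=["rare", "bulk"]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["S1", "S2"], "density": [8e5, 8e5],
            "replicate_group": ["R1", "R1"],
        }))
        by_count = feature2(table, meta)
        by_fraction = feature2(table, meta, FilterConfig(presence_threshold=1e-3))
        assert by_count["rare"] == frozenset({"R1"})
        assert by_fraction["rare"] == frozenset()

    def test_larger_groups_use_exactly_one_rule(self):
        table = OtuTable(pd.DataFrame(
            {"S1": [4, 4], "S2": [0, 4], "S3": [0, 4]}, index=["a", "b"]
        ))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["S1", "S2", "S3"], "density": [8e5] * 3,
            "replicate_group": ["R1"] * 3,
        }))
        groups = feature2(table, meta)
        assert groups["a"] == frozenset({"R1"})
        assert groups["b"] == frozenset()

    def test_singleton_group_skipped_with_warning(self):
        table = OtuTable(pd.DataFrame({"S1": [1], "S2": [1], "S3": [1]},
                                      index=["a"]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["S1", "S2", "S3"], "density": [8e5] * 3,
            "replicate_group": ["R1", "R1", "lonely"],
        }))
        with pytest.warns(UserWarning, match="lonely"):
            groups = feature2(table, meta)
        assert groups["a"] == frozenset()

    def test_no_replicate_structure_is_analysis_error(self):
        table = OtuTable(pd.DataFrame({"S1": [1], "S2": [1]}, index=["a"]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["S1", "S2"], "density": [8e5, 8e5],
            "replicate_group": ["G1", "G2"],
        }))
        with pytest.warns(UserWarning):
            with pytest.raises(AnalysisError):
                feature2(table, meta)


class TestFilterConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.5},
            {"min_prevalence": -0.1},
            {"presence_threshold": 0.0},
            {"presence_threshold": 1.5},
            {"multiple_testing": "bonferroni"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FilterConfig(**kwargs)


class TestApplyFilter:
    def fitted(self, values_by_otu, densities=None, groups=None):
        n = len(next(iter(values_by_otu.values())))
        samples = [f"S{i + 1}" for i in range(n)]
        table = OtuTable(pd.DataFrame(values_by_otu, index=samples).T)
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": samples,
            "density": densities or [8.0 * 10.0**k for k in range(2, 2 + n)],
            "replicate_group": groups or samples,
        }))
        return table, ContaminantModel(table, meta).fit()

    def test_f1_removal_conserves_unflagged_reads(self):
        table, res = self.fitted(
            {"down": [100, 50, 25, 12, 6, 3, 2, 1],
             "up": [1, 2, 3, 6, 12, 25, 50, 100],
             "mid": [10] * 8},
            groups=["G1", "G1", "G2", "G2", "G3", "G3", "G4", "G4"],
        )
        assert bool(res.calls.loc["down", "feature1"])
        filtered, report = res.apply_filter("F1")
        removed = table.counts.loc["down"].sum()
        assert filtered.total_reads() == table.total_reads() - removed
        assert (filtered.counts.loc["up"] == table.counts.loc["up"]).all()
        assert set(report["reason"]) == {"F1"}

    def test_no_flags_is_identity(self):
        # constant composition across the ladder: rho undefined, no singletons
        table, res = self.fitted(
            {"a": [2, 4, 6, 8, 10, 12, 14, 16], "b": [1, 2, 3, 4, 5, 6, 7, 8]},
            groups=["G1", "G1", "G2", "G2", "G3", "G3", "G4", "G4"],
        )
        assert not res.calls["feature1"].any()
        for mode in ("F1", "F2", "F3"):
            filtered, report = res.apply_filter(mode)
            assert filtered == table
            assert len(report) == 0

    def test_f2_zeroes_only_within_singleton_group(self):
        table, res = self.fitted(
            {"spotty": [5, 0, 4, 4], "solid": [3, 3, 3, 3]},
            densities=[8e5, 8e5, 8e6, 8e6],
            groups=["R1", "R1", "R2", "R2"],
        )
        filtered, report = res.apply_filter("F2")
        assert filtered.counts.loc["spotty"].tolist() == [0, 0, 4, 4]
        assert filtered.counts.loc["solid"].tolist() == [3, 3, 3, 3]
        assert report["reason"].tolist() == ["F2"]

    def test_f3_double_flag_reported_once_under_f1(self):
        table, res = self.fitted(
            {"both": [100, 80, 40, 30, 10, 8, 2, 0],
             "up": [1, 2, 3, 6, 12, 25, 50, 100]},
            groups=["G1", "G1", "G2", "G2", "G3", "G3", "G4", "G4"],
        )
        assert bool(res.calls.loc["both", "feature1"])
        assert len(res.feature2_groups["both"]) > 0
        filtered, report = res.apply_filter("F3")
        sub = report[report["otu_id"] == "both"]
        assert set(sub["reason"]) == {"F1"}
        assert (filtered.counts.loc["both"] == 0).all()

    def test_unknown_mode_rejected(self, fitted):
        with pytest.raises(ValueError, match="mode"):
            fitted.apply_filter("F9")

    def test_filtering_never_increases_any_cell(self, default_dataset, fitted):
        for mode in ("F1", "F2", "F3"):
            filtered, _ = fitted.apply_filter(mode)
            assert (filtered.counts.to_numpy()
                    <= default_dataset.table.counts.to_numpy()).all()

    def test_f2_idempotent_under_recomputed_calls(self):
        table, res = self.fitted(
            {"spotty": [5, 0, 4, 4], "solid": [3, 3, 3, 3]},
            densities=[8e5, 8e5, 8e6, 8e6],
            groups=["R1", "R1", "R2", "R2"],
        )
        once, _ = res.apply_filter("F2")
        res2 = ContaminantModel(once, res.metadata, res.config).fit()
        twice, report = res2.apply_filter("F2")
        assert twice == once
        assert len(report) == 0

    def test_stale_calls_rejected(self, tiny_table, fitted):
        with pytest.raises(ValidationError):
            apply_filter(tiny_table, fitted, "F1")


class TestModelInterface:
    def test_summary_mentions_key_numbers(self, fitted):
        text = fitted.summary()
        assert "Feature 1" in text and "Feature 2" in text
        assert str(len(fitted.calls)) in text

    def test_to_frame_flattens_groups(self, fitted):
        frame = fitted.to_frame()
        assert "feature2_groups" in frame.columns
        assert frame["feature2_groups"].map(lambda s: isinstance(s, str)).all()

    def test_labels_partition_otus(self, fitted):
        labels = set(fitted.calls["label"])
        assert labels <= {"contaminant", "retained"}
        flagged = set(fitted.flagged("any"))
        assert flagged == set(fitted.calls.index[fitted.calls["label"] == "contaminant"])

    def test_from_files(self, tmp_path, default_dataset):
        from lowbiom import write_metadata, write_otu_table

        write_otu_table(default_dataset.table, tmp_path / "t.tsv")
        write_metadata(default_dataset.metadata, tmp_path / "m.tsv")
        res = ContaminantModel.from_files(tmp_path / "t.tsv", tmp_path / "m.tsv").fit()
        assert len(res.calls) == default_dataset.table.shape[0]
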