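import itertools

import numpy as np
import pandas as pd
import pytest

from radstab import (build_report, demo_config, filter_frequency_above_reference,
                     icc_range_over_binwidths, load_config,
                     normalization_delta, rank_histogram_over_binwidths,
                     run_study, top_k_per_class, volume_reference)
from radstab.study_pipeline import ConfigurationError


def make_icc_table(entries):
    """entries: (feature_class, feature, filter, bin_width, icc[, norm])."""
    rows = []
    for e in entries:
        cls, feat, filt, w, icc = e[:5]
        norm = e[5] if len(e) > 5 else "none"
        rows.append({"image_type": "synthetic", "roi": "tumor",
                     "normalization": norm, "filter": filt, "bin_width": w,
                     "dim": "2D", "feature_class": cls, "feature": feat,
                     "n": 15, "icc": icc, "ci_low": icc - 0.1,
                     "ci_high": min(icc + 0.1, 1.0), "bms": 1.0, "wms": 0.1})
    return pd.DataFrame(rows)


class TestVolumeReference:
    def test_lookup(self):
        t = make_icc_table([("shape", "Volume", "original", 15.0, 0.7),
                            ("firstorder", "Mean", "original", 15.0, 0.9)])
        assert volume_reference(t, "tumor", "synthetic") == 0.7

    def test_reference_same_under_any_filter_fingerprint(self):
        t = make_icc_table([("shape", "Volume", f, w, 0.7)
                            for f in ("original", "square") for w in (10.0, 15.0)])
        assert volume_reference(t, "tumor", "synthetic") == 0.7

    def test_missing_volume_raises(self):
        t = make_icc_table([("firstorder", "Mean", "original", 15.0, 0.9)])
        with pytest.raises(ConfigurationError):
            volume_reference(t, "tumor", "synthetic")
        nan = make_icc_table([("shape", "Volume", "original", 15.0, np.nan)])
        with pytest.raises(ConfigurationError):
            volume_reference(nan, "tumor", "synthetic")


class TestBinWidthSummaries:
    def test_range_hand_value_and_zero_case(self):
        t = make_icc_table([("glcm", "Contrast", "original", w, icc)
                            for w, icc in zip((10, 15, 20, 40), (0.5, 0.6, 0.7, 0.8))]
                           + [("glcm", "Idm", "original", w, 0.4)
                              for w in (10, 15, 20, 40)])
        out = icc_range_over_binwidths(t)
        by_feat = out.set_index("feature")["icc_range"]
        assert by_feat["Contrast"] == pytest.approx(0.3)
        assert by_feat["Idm"] == 0.0

    def test_range_matches_bruteforce_scan(self, rng):
        entries = [("glcm", f"F{i}", filt, w, rng.uniform(-1, 1))
                   for i in range(5) for filt in ("original", "square")
                   for w in (10, 15, 20, 40)]
        t = make_icc_table(entries)
        out = icc_range_over_binwidths(t)
        for (feat, filt), grp in t.groupby(["feature", "filter"]):
            expect = grp["icc"].max() - grp["icc"].min()
            row = out[(out["feature"] == feat) & (out["filter"] == filt)]
            assert row["icc_range"].iloc[0] == pytest.approx(expect)

    def test_single_binwidth_key_skipped_with_warning(self):
        t = make_icc_table([("glcm", "Contrast", "original", 15.0, 0.5)])
        with pytest.warns(UserWarning):
            out = icc_range_over_binwidths(t)
        assert out.empty

    def test_rank_histogram_best_width_and_ties(self):
        t = make_icc_table([("glcm", "Contrast", "original", w, icc)
                            for w, icc in zip((10, 15, 20, 40), (0.5, 0.6, 0.7, 0.8))])
        hist = rank_histogram_over_binwidths(t)
        assert hist.loc[1, 40.0] == 1 and hist.loc[4, 10.0] == 1
        tied = make_icc_table([("glcm", "Idm", "original", w, 0.5)
                               for w in (10, 15, 20, 40)])
        hist = rank_histogram_over_binwidths(tied)
        assert (hist.loc[1] == 1).all()  # all widths share the better rank

    def test_rank_histogram_columns_conserve_key_count(self, rng):
        entries = [("glcm", f"F{i}", filt, w, rng.uniform(-1, 1))
                   for i in range(7) for filt in ("original", "square")
                   for w in (10, 15, 20, 40)]
        hist = rank_histogram_over_binwidths(make_icc_table(entries))
        assert (hist.sum(axis=0) == 14).all()


class TestTopK:
    def test_selects_best_three(self):
        t = make_icc_table([("glcm", f, "original", 15.0, icc) for f, icc in
                            [("A", 0.9), ("B", 0.8), ("C", 0.7), ("D", 0.6)]])
        out = top_k_per_class(t, k=3)
        assert list(out["feature"]) == ["A", "B", "C"]

    def test_k_larger_than_class(self):
        t = make_icc_table([("glszm", "A", "original", 15.0, 0.5)])
        assert len(top_k_per_class(t, k=3)) == 1

    def test_best_configuration_is_max_over_filters(self):
        t = make_icc_table([("glcm", "A", "original", 15.0, 0.2),
                            ("glcm", "A", "square", 15.0, 0.9),
                            ("glcm", "B", "original", 15.0, 0.5),
                            ("glcm", "B", "square", 15.0, 0.4)])
        out = top_k_per_class(t, k=1)
        assert list(out["feature"]) == ["A"]
        assert out["best_icc"].iloc[0] == pytest.approx(0.9)

    def test_ties_broken_lexicographically(self):
        t = make_icc_table([("glcm", f, "original", 15.0, 0.5) for f in "DCBA"])
        out = top_k_per_class(t, k=2)
        assert list(out["feature"]) == ["A", "B"]

    def test_matches_bruteforce_sort(self, rng):
        entries = [(cls, f"F{i}", filt, 15.0, round(rng.uniform(-1, 1), 6))
                   for cls in ("glcm", "glrlm") for i in range(6)
                   for filt in ("original", "square", "logarithm")]
        t = make_icc_table(entries)
        out = top_k_per_class(t, k=3)
        for cls, grp in t.groupby("feature_class"):
            best = grp.groupby("feature")["icc"].max()
            expect = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            got = out[out["feature_class"] == cls]
            assert list(got["feature"]) == [f for f, _ in expect]


class TestFilterFrequency:
    def test_multi_filter_attribution(self):
        t = make_icc_table([("glcm", "A", f, 15.0, 0.9)
                            for f in ("original", "square", "logarithm")]
                           + [("glcm", "B", "original", 15.0, 0.1)])
        counts, total = filter_frequency_above_reference(t, reference=0.5)
        assert total == 1
        assert counts["original"] == 1 and counts["square"] == 1
        assert counts.sum() == 3  # one feature counted under each of 3 filters

    def test_none_above_reference(self):
        t = make_icc_table([("glcm", "A", "original", 15.0, 0.2)])
        counts, total = filter_frequency_above_reference(t, reference=0.9)
        assert total == 0 and (counts == 0).all()

    def test_matches_bruteforce_threshold_scan(self, rng):
        entries = [("glcm", f"F{i}", filt, 15.0, rng.uniform(-1, 1))
                   for i in range(8) for filt in ("original", "square")]
        t = make_icc_table(entries)
        ref = 0.3
        counts, total = filter_frequency_above_reference(t, ref)
        for filt in ("original", "square"):
            expect = sum(1 for e in entries if e[2] == filt and e[4] > ref)
            assert counts[filt] == expect
        assert total == len({e[1] for e in entries if e[4] > ref})


class TestNormalizationDelta:
    def _tables(self, rng):
        a = make_icc_table([("glcm", f"F{i}", "original", 15.0,
                             rng.uniform(-1, 1), "none") for i in range(6)])
        b = a.copy()
        b["normalization"] = "reference_region"
        b["icc"] = rng.uniform(-1, 1, size=len(b))
        return a, b

    def test_identical_tables_zero_delta(self, rng):
        a, _ = self._tables(rng)
        deltas, _ = normalization_delta(a, a)
        assert np.allclose(deltas["delta"], 0.0)

    def test_antisymmetry(self, rng):
        a, b = self._tables(rng)
        d_ab, _ = normalization_delta(a, b)
        d_ba, _ = normalization_delta(b, a)
        np.testing.assert_allclose(d_ab["delta"].to_numpy(),
                                   -d_ba["delta"].to_numpy())

    def test_elementwise_subtraction_and_top_union(self, rng):
        a, b = self._tables(rng)
        deltas, union = normalization_delta(a, b, k=3)
        merged = a.merge(b, on=["feature"], suffixes=("_a", "_b"))
        expect = dict(zip(merged["feature"], merged["icc_b"] - merged["icc_a"]))
        for _, row in deltas.iterrows():
            assert row["delta"] == pytest.approx(expect[row["feature"]])
        top_a = set(top_k_per_class(a, k=3)["feature"])
        top_b = set(top_k_per_class(b, k=3)["feature"])
        assert set(union["feature"]) == top_a | top_b
        assert 3 <= len(union) <= 6

    def test_unmatched_keys_dropped_with_warning(self, rng):
        a, b = self._tables(rng)
        with pytest.warns(UserWarning):
            deltas, _ = normalization_delta(a, b.iloc[:-2])
        assert len(deltas) == len(a) - 2


class TestRunStudy:
    @pytest.fixture(scope="class")
    def study(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("study")
        cfg = demo_config(n_subjects=3, seed=4)
        cfg["filters"] = {"specs": ["original", "square"]}
        cfg["rois"] = ["tumor"]
        report = run_study(cfg, out)
        return cfg, out, report

    def test_smoke_and_artifacts(self, study):
        _, out, report = study
        for name in ("features.csv", "icc.csv", "report/icc.csv",
                     "report/volume_reference.csv", "report/rank_histogram.csv",
                     "report/top3_per_class.csv", "report/filter_frequency.csv"):
            assert (out / name).exists()
        assert ("tumor", "synthetic") in report.references

    def test_summaries_consistent_with_table_cardinality(self, study):
        _, _, report = study
        n_keys = report.icc.dropna(subset=["icc"]).groupby(
            [c for c in report.icc.columns if c in
             ("image_type", "roi", "normalization", "filter", "dim",
              "feature_class", "feature")]).ngroups
        assert (report.rank_histogram.sum(axis=0) <= n_keys).all()
        for key, counts in report.filter_frequency.items():
            # each per-filter count is bounded by the distinct-feature total
            assert (counts <= report.features_above_reference[key]).all()

    def test_report_idempotent_from_persisted_icc(self, study):
        _, out, report = study
        rebuilt = build_report(pd.read_csv(out / "icc.csv"))
        pd.testing.assert_frame_equal(
            rebuilt.top3.reset_index(drop=True), report.top3.reset_index(drop=True))
        pd.testing.assert_frame_equal(rebuilt.icc_ranges, report.icc_ranges)
        assert rebuilt.references == report.references

    def test_rerun_same_seed_byte_identical(self, study, tmp_path):
        cfg, out, _ = study
        run_study(cfg, tmp_path / "again")
        for name in ("features.csv", "icc.csv"):
            assert (tmp_path / "again" / name).read_bytes() == (out / name).read_bytes()


class TestConfig:
    def test_defaults_and_unknown_keys(self):
        cfg = load_config(None)
        assert cfg["bin_widths"] == [10.0, 15.0, 20.0, 40.0]
        with pytest.raises(ConfigurationError):
            load_config({"bogus": 1})

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 9\nbin_widths: [15]\nrois: [tumor]\n")
        cfg = load_config(path)
        assert cfg["seed"] == 9 and cfg["bin_widths"] == [15]


def test_cli_full_chain(tmp_path):
    from click.testing import CliRunner

    from radstab.cli import main

    runner = CliRunner()
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "seed: 3\n"
        "cohort: {n_subjects: 2, shape: [8, 26, 26], lesion_center_jitter_mm: 0.0}\n"
        "filters: {specs: [original]}\n"
        "bin_widths: [15]\n"
        "rois: [tumor]\n"
        "normalization: [none]\n")
    r = runner.invoke(main, ["simulate", "--config", str(cfg),
                             "--out", str(tmp_path / "cohort")])
    assert r.exit_code == 0, r.output
    manifest = r.output.strip()
    r = runner.invoke(main, ["extract", "--manifest", manifest, "--config", str(cfg),
                             "--out", str(tmp_path / "features.csv")])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, ["icc", "--features", str(tmp_path / "features.csv"),
                             "--out", str(tmp_path / "icc.csv")])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, ["report", "--icc", str(tmp_path / "icc.csv"),
                             "--out", str(tmp_path / "report")])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "report" / "top3_per_class.csv").exists()
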