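import numpy as np
import pytest

from honfc import (
    EvalConfig,
    EvaluationReport,
    Grids,
    compare_models,
    compute_metrics,
    concat_pipeline,
    feature_frequency,
    run_repeated_cv,
)

from _oracles import paired_t

FAST_GRIDS = Grids(lambdas=(0.3,), costs=(1.0,), alphas=(0.5,))


def fast_config(levels, mode="ensemble", **kw):
    kw.setdefault("folds", 5)
    kw.setdefault("repetitions", 2)
    kw.setdefault("inner_folds", 3)
    kw.setdefault("grids", FAST_GRIDS)
    return EvalConfig(levels=levels, mode=mode, **kw)


class TestComputeMetrics:
    def test_single_class_perfect_case(self):
        m = compute_metrics(7, 0, 0, 0)
        assert m["ACC"] == 1.0 and m["TPR"] == 1.0 and m["PPV"] == 1.0
        assert m["TNR"] is None and m["NPV"] is None

    def test_hand_computed_example(self):
        m = compute_metrics(5, 4, 1, 2)
        assert m["ACC"] == pytest.approx(0.75)
        assert m["TPR"] == pytest.approx(5 / 7)
        assert m["TNR"] == pytest.approx(0.8)
        assert m["PPV"] == pytest.approx(5 / 6)
        assert m["NPV"] == pytest.approx(2 / 3)
        ppv, tpr = 5 / 6, 5 / 7
        assert m["F1"] == pytest.approx(2 * ppv * tpr / (ppv + tpr))

    def test_class_role_swap_symmetry(self):
        a = compute_metrics(5, 4, 1, 2)
        b = compute_metrics(4, 5, 2, 1)
        assert a["ACC"] == b["ACC"]
        assert a["TPR"] == b["TNR"] and a["TNR"] == b["TPR"]
        assert a["PPV"] == b["NPV"] and a["NPV"] == b["PPV"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_metrics(-1, 2, 3, 4)


class TestRunRepeatedCV:
    def test_determinism_same_seed_identical_report(
            self, small_cohort_features):
        cfg = fast_config((0, 1), base_seed=5)
        r1 = run_repeated_cv(small_cohort_features, cfg)
        r2 = run_repeated_cv(small_cohort_features, cfg)
        assert r1.to_json() == r2.to_json()

    def test_folds_partition_cohort_and_are_stratified(
            self, small_cohort_features):
        cfg = fast_config((0,), base_seed=1)
        report = run_repeated_cv(small_cohort_features, cfg)
        ids = report.subject_ids
        labels = dict(zip(ids, small_cohort_features[0].labels))
        pos_ratio = np.mean(small_cohort_features[0].labels == 1)
        for rep in range(cfg.repetitions):
            test_sets = [rec.test_ids for rec in report.per_fold
                         if rec.repetition == rep]
            flat = [sid for fold in test_sets for sid in fold]
            assert sorted(flat) == sorted(ids)  # disjoint + exhaustive
            for fold in test_sets:
                n_pos = sum(labels[s] == 1 for s in fold)
                assert abs(n_pos - pos_ratio * len(fold)) <= 1.0

    def test_ceiling_accuracy_with_huge_planted_effect(self):
        from conftest import make_cohort_features
        from honfc.simulate import SyntheticCohortSpec

        spec = SyntheticCohortSpec(
            n_pos=15, n_neg=15, R=10, T=120, n_modules=1,
            within_module_corr=0.0,
            loworder_edges=((3, 1, 0.85), (7, 2, 0.85)),
            noise_sd=0.0, seed=2)
        sets = make_cohort_features(spec, t=0)
        cfg = fast_config((0,), repetitions=1, base_seed=0)
        report = run_repeated_cv(sets, cfg)
        assert all(rec.metrics["ACC"] == 1.0 for rec in report.per_fold)

    def test_aggregate_equals_mean_of_per_fold_metrics(
            self, small_cohort_features):
        cfg = fast_config((0,), base_seed=3)
        report = run_repeated_cv(small_cohort_features, cfg)
        for name in ("ACC", "TPR", "TNR"):
            vals = [rec.metrics[name] for rec in report.per_fold
                    if rec.metrics[name] is not None]
            assert report.aggregate[name] == pytest.approx(np.mean(vals))

    def test_too_small_cohort_reports_minimum_size(
            self, small_cohort_features):
        cfg = EvalConfig(levels=(0,), folds=25, repetitions=1,
                         grids=FAST_GRIDS)
        with pytest.raises(ValueError, match="too small"):
            run_repeated_cv(small_cohort_features, cfg)

    def test_report_json_round_trip(self, small_cohort_features):
        cfg = fast_config((0, 1), base_seed=5)
        report = run_repeated_cv(small_cohort_features, cfg)
        clone = EvaluationReport.from_dict(
            __import__("json").loads(report.to_json()))
        assert clone.to_json() == report.to_json()


class TestConcatPipeline:
    def test_single_level_is_error(self, small_cohort_features):
        with pytest.raises(ValueError, match="at least 2"):
            concat_pipeline(small_cohort_features, [0],
                            folds=5, repetitions=1, grids=FAST_GRIDS)

    def test_level_tags_map_back_to_source_level(
            self, small_cohort_features):
        report = concat_pipeline(small_cohort_features, [0, 1],
                                 folds=5, repetitions=1, base_seed=2,
                                 inner_folds=3, grids=FAST_GRIDS)
        d = small_cohort_features[0].n_features
        for rec in report.per_fold:
            for lev, edges in rec.selected_edges.items():
                assert lev in (0, 1)
                for a, b in edges:
                    assert 0 <= b < a < 16
        assert report.config["mode"] == "concat"

    def test_duplicated_level_bounds_selection_count(
            self, small_cohort_features):
        """Concatenating a level with itself cannot select more than the
        single run's count plus one extra copy of each feature."""
        from honfc.features import concat_feature_sets, lasso_select
        from honfc import ColumnScaler

        fs = small_cohort_features[0]
        dup = concat_feature_sets({0: fs, 1: fs}, [0, 1])
        # duplicated columns, identical content
        assert dup.n_features == 2 * fs.n_features

        X = ColumnScaler.fit(fs.features).transform(fs.features)
        Xd = ColumnScaler.fit(dup.features).transform(dup.features)
        y = fs.labels.astype(float)
        single = lasso_select(X, y, 5.0).n_selected
        double = lasso_select(Xd, y, 5.0).n_selected
        assert double <= single + fs.n_features


class TestCompareModels:
    def _fake_report(self, accs, fingerprint="f"):
        per_fold = [
            type("R", (), {"metrics": {"ACC": a}, "repetition": 0,
                           "fold": i})()
            for i, a in enumerate(accs)
        ]
        rep = EvaluationReport.__new__(EvaluationReport)
        rep.config = {}
        rep.per_fold = per_fold
        rep.aggregate = {}
        rep.undefined_counts = {}
        rep.partition_fingerprint = fingerprint
        rep.subject_ids = []
        return rep

    def test_self_comparison_is_degenerate_with_p_one(self):
        r = self._fake_report([0.8, 0.7, 0.9])
        res = compare_models(r, r)
        assert res.degenerate and res.p_value == 1.0

    def test_matches_textbook_paired_t(self):
        a, b = [0.8, 0.7, 0.9, 0.6], [0.6, 0.5, 0.7, 0.5]
        res = compare_models(self._fake_report(a), self._fake_report(b))
        t_exp, p_exp = paired_t(a, b)
        assert res.t_statistic == pytest.approx(t_exp, abs=1e-10)
        assert res.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_antisymmetry(self):
        a, b = [0.8, 0.7, 0.9, 0.6], [0.6, 0.5, 0.7, 0.5]
        ra, rb = self._fake_report(a), self._fake_report(b)
        fwd, rev = compare_models(ra, rb), compare_models(rb, ra)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_mismatched_partitions_rejected(self):
        ra = self._fake_report([0.8, 0.7], fingerprint="a")
        rb = self._fake_report([0.6, 0.5], fingerprint="b")
        with pytest.raises(ValueError, match="different partitions"):
            compare_models(ra, rb)


class TestFeatureFrequency:
    def test_ceiling_and_row_contract(self, small_cohort_features):
        cfg = fast_config((0,), base_seed=4)
        report = run_repeated_cv(small_cohort_features, cfg)
        tables = feature_frequency(report, top_n=10)
        table = tables[0]
        assert len(table) == 10
        n_fits = cfg.folds * cfg.repetitions
        assert table["frequency"].max() <= n_fits
        # descending frequency, lexicographic tie-break
        freqs = table["frequency"].tolist()
        assert freqs == sorted(freqs, reverse=True)

    def test_planted_edges_dominate_frequency_table(self):
        from conftest import make_cohort_features
        from honfc.simulate import SyntheticCohortSpec

        spec = SyntheticCohortSpec(
            n_pos=20, n_neg=20, R=12, T=100, n_modules=1,
            within_module_corr=0.0,
            loworder_edges=((3, 1, 0.7), (7, 2, 0.7), (10, 4, 0.7)),
            noise_sd=0.1, seed=9)
        sets = make_cohort_features(spec, t=0)
        # a penalty strong enough that only persistent signal survives
        sparse = Grids(lambdas=(15.0,), costs=(1.0,), alphas=(0.5,))
        report = run_repeated_cv(
            sets, fast_config((0,), base_seed=0, grids=sparse))
        top = feature_frequency(report, top_n=3)[0]
        top_edges = set(zip(top["roi_a"], top["roi_b"]))
        assert {(3, 1), (7, 2), (10, 4)} == top_edges
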