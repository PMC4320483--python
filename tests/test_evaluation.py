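"""Cross-validation machinery: splits, combinations, kappa, summaries."""

import numpy as np
import pandas as pd
import pytest

from modeshift import (
    ConfusionTable,
    EvalConfig,
    cohens_kappa,
    collapse_motorized,
    enumerate_splits,
    evaluate_split,
    metric_combinations,
    observation_time_share,
    observed_agreement,
    person_mode_map,
    run_crossval,
    run_sensitivity,
    summarize,
)
from modeshift.errors import ConfigError, DataError
from modeshift.features import METRIC_NAMES


def full_mode_map(n_persons=12):
    return {f"p{i:02d}": frozenset({"walk", "bike", "train", "bus", "car"})
            for i in range(1, n_persons + 1)}


class TestEnumerateSplits:
    def test_twelve_choose_four(self):
        splits = enumerate_splits(full_mode_map(12), val_size=4)
        assert len(splits) == 495
        assert all(s.valid_dev and s.valid_val for s in splits)

    def test_four_choose_two(self):
        assert len(enumerate_splits(full_mode_map(4), val_size=2)) == 6

    def test_single_carrier_mode_invalidates_dev(self):
        pm = full_mode_map(6)
        pm["p01"] = frozenset({"walk", "bike", "train", "bus", "car"})
        for p in list(pm)[1:]:
            pm[p] = frozenset({"bike", "train", "bus", "car"})  # only p01 walks
        splits = enumerate_splits(pm, val_size=2)
        for s in splits:
            assert s.valid_dev == ("p01" in s.dev_persons)
            assert s.valid_val == ("p01" in s.val_persons)

    def test_deterministic_lexicographic_order(self):
        splits = enumerate_splits(full_mode_map(5), val_size=2)
        vals = [s.val_persons for s in splits]
        assert vals == sorted(vals)

    def test_bad_val_size(self):
        with pytest.raises(ConfigError):
            enumerate_splits(full_mode_map(4), val_size=4)


class TestMetricCombinations:
    def test_counts(self):
        assert len(metric_combinations(METRIC_NAMES, 3)) == 63
        assert len(metric_combinations(METRIC_NAMES, 1)) == 7
        assert len(metric_combinations(("a", "b"), 3)) == 3


class TestCollapse:
    @pytest.mark.parametrize(
        "label,expected",
        [("train", "motorized"), ("bus", "motorized"), ("car", "motorized"),
         ("walk", "walk"), ("bike", "bike")],
    )
    def test_mapping(self, label, expected):
        assert collapse_motorized(label) == expected

    def test_never_decreases_agreement(self):
        rng = np.random.default_rng(17)
        labels = np.array(["walk", "bike", "train", "bus", "car"])
        for _ in range(50):
            true = rng.choice(labels, 40)
            pred = rng.choice(labels, 40)
            before = observed_agreement(ConfusionTable.from_labels(true, pred))
            after = observed_agreement(
                ConfusionTable.from_labels(
                    [collapse_motorized(t) for t in true],
                    [collapse_motorized(p) for p in pred],
                )
            )
            assert after >= before


class TestKappa:
    def test_perfect_diagonal(self):
        assert cohens_kappa(np.diag([5, 7, 9])) == 1.0

    def test_degenerate_single_true_class(self):
        # all validation sequences are one mode; 97% predicted as such
        counts = np.array([[97, 3], [0, 0]])
        assert cohens_kappa(counts) == 0.0
        assert observed_agreement(counts) == pytest.approx(0.97)

    def test_independence_table(self):
        assert cohens_kappa(np.array([[25, 25], [25, 25]])) == 0.0

    def test_single_cell_convention(self):
        assert cohens_kappa(np.array([[10, 0], [0, 0]])) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            cohens_kappa(np.zeros((2, 2)))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            counts = rng.integers(0, 20, (4, 4))
            counts[0, 0] += 1  # non-empty
            perm = rng.permutation(4)
            permuted = counts[np.ix_(perm, perm)]
            assert cohens_kappa(permuted) == pytest.approx(cohens_kappa(counts))

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(23)
        labels = ["walk", "bike", "bus"]
        for _ in range(25):
            true = rng.choice(labels, 60)
            pred = rng.choice(labels, 60)
            ct = ConfusionTable.from_labels(true, pred, labels)
            assert cohens_kappa(ct) == pytest.approx(
                cohen_kappa_score(true, pred, labels=labels)
            )

    def test_agreement_extremes(self):
        assert observed_agreement(np.diag([3, 3])) == 1.0
        assert observed_agreement(np.array([[0, 4], [6, 0]])) == 0.0


def toy_features():
    """Four persons, perfectly separable two-mode cohort."""
    rows = []
    rng = np.random.default_rng(29)
    for pid in ("a", "b", "c", "d"):
        for mode, level in (("walk", 4.0), ("bus", 40.0)):
            for i in range(6):
                dur = 100 if i % 2 else 20
                rows.append(
                    {
                        "person_id": pid,
                        "commute_id": "c1",
                        "mode": mode,
                        "duration_s": dur,
                        "stratum": ">60s" if dur > 60 else "16-30s",
                        "p95": level + rng.normal(0, 0.3),
                        "accel": 1.0 + rng.normal(0, 0.05),
                        "decel": -1.0 + rng.normal(0, 0.05),
                    }
                )
    return pd.DataFrame(rows)


class TestEvaluateSplit:
    def test_separable_cohort_gets_kappa_one(self):
        feats = toy_features()
        splits = enumerate_splits(person_mode_map(feats), val_size=2)
        results = evaluate_split(splits[0], ("p95",), "five_class", feats)
        assert results, "valid split must produce results"
        for r in results:
            assert r.kappa == 1.0 and r.observed_agreement == 1.0

    def test_deterministic(self):
        feats = toy_features()
        split = enumerate_splits(person_mode_map(feats), val_size=2)[1]
        a = evaluate_split(split, ("p95", "accel"), "five_class", feats)
        b = evaluate_split(split, ("p95", "accel"), "five_class", feats)
        assert a == b

    def test_stratum_rows_cover_val_sequences(self):
        feats = toy_features()
        split = enumerate_splits(person_mode_map(feats), val_size=2)[0]
        results = evaluate_split(split, ("p95",), "five_class", feats)
        strata = {r.stratum: r.n_sequences for r in results}
        assert strata["all"] == sum(v for k, v in strata.items() if k != "all")


class TestRunCrossval:
    def test_summary_median_and_superset(self):
        feats = toy_features()
        config = EvalConfig(val_size=2)
        results, summaries = run_crossval(feats, None, [("p95",)], "five_class", config)
        sens_results, _ = run_sensitivity(feats, None, [("p95",)], "five_class", config)
        assert len(sens_results) >= len(results)
        main_keys = {(r.split.val_persons, r.stratum) for r in results}
        sens_keys = {(r.split.val_persons, r.stratum) for r in sens_results}
        assert main_keys <= sens_keys
        for row in summaries:
            assert row.kappa_q25 <= row.kappa_median <= row.kappa_q75

    def test_duplicated_results_leave_medians_unchanged(self):
        feats = toy_features()
        results, summaries = run_crossval(feats, None, [("p95",)], "five_class", EvalConfig(val_size=2))
        doubled = summarize(list(results) * 2)
        by_key = {(r.combination, r.scheme, r.stratum): r for r in summaries}
        for row in doubled:
            ref = by_key[(row.combination, row.scheme, row.stratum)]
            assert row.kappa_median == ref.kappa_median
            assert row.n_splits == 2 * ref.n_splits

    def test_three_class_collapses_before_fit(self):
        feats = toy_features().replace({"bus": "train"})
        # five-class now has walk/train; three-class walk/motorized
        _, summaries = run_crossval(feats, None, [("p95",)], "three_class", EvalConfig(val_size=2))
        assert summaries and all(r.scheme == "three_class" for r in summaries)


class TestObservationTimeShare:
    def test_examples(self):
        assert observation_time_share([30, 70], 60) == pytest.approx(0.7)
        assert observation_time_share([10, 20, 60, 61], 60) == pytest.approx(61 / 151)
        assert observation_time_share([100, 200], 60) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            observation_time_share([])

    def test_accepts_feature_frame(self):
        df = pd.DataFrame({"duration_s": [30, 70]})
        assert observation_time_share(df, 60) == pytest.approx(0.7)
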