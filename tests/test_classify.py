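"""Splitting, normalization, classifiers, majority voting and grid search."""

import numpy as np
import pandas as pd
import pytest

from rwefc.classify import (
    ClassifierSpec,
    DataSplit,
    default_grid,
    evaluate,
    grid_search,
    knn,
    majority_vote,
    normalize_features,
    split_by_participant,
    svm,
    train_predict,
)


def feature_table(blobs: dict[str, tuple[float, int, int]], n_features=3, noise=0.1, seed=0):
    """Toy epoch table: per group (center, n_participants, epochs_each)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, (center, n_pp, n_ep) in blobs.items():
        for p in range(n_pp):
            pid = f"{group}{p + 1:02d}"
            for e in range(n_ep):
                vec = center + noise * rng.standard_normal(n_features)
                row = {"participant_id": pid, "group": group, "epoch_index": e}
                row.update({f"f{i + 1:03d}": vec[i] for i in range(n_features)})
                rows.append(row)
    return pd.DataFrame(rows)


def truth_of(features):
    return features[["participant_id", "group"]].drop_duplicates()


class TestNormalization:
    def test_min_max_arithmetic(self):
        train = pd.DataFrame({"f001": [2.0, 4.0, 6.0]})
        out, _ = normalize_features(train)
        np.testing.assert_allclose(out["f001"], [0.0, 0.5, 1.0])

    def test_test_set_clipped_with_train_scaler(self):
        train = pd.DataFrame({"f001": [2.0, 6.0]})
        test = pd.DataFrame({"f001": [8.0, 1.0, 4.0]})
        _, test_n, _ = normalize_features(train, test)
        np.testing.assert_allclose(test_n["f001"], [1.0, 0.0, 0.5])

    def test_constant_feature_maps_to_zero(self):
        train = pd.DataFrame({"f001": [3.0, 3.0, 3.0]})
        out, _ = normalize_features(train)
        np.testing.assert_allclose(out["f001"], 0.0)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_features(pd.DataFrame({"f001": []}))


class TestSplit:
    def _truth(self, n_hc=8, n_mci=8, n_ppa=14):
        rows = [
            {"participant_id": f"{g}{i:02d}", "group": g}
            for g, n in (("HC", n_hc), ("MCI", n_mci), ("PPA", n_ppa))
            for i in range(n)
        ]
        return pd.DataFrame(rows)

    def test_study_layout_uses_published_counts(self):
        split = split_by_participant(self._truth(), seed=0)
        truth = self._truth().set_index("participant_id")["group"]
        train_counts = truth.loc[list(split.train_participants)].value_counts()
        test_counts = truth.loc[list(split.test_participants)].value_counts()
        assert dict(train_counts) == {"HC": 6, "MCI": 5, "PPA": 10}
        assert dict(test_counts) == {"HC": 2, "MCI": 3, "PPA": 4}

    def test_deterministic_and_disjoint(self):
        s1 = split_by_participant(self._truth(), seed=7)
        s2 = split_by_participant(self._truth(), seed=7)
        assert s1 == s2
        assert not set(s1.train_participants) & set(s1.test_participants)
        assert split_by_participant(self._truth(), seed=8) != s1

    def test_generic_ratio_for_other_layouts(self):
        split = split_by_participant(self._truth(4, 4, 4), ratio=0.7, seed=0)
        assert len(split.train_participants) == 9  # round(0.7 * 4) = 3 per group
        assert len(split.test_participants) == 3

    def test_tiny_group_rejected(self):
        truth = pd.DataFrame(
            {"participant_id": ["a", "b", "c"], "group": ["HC", "HC", "MCI"]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            split_by_participant(truth)

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError, match="both"):
            DataSplit(("a", "b"), ("b", "c"))


class TestClassifiers:
    def test_knn_k1_reproduces_train_labels(self):
        features = feature_table(
            {"HC": (0.0, 3, 5), "MCI": (1.0, 3, 5)}, noise=0.05, seed=1
        )
        cols = ["f001", "f002", "f003"]
        pred_tr, _, _, _ = train_predict(knn(1, "cityblock"), features, features, cols)
        assert (pred_tr == features["group"]).all()

    def test_linear_svm_separates_clusters(self):
        features = feature_table({"HC": (0.0, 2, 4), "PPA": (2.0, 2, 4)}, noise=0.05)
        cols = ["f001", "f002", "f003"]
        test = feature_table({"HC": (0.0, 2, 4), "PPA": (2.0, 2, 4)}, noise=0.05, seed=9)
        _, pred_te, _, _ = train_predict(svm("linear"), features, test, cols)
        assert (pred_te == test["group"]).all()

    def test_knn3_matches_exhaustive_neighbor_search(self):
        # hand-built 5-point instance in 1-D, cityblock distance
        train = pd.DataFrame(
            {
                "participant_id": list("abcde"),
                "group": ["HC", "HC", "MCI", "MCI", "MCI"],
                "f001": [0.0, 1.0, 3.0, 4.0, 5.0],
            }
        )
        test = pd.DataFrame({"participant_id": ["q"], "group": ["HC"], "f001": [1.8]})
        _, pred_te, _, _ = train_predict(knn(3, "cityblock"), train, test, ["f001"])
        # distances from 1.8: (1.8, 0.8, 1.2, 2.2, 3.2); 3 nearest are
        # 1.0 (HC), 3.0 (MCI), 0.0 (HC) -> 2-of-3 HC
        assert pred_te[0] == "HC"

    def test_k_larger_than_train_rejected(self):
        features = feature_table({"HC": (0.0, 2, 2), "MCI": (1.0, 2, 2)})
        with pytest.raises(ValueError, match="exceeds"):
            train_predict(knn(101, "euclidean"), features, features, ["f001"])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="knn", k=0, metric="cityblock")
        with pytest.raises(ValueError):
            ClassifierSpec(family="svm", kernel="sigmoid")
        with pytest.raises(ValueError):
            ClassifierSpec(family="forest")

    def test_default_grid_composition(self):
        grid = default_grid()
        assert len(grid) == 23
        assert sum(1 for s in grid if s.family == "knn") == 9
        assert sum(1 for s in grid if s.kernel == "rbf") == 8


class TestMajorityVote:
    def test_simple_majority(self):
        labels, tallies, ties = majority_vote(
            np.array(["p", "p", "p"]), np.array(["PPA", "PPA", "MCI"])
        )
        assert labels == {"p": "PPA"}
        assert tallies["p"] == {"MCI": 1, "PPA": 2}
        assert not ties

    def test_singleton(self):
        labels, _, _ = majority_vote(np.array(["p"]), np.array(["HC"]))
        assert labels == {"p": "HC"}

    def test_tie_broken_by_mean_score(self):
        pids = np.array(["p", "p"])
        preds = np.array(["HC", "MCI"])
        scores = np.array([[0.4, 0.6], [0.45, 0.55]])  # MCI scores higher on average
        labels, _, ties = majority_vote(pids, preds, scores, classes=["HC", "MCI"])
        assert labels == {"p": "MCI"}
        assert ties == {"p"}

    def test_tie_without_scores_uses_canonical_order(self):
        labels, _, ties = majority_vote(np.array(["p", "p"]), np.array(["MCI", "HC"]))
        assert labels == {"p": "HC"}  # HC < MCI < PPA
        assert ties == {"p"}


class TestEvaluate:
    def test_perfect_separation(self):
        features = feature_table({"HC": (0.0, 4, 6), "MCI": (1.0, 4, 6)}, noise=0.02)
        split = split_by_participant(truth_of(features), seed=0)
        report = evaluate(features, split, knn(1, "cityblock"), "hc-mci")
        assert report.epoch_accuracy == {"train": 100.0, "test": 100.0}
        assert report.participant_accuracy == {"train": 100.0, "test": 100.0}
        cm = np.array(report.confusion_epoch["test"])
        assert cm[0, 1] == 0 and cm[1, 0] == 0

    def test_no_epoch_leakage_across_split(self):
        features = feature_table({"HC": (0.0, 4, 6), "MCI": (1.0, 4, 6)})
        split = split_by_participant(truth_of(features), seed=3)
        test_pids = set(split.test_participants)
        report = evaluate(features, split, knn(1, "cityblock"), "hc-mci")
        assert set(report.votes["test"]) == test_pids
        assert set(report.votes["train"]).isdisjoint(test_pids)

    def test_participant_accuracy_consistent_with_votes(self):
        features = feature_table({"HC": (0.0, 4, 5), "MCI": (0.4, 4, 5)}, noise=0.3)
        split = split_by_participant(truth_of(features), seed=1)
        report = evaluate(features, split, knn(3, "euclidean"), "hc-mci")
        recomputed = []
        for pid, counts in report.votes["test"].items():
            vote = max(sorted(counts), key=lambda c: counts[c])
            recomputed.append(vote == ("HC" if pid.startswith("HC") else "MCI"))
        if not report.tied_participants["test"]:
            assert report.participant_accuracy["test"] == pytest.approx(
                100.0 * np.mean(recomputed)
            )

    def test_votes_can_beat_epoch_accuracy(self):
        # 3 test participants, each barely majority-correct: participant level
        # reaches 100% while epoch level stays near 50%
        rows = []
        for p, group in enumerate(["HC", "HC", "MCI"]):
            other = "MCI" if group == "HC" else "HC"
            center = {"HC": 0.0, "MCI": 1.0}
            values = [center[group]] * 3 + [center[other]] * 2  # 3-2 split of 5 epochs
            for e, v in enumerate(values):
                rows.append(
                    {
                        "participant_id": f"T{p}",
                        "group": group,
                        "epoch_index": e,
                        "f001": v,
                    }
                )
        test = pd.DataFrame(rows)
        train = feature_table({"HC": (0.0, 2, 4), "MCI": (1.0, 2, 4)}, n_features=1, noise=0.01)
        features = pd.concat([train, test], ignore_index=True)
        split = DataSplit(
            tuple(train["participant_id"].unique()), tuple(test["participant_id"].unique())
        )
        report = evaluate(features, split, knn(1, "cityblock"), "hc-mci")
        assert report.participant_accuracy["test"] == 100.0
        assert report.epoch_accuracy["test"] == pytest.approx(100.0 * 9 / 15)

    def test_unknown_comparison_rejected(self):
        features = feature_table({"HC": (0.0, 2, 2), "MCI": (1.0, 2, 2)})
        split = split_by_participant(truth_of(features))
        with pytest.raises(ValueError, match="unknown comparison"):
            evaluate(features, split, knn(1, "cityblock"), "hc-vs-all")


class TestGridSearch:
    def test_single_spec_grid(self):
        features = feature_table({"HC": (0.0, 3, 4), "MCI": (1.0, 3, 4)})
        split = split_by_participant(truth_of(features), seed=0)
        results = grid_search(features, split, "hc-mci", grid=[svm("linear")])
        assert len(results) == 1
        assert results[0][0].kernel == "linear"

    def test_perfect_spec_ranked_first(self):
        features = feature_table({"HC": (0.0, 3, 6), "PPA": (1.0, 3, 6)}, noise=0.02)
        split = split_by_participant(truth_of(features), seed=0)
        # k=12 on 24 separable train epochs is chance-ish; k=1 is perfect
        results = grid_search(
            features, split, "hc-ppa", grid=[knn(12, "euclidean"), knn(1, "cityblock")]
        )
        assert results[0][0].k == 1

    def test_deterministic_ranking(self):
        features = feature_table({"HC": (0.0, 3, 5), "MCI": (0.5, 3, 5)}, noise=0.4)
        split = split_by_participant(truth_of(features), seed=2)
        r1 = grid_search(features, split, "hc-mci")
        r2 = grid_search(features, split, "hc-mci")
        assert [s.label() for s, _ in r1] == [s.label() for s, _ in r2]

    def test_infeasible_specs_skipped(self):
        features = feature_table({"HC": (0.0, 3, 3), "MCI": (1.0, 3, 3)})
        split = split_by_participant(truth_of(features), seed=0)
        results = grid_search(
            features, split, "hc-mci", grid=[knn(101, "cityblock"), knn(1, "cityblock")]
        )
        assert [s.k for s, _ in results] == [1]
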