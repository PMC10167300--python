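"""DRB345 copy-number classifier, Hand & Till AUC, similarity, filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hlacomposite.drb_copynumber import (
    CopyNumberVector,
    compute_ratio_features,
    copy_number_similarity,
    evaluate_holdout,
    filter_genotype_by_copy_number,
    hand_till_auc,
    predict_copy_numbers,
    train_copy_number_model,
)
from hlacomposite.hla_model import LocusGenotype


def brute_force_hand_till(scores, labels):
    """Independent oracle: explicit pairwise comparison counting, no ranks."""
    classes = sorted(set(labels))
    col = {c: i for i, c in enumerate(classes)}

    def pair_auc(pos_idx, neg_idx, column):
        total = 0.0
        for i in pos_idx:
            for j in neg_idx:
                if scores[i][column] > scores[j][column]:
                    total += 1.0
                elif scores[i][column] == scores[j][column]:
                    total += 0.5
        return total / (len(pos_idx) * len(neg_idx))

    pairs = list(itertools.combinations(classes, 2))
    acc = 0.0
    for ci, cj in pairs:
        idx_i = [k for k, y in enumerate(labels) if y == ci]
        idx_j = [k for k, y in enumerate(labels) if y == cj]
        a_ij = pair_auc(idx_i, idx_j, col[ci])
        a_ji = pair_auc(idx_j, idx_i, col[cj])
        acc += (a_ij + a_ji) / 2
    return acc / len(pairs)


class TestHandTill:
    def test_perfect_separation(self):
        scores = np.eye(3)[[0, 0, 1, 1, 2, 2]]
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert hand_till_auc(scores, labels, classes=[0, 1, 2]) == 1.0

    def test_uninformative_scores(self):
        scores = np.full((6, 3), 1 / 3)
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert hand_till_auc(scores, labels, classes=[0, 1, 2]) == 0.5

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            hand_till_auc(np.ones((3, 2)), np.zeros(3), classes=[0, 1])

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            labels = rng.integers(0, 3, size=n)
            while len(np.unique(labels)) < 2:
                labels = rng.integers(0, 3, size=n)
            raw = rng.random((n, 3))
            scores = raw / raw.sum(axis=1, keepdims=True)
            present = sorted(np.unique(labels))
            sub = scores[:, present]
            ours = hand_till_auc(sub, labels, classes=present)
            assert ours == pytest.approx(brute_force_hand_till(sub.tolist(), labels.tolist()))

    def test_matches_sklearn_ovo_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        labels = rng.integers(0, 3, size=60)
        raw = rng.random((60, 3)) + np.eye(3)[labels]  # informative but noisy
        scores = raw / raw.sum(axis=1, keepdims=True)
        ours = hand_till_auc(scores, labels, classes=[0, 1, 2])
        ref = roc_auc_score(labels, scores, multi_class="ovo", average="macro")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_reduces_to_binary_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=40)
        p1 = rng.random(40)
        scores = np.column_stack([1 - p1, p1])
        ours = hand_till_auc(scores, labels, classes=[0, 1])
        assert ours == pytest.approx(roc_auc_score(labels, p1))

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, size=30)
        scores = rng.random((30, 3))
        a = hand_till_auc(scores, labels, classes=[0, 1, 2])
        b = hand_till_auc(np.exp(3 * scores), labels, classes=[0, 1, 2])
        assert a == pytest.approx(b)


class TestSimilarity:
    def test_identical_vectors(self):
        v = CopyNumberVector(1, 0, 1)
        assert copy_number_similarity(v, v) == 1.0

    def test_maximum_distance_is_six(self):
        assert copy_number_similarity(
            CopyNumberVector(0, 0, 0), CopyNumberVector(2, 2, 2)
        ) == 0.0

    def test_single_step(self):
        assert copy_number_similarity(
            CopyNumberVector(1, 0, 2), CopyNumberVector(1, 1, 2)
        ) == pytest.approx(1 - 1 / 6)

    def test_symmetric_and_identity_iff_equal(self):
        vs = [CopyNumberVector(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 2)]
        for u in vs:
            for w in vs:
                assert copy_number_similarity(u, w) == copy_number_similarity(w, u)
                assert (copy_number_similarity(u, w) == 1.0) == (u == w)

    def test_validity_flag(self):
        assert not CopyNumberVector(2, 2, 2).is_biologically_valid
        assert CopyNumberVector(1, 1, 0).is_biologically_valid
        with pytest.raises(ValueError):
            CopyNumberVector(3, 0, 0)


class TestRatioFeatures:
    def test_simple_ratio(self):
        df = pd.DataFrame(
            {"sample_id": ["s1"] * 2, "locus": ["DRB1", "DRB3"], "reads": [100, 50]}
        )
        feats = compute_ratio_features(df)
        assert feats.loc["s1", "ratio_drb3"] == 0.5
        assert feats.loc["s1", "ratio_drb4"] == 0.0  # missing paralog = 0 reads
        assert bool(feats.loc["s1", "callable"])

    def test_zero_drb1_flagged_uncallable(self):
        df = pd.DataFrame(
            {"sample_id": ["s1"] * 2, "locus": ["DRB1", "DRB3"], "reads": [0, 50]}
        )
        feats = compute_ratio_features(df)
        assert not bool(feats.loc["s1", "callable"])
        assert np.isnan(feats.loc["s1", "ratio_drb3"])


def _separable_cohort(n=300, seed=0, sigma=0.02):
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i in range(n):
        sid = f"s{i:03d}"
        cn = {p: int(c) for p, c in zip(("drb3", "drb4", "drb5"), rng.integers(0, 3, 3))}
        rows.append({"sample_id": sid, "locus": "DRB1", "reads": 1000})
        for locus, key in (("DRB3", "drb3"), ("DRB4", "drb4"), ("DRB5", "drb5")):
            ratio = max(0.0, cn[key] * 0.5 + rng.normal(0, sigma))
            rows.append({"sample_id": sid, "locus": locus, "reads": int(ratio * 1000)})
        truth_rows.append({"sample_id": sid, **cn})
    return (
        pd.DataFrame(rows),
        pd.DataFrame(truth_rows).set_index("sample_id"),
    )


class TestKnnModel:
    def test_separated_classes_classify_perfectly(self):
        reads, truth = _separable_cohort(n=200, seed=1, sigma=0.02)
        feats = compute_ratio_features(reads)
        model = train_copy_number_model(feats, truth, seed=1)
        holdout = feats.loc[model.holdout_samples]
        preds, scores = predict_copy_numbers(model, holdout)
        for key in ("drb3", "drb4", "drb5"):
            assert (preds[key] == truth.loc[preds.index, key]).all()
        for paralog, frame in scores.items():
            assert np.allclose(frame.sum(axis=1), 1.0)

    def test_full_train_fraction_rejected(self):
        reads, truth = _separable_cohort(n=40, seed=2)
        feats = compute_ratio_features(reads)
        with pytest.raises(ValueError):
            train_copy_number_model(feats, truth, train_fraction=1.0)

    def test_tie_broken_toward_lower_copy_number(self):
        # training points straddle the query symmetrically: 2 votes each for
        # 0 and 1 copies at k=4 -> predict the lower class
        from sklearn.neighbors import KNeighborsClassifier

        from hlacomposite.drb_copynumber import CopyNumberModel

        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        est = KNeighborsClassifier(n_neighbors=4).fit(X, y)
        model = CopyNumberModel(mode="per-paralog", estimators={
            "DRB3": est, "DRB4": est, "DRB5": est,
        })
        feats = pd.DataFrame(
            {"ratio_drb3": [0.5], "ratio_drb4": [0.5], "ratio_drb5": [0.5],
             "callable": [True]},
            index=["q"],
        )
        preds, scores = predict_copy_numbers(model, feats)
        assert preds.loc["q", "drb3"] == 0
        assert scores["DRB3"].loc["q", 0] == scores["DRB3"].loc["q", 1] == 0.5

    def test_uncallable_samples_emit_no_prediction(self):
        reads, truth = _separable_cohort(n=60, seed=3)
        reads.loc[(reads.sample_id == "s000") & (reads.locus == "DRB1"), "reads"] = 0
        feats = compute_ratio_features(reads)
        model = train_copy_number_model(feats, truth, seed=3)
        preds, _ = predict_copy_numbers(model, feats)
        assert "s000" not in preds.index

    def test_parameter_recovery_auc(self):
        """Class-conditional ratio means {0, 0.45, 0.9}, sigma 0.05:
        holdout Hand & Till AUC >= 0.95 on a 300-sample cohort."""
        from hlacomposite.synthetic import SimulationConfig, simulate_cohort, simulate_read_counts

        config = SimulationConfig(seed=123, n_samples=300)
        _, copy_numbers = simulate_cohort(config)
        reads = simulate_read_counts(copy_numbers, config)
        feats = compute_ratio_features(reads)
        model = train_copy_number_model(feats, copy_numbers, seed=123)
        ev = evaluate_holdout(model, feats, copy_numbers)
        aucs = [a for a in ev["auc"].values() if not np.isnan(a)]
        assert aucs and all(a >= 0.95 for a in aucs)
        assert ev["mean_similarity"] >= 0.9


class TestFilter:
    def test_zero_copies_empties_the_call(self, gt):
        calls = {"DRB3": gt("DRB3", "DRB3*01:01", "DRB3*02:02", ranked=True)}
        out = filter_genotype_by_copy_number(calls, CopyNumberVector(0, 0, 0))
        assert out["DRB3"].is_empty

    def test_matching_copy_number_unchanged(self, gt):
        g = gt("DRB4", "DRB4*01:01", "DRB4*01:03", ranked=True)
        out = filter_genotype_by_copy_number({"DRB4": g}, CopyNumberVector(0, 2, 0))
        assert out["DRB4"] == g

    def test_top_one_keeps_first_ranked(self, gt):
        g = gt("DRB5", "DRB5*01:01", "DRB5*02:02", ranked=True)
        out = filter_genotype_by_copy_number({"DRB5": g}, CopyNumberVector(0, 0, 1))
        assert [str(a) for a in out["DRB5"].alleles] == ["DRB5*01:01"]

    def test_unranked_truncation_is_an_error(self, gt):
        g = gt("DRB3", "DRB3*01:01", "DRB3*02:02")  # ranked=False
        with pytest.raises(ValueError, match="rank"):
            filter_genotype_by_copy_number({"DRB3": g}, CopyNumberVector(1, 0, 0))

    def test_missing_paralog_returns_empty(self, gt):
        out = filter_genotype_by_copy_number({}, CopyNumberVector(1, 1, 0))
        assert all(out[p].is_empty for p in ("DRB3", "DRB4", "DRB5"))
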