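import numpy as np
import pytest

from hdspeech.io import VisitRecord
from hdspeech.models import classify_loso, loso_folds, regress_loso
from hdspeech.simulate import default_cohort_spec, generate_cohort


def toy_visits(n_subjects, visits_each=1, feature_fn=None, group_fn=None, seed=0):
    rng = np.random.default_rng(seed)
    visits = []
    for s in range(n_subjects):
        group = group_fn(s) if group_fn else ("HD" if s % 2 else "CTR")
        for v in range(visits_each):
            feats = feature_fn(s, v, rng, group) if feature_fn else {"f": float(s)}
            visits.append(
                VisitRecord(
                    subject_id=f"s{s}", visit_id=f"s{s}_v{v}", group=group,
                    moca=25.0, uhdrs_functional=20.0, uhdrs_motor=5.0,
                    dysarthria=0, features=feats,
                )
            )
    return visits


class TestLosoFolds:
    def test_three_subjects_two_visits(self):
        visits = toy_visits(3, visits_each=2)
        folds = loso_folds(visits)
        assert len(folds.folds) == 3
        for train, test in folds.folds:
            assert len(test) == 2

    def test_no_subject_leakage(self):
        visits = toy_visits(8, visits_each=3)
        folds = loso_folds(visits)
        all_test = []
        for train, test in folds.folds:
            train_subj = {visits[i].subject_id for i in train}
            test_subj = {visits[i].subject_id for i in test}
            assert not train_subj & test_subj
            assert len(test_subj) == 1
            all_test.extend(test)
        assert sorted(all_test) == list(range(len(visits)))

    def test_unequal_visit_counts(self):
        visits = toy_visits(2, visits_each=1) + toy_visits(1, visits_each=4, seed=1)
        # relabel third subject to avoid id collision
        for v in visits[2:]:
            v.subject_id = "extra"
        folds = loso_folds(visits)
        sizes = sorted(len(test) for _, test in folds.folds)
        assert sizes == [1, 1, 4]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds(toy_visits(1))


class TestClassification:
    def test_separable_toy_problem_is_perfect(self):
        def feats(s, v, rng, group):
            base = 0.0 if group == "CTR" else 10.0
            return {"a": base + rng.normal(0, 0.1), "b": -base + rng.normal(0, 0.1)}

        visits = toy_visits(12, feature_fn=feats)
        report = classify_loso(visits, ["a", "b"], seed=0, n_trees=50)
        assert report.balanced_accuracy == 100.0
        assert report.auc == 1.0

    def test_default_cohort_recovers_groups(self):
        visits = generate_cohort(seed=21)
        feats = [
            "speech_to_pause_ratio", "similarity_dtw", "articulatory_rate_w_s",
            "total_pause_time_s", "total_signal_time_s", "intelligibility_dtw",
            "mean_pause_length_s", "ratio_missing_words",
        ]
        report = classify_loso(visits, feats, seed=0, n_trees=200)
        assert report.per_class_recall["HD"] >= 80.0
        assert report.auc >= 0.8
        # confusion rows sum to class visit counts
        assert report.confusion.loc["HD"].sum() == 18

    def test_deterministic_under_seed(self):
        visits = generate_cohort(seed=2)
        feats = ["speech_to_pause_ratio", "total_pause_time_s"]
        r1 = classify_loso(visits, feats, seed=7, n_trees=50)
        r2 = classify_loso(visits, feats, seed=7, n_trees=50)
        assert r1.auc == r2.auc
        assert r1.per_class_recall == r2.per_class_recall

    def test_permuted_labels_near_chance(self):
        visits = generate_cohort(seed=3)
        feats = ["speech_to_pause_ratio", "total_pause_time_s", "similarity_dtw"]
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            groups = [v.group for v in visits]
            # permute at the subject level to keep visits consistent
            subjects = sorted({v.subject_id for v in visits})
            perm = dict(zip(subjects, rng.permutation([
                next(v.group for v in visits if v.subject_id == s) for s in subjects
            ])))
            permuted = [
                VisitRecord(
                    subject_id=v.subject_id, visit_id=v.visit_id,
                    group=perm[v.subject_id], moca=v.moca,
                    uhdrs_functional=v.uhdrs_functional, uhdrs_motor=v.uhdrs_motor,
                    dysarthria=v.dysarthria, features=v.features,
                )
                for v in visits
            ]
            aucs.append(classify_loso(permuted, feats, seed=0, n_trees=50).auc)
        assert 0.3 <= float(np.mean(aucs)) <= 0.7

    def test_dysarthria_labels_supported(self):
        visits = generate_cohort(seed=4)
        feats = ["total_signal_time_s", "mean_pause_length_s"]
        report = classify_loso(visits, feats, label_field="dysarthria", seed=0,
                               n_trees=50)
        assert set(report.classes) <= {0, 1, 2}
        assert 0.0 <= report.auc <= 1.0


class TestRegression:
    def test_noiseless_target_recovered(self):
        def feats(s, v, rng, group):
            return {"x": float(s) + rng.normal(0, 0.01)}

        visits = toy_visits(30, feature_fn=feats)
        for v in visits:
            v.uhdrs_motor = v.features["x"]
        report = regress_loso(visits, ["x"], target="uhdrs_motor", seed=0, n_trees=100)
        assert report.explained_variance >= 0.95

    def test_independent_target_not_explained(self):
        rng = np.random.default_rng(5)

        def feats(s, v, r, group):
            return {"x": float(r.normal()), "y": float(r.normal())}

        visits = toy_visits(36, feature_fn=feats, seed=5)
        for v in visits:
            v.uhdrs_motor = float(rng.normal(50, 10))
        report = regress_loso(visits, ["x", "y"], target="uhdrs_motor", seed=0,
                              n_trees=100)
        assert report.explained_variance <= 0.1

    def test_mean_prediction_zero_explained_variance(self):
        # definition check: residual variance equal to target variance
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        ev = 1 - np.var(y - yhat) / np.var(y)
        assert ev == 0.0

    def test_importances_rank_planted_signal_first(self):
        def feats(s, v, rng, group):
            signal = float(s)
            return {
                "signal": signal + rng.normal(0, 0.1),
                "n1": float(rng.normal()),
                "n2": float(rng.normal()),
            }

        visits = toy_visits(25, feature_fn=feats, seed=9)
        for v in visits:
            v.uhdrs_motor = v.features["signal"]
        report = regress_loso(visits, ["signal", "n1", "n2"], target="uhdrs_motor",
                              seed=0, n_trees=100)
        imp = report.feature_importances
        assert imp.idxmax() == "signal"
        assert imp.sum() == pytest.approx(1.0, abs=1e-6)
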