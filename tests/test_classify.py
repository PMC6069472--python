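"""Stream classifiers, majority voting, LOSO evaluation, AUC, subgroups."""

import itertools

import numpy as np
import pytest

from painface import classify, pipeline, synthetic
from painface.classify import majority_vote, roc_auc, subgroup_filter
from painface.data import PainInstance, SubjectRecord
from oracles import pair_count_auc


def _toy_stream(rng, n_per=12, sep=8.0, d=20):
    X = rng.normal(size=(2 * n_per, d))
    X[:n_per, 0] += sep
    labels = ["pain"] * n_per + ["no_pain"] * n_per
    return X, labels


# --- single-stream classifier ---------------------------------------------

def test_separable_toy_reaches_perfect_training_accuracy(rng):
    X, labels = _toy_stream(rng)
    clf = classify.train_stream(X, labels, stream="toy")
    pred, conf = clf.predict(X)
    assert pred == labels
    assert np.all(conf >= 0)


def test_training_is_deterministic(rng):
    X, labels = _toy_stream(rng)
    s1 = classify.train_stream(X, labels).decision_scores(X)
    s2 = classify.train_stream(X, labels).decision_scores(X)
    np.testing.assert_array_equal(s1, s2)


def test_label_flip_negates_decision_scores(rng):
    X, labels = _toy_stream(rng)
    flipped = ["no_pain" if l == "pain" else "pain" for l in labels]
    s1 = classify.train_stream(X, labels).decision_scores(X)
    s2 = classify.train_stream(X, flipped).decision_scores(X)
    # agreement is limited by the SVM solver's convergence tolerance
    np.testing.assert_allclose(s1, -s2, atol=1e-2)


def test_single_class_training_rejected(rng):
    X, _ = _toy_stream(rng)
    with pytest.raises(ValueError):
        classify.train_stream(X, ["pain"] * X.shape[0])


# --- majority voting ------------------------------------------------------

def test_strict_majority_wins():
    assert majority_vote(["pain", "pain", "no_pain"], [0.1, 0.1, 9.0]) == "pain"


def test_all_three_voter_patterns_match_counting_oracle(rng):
    for votes in itertools.product(["pain", "no_pain"], repeat=3):
        confs = rng.uniform(0.1, 1.0, size=3)
        expected = "pain" if sum(v == "pain" for v in votes) >= 2 else "no_pain"
        assert majority_vote(list(votes), confs) == expected


def test_tie_goes_to_most_confident_voter():
    assert majority_vote(["pain", "no_pain"], [0.2, 0.9]) == "no_pain"
    assert majority_vote(["pain", "no_pain"], [0.9, 0.2]) == "pain"
    assert majority_vote(["pain", "no_pain", "pain", "no_pain"], [0.1, 0.2, 0.3, 0.9]) == "no_pain"


def test_majority_vote_contracts():
    with pytest.raises(ValueError):
        majority_vote([], [])
    with pytest.raises(ValueError):
        majority_vote(["pain"], [0.1, 0.2])
    assert majority_vote(["pain"], [0.0]) == "pain"


# --- ROC / AUC ------------------------------------------------------------

def test_auc_perfect_and_reversed_ranking():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], ["no_pain", "no_pain", "pain", "pain"]) == 1.0
    assert roc_auc([0.9, 0.8, 0.2, 0.1], ["no_pain", "no_pain", "pain", "pain"]) == 0.0


def test_auc_matches_pair_counting_oracle(rng):
    oracle = pair_count_auc
    scores = [0.1, 0.4, 0.35, 0.8]
    y = [0, 0, 1, 1]
    assert roc_auc(scores, y) == pytest.approx(oracle(scores, y))
    for _ in range(20):
        n = int(rng.integers(4, 30))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        assert roc_auc(scores, y) == pytest.approx(oracle(list(scores), list(y)))


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], ["pain", "pain"])


# --- subgroup filtering ---------------------------------------------------

def _instance(subject, nips=5):
    return PainInstance(subject=subject, epoch_id="T1", streams={}, nips_score=nips)


def test_preterm_cut_at_37_weeks():
    ages = [30.0, 36.9, 37.0, 40.0]
    insts = [_instance(SubjectRecord(f"S{i}", "male", a, "white")) for i, a in enumerate(ages)]
    preterm = subgroup_filter(insts, "preterm")
    assert [i.subject.gestational_age_weeks for i in preterm] == [30.0, 36.9]
    full = subgroup_filter(insts, "full_term")
    assert [i.subject.gestational_age_weeks for i in full] == [37.0, 40.0]


def test_gender_partition_and_idempotence():
    insts = [
        _instance(SubjectRecord("S0", "male", 38.0, "white")),
        _instance(SubjectRecord("S1", "female", 38.0, "black")),
        _instance(SubjectRecord("S2", "unknown", 38.0, "asian")),
    ]
    male = subgroup_filter(insts, "male")
    female = subgroup_filter(insts, "female")
    assert len(male) + len(female) == 2
    assert subgroup_filter(male, "male") == male


def test_empty_subgroup_warns():
    insts = [_instance(SubjectRecord("S0", "male", 38.0, "white"))]
    with pytest.warns(UserWarning, match="matched no instances"):
        out = subgroup_filter(insts, "asian")
    assert out == []


def test_unknown_criterion_rejected():
    with pytest.raises(ValueError):
        subgroup_filter([], "lefthanded")


# --- LOSO -----------------------------------------------------------------

@pytest.fixture(scope="module")
def geometry_instances():
    spec = synthetic.CohortSpec(
        n_subjects=5, epochs_per_subject=4, frames_per_epoch=20, render_images=False, seed=21
    )
    records = synthetic.generate_cohort(spec)
    return records, pipeline.build_instances(records, streams=("DG_DisFace", "DG_DisPose"))


def test_loso_partitions_instances_by_subject(geometry_instances):
    _, instances = geometry_instances
    result = classify.loso_evaluate(instances, streams=("DG_DisFace",))
    assert all(p is not None for p in result.predictions)
    assert len(result.predictions) == len(instances)
    assert result.skipped_subjects == []


def test_loso_never_leaks_subjects(geometry_instances, monkeypatch):
    """Every fold's training set excludes the held-out subject entirely."""
    _, instances = geometry_instances
    seen = []
    original = classify.train_fusion

    def spy(train, streams, config=None, side="whole"):
        seen.append({i.subject.subject_id for i in train})
        return original(train, streams, config=config, side=side)

    monkeypatch.setattr(classify, "train_fusion", spy)
    classify.loso_evaluate(instances, streams=("DG_DisFace",))
    subjects = {i.subject.subject_id for i in instances}
    assert len(seen) == len(subjects)
    for train_subjects in seen:
        assert len(subjects - train_subjects) == 1


def test_single_stream_fusion_equals_stream_prediction(geometry_instances):
    _, instances = geometry_instances
    model = classify.train_fusion(instances, ("DG_DisFace",))
    X = np.stack([i.streams["DG_DisFace"] for i in instances])
    labels, conf = model.classifiers[0].predict(X)
    for i, inst in enumerate(instances):
        pred = model.predict(inst.streams)
        assert pred.label == labels[i]
        assert pred.confidences["DG_DisFace"] == pytest.approx(conf[i])


def test_loso_skips_single_class_folds():
    """With one subject holding all no-pain instances, its removal leaves a
    single-class training set only for the *other* folds."""
    rng = np.random.default_rng(0)
    subjects = [SubjectRecord(f"S{i}", "male", 38.0, "white") for i in range(3)]
    insts = []
    for i, subj in enumerate(subjects):
        for j in range(2):
            nips = 0 if i == 0 else 5  # subject 0 carries every no-pain epoch
            inst = PainInstance(
                subject=subj, epoch_id="T1" if nips else "T0",
                streams={"DG_DisFace": rng.normal(size=30)}, nips_score=nips,
            )
            insts.append(inst)
    with pytest.warns(UserWarning, match="skipped"):
        result = classify.loso_evaluate(insts, streams=("DG_DisFace",))
    assert result.skipped_subjects == ["S0"]
    assert all(p is None for p, i in zip(result.predictions, insts) if i.subject.subject_id == "S0")
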