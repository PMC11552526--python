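import numpy as np
import pytest

from bilatdot import (
    Cohort,
    DegenerateDataError,
    LabeledSample,
    RepresentationSpec,
    SimulationParams,
    ValidationError,
    final_evaluate,
    generate_cohort,
    make_split_plan,
    select_model,
    train_linear_classifier,
)
from bilatdot.model_selection import unit_ids_and_labels


def labels_of(cohort, mode):
    return unit_ids_and_labels(cohort, mode)[1]


@pytest.fixture(scope="module")
def study_cohort():
    """63 subjects, 18 positive, tiny blocks — split arithmetic fixture."""
    return generate_cohort(SimulationParams(
        n_subjects=63, n_sources=2, n_detectors=4, n_frames=16, seed=2))


class TestSplitArithmetic:
    def test_unilateral_counts_for_63_subjects(self, study_cohort):
        plan = make_split_plan(study_cohort, "unilateral", test_frac=0.2, val_frac=0.2,
                               n_splits=20, seed=0)
        n_units = len(plan.model_selection_ids) + len(plan.test_ids)
        assert n_units == 126
        assert len(plan.model_selection_ids) == 101
        assert len(plan.test_ids) == 25
        for train, val in plan.shuffle_splits:
            assert (len(train), len(val)) == (81, 20)

    def test_bilateral_counts_for_63_subjects(self, study_cohort):
        plan = make_split_plan(study_cohort, "bilateral", test_frac=0.2, val_frac=0.2,
                               n_splits=20, seed=0)
        assert len(plan.model_selection_ids) == 51
        assert len(plan.test_ids) == 12
        for train, val in plan.shuffle_splits:
            assert (len(train), len(val)) == (41, 10)

    def test_disjoint_and_covering(self, study_cohort):
        plan = make_split_plan(study_cohort, "unilateral", seed=3)
        ms, ts = set(plan.model_selection_ids), set(plan.test_ids)
        assert not ms & ts
        assert len(ms | ts) == 126
        for train, val in plan.shuffle_splits:
            assert not set(train) & set(val)
            assert set(train) | set(val) == ms

    @pytest.mark.parametrize("mode", ["unilateral", "bilateral"])
    def test_stratification_within_one_unit(self, study_cohort, mode):
        plan = make_split_plan(study_cohort, mode, seed=4)
        labels = labels_of(study_cohort, mode)
        n_units = len(plan.model_selection_ids) + len(plan.test_ids)
        pos_rate = sum(labels.values()) / n_units
        for subset in (plan.test_ids, *[v for _, v in plan.shuffle_splits]):
            n_pos = sum(labels[u] for u in subset)
            assert abs(n_pos - pos_rate * len(subset)) <= 1.0

    def test_splits_overlap_across_draws(self, study_cohort):
        plan = make_split_plan(study_cohort, "bilateral", n_splits=20, seed=5)
        vals = [set(v) for _, v in plan.shuffle_splits]
        assert any(a & b for i, a in enumerate(vals) for b in vals[i + 1:])

    def test_deterministic_in_seed(self, study_cohort):
        a = make_split_plan(study_cohort, "bilateral", seed=6)
        b = make_split_plan(study_cohort, "bilateral", seed=6)
        assert a == b
        c = make_split_plan(study_cohort, "bilateral", seed=7)
        assert a.test_ids != c.test_ids

    def test_invalid_fractions(self, study_cohort):
        with pytest.raises(ValidationError):
            make_split_plan(study_cohort, "bilateral", test_frac=0.0)

    def test_unilateral_labels_follow_laterality(self, study_cohort):
        labels = labels_of(study_cohort, "unilateral")
        for rec in study_cohort:
            for side in ("left", "right"):
                assert labels[f"{rec.subject_id}/{side}"] == int(rec.tumor_side == side)


class TestLinearClassifier:
    def test_separable_toy_ranking(self):
        samples = [LabeledSample(np.array([0.0, 0.0]), 0, "a"),
                   LabeledSample(np.array([1.0, 1.0]), 1, "b")]
        scorer = train_linear_classifier(samples, C=1.0)
        scores = scorer(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert scores[1] > scores[0]

    def test_training_auc_one_on_separable_set(self):
        from bilatdot import roc_auc
        rng = np.random.default_rng(20)
        X = np.r_[rng.normal(0, 0.1, size=(10, 3)), rng.normal(3, 0.1, size=(10, 3))]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        samples = [LabeledSample(x, int(l), str(i)) for i, (x, l) in enumerate(zip(X, y))]
        scorer = train_linear_classifier(samples, C=1.0)
        assert roc_auc(scorer(X), y).auc == 1.0

    def test_small_c_majority_pull(self):
        # contradictory duplicated points: heavy regularization follows majority
        samples = (
            [LabeledSample(np.array([1.0]), 1, f"p{i}") for i in range(3)]
            + [LabeledSample(np.array([1.0]), 0, "n0")]
            + [LabeledSample(np.array([-1.0]), 0, f"m{i}") for i in range(3)]
            + [LabeledSample(np.array([-1.0]), 1, "q0")]
        )
        scorer = train_linear_classifier(samples, C=1e-4)
        s = scorer(np.array([[1.0], [-1.0]]))
        assert s[0] > s[1]  # majority-positive location scores higher
        assert abs(s[0] - s[1]) < 1.0  # scores pulled toward equality

    def test_single_class_raises(self):
        samples = [LabeledSample(np.array([float(i)]), 1, str(i)) for i in range(4)]
        with pytest.raises(DegenerateDataError, match="single class"):
            train_linear_classifier(samples, C=1.0)

    def test_identical_features_raise(self):
        samples = [LabeledSample(np.array([2.0, 2.0]), i % 2, str(i)) for i in range(6)]
        with pytest.raises(DegenerateDataError, match="identical"):
            train_linear_classifier(samples, C=1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(12, 4))
        y = rng.integers(0, 2, size=12)
        y[:2] = [0, 1]
        samples = [LabeledSample(x, int(l), str(i)) for i, (x, l) in enumerate(zip(X, y))]
        s1 = train_linear_classifier(samples, C=1.0)(X)
        s2 = train_linear_classifier(samples, C=1.0)(X)
        np.testing.assert_array_equal(s1, s2)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SimulationParams(
        n_subjects=24, prevalence=8 / 24, n_sources=4, n_detectors=8,
        n_frames=64, seed=9))


class TestSelection:
    def test_single_candidate_returned_with_its_auc(self, cohort):
        spec = RepresentationSpec((760,), ("relative_change",), "sf")
        plan = make_split_plan(cohort, "bilateral", n_splits=5, seed=1)
        result = select_model(cohort, [spec], plan=plan, C_grid=[1.0])
        assert result.best_spec == spec
        assert result.best_C == 1.0
        assert len(result.per_spec_table) == 1
        assert 0.0 <= result.validation_auc_mean <= 1.0

    def test_candidate_order_only_affects_documented_tiebreak(self, cohort):
        specs = [RepresentationSpec((760,), ("zscore",), "sf"),
                 RepresentationSpec((830,), ("zscore",), "sf")]
        plan = make_split_plan(cohort, "bilateral", n_splits=5, seed=1)
        r1 = select_model(cohort, specs, plan=plan, C_grid=[1.0])
        r2 = select_model(cohort, specs[::-1], plan=plan, C_grid=[1.0])
        table1 = {(s, c): a for s, c, a in r1.per_spec_table}
        table2 = {(s, c): a for s, c, a in r2.per_spec_table}
        assert table1 == table2
        if len({a for a in table1.values()}) == 2:  # no tie: same winner
            assert r1.best_spec == r2.best_spec

    def test_end_to_end_determinism(self, cohort):
        spec = RepresentationSpec((760, 830), ("relative_change",), "sf")
        plan = make_split_plan(cohort, "bilateral", n_splits=5, seed=2)
        results = [select_model(cohort, [spec], plan=plan, C_grid=[0.1, 1.0]) for _ in range(2)]
        assert results[0] == results[1]
        rocs = [final_evaluate(cohort, results[0], plan) for _ in range(2)]
        assert rocs[0] == rocs[1]

    def test_mode_mismatch_rejected(self, cohort):
        spec = RepresentationSpec((760,), ("zscore",), "sf")
        plan = make_split_plan(cohort, "bilateral", n_splits=3, seed=1)
        with pytest.raises(ValidationError, match="mode"):
            select_model(cohort, [spec], plan=plan, mode="unilateral")
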